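"""Annotate a phosphopeptide's theoretical fragment ions.

Parses a modified sequence, enumerates its feasible fragment ions over the
36 peak types (b/y series, nine neutral-loss classes, charges 1-2), and
prints the singly charged backbone ladder.  The m/z values are monoisotopic;
'p'-class ions only exist for fragments that actually contain a phosphate.
"""

import phosflr as pf

peptide = pf.parse_modified_sequence("S[Phospho]TLVLHDLLK", charge=2)
print(f"peptidoform : {pf.format_modified_sequence(peptide)} (z={peptide.charge})")
print(f"precursor   : {pf.precursor_mz(peptide):.4f} Th")

ions = pf.theoretical_spectrum(peptide)
print(f"feasible fragment ions: {len(ions)} of {9 * (len(peptide.sequence) - 1) * 4}")

print("\nsingly charged backbone ladder (loss-free):")
for ion in ions:
    if ion.type.fragment_charge == 1 and ion.type.loss == "":
        print(f"  {ion.type.series}{ion.cleavage_index:<3d} {ion.mz:10.4f} Th")

print("\nphosphoric-acid loss satellites of b-ions (only where the fragment "
      "holds the phosphate):")
for ion in ions:
    if ion.type.label == "bp1":
        print(f"  b{ion.cleavage_index}-H3PO4  {ion.mz:10.4f} Th")
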
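"""Build the three DIA spectral-library flavors from an FLR-filtered run.

After target-decoy re-analysis, accepted identifications are exported as a
peptide-centric DIA library in three modes that differ only in intensity
provenance: fully predicted, hybrid (predicted only where the site was
re-localized away from the engine's call), and re-localized experimental.
Retention times always come from the experiment.
"""

from pathlib import Path

import phosflr as pf
from phosflr.synthetic_data import SimulationConfig, simulate_dataset

config = SimulationConfig(n_peptides=60, seed=11)
dataset = simulate_dataset(config)
predictor = pf.BaselinePredictor()

records, db = pf.analyze_dataset(
    dataset.spectra, dataset.identifications, predictor, method=1, seed=11
)
records = [r for r in records if not r.unscorable]
curve = pf.flr_curve(records, db.N_decoy, db.N_target)
_, _, accepted = pf.threshold_at_flr(curve, 0.01, records)
print(f"{len(accepted)} PSMs accepted at estimated FLR <= 1%")

spectra = {s.spectrum_id: s for s in dataset.spectra}
engine = {
    str(r.spectrum_id): pf.parse_modified_sequence(
        str(r.engine_modified_sequence), int(r.charge)
    )
    for r in dataset.ground_truth.itertuples()
}
# stand-in retention times; with real data these come from the DDA run
rt = {sid: 10.0 + 0.5 * i for i, sid in enumerate(spectra)}

out = Path("scratch/libraries")
out.mkdir(parents=True, exist_ok=True)
for mode in pf.LIBRARY_MODES:
    entries = pf.build_library(accepted, spectra, predictor, mode, engine, rt)
    n_relocalized = sum(
        1 for e in entries
        if e.peptidoform.mods != engine[
            max(
                (r for r in accepted
                 if not r.is_decoy
                 and pf.format_modified_sequence(r.best_candidate)
                 == pf.format_modified_sequence(e.peptidoform)),
                key=lambda r: r.best_cosine,
            ).spectrum_id
        ].mods
    )
    path = out / f"library_{mode}.tsv"
    pf.write_library(entries, path)
    print(f"{mode:26s}: {len(entries)} precursors "
          f"({n_relocalized} with a re-localized site) -> {path}")
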
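"""Peptide/modification data model and monoisotopic mass arithmetic.

A :class:`Peptidoform` is a peptide sequence plus positioned modifications and a
precursor charge -- the unit that targets, decoys, and spectral-library entries
are made of.  Modification positions are 1-based residue indices; position 0
denotes the protein N-terminus (acetylation).

Only monoisotopic masses are used: HCD/Q-TOF fragment data are monoisotopic,
and average masses have no role in spectral matching.  Cysteine is *not*
implicitly carbamidomethylated; fixed modifications must be written out
explicitly in input tables so the data model carries no hidden state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "PROTON",
    "WATER",
    "NH3",
    "H3PO4",
    "RESIDUE_MASS",
    "ModificationType",
    "MODIFICATIONS",
    "Peptidoform",
    "parse_modified_sequence",
    "format_modified_sequence",
    "peptide_neutral_mass",
    "precursor_mz",
    "PeptideError",
]

# Monoisotopic constants (Da).
PROTON = 1.007276466622
WATER = 18.010564684
NH3 = 17.026549101
H3PO4 = 97.976895575

#: Monoisotopic residue masses (amino acid minus water), Da.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146372,
    "A": 71.03711379,
    "S": 87.03202841,
    "P": 97.05276385,
    "V": 99.06841391,
    "T": 101.04767847,
    "C": 103.00918448,
    "L": 113.08406398,
    "I": 113.08406398,
    "N": 114.04292744,
    "D": 115.02694302,
    "Q": 128.05857751,
    "K": 128.09496302,
    "E": 129.04259309,
    "M": 131.04048509,
    "H": 137.05891186,
    "F": 147.06841391,
    "R": 156.10111102,
    "Y": 163.06332853,
    "W": 186.07931295,
}

MAX_PEPTIDE_LENGTH = 511  # sequences must be shorter than 512 residues


class PeptideError(ValueError):
    """Raised for malformed sequences, modifications, or positions."""


@dataclass(frozen=True)
class ModificationType:
    """A supported post-translational modification.

    ``allowed_targets`` is the residue set a *target* peptidoform may carry the
    modification on ("nterm" for protein N-terminal acetylation).  Decoy
    generation deliberately places phosphate on non-S/T/Y residues, so target
    rules are enforced only when parsing in strict mode.
    """

    name: str
    delta_mass: float
    allowed_targets: frozenset[str] | str
    neutral_loss_eligible: bool = False


MODIFICATIONS: dict[str, ModificationType] = {
    "Phospho": ModificationType("Phospho", 79.96633052, frozenset("STY"), True),
    "Oxidation": ModificationType("Oxidation", 15.99491462, frozenset("M")),
    "Carbamidomethyl": ModificationType("Carbamidomethyl", 57.02146372, frozenset("C")),
    "Acetyl": ModificationType("Acetyl", 42.01056468, "nterm"),
}

# Legacy one-token prefixes parsed for interoperability, never emitted.
_PREFIX_MODS = {"p": "Phospho", "ox": "Oxidation", "cam": "Carbamidomethyl"}

_TOKEN_RE = re.compile(r"(p|ox|cam)?([A-Z])(?:\[([A-Za-z]+)\])?")


@dataclass(frozen=True)
class Peptidoform:
    """A peptide sequence with positioned modifications and precursor charge.

    ``mods`` is a sorted tuple of ``(position, modification name)`` pairs with
    1-based positions (0 = protein N-terminus).  Instances are immutable and
    hashable so they can serve as dictionary keys for predictor caches and
    spectral libraries.
    """

    sequence: str
    mods: tuple[tuple[int, str], ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("empty sequence")
        if len(self.sequence) > MAX_PEPTIDE_LENGTH:
            raise PeptideError(
                f"sequence length {len(self.sequence)} exceeds {MAX_PEPTIDE_LENGTH}"
            )
        for aa in self.sequence:
            if aa not in RESIDUE_MASS:
                raise PeptideError(f"unknown residue symbol {aa!r}")
        if self.charge < 1:
            raise PeptideError(f"charge must be >= 1, got {self.charge}")
        object.__setattr__(self, "mods", tuple(sorted(self.mods)))
        seen: set[int] = set()
        for pos, name in self.mods:
            if name not in MODIFICATIONS:
                raise PeptideError(f"unknown modification {name!r}")
            if pos < 0 or pos > len(self.sequence):
                raise PeptideError(f"mod position {pos} outside 1..{len(self.sequence)}")
            if pos == 0 and name != "Acetyl":
                raise PeptideError(f"position 0 is reserved for Acetyl, got {name!r}")
            if pos in seen:
                raise PeptideError(f"more than one modification at position {pos}")
            seen.add(pos)

    # -- convenience views -------------------------------------------------

    @property
    def phospho_positions(self) -> tuple[int, ...]:
        return tuple(pos for pos, name in self.mods if name == "Phospho")

    @property
    def phospho_count(self) -> int:
        return len(self.phospho_positions)

    @property
    def candidate_sites(self) -> tuple[int, ...]:
        """1-based positions of S/T/Y residues (potential phosphosites)."""
        return tuple(i for i, aa in enumerate(self.sequence, 1) if aa in "STY")

    def mod_at(self, pos: int) -> str | None:
        for p, name in self.mods:
            if p == pos:
                return name
        return None

    def __str__(self) -> str:  # pragma: no cover - thin alias
        return format_modified_sequence(self)


def parse_modified_sequence(
    text: str, charge: int, strict_targets: bool = False
) -> Peptidoform:
    """Parse a modified-sequence string into a :class:`Peptidoform`.

    Two dialects are accepted: the canonical bracket dialect ``S[Phospho]``
    (with protein N-terminal acetyl written as a leading ``[Acetyl]-``) and the
    legacy prefix dialect ``pS`` / ``oxM`` / ``camC`` found in search-engine
    exports.  With ``strict_targets=True`` a phosphate on a non-S/T/Y residue
    is rejected; the default is permissive so decoy peptidoforms round-trip.
    """
    if charge < 1:
        raise PeptideError(f"charge must be >= 1, got {charge}")
    text = text.strip()
    mods: list[tuple[int, str]] = []
    if text.startswith("[Acetyl]-"):
        mods.append((0, "Acetyl"))
        text = text[len("[Acetyl]-") :]
    seq_chars: list[str] = []
    i = 0
    pos = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if not m or not m.group(2):
            raise PeptideError(f"cannot parse sequence at offset {i} in {text!r}")
        prefix, residue, bracket = m.groups()
        if prefix and bracket:
            raise PeptideError(f"both prefix and bracket modification at offset {i}")
        pos += 1
        seq_chars.append(residue)
        name = _PREFIX_MODS[prefix] if prefix else bracket
        if name:
            if name not in MODIFICATIONS:
                raise PeptideError(f"unknown modification token {name!r}")
            mods.append((pos, name))
        i = m.end()
    sequence = "".join(seq_chars)
    if strict_targets:
        for p, name in mods:
            mod = MODIFICATIONS[name]
            if mod.allowed_targets == "nterm":
                continue
            if sequence[p - 1] not in mod.allowed_targets:
                raise PeptideError(
                    f"{name} on residue {sequence[p - 1]}{p} violates target rule "
                    f"{sorted(mod.allowed_targets)}"
                )
    return Peptidoform(sequence, tuple(mods), charge)


def format_modified_sequence(p: Peptidoform) -> str:
    """Format in the canonical bracket dialect; inverse of the parser."""
    out: list[str] = []
    by_pos = dict(p.mods)
    if by_pos.get(0) == "Acetyl":
        out.append("[Acetyl]-")
    for i, aa in enumerate(p.sequence, 1):
        out.append(aa)
        name = by_pos.get(i)
        if name:
            out.append(f"[{name}]")
    return "".join(out)


def peptide_neutral_mass(p: Peptidoform) -> float:
    """Monoisotopic neutral mass: residues + water + modification deltas."""
    mass = sum(RESIDUE_MASS[aa] for aa in p.sequence) + WATER
    mass += sum(MODIFICATIONS[name].delta_mass for _, name in p.mods)
    return mass


def precursor_mz(p: Peptidoform) -> float:
    """Precursor m/z in Th: (neutral mass + z protons) / z."""
    return (peptide_neutral_mass(p) + p.charge * PROTON) / p.charge


def residue_mod_masses(p: Peptidoform) -> list[float]:
    """Per-residue mass including its modification (N-term acetyl counted on
    residue 1, where it travels with b-type fragments)."""
    masses = [RESIDUE_MASS[aa] for aa in p.sequence]
    for pos, name in p.mods:
        idx = 0 if pos == 0 else pos - 1
        masses[idx] += MODIFICATIONS[name].delta_mass
    return masses
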
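"""The 36 fragment-peak types and theoretical fragment m/z computation.

Phosphopeptide HCD spectra are annotated on a fixed grid of 36 fragment-peak
types: b and y series, nine neutral-loss classes (none, -H2O ("o"), -NH3
("n"), -H3PO4 ("p"), the pairwise combinations "op"/"np", and the double
phosphate losses "2p"/"o2p"/"n2p"), and fragment charges 1 and 2.  The
enumeration order is fixed so that intensity vectors from different sources
are comparable coordinate by coordinate.

Phospho-loss classes are feasibility-gated by the number of phosphate groups
the fragment actually contains: a fragment holding no phosphate cannot lose
H3PO4, and a single-phospho fragment cannot lose two.  Water/ammonia losses
are emitted for every fragment without residue-composition gating, keeping
target and decoy treatment symmetric.  b1 ions are emitted: with adjacent
candidate sites they are often the site-determining ions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide_core import H3PO4, NH3, PROTON, WATER, Peptidoform, residue_mod_masses

__all__ = [
    "FragmentType",
    "FragmentIon",
    "FRAGMENT_TYPES",
    "enumerate_fragment_types",
    "fragment_mz",
    "fragment_grid",
    "theoretical_spectrum",
]

#: Mass removed by each neutral-loss class, Da.
LOSS_MASS: dict[str, float] = {
    "": 0.0,
    "o": WATER,
    "n": NH3,
    "p": H3PO4,
    "op": WATER + H3PO4,
    "np": NH3 + H3PO4,
    "2p": 2 * H3PO4,
    "o2p": WATER + 2 * H3PO4,
    "n2p": NH3 + 2 * H3PO4,
}

#: Number of phosphate groups a fragment must contain for the loss class.
PHOSPHO_REQUIRED: dict[str, int] = {
    "": 0, "o": 0, "n": 0,
    "p": 1, "op": 1, "np": 1,
    "2p": 2, "o2p": 2, "n2p": 2,
}


@dataclass(frozen=True)
class FragmentType:
    """One of the 36 peak types: series (b/y), neutral-loss class, charge."""

    series: str
    loss: str
    fragment_charge: int

    @property
    def label(self) -> str:
        """Compact name, e.g. ``b1``, ``bn1``, ``yo2p2``."""
        return f"{self.series}{self.loss}{self.fragment_charge}"

    @classmethod
    def from_label(cls, label: str) -> "FragmentType":
        series, loss, charge = label[0], label[1:-1], int(label[-1])
        ft = cls(series, loss, charge)
        if ft not in _TYPE_SET:
            raise ValueError(f"unknown fragment type label {label!r}")
        return ft


def _build_types() -> tuple[FragmentType, ...]:
    types: list[FragmentType] = []
    for loss_block in (("", "n", "o"), ("p", "np", "op"), ("2p", "n2p", "o2p")):
        for series in "by":
            for charge in (1, 2):
                for loss in loss_block:
                    types.append(FragmentType(series, loss, charge))
    return tuple(types)


#: All 36 fragment types in canonical order
#: (b1, bn1, bo1, b2, bn2, bo2, y1, ..., yo2p2).
FRAGMENT_TYPES: tuple[FragmentType, ...] = _build_types()
_TYPE_SET = frozenset(FRAGMENT_TYPES)
TYPE_INDEX: dict[FragmentType, int] = {t: i for i, t in enumerate(FRAGMENT_TYPES)}


def enumerate_fragment_types() -> tuple[FragmentType, ...]:
    """Return the 36 fragment types in their fixed canonical order."""
    return FRAGMENT_TYPES


@dataclass(frozen=True)
class FragmentIon:
    """A typed fragment peak: type, cleavage index, m/z, feasibility.

    ``cleavage_index`` counts N-terminal residues for b ions and C-terminal
    residues for y ions (1-based, at most length-1).
    """

    type: FragmentType
    cleavage_index: int
    mz: float
    feasible: bool


def _prefix_arrays(p: Peptidoform) -> tuple[np.ndarray, np.ndarray, float]:
    """Cumulative residue+mod masses and cumulative phospho counts."""
    masses = np.asarray(residue_mod_masses(p))
    cum = np.cumsum(masses)
    phospho = np.zeros(len(p.sequence), dtype=int)
    for pos in p.phospho_positions:
        phospho[pos - 1] = 1
    return cum, np.cumsum(phospho), float(cum[-1])


def fragment_neutral_mass(p: Peptidoform, series: str, k: int) -> float:
    """Neutral (uncharged, loss-free) mass of the b_k or y_k fragment."""
    cum, _, total = _prefix_arrays(p)
    L = len(p.sequence)
    if not 1 <= k <= L - 1:
        raise ValueError(f"cleavage index {k} outside 1..{L - 1}")
    if series == "b":
        return float(cum[k - 1])
    if series == "y":
        return float(total - cum[L - k - 1] + WATER)
    raise ValueError(f"unknown series {series!r}")


def _fragment_phospho_count(p: Peptidoform, series: str, k: int) -> int:
    phospho = p.phospho_positions
    L = len(p.sequence)
    if series == "b":
        return sum(1 for pos in phospho if pos <= k)
    return sum(1 for pos in phospho if pos > L - k)


def fragment_mz(p: Peptidoform, f: FragmentType, k: int) -> FragmentIon:
    """Theoretical m/z of one fragment ion.

    The ion is infeasible (``feasible=False``, m/z reported as 0) when the
    fragment contains fewer phosphate groups than the loss class removes, or
    when the loss would drive the mass non-positive.
    """
    neutral = fragment_neutral_mass(p, f.series, k)
    n_phos = _fragment_phospho_count(p, f.series, k)
    if n_phos < PHOSPHO_REQUIRED[f.loss]:
        return FragmentIon(f, k, 0.0, False)
    mass = neutral - LOSS_MASS[f.loss]
    if mass <= 0:
        return FragmentIon(f, k, 0.0, False)
    mz = (mass + f.fragment_charge * PROTON) / f.fragment_charge
    return FragmentIon(f, k, mz, True)


def fragment_grid(p: Peptidoform) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized theoretical grid over (cleavage index, 36 types).

    Returns ``(mz, feasible)`` arrays of shape ``(L-1, 36)``; infeasible
    entries carry m/z 0.  This grid is the shared coordinate system for
    predicted intensities and matched experimental intensities.
    """
    cum, phospho_cum, total = _prefix_arrays(p)
    L = len(p.sequence)
    ks = np.arange(1, L)
    b_neutral = cum[:-1]
    y_neutral = total - cum[: L - 1][::-1] + WATER
    b_phos = phospho_cum[:-1]
    y_phos = phospho_cum[-1] - phospho_cum[: L - 1][::-1]

    mz = np.zeros((L - 1, len(FRAGMENT_TYPES)))
    feasible = np.zeros((L - 1, len(FRAGMENT_TYPES)), dtype=bool)
    for j, f in enumerate(FRAGMENT_TYPES):
        neutral = b_neutral if f.series == "b" else y_neutral
        nph = b_phos if f.series == "b" else y_phos
        mass = neutral - LOSS_MASS[f.loss]
        ok = (nph >= PHOSPHO_REQUIRED[f.loss]) & (mass > 0)
        mz[ok, j] = (mass[ok] + f.fragment_charge * PROTON) / f.fragment_charge
        feasible[:, j] = ok
    return mz, feasible


def theoretical_spectrum(p: Peptidoform) -> list[FragmentIon]:
    """All feasible fragment ions, ordered cleavage-index major, type minor."""
    if len(p.sequence) < 2:
        raise ValueError("need at least 2 residues to fragment")
    mz, feasible = fragment_grid(p)
    ions: list[FragmentIon] = []
    for k in range(1, len(p.sequence)):
        for j, f in enumerate(FRAGMENT_TYPES):
            if feasible[k - 1, j]:
                ions.append(FragmentIon(f, k, float(mz[k - 1, j]), True))
    return ions
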
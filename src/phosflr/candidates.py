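"""Per-spectrum candidate databases: target isoforms plus decoys.

For every identified phosphopeptide spectrum the candidate set holds all
positional phosphosite isoforms (the targets) and one decoy per
(target, phosphate).  Two decoy constructions are supported:

* **Method 1** -- swap the whole phosphorylated residue with a randomly
  chosen non-candidate (non-S/T/Y) residue; the phosphate travels with its
  residue, so the decoy is a sequence permutation of the target.
* **Method 2** -- keep the sequence and shift the phosphate itself onto a
  randomly chosen non-candidate residue, producing a phospho group on a
  non-canonical residue.

Both constructions conserve composition, so every decoy is exactly isobaric
with its parent target -- the property that lets decoy hits trace false
localizations without perturbing precursor selection.

Spectra whose peptide has no alternative site (number of candidate S/T/Y
equal to the number of phosphates) cannot be re-localized; they are excluded
from re-analysis and kept in a pass-through list.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peptide_core import (
    Peptidoform,
    PeptideError,
    parse_modified_sequence,
)

__all__ = [
    "CandidateSet",
    "CandidateDatabase",
    "DecoyGenerationError",
    "enumerate_isoforms",
    "decoy_method1",
    "decoy_method2",
    "build_candidate_database",
    "DEFAULT_COLUMN_MAP",
]

log = logging.getLogger(__name__)

MAX_PHOSPHO_DEFAULT = 2  # peptides with more phosphates are dropped by default


class DecoyGenerationError(RuntimeError):
    """No non-candidate residue is available to build a decoy."""


@dataclass
class CandidateSet:
    """All candidates competing for one spectrum."""

    spectrum_id: str
    targets: list[Peptidoform]
    decoys: list[tuple[Peptidoform, int]]  # (decoy, parent target index)
    reanalyzable: bool

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def n_decoys(self) -> int:
        return len(self.decoys)


@dataclass
class CandidateDatabase:
    """Candidate sets for a run plus the global target/decoy tallies used by
    the FLR estimator."""

    sets: list[CandidateSet]
    passthrough: list[CandidateSet] = field(default_factory=list)
    n_dropped_multiphospho: int = 0
    n_malformed: int = 0
    seed: int | None = None

    @property
    def N_target(self) -> int:
        return sum(cs.n_targets for cs in self.sets)

    @property
    def N_decoy(self) -> int:
        return sum(cs.n_decoys for cs in self.sets)


def enumerate_isoforms(p: Peptidoform) -> list[Peptidoform]:
    """All positional phosphosite isoforms of ``p``.

    One peptidoform per size-m subset of the candidate S/T/Y positions, where
    m is the phosphate count; non-phospho modifications stay in place.  The
    result has C(c, m) entries for c candidate sites, in deterministic
    subset-enumeration order.
    """
    m = p.phospho_count
    if m < 1:
        raise ValueError("not a phosphopeptide (no phospho modification)")
    sites = p.candidate_sites
    if m > len(sites):
        raise ValueError(
            f"{m} phosphates but only {len(sites)} candidate sites in {p.sequence}"
        )
    fixed = tuple((pos, name) for pos, name in p.mods if name != "Phospho")
    isoforms = []
    for subset in itertools.combinations(sites, m):
        mods = fixed + tuple((pos, "Phospho") for pos in subset)
        isoforms.append(Peptidoform(p.sequence, mods, p.charge))
    return isoforms


def _non_candidate_positions(p: Peptidoform) -> list[int]:
    return [i for i, aa in enumerate(p.sequence, 1) if aa not in "STY"]


def _swap_decoy(target: Peptidoform, i: int, j: int) -> Peptidoform:
    """Method-1 core: swap residues at 1-based positions i and j, mods
    travelling with their residues."""
    seq = list(target.sequence)
    seq[i - 1], seq[j - 1] = seq[j - 1], seq[i - 1]
    mods = []
    for pos, name in target.mods:
        if pos == i:
            mods.append((j, name))
        elif pos == j:
            mods.append((i, name))
        else:
            mods.append((pos, name))
    return Peptidoform("".join(seq), tuple(mods), target.charge)


def _shift_decoy(target: Peptidoform, i: int, j: int) -> Peptidoform:
    """Method-2 core: move the phosphate at position i to position j."""
    mods = []
    for pos, name in target.mods:
        if pos == i and name == "Phospho":
            mods.append((j, name))
        else:
            mods.append((pos, name))
    return Peptidoform(target.sequence, tuple(mods), target.charge)


def _draw_decoys(target, rng, build, avoid, preserve_cterm):
    non_cand = _non_candidate_positions(target)
    if preserve_cterm and len(non_cand) > 1:
        non_cand = [j for j in non_cand if j != len(target.sequence)]
    # method 2 additionally must not stack a phosphate on an occupied position
    decoys = []
    avoid_set = {(d.sequence, d.mods) for d in avoid}
    for i in target.phospho_positions:
        choices = [j for j in non_cand if target.mod_at(j) is None or build is _swap_decoy]
        if not choices:
            raise DecoyGenerationError(
                f"no non-candidate residue available in {target.sequence}"
            )
        decoy = None
        for _ in range(len(choices)):
            j = int(rng.choice(choices))
            decoy = build(target, i, j)
            if (decoy.sequence, decoy.mods) not in avoid_set:
                break
        else:
            log.warning(
                "decoy for %s collides with an existing candidate after "
                "%d redraws; accepting as-is",
                target.sequence,
                len(choices),
            )
        decoys.append(decoy)
        avoid_set.add((decoy.sequence, decoy.mods))
    return decoys


def decoy_method1(
    target: Peptidoform,
    rng: np.random.Generator,
    avoid: tuple[Peptidoform, ...] = (),
    preserve_cterm: bool = False,
) -> list[Peptidoform]:
    """One residue-exchange decoy per phosphorylated residue of ``target``.

    Draws that reproduce a peptidoform in ``avoid`` (e.g. the target isoforms
    or earlier decoys) are re-drawn up to the number of available positions,
    then accepted with a warning.  ``preserve_cterm=True`` excludes the
    C-terminal residue from swapping for users worried about tryptic realism.
    """
    return _draw_decoys(target, rng, _swap_decoy, avoid, preserve_cterm)


def decoy_method2(
    target: Peptidoform,
    rng: np.random.Generator,
    avoid: tuple[Peptidoform, ...] = (),
    preserve_cterm: bool = False,
) -> list[Peptidoform]:
    """One phosphate-shift decoy per phosphorylated residue (sequence kept)."""
    return _draw_decoys(target, rng, _shift_decoy, avoid, preserve_cterm)


#: Canonical column names and accepted aliases in search-result tables.
DEFAULT_COLUMN_MAP: dict[str, tuple[str, ...]] = {
    "spectrum_id": ("spectrum_id", "Spectrum", "Title", "MS/MS scan number"),
    "sequence": ("sequence", "Sequence", "Peptide"),
    "modified_sequence": (
        "modified_sequence",
        "Modified sequence",
        "EG.ModifiedPeptide",
    ),
    "charge": ("charge", "Charge", "FG.Charge", "z"),
    "localization_probability": (
        "localization_probability",
        "Localization prob",
        "PTM.SiteProbability",
        "AScore",
    ),
}


def _resolve_columns(df: pd.DataFrame, column_map) -> dict[str, str]:
    resolved = {}
    for canonical, aliases in column_map.items():
        for alias in aliases:
            if alias in df.columns:
                resolved[canonical] = alias
                break
        else:
            if canonical != "sequence":  # derivable from modified_sequence
                raise ValueError(f"missing required column for {canonical!r}")
    return resolved


def build_candidate_database(
    identifications,
    method: int = 1,
    seed: int = 0,
    max_phospho: int = MAX_PHOSPHO_DEFAULT,
    column_map: dict[str, tuple[str, ...]] | None = None,
    preserve_cterm: bool = False,
) -> CandidateDatabase:
    """Build target isoforms and decoys for every row of a search-result table.

    ``identifications`` is a DataFrame or the path to a tab-separated table
    with (aliases of) columns spectrum_id, modified_sequence, charge,
    localization_probability.  Rows with more than ``max_phospho`` phosphates
    (default 2: higher multiplicities are rarely observed) are dropped with a
    logged count; rows without an alternative candidate site go to the
    pass-through list.  Decoys are generated for every target isoform, so a
    spectrum with c candidate sites and m phosphates contributes C(c, m)
    targets and m x C(c, m) decoys.  A fixed ``seed`` makes the database
    byte-identical across runs.
    """
    if method not in (1, 2):
        raise ValueError(f"decoy method must be 1 or 2, got {method}")
    if isinstance(identifications, (str, bytes)) or hasattr(identifications, "__fspath__"):
        identifications = pd.read_csv(identifications, sep="\t", comment="#")
    cols = _resolve_columns(identifications, column_map or DEFAULT_COLUMN_MAP)
    rng = np.random.default_rng(seed)
    gen = decoy_method1 if method == 1 else decoy_method2

    sets: list[CandidateSet] = []
    passthrough: list[CandidateSet] = []
    dropped = 0
    malformed = 0
    for row_number, row in enumerate(identifications.itertuples(index=False)):
        rowd = row._asdict() if hasattr(row, "_asdict") else dict(row)
        try:
            reported = parse_modified_sequence(
                str(rowd[cols["modified_sequence"]]), int(rowd[cols["charge"]])
            )
            if reported.phospho_count < 1:
                raise PeptideError("row is not a phosphopeptide")
        except (PeptideError, KeyError, ValueError) as exc:
            log.warning("malformed identification row %d: %s", row_number, exc)
            malformed += 1
            continue
        sid = str(rowd[cols["spectrum_id"]])
        if reported.phospho_count > max_phospho:
            dropped += 1
            continue
        reanalyzable = len(reported.candidate_sites) > reported.phospho_count
        if not reanalyzable:
            passthrough.append(CandidateSet(sid, [reported], [], False))
            continue
        targets = enumerate_isoforms(reported)
        decoys: list[tuple[Peptidoform, int]] = []
        avoid: list[Peptidoform] = list(targets)
        try:
            for ti, target in enumerate(targets):
                for decoy in gen(target, rng, avoid=tuple(avoid), preserve_cterm=preserve_cterm):
                    decoys.append((decoy, ti))
                    avoid.append(decoy)
        except DecoyGenerationError as exc:
            log.warning("spectrum %s excluded from re-analysis: %s", sid, exc)
            passthrough.append(CandidateSet(sid, [reported], [], False))
            continue
        sets.append(CandidateSet(sid, targets, decoys, True))
    if dropped:
        log.info("dropped %d rows with > %d phosphates", dropped, max_phospho)
    db = CandidateDatabase(
        sets=sets,
        passthrough=passthrough,
        n_dropped_multiphospho=dropped,
        n_malformed=malformed,
        seed=seed,
    )
    if not db.sets and not db.passthrough:
        raise ValueError("empty candidate database: no parsable identifications")
    return db
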
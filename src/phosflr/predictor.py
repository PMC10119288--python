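"""Pluggable spectrum predictors for target/decoy scoring.

The FLR machinery is predictor-agnostic: anything exposing
``predict(peptidoform) -> PredictedSpectrum`` with non-negative intensities
on the 36-type fragment grid (infeasible ions zero) can drive it.  Two
implementations ship here:

* :class:`BaselinePredictor` -- a deterministic rule-based model of HCD
  phosphopeptide fragmentation: unimodal b/y intensity profiles over the
  cleavage index, neutral-loss satellites as fixed fractions of the parent
  ion (phosphoric-acid loss strong for phospho-S/T, weak for phospho-Y),
  charge-2 ions attenuated.  It distinguishes positional isoforms through
  both fragment masses and loss eligibility.
* :class:`LibraryPredictor` -- exact lookup in a spectral library table, for
  plugging in externally predicted or experimental spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Protocol, runtime_checkable

import numpy as np
import pandas as pd

from .fragmentation import FRAGMENT_TYPES, FragmentType, fragment_grid
from .peptide_core import Peptidoform, format_modified_sequence, precursor_mz

__all__ = [
    "PredictedSpectrum",
    "SpectrumPredictor",
    "BaselinePredictor",
    "BaselineConfig",
    "SpectralLibraryEntry",
    "LibraryPredictor",
    "LibraryMiss",
    "read_library",
    "write_library",
]


@dataclass(frozen=True)
class PredictedSpectrum:
    """Predicted fragment intensities on the (cleavage index x 36 type) grid.

    ``mz`` and ``intensity`` are flattened parallel arrays over the full grid
    (cleavage-index major); infeasible coordinates have m/z 0 and intensity 0.
    """

    peptidoform: Peptidoform
    mz: np.ndarray
    intensity: np.ndarray

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (len(self.peptidoform.sequence) - 1, len(FRAGMENT_TYPES))


@runtime_checkable
class SpectrumPredictor(Protocol):
    """Contract every predictor must satisfy."""

    name: str
    deterministic: bool

    def predict(self, p: Peptidoform) -> PredictedSpectrum: ...


@dataclass(frozen=True)
class BaselineConfig:
    """Constants of the rule-based predictor (all relative intensities).

    ``phospho_loss_frac_st`` applies when the fragment carries phosphate on a
    residue other than tyrosine (serine/threonine, and the non-canonical
    residues decoys phosphorylate, which are treated as equally labile);
    ``phospho_loss_frac_y`` when only phospho-tyrosine is present.  Combined
    losses multiply; double-phosphate losses square the single-loss fraction.
    """

    water_loss_frac: float = 0.2
    ammonia_loss_frac: float = 0.2
    phospho_loss_frac_st: float = 0.5
    phospho_loss_frac_y: float = 0.1
    charge2_scale: float = 0.3
    b_series_scale: float = 0.6
    y_series_scale: float = 1.0
    profile_width_fraction: float = 0.35  # Gaussian width relative to length


class BaselinePredictor:
    """Deterministic rule-based surrogate spectrum predictor."""

    name = "baseline"
    deterministic = True

    def __init__(self, config: BaselineConfig | None = None):
        self.config = config or BaselineConfig()
        self._cache: dict[tuple[str, int], PredictedSpectrum] = {}

    def _loss_fraction(self, p: Peptidoform, series: str, k: int, loss: str) -> float:
        cfg = self.config
        frac = 1.0
        # decompose the loss label: optional water/ammonia prefix, then p/2p
        if loss.startswith("o"):
            frac *= cfg.water_loss_frac
            loss_rest = loss[1:]
        elif loss.startswith("n"):
            frac *= cfg.ammonia_loss_frac
            loss_rest = loss[1:]
        else:
            loss_rest = loss
        if loss_rest in ("p", "2p"):
            L = len(p.sequence)
            in_frag = [
                pos for pos in p.phospho_positions
                if (pos <= k if series == "b" else pos > L - k)
            ]
            only_y = bool(in_frag) and all(p.sequence[i - 1] == "Y" for i in in_frag)
            base = cfg.phospho_loss_frac_y if only_y else cfg.phospho_loss_frac_st
            frac *= base if loss_rest == "p" else base * base
        return frac

    def predict(self, p: Peptidoform) -> PredictedSpectrum:
        key = (format_modified_sequence(p), p.charge)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        cfg = self.config
        mz, feasible = fragment_grid(p)
        L = len(p.sequence)
        ks = np.arange(1, L, dtype=float)
        width = max(cfg.profile_width_fraction * L, 1.0)
        profile = np.exp(-0.5 * ((ks - L / 2.0) / width) ** 2)
        intensity = np.zeros_like(mz)
        for j, f in enumerate(FRAGMENT_TYPES):
            series_scale = cfg.b_series_scale if f.series == "b" else cfg.y_series_scale
            charge_scale = 1.0 if f.fragment_charge == 1 else cfg.charge2_scale
            if f.loss == "":
                col = profile * series_scale * charge_scale
            else:
                col = np.array(
                    [
                        profile[k - 1]
                        * series_scale
                        * charge_scale
                        * self._loss_fraction(p, f.series, k, f.loss)
                        for k in range(1, L)
                    ]
                )
            intensity[:, j] = col
        intensity[~feasible] = 0.0
        peak = intensity.max(initial=0.0)
        if peak > 0:
            intensity = intensity / peak
        pred = PredictedSpectrum(p, mz.ravel(), intensity.ravel())
        self._cache[key] = pred
        return pred


# ---------------------------------------------------------------------------
# Spectral-library entries and the lookup predictor

@dataclass
class SpectralLibraryEntry:
    """One library precursor: a peptidoform and its annotated fragments.

    ``fragments`` rows are ``(FragmentType, cleavage_index, mz, intensity)``
    with intensities normalized to [0, 1].  ``retention_time`` is in the
    producing experiment's units (typically minutes) and is optional.
    """

    peptidoform: Peptidoform
    fragments: list[tuple[FragmentType, int, float, float]]
    retention_time: float | None = None
    score: float = 0.0

    @property
    def key(self) -> tuple[str, int]:
        return (format_modified_sequence(self.peptidoform), self.peptidoform.charge)


class LibraryMiss(KeyError):
    """Requested peptidoform/charge is absent from the library."""


class LibraryPredictor:
    """Exact-key library lookup satisfying the predictor contract.

    Duplicate (peptidoform, charge) keys keep the highest-scoring entry
    (input order breaks score ties); a miss raises :class:`LibraryMiss` so the
    caller can decide whether to fall back to another predictor.
    """

    name = "library"
    deterministic = True

    def __init__(self, entries: Iterable[SpectralLibraryEntry]):
        self._entries: dict[tuple[str, int], SpectralLibraryEntry] = {}
        for e in entries:
            old = self._entries.get(e.key)
            if old is None or e.score > old.score:
                self._entries[e.key] = e

    def __len__(self) -> int:
        return len(self._entries)

    def predict(self, p: Peptidoform) -> PredictedSpectrum:
        key = (format_modified_sequence(p), p.charge)
        entry = self._entries.get(key)
        if entry is None:
            raise LibraryMiss(key)
        mz, feasible = fragment_grid(p)
        n_types = len(FRAGMENT_TYPES)
        from .fragmentation import TYPE_INDEX

        intensity = np.zeros_like(mz)
        grid_mz = mz.copy()
        for ftype, k, fmz, fint in entry.fragments:
            intensity[k - 1, TYPE_INDEX[ftype]] = fint
            grid_mz[k - 1, TYPE_INDEX[ftype]] = fmz
        return PredictedSpectrum(p, grid_mz.ravel(), intensity.ravel())


# ---------------------------------------------------------------------------
# Library table I/O (vendor-neutral flat TSV, one fragment per row)

_LIB_COLUMNS = [
    "modified_sequence",
    "precursor_charge",
    "precursor_mz",
    "fragment_type",
    "fragment_series",
    "fragment_loss",
    "fragment_index",
    "fragment_charge",
    "fragment_mz",
    "relative_intensity",
    "retention_time",
]


def write_library(entries: Iterable[SpectralLibraryEntry], path) -> None:
    rows = []
    for e in entries:
        modseq = format_modified_sequence(e.peptidoform)
        pmz = precursor_mz(e.peptidoform)
        for ftype, k, fmz, fint in e.fragments:
            rows.append(
                {
                    "modified_sequence": modseq,
                    "precursor_charge": e.peptidoform.charge,
                    "precursor_mz": round(pmz, 6),
                    "fragment_type": ftype.label,
                    "fragment_series": ftype.series,
                    "fragment_loss": ftype.loss,
                    "fragment_index": k,
                    "fragment_charge": ftype.fragment_charge,
                    "fragment_mz": round(fmz, 6),
                    "relative_intensity": round(fint, 6),
                    "retention_time": "" if e.retention_time is None else round(e.retention_time, 4),
                }
            )
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library(path) -> list[SpectralLibraryEntry]:
    """Read a flat fragment-per-row library TSV.

    Only ``modified_sequence, charge (or precursor_charge), fragment_type,
    fragment_index, fragment_mz, relative_intensity`` are required;
    ``retention_time`` is optional.
    """
    df = pd.read_csv(path, sep="\t")
    charge_col = "precursor_charge" if "precursor_charge" in df.columns else "charge"
    entries: list[SpectralLibraryEntry] = []
    from .peptide_core import parse_modified_sequence

    for (modseq, charge), grp in df.groupby(["modified_sequence", charge_col], sort=False):
        p = parse_modified_sequence(str(modseq), int(charge))
        fragments = [
            (
                FragmentType.from_label(str(r.fragment_type)),
                int(r.fragment_index),
                float(r.fragment_mz),
                float(r.relative_intensity),
            )
            for r in grp.itertuples()
        ]
        rt = None
        if "retention_time" in grp.columns:
            rts = pd.to_numeric(grp["retention_time"], errors="coerce").dropna()
            if len(rts):
                rt = float(rts.iloc[0])
        entries.append(SpectralLibraryEntry(p, fragments, retention_time=rt))
    return entries
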
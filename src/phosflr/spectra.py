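"""Experimental spectra: MGF I/O, normalization, ppm matching, similarity.

Spectral similarity is computed on the annotated fragment grid: the predicted
spectrum exists only on the 36-type grid, so the experimental spectrum is
projected onto the same grid by nearest-peak matching within a ppm tolerance
(default 25 ppm), with unmatched coordinates set to the missing value (0).
Unannotated experimental peaks do not enter the similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from pyteomics import mgf as _mgf
from scipy import stats as _stats

__all__ = [
    "ExperimentalSpectrum",
    "MatchingParams",
    "read_mgf",
    "write_mgf",
    "normalize_intensities",
    "match_peaks",
    "cosine_similarity",
    "pearson_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class ExperimentalSpectrum:
    """A centroided peak list with precursor information.

    Peaks are stored as parallel arrays sorted by ascending m/z; intensities
    are non-negative arbitrary units.  ``precursor_charge`` may be None when
    the source MGF block carries no CHARGE line.
    """

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int | None
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size == 0:
            raise ValueError(f"spectrum {self.spectrum_id!r} has no peaks")
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")


@dataclass(frozen=True)
class MatchingParams:
    """Peak-matching and scoring parameters.

    ``transform='raw'`` scores cosine on max-normalized intensities;
    ``'normalized_log'`` applies the 0-1 normalization followed by log2(x+1)
    to both vectors before scoring (the transform used at model-training
    ingest, offered here as an option).
    """

    tolerance_ppm: float = 25.0
    missing_value: float = 0.0
    transform: str = "raw"

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be > 0")
        if self.transform not in ("raw", "normalized_log"):
            raise ValueError(f"unknown transform {self.transform!r}")


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)

def read_mgf(path) -> list[ExperimentalSpectrum]:
    """Read an MGF file; spectrum ids come from TITLE lines.

    Malformed blocks are skipped with a logged warning; a file yielding zero
    spectra is an error.
    """
    spectra: list[ExperimentalSpectrum] = []
    with _mgf.MGF(str(path)) as reader:
        for i, entry in enumerate(reader):
            try:
                params = entry["params"]
                title = str(params.get("title", f"index={i}"))
                pepmass = params["pepmass"][0]
                charge_field = params.get("charge")
                charge = int(charge_field[0]) if charge_field else None
                spectra.append(
                    ExperimentalSpectrum(
                        spectrum_id=title,
                        precursor_mz=float(pepmass),
                        precursor_charge=charge,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
            except (KeyError, ValueError, TypeError, IndexError) as exc:
                log.warning("skipping malformed MGF block %d: %s", i, exc)
    if not spectra:
        raise ValueError(f"no spectra could be read from {path}")
    return spectra


def write_mgf(spectra, path, mz_decimals: int = 4, intensity_decimals: int = 1) -> None:
    """Write spectra as MGF with fixed decimal formatting (4 for m/z, 1 for
    intensity by default) so written files are byte-reproducible."""
    entries = []
    for s in spectra:
        params = {"title": s.spectrum_id, "pepmass": s.precursor_mz}
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    fmt = f"%.{mz_decimals}f %.{intensity_decimals}f"
    with open(path, "w") as fh:
        _mgf.write(entries, fh, fragment_format=fmt, write_charges=False, use_numpy=True)


# ---------------------------------------------------------------------------
# Normalization and matching

def normalize_intensities(values) -> np.ndarray:
    """Scale to 0-1 by the maximum, then log2(x + 1); output lies in [0, 1]."""
    v = np.asarray(values, dtype=float)
    peak = v.max(initial=0.0)
    if peak <= 0:
        raise ValueError("cannot normalize an all-zero intensity vector")
    return np.log2(v / peak + 1.0)


def match_peaks(
    theoretical_mz, spectrum: ExperimentalSpectrum, params: MatchingParams = MatchingParams()
) -> np.ndarray:
    """Project experimental intensities onto a theoretical m/z grid.

    For each theoretical m/z the closest experimental peak within the ppm
    tolerance supplies its intensity; otherwise the missing value (default 0)
    is used.  One experimental peak may satisfy several theoretical ions (no
    exclusivity); ties break to the smallest ppm error by construction.
    Theoretical entries with m/z <= 0 (infeasible ions) stay at the missing
    value.
    """
    theo = np.asarray(theoretical_mz, dtype=float)
    out = np.full(theo.shape, params.missing_value, dtype=float)
    flat = theo.ravel()
    valid = flat > 0
    if not valid.any():
        return out
    smz, sint = spectrum.mz, spectrum.intensity
    idx = np.searchsorted(smz, flat[valid])
    lo = np.clip(idx - 1, 0, smz.size - 1)
    hi = np.clip(idx, 0, smz.size - 1)
    d_lo = np.abs(smz[lo] - flat[valid])
    d_hi = np.abs(smz[hi] - flat[valid])
    best = np.where(d_lo <= d_hi, lo, hi)
    err = np.minimum(d_lo, d_hi)
    within = err / flat[valid] <= params.tolerance_ppm * 1e-6
    res = np.full(flat.shape, params.missing_value, dtype=float)
    matched = np.where(valid)[0][within]
    res[matched] = sint[best[within]]
    return res.reshape(theo.shape)


# ---------------------------------------------------------------------------
# Similarity metrics

def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two aligned intensity vectors, in [0, 1].

    Returns 0 (with a debug log) if either vector is all-zero.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        log.debug("cosine of an all-zero vector -> 0")
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def pearson_correlation(a, b) -> float:
    """Product-moment correlation between two aligned vectors, in [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(_stats.pearsonr(a, b).statistic)
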
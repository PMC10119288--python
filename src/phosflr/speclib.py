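"""DIA spectral-library construction from FLR-filtered identifications.

Three build modes differ only in where fragment intensities come from:

* ``predicted`` -- every entry carries predictor intensities;
* ``hybrid`` -- predictor intensities only where the re-localized site
  assignment differs from the upstream engine's, experimental intensities
  (annotated on the fragment grid) elsewhere;
* ``relocalized_experimental`` -- experimental intensities throughout, with
  the re-localized peptidoform as the identification.

Retention times are always experimental.  Callers are expected to pass PSMs
already filtered to the working FLR (typically estimated FLR <= 0.01).
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .flr_engine import PSMRecord
from .fragmentation import FRAGMENT_TYPES, fragment_grid
from .peptide_core import Peptidoform, format_modified_sequence
from .predictor import SpectralLibraryEntry
from .spectra import ExperimentalSpectrum, MatchingParams, match_peaks

__all__ = ["LIBRARY_MODES", "build_library"]

log = logging.getLogger(__name__)

LIBRARY_MODES = ("predicted", "hybrid", "relocalized_experimental")

MIN_FRAGMENTS_DEFAULT = 4


def _fragments_from_grid(mz_flat, intensity_flat, n_positions):
    mz = np.asarray(mz_flat).reshape(n_positions, len(FRAGMENT_TYPES))
    intensity = np.asarray(intensity_flat).reshape(n_positions, len(FRAGMENT_TYPES))
    peak = intensity.max(initial=0.0)
    if peak > 0:
        intensity = intensity / peak
    out = []
    for k in range(n_positions):
        for j, f in enumerate(FRAGMENT_TYPES):
            if intensity[k, j] > 0 and mz[k, j] > 0:
                out.append((f, k + 1, float(mz[k, j]), float(intensity[k, j])))
    return out


def _experimental_fragments(
    p: Peptidoform, spectrum: ExperimentalSpectrum, params: MatchingParams
):
    mz, _ = fragment_grid(p)
    matched = match_peaks(mz, spectrum, params)
    return _fragments_from_grid(mz.ravel(), matched.ravel(), len(p.sequence) - 1)


def _predicted_fragments(p: Peptidoform, predictor):
    pred = predictor.predict(p)
    return _fragments_from_grid(pred.mz, pred.intensity, len(p.sequence) - 1)


def build_library(
    psms: Sequence[PSMRecord],
    spectra: Mapping[str, ExperimentalSpectrum] | Iterable[ExperimentalSpectrum],
    predictor,
    mode: str,
    engine_assignments: Mapping[str, Peptidoform],
    rt_source: Mapping[str, float] | None = None,
    params: MatchingParams = MatchingParams(),
    min_fragments: int = MIN_FRAGMENTS_DEFAULT,
) -> list[SpectralLibraryEntry]:
    """Build one spectral library from accepted PSMs.

    ``engine_assignments`` maps spectrum_id to the upstream engine's reported
    peptidoform (used by the hybrid mode's provenance rule);``rt_source``
    maps spectrum_id to experimental retention times.  Decoy hits are never
    exported.  PSMs whose spectrum is missing are dropped with a warning;
    duplicate (peptidoform, charge) keys keep the highest-cosine entry;
    entries with fewer than ``min_fragments`` annotated fragments are dropped
    with a logged count.
    """
    if mode not in LIBRARY_MODES:
        raise ValueError(f"mode must be one of {LIBRARY_MODES}, got {mode!r}")
    if not isinstance(spectra, Mapping):
        spectra = {s.spectrum_id: s for s in spectra}
    rt_source = rt_source or {}

    best: dict[tuple[str, int], SpectralLibraryEntry] = {}
    n_missing = n_thin = 0
    for psm in psms:
        if psm.is_decoy or psm.unscorable:
            continue
        spectrum = spectra.get(psm.spectrum_id)
        if spectrum is None:
            n_missing += 1
            continue
        p = psm.best_candidate
        engine = engine_assignments.get(psm.spectrum_id)
        relocalized = engine is None or p.mods != engine.mods
        if mode == "predicted" or (mode == "hybrid" and relocalized):
            fragments = _predicted_fragments(p, predictor)
        else:
            fragments = _experimental_fragments(p, spectrum, params)
        if len(fragments) < min_fragments:
            n_thin += 1
            continue
        entry = SpectralLibraryEntry(
            peptidoform=p,
            fragments=fragments,
            retention_time=rt_source.get(psm.spectrum_id),
            score=psm.best_cosine,
        )
        old = best.get(entry.key)
        if old is None or entry.score > old.score:
            best[entry.key] = entry
    if n_missing:
        log.warning("%d PSMs dropped: spectrum missing", n_missing)
    if n_thin:
        log.info("%d entries dropped with fewer than %d fragments", n_thin, min_fragments)
    return list(best.values())
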
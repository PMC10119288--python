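"""Spectrum scoring, delta scores, and FLR estimation/evaluation.

Each spectrum is scored against all its candidates (target isoforms and
decoys) by cosine similarity between the predicted spectrum and the
experimental intensities matched onto the same fragment grid.  The best
candidate wins (ties resolve to the decoy, the conservative choice), and the
**delta score** is the winning cosine minus the cosine of the nearest-scoring
*target* isoform (excluding the winner itself when it is a target): a large
delta means no competing site explains the spectrum nearly as well.

Ranking all spectra by delta score and sweeping a threshold gives the
estimated FLR at each cutoff

    FLR_estimated = (N_decoy + N_target) / N_decoy * #D / (#T + #D)

where N_decoy/N_target are the global database tallies and #D/#T count decoy
and target hits above the cutoff.  With ground truth available (synthetic
data) the real FLR is FP / (TP + FP), a hit counting as TP only when the full
modified sequence -- sites included -- matches the truth; decoy hits count as
FP.  Repeated analyses (n = 10 by default, matching the repeat design the
confidence coefficient 2.26 at 9 degrees of freedom belongs to) yield 95%
confidence half-widths  2.26 * sqrt(sum (x_i - mean)^2 / (n (n-1))).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .candidates import CandidateDatabase, CandidateSet, build_candidate_database
from .peptide_core import Peptidoform, format_modified_sequence
from .spectra import ExperimentalSpectrum, MatchingParams, cosine_similarity, match_peaks, normalize_intensities

__all__ = [
    "PSMRecord",
    "score_spectrum",
    "estimate_flr",
    "real_flr",
    "flr_curve",
    "curve_at_thresholds",
    "threshold_at_flr",
    "ci_coefficient",
    "ci_halfwidth",
    "repeat_with_ci",
    "analyze_dataset",
]

log = logging.getLogger(__name__)


@dataclass
class PSMRecord:
    """Best candidate for one spectrum, with cosine and delta score."""

    spectrum_id: str
    best_candidate: Peptidoform
    is_decoy: bool
    best_cosine: float
    delta_score: float
    all_candidate_scores: list[tuple[Peptidoform, float, bool]] = field(
        default_factory=list
    )
    unscorable: bool = False


def _transformed(vec: np.ndarray, params: MatchingParams) -> np.ndarray:
    if params.transform == "normalized_log" and vec.max(initial=0.0) > 0:
        return normalize_intensities(vec)
    return vec


def score_spectrum(
    s: ExperimentalSpectrum,
    cs: CandidateSet,
    predictor,
    params: MatchingParams = MatchingParams(),
) -> PSMRecord:
    """Score one spectrum against its candidate set.

    Cosine similarity is computed for every target and decoy; the best
    candidate is reported with a tie on the best cosine resolved in favor of
    the decoy.  A record where every candidate's matched experimental vector
    is all-zero is flagged unscorable (and later excluded from ranking).
    """
    if not cs.targets and not cs.decoys:
        raise ValueError(f"empty candidate set for spectrum {cs.spectrum_id!r}")
    scored: list[tuple[Peptidoform, float, bool]] = []
    any_signal = False
    for cand, is_decoy in [(t, False) for t in cs.targets] + [
        (d, True) for d, _ in cs.decoys
    ]:
        pred = predictor.predict(cand)
        exp_vec = match_peaks(pred.mz, s, params)
        if exp_vec.max(initial=0.0) > 0:
            any_signal = True
        cos = cosine_similarity(
            _transformed(pred.intensity, params), _transformed(exp_vec, params)
        )
        scored.append((cand, cos, is_decoy))

    # best by cosine; exact ties resolve to the decoy (conservative FLR)
    best_idx = max(
        range(len(scored)), key=lambda i: (scored[i][1], scored[i][2])
    )
    best_cand, best_cos, best_is_decoy = scored[best_idx]
    target_cosines = [
        cos
        for i, (cand, cos, is_decoy) in enumerate(scored)
        if not is_decoy and i != best_idx
    ]
    if target_cosines:
        delta = best_cos - max(target_cosines)
    else:
        # single-target edge case: no competing target exists
        delta = best_cos
        log.debug("spectrum %s has a single target candidate", cs.spectrum_id)
    return PSMRecord(
        spectrum_id=cs.spectrum_id,
        best_candidate=best_cand,
        is_decoy=best_is_decoy,
        best_cosine=best_cos,
        delta_score=delta,
        all_candidate_scores=scored,
        unscorable=not any_signal,
    )


def estimate_flr(N_decoy: int, N_target: int, D: int, T: int) -> float:
    """Estimated FLR from decoy counts, capped at 1.

    ``(N_decoy + N_target) / N_decoy * D / (T + D)``.
    """
    if N_decoy <= 0:
        raise ValueError("N_decoy must be > 0")
    if T + D <= 0:
        raise ValueError("T + D must be > 0")
    return min(1.0, (N_decoy + N_target) / N_decoy * D / (T + D))


def _is_true_hit(record: PSMRecord, truth: Peptidoform) -> bool:
    if record.is_decoy:
        return False
    b = record.best_candidate
    return b.sequence == truth.sequence and b.mods == truth.mods


def real_flr(records: Sequence[PSMRecord], ground_truth: dict[str, Peptidoform]) -> float:
    """Ground-truth FLR: FP / (TP + FP).

    A hit is a true positive only when the full modified sequence (sites
    included) matches the truth for its spectrum; decoy hits are false
    positives.
    """
    tp = fp = 0
    for r in records:
        if r.spectrum_id not in ground_truth:
            raise KeyError(f"no ground truth for spectrum {r.spectrum_id!r}")
        if _is_true_hit(r, ground_truth[r.spectrum_id]):
            tp += 1
        else:
            fp += 1
    if tp + fp == 0:
        raise ValueError("no records")
    return fp / (tp + fp)


def flr_curve(
    records: Sequence[PSMRecord],
    N_decoy: int,
    N_target: int,
    ground_truth: dict[str, Peptidoform] | None = None,
) -> pd.DataFrame:
    """Descending delta-score sweep with cumulative estimated (and real) FLR.

    Records tied on the delta score form atomic groups -- a threshold admits
    all of a tie group or none -- so the curve has one row per distinct delta
    value with cumulative target hits (#T), decoy hits (#D), the estimated
    FLR, and, when ground truth is supplied, the real FLR.  Unscorable
    records are excluded with a logged count.
    """
    usable = [r for r in records if not r.unscorable]
    if len(usable) < len(records):
        log.info("excluded %d unscorable records from the sweep", len(records) - len(usable))
    if not usable:
        raise ValueError("no scorable records")
    usable.sort(key=lambda r: -r.delta_score)
    rows = []
    n_t = n_d = tp = fp = 0
    i = 0
    while i < len(usable):
        j = i
        while j < len(usable) and usable[j].delta_score == usable[i].delta_score:
            r = usable[j]
            if r.is_decoy:
                n_d += 1
            else:
                n_t += 1
            if ground_truth is not None:
                if _is_true_hit(r, ground_truth[r.spectrum_id]):
                    tp += 1
                else:
                    fp += 1
            j += 1
        row = {
            "delta_score": usable[i].delta_score,
            "n_accepted": n_t + n_d,
            "n_target_hits": n_t,
            "n_decoy_hits": n_d,
            "flr_estimated": estimate_flr(N_decoy, N_target, n_d, n_t),
        }
        if ground_truth is not None:
            row["flr_real"] = fp / (tp + fp)
        rows.append(row)
        i = j
    return pd.DataFrame(rows)


def curve_at_thresholds(
    curve: pd.DataFrame, thresholds, column: str = "flr_estimated"
) -> np.ndarray:
    """Evaluate a cumulative curve column on a fixed delta-threshold grid.

    For each threshold t the value is the column at the largest accepted
    prefix (all records with delta >= t); NaN where no record is accepted.
    Puts repeated runs on a common axis for averaging and confidence bands.
    """
    deltas = curve["delta_score"].to_numpy()
    vals = curve[column].to_numpy()
    out = np.full(len(thresholds), np.nan)
    for i, t in enumerate(thresholds):
        idx = np.nonzero(deltas >= t)[0]
        if idx.size:
            out[i] = vals[idx[-1]]
    return out


def threshold_at_flr(
    curve: pd.DataFrame,
    alpha: float = 0.01,
    records: Sequence[PSMRecord] | None = None,
):
    """Largest accepted prefix with estimated FLR <= alpha.

    Returns ``(delta threshold, n accepted, accepted records)``; the record
    list is None unless ``records`` is supplied.  Raises ``ValueError`` when
    no cutoff satisfies alpha.
    """
    if curve.empty:
        raise ValueError("empty curve")
    ok = curve[curve["flr_estimated"] <= alpha]
    if ok.empty:
        raise ValueError(f"no delta-score threshold reaches estimated FLR <= {alpha}")
    row = ok.iloc[-1]
    threshold = float(row["delta_score"])
    accepted = None
    if records is not None:
        accepted = [r for r in records if not r.unscorable and r.delta_score >= threshold]
    return threshold, int(row["n_accepted"]), accepted


def ci_coefficient(n: int) -> float:
    """Two-sided 95% confidence coefficient for n repeats.

    The constant 2.26 is used verbatim at n = 10 (9 degrees of freedom);
    other repeat counts fall back to the Student-t quantile.
    """
    if n < 2:
        raise ValueError("need n >= 2 repeats for a confidence coefficient")
    if n == 10:
        return 2.26
    return float(_stats.t.ppf(0.975, n - 1))


def ci_halfwidth(values: Sequence[float]) -> float:
    """95% confidence half-width of the mean of repeat measurements.

    ``coef * sqrt(sum (x_i - mean)^2 / (n (n-1)))``; by convention the
    half-width is 0 when only one valid value exists.
    """
    x = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    n = x.size
    if n <= 1:
        return 0.0
    mean = x.mean()
    return ci_coefficient(n) * float(np.sqrt(np.sum((x - mean) ** 2) / (n * (n - 1))))


def repeat_with_ci(
    run: Callable[[int], np.ndarray],
    n: int = 10,
    seeds: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Repeat a pipeline closure over seeds and summarize per-threshold values.

    ``run(seed)`` must return an array of measurements aligned on a fixed
    threshold grid (NaN marks an invalid value at that cutoff).  Returns
    ``(mean, half-width)`` arrays; positions where only one repeat produced a
    valid value get half-width 0, and all-invalid positions are NaN.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seeds is None:
        seeds = range(n)
    seeds = list(seeds)[:n]
    results = np.vstack([np.asarray(run(s), dtype=float) for s in seeds])
    valid = np.isfinite(results)
    counts = valid.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, np.nansum(np.where(valid, results, 0.0), axis=0) / np.maximum(counts, 1), np.nan)
    half = np.zeros(results.shape[1])
    for j in range(results.shape[1]):
        half[j] = ci_halfwidth(results[valid[:, j], j]) if counts[j] > 1 else 0.0
    return means, half


def analyze_dataset(
    spectra: Sequence[ExperimentalSpectrum],
    identifications,
    predictor,
    method: int = 1,
    seed: int = 0,
    params: MatchingParams = MatchingParams(),
    max_phospho: int = 2,
) -> tuple[list[PSMRecord], CandidateDatabase]:
    """End-to-end convenience: build the candidate database and score every
    re-analyzable spectrum that has an MGF entry."""
    db = build_candidate_database(identifications, method=method, seed=seed, max_phospho=max_phospho)
    by_id = {s.spectrum_id: s for s in spectra}
    records: list[PSMRecord] = []
    missing = 0
    for cs in db.sets:
        spec = by_id.get(cs.spectrum_id)
        if spec is None:
            missing += 1
            continue
        records.append(score_spectrum(spec, cs, predictor, params))
    if missing:
        log.warning("%d candidate sets had no matching spectrum", missing)
    return records, db
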
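"""Delta scoring, FLR estimation (decoy-based and ground-truth), CI math."""

import numpy as np
import pandas as pd
import pytest

import phosflr as pf
from phosflr.flr_engine import (
    PSMRecord,
    ci_coefficient,
    ci_halfwidth,
    curve_at_thresholds,
    estimate_flr,
    flr_curve,
    real_flr,
    repeat_with_ci,
    score_spectrum,
    threshold_at_flr,
)
from phosflr.peptide_core import Peptidoform
from phosflr.predictor import PredictedSpectrum


class StubPredictor:
    """Returns preset intensity vectors on a shared 3-peak grid, letting the
    tests dial in exact cosine scores."""

    name = "stub"
    deterministic = True
    GRID = np.array([100.0, 200.0, 300.0])

    def __init__(self, table):
        self.table = {str(k): np.asarray(v, dtype=float) for k, v in table.items()}

    def predict(self, p):
        return PredictedSpectrum(p, self.GRID, self.table[str(p)])


def candset(targets, decoys):
    return pf.CandidateSet("s1", targets, [(d, 0) for d in decoys], True)


def uniform_spectrum():
    return pf.ExperimentalSpectrum(
        "s1", 500.0, 2, StubPredictor.GRID.copy(), np.array([1.0, 1.0, 1.0])
    )


TA = Peptidoform("SATK", ((1, "Phospho"),), 2)
TB = Peptidoform("SATK", ((3, "Phospho"),), 2)
DY = Peptidoform("ASTK", ((2, "Phospho"),), 2)


class TestScoreSpectrum:
    def test_best_target_delta_to_runner_up_target(self):
        # cosines against the flat spectrum: TA=1.0, TB=0.816, DY=0.577
        pred = StubPredictor({str(TA): [1, 1, 1], str(TB): [1, 1, 0], str(DY): [1, 0, 0]})
        rec = score_spectrum(uniform_spectrum(), candset([TA, TB], [DY]), pred)
        assert rec.best_candidate == TA and not rec.is_decoy
        assert rec.best_cosine == pytest.approx(1.0)
        assert rec.delta_score == pytest.approx(1.0 - np.sqrt(2 / 3), abs=1e-9)

    def test_best_decoy_delta_to_closest_target(self):
        pred = StubPredictor({str(TA): [1, 1, 0], str(TB): [1, 0, 0], str(DY): [1, 1, 1]})
        rec = score_spectrum(uniform_spectrum(), candset([TA, TB], [DY]), pred)
        assert rec.is_decoy
        assert rec.delta_score == pytest.approx(1.0 - np.sqrt(2 / 3), abs=1e-9)

    def test_tie_resolves_to_decoy(self):
        pred = StubPredictor({str(TA): [1, 1, 1], str(TB): [1, 0, 0], str(DY): [1, 1, 1]})
        rec = score_spectrum(uniform_spectrum(), candset([TA, TB], [DY]), pred)
        assert rec.is_decoy

    def test_single_target_edge_delta_is_best_cosine(self):
        pred = StubPredictor({str(TA): [1, 1, 1], str(DY): [1, 0, 0]})
        rec = score_spectrum(uniform_spectrum(), candset([TA], [DY]), pred)
        assert rec.delta_score == pytest.approx(rec.best_cosine)

    def test_no_matching_peaks_flags_unscorable(self):
        pred = StubPredictor({str(TA): [1, 1, 1], str(DY): [1, 0, 0]})
        far = pf.ExperimentalSpectrum("s1", 500.0, 2, np.array([900.0]), np.array([5.0]))
        rec = score_spectrum(far, candset([TA], [DY]), pred)
        assert rec.unscorable

    def test_empty_candidate_set_rejected(self):
        with pytest.raises(ValueError):
            score_spectrum(uniform_spectrum(), pf.CandidateSet("s1", [], [], True),
                           StubPredictor({}))


class TestEstimator:
    @pytest.mark.parametrize(
        "nd, nt, d, t, expected",
        [
            (100, 100, 1, 99, 0.02),
            (100, 100, 0, 100, 0.0),
            (200, 100, 2, 98, 0.03),
            (10, 10, 10, 0, 1.0),  # capped
        ],
    )
    def test_reference_values(self, nd, nt, d, t, expected):
        assert estimate_flr(nd, nt, d, t) == pytest.approx(expected)

    def test_equal_database_halves_reduce_to_2d_over_n(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(10, 500))
            d = int(rng.integers(0, n + 1))
            assert estimate_flr(1000, 1000, d, n - d) == pytest.approx(
                min(1.0, 2 * d / n)
            )

    def test_zero_denominators_rejected(self):
        with pytest.raises(ValueError):
            estimate_flr(0, 10, 1, 9)
        with pytest.raises(ValueError):
            estimate_flr(10, 10, 0, 0)


def record(sid, cand, is_decoy, delta, cosine=0.9):
    return PSMRecord(sid, cand, is_decoy, cosine, delta)


class TestRealFlr:
    def test_reference_ratios(self):
        truth = {f"s{i}": TA for i in range(100)}
        recs = [record(f"s{i}", TA, False, 0.5) for i in range(99)]
        recs.append(record("s99", TB, False, 0.5))  # wrong site
        assert real_flr(recs, truth) == pytest.approx(0.01)

    def test_decoy_hits_count_as_false_positives(self):
        truth = {"s0": TA}
        assert real_flr([record("s0", TA, True, 0.5)], truth) == 1.0

    def test_all_true(self):
        truth = {"s0": TA}
        assert real_flr([record("s0", TA, False, 0.5)], truth) == 0.0


class TestCurveAndThreshold:
    def test_all_target_curve_is_zero(self):
        recs = [record(f"s{i}", TA, False, 0.5 - 0.01 * i) for i in range(10)]
        curve = flr_curve(recs, 10, 10)
        assert (curve["flr_estimated"] == 0).all()

    def test_alternating_curve_saturates(self):
        recs = []
        for k in range(5):
            recs.append(record(f"t{k}", TA, False, 1.0 - 0.1 * k))
            recs.append(record(f"d{k}", DY, True, 0.95 - 0.1 * k))
        curve = flr_curve(recs, 100, 100, None)
        # at every even rank 2k: estimated = 2 * k / 2k = 1 (capped)
        even = curve[curve["n_accepted"] % 2 == 0]
        assert (even["flr_estimated"] == 1.0).all()

    def test_tie_groups_are_atomic(self):
        recs = [
            record("a", TA, False, 0.5),
            record("b", TA, False, 0.5),
            record("c", DY, True, 0.5),
            record("d", TA, False, 0.1),
        ]
        curve = flr_curve(recs, 10, 10)
        assert list(curve["n_accepted"]) == [3, 4]

    def test_threshold_prefix_rule(self):
        recs = [
            record("a", TA, False, 0.9),
            record("b", TA, False, 0.8),
            record("c", DY, True, 0.7),
        ]
        curve = flr_curve(recs, 100, 100)
        thr, n_acc, accepted = threshold_at_flr(curve, alpha=0.01, records=recs)
        assert n_acc == 2 and thr == pytest.approx(0.8)
        assert {r.spectrum_id for r in accepted} == {"a", "b"}

    def test_threshold_alpha_one_accepts_all(self):
        recs = [record("a", TA, False, 0.9), record("c", DY, True, 0.7)]
        curve = flr_curve(recs, 100, 100)
        _, n_acc, _ = threshold_at_flr(curve, alpha=1.0, records=recs)
        assert n_acc == 2

    def test_all_decoy_curve_has_no_acceptance(self):
        recs = [record("c", DY, True, 0.7)]
        curve = flr_curve(recs, 100, 100)
        with pytest.raises(ValueError):
            threshold_at_flr(curve, alpha=0.01)

    def test_unscorable_records_excluded(self):
        recs = [
            record("a", TA, False, 0.9),
            PSMRecord("u", TA, False, 0.0, 0.0, unscorable=True),
        ]
        curve = flr_curve(recs, 10, 10)
        assert curve["n_accepted"].max() == 1

    def test_curve_at_thresholds_lookup(self):
        recs = [
            record("a", TA, False, 0.9),
            record("b", TA, False, 0.5),
            record("c", DY, True, 0.2),
        ]
        curve = flr_curve(recs, 100, 100)
        vals = curve_at_thresholds(curve, [0.95, 0.6, 0.3, 0.0])
        assert np.isnan(vals[0])
        assert vals[1] == pytest.approx(0.0)
        assert vals[3] == pytest.approx(estimate_flr(100, 100, 1, 2))


class TestConfidenceIntervals:
    def test_n10_uses_tabulated_coefficient(self):
        assert ci_coefficient(10) == 2.26

    def test_other_n_use_t_quantile(self):
        from scipy import stats

        assert ci_coefficient(5) == pytest.approx(stats.t.ppf(0.975, 4))

    def test_identical_repeats_have_zero_halfwidth(self):
        assert ci_halfwidth([0.5] * 10) == 0.0

    def test_reference_halfwidth(self):
        values = [0.0] * 5 + [2.0] * 5
        assert ci_halfwidth(values) == pytest.approx(0.7535, abs=1e-3)

    def test_single_valid_value_gives_zero(self):
        assert ci_halfwidth([1.0]) == 0.0
        assert ci_halfwidth([1.0, np.nan]) == 0.0

    def test_repeat_with_ci_aggregates(self):
        def run(seed):
            return np.array([seed % 2 * 2.0, np.nan if seed else 1.0])

        means, half = repeat_with_ci(run, n=10, seeds=range(10))
        assert means[0] == pytest.approx(1.0)
        assert half[0] == pytest.approx(0.7535, abs=1e-3)
        assert means[1] == pytest.approx(1.0)  # only seed 0 valid
        assert half[1] == 0.0
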
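"""Softmax-threshold calibration, retention and overconfidence tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pathdistill import (
    ABSTAIN_ALL,
    PredictionSet,
    ThresholdTable,
    apply_abstention,
    bootstrap_accuracy_ci,
    calibrate_threshold,
    calibrate_thresholds,
    count_overconfident_wrong,
    ensemble_size_curve,
    percentile_ci,
    retained_count,
    threshold_grid,
    wrong_confidence_histogram,
)
from pathdistill.abstention import CalibrationWarning


def brute_force_threshold(conf, correct, target):
    """Independent oracle: scan the whole grid, return the smallest value
    whose non-empty retained set is at least `target` accurate."""
    conf = np.asarray(conf, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    for tau in [i / 1000.0 for i in range(1, 1000)]:
        keep = conf >= tau
        if keep.sum() == 0:
            break
        if correct[keep].mean() >= target:
            return tau
    return ABSTAIN_ALL


class TestThresholdGrid:
    def test_exact_grid(self):
        grid = threshold_grid()
        assert len(grid) == 999
        assert grid[0] == 0.001
        assert grid[-1] == 0.999
        assert all(grid[i] == (i + 1) / 1000.0 for i in range(999))
        assert (np.diff(grid) > 0).all()


class TestCalibrateThreshold:
    def test_worked_example(self):
        # at 0.700 the retained set {0.7 wrong, 0.9 right} is 50% accurate;
        # at 0.701 only the correct 0.9 document remains
        tau = calibrate_threshold(
            np.array([0.6, 0.7, 0.9]), np.array([True, False, True]), 0.97
        )
        assert tau == 0.701

    def test_all_correct_gives_smallest_grid_value(self):
        tau = calibrate_threshold(np.array([0.3, 0.8]), np.array([True, True]), 0.97)
        assert tau == 0.001

    def test_all_wrong_gives_sentinel_with_warning(self):
        with pytest.warns(CalibrationWarning):
            tau = calibrate_threshold(
                np.array([0.5, 0.9]), np.array([False, False]), 0.97
            )
        assert tau == ABSTAIN_ALL

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            calibrate_threshold(np.array([]), np.array([]), 0.97)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        seed=st.integers(0, 2**31 - 1),
        n=st.integers(1, 40),
        target=st.sampled_from([0.5, 0.8, 0.9, 0.97, 1.0]),
    )
    def test_matches_brute_force_oracle(self, seed, n, target):
        rng = np.random.default_rng(seed)
        conf = np.round(rng.random(n), 4)
        correct = rng.random(n) < 0.7
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CalibrationWarning)
            assert calibrate_threshold(conf, correct, target) == brute_force_threshold(
                conf, correct, target
            )


def _pset(conf_label_pairs, K=4):
    """Build a single-task PredictionSet with given (confidence, correct)."""
    rows, labels = [], []
    for conf, correct in conf_label_pairs:
        row = np.full(K, (1 - conf) / (K - 1))
        row[0] = conf
        rows.append(row)
        labels.append(0 if correct else 1)
    pset = PredictionSet(
        ids=[f"d{i}" for i in range(len(rows))],
        probs={"site": np.array(rows)},
    )
    return pset, {"site": np.array(labels)}


class TestApplyAbstention:
    def test_worked_example(self):
        pset, labels = _pset([(0.5, False), (0.8, True), (0.95, True)])
        table = ThresholdTable(thresholds={"site": 0.701})
        rep = apply_abstention(pset, labels, table)
        r = rep.tasks["site"]
        assert r.retained == 2
        assert r.rp == pytest.approx(66.6667, abs=1e-3)
        assert r.accuracy == 1.0

    def test_tiny_threshold_retains_everything(self):
        pset, labels = _pset([(0.5, True), (0.9, False)])
        rep = apply_abstention(pset, labels, ThresholdTable(thresholds={"site": 0.001}))
        assert rep.tasks["site"].rp == 100.0

    def test_sentinel_abstains_all(self):
        pset, labels = _pset([(0.99, True)])
        rep = apply_abstention(
            pset, labels, ThresholdTable(thresholds={"site": ABSTAIN_ALL})
        )
        r = rep.tasks["site"]
        assert r.retained == 0 and r.rp == 0.0 and r.accuracy is None

    def test_rp_equals_100_minus_abstention_rate(self):
        pset, labels = _pset([(c, True) for c in (0.2, 0.5, 0.77, 0.9)])
        rep = apply_abstention(pset, labels, ThresholdTable(thresholds={"site": 0.6}))
        r = rep.tasks["site"]
        assert r.rp + r.abstention_rate == pytest.approx(100.0)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_retention_non_increasing_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        pairs = [(c, bool(r < 0.5)) for c, r in zip(rng.random(30), rng.random(30))]
        pset, labels = _pset(pairs)
        rps = []
        for tau in (0.001, 0.25, 0.5, 0.75, 0.999):
            rep = apply_abstention(pset, labels, ThresholdTable(thresholds={"site": tau}))
            rps.append(rep.tasks["site"].rp)
        assert all(a >= b for a, b in zip(rps, rps[1:]))

    def test_calibrate_then_apply_meets_target_in_sample(self):
        rng = np.random.default_rng(0)
        pairs = [(c, bool(r < c)) for c, r in zip(rng.random(500), rng.random(500))]
        pset, labels = _pset(pairs)
        table = calibrate_thresholds(pset, labels, target=0.9)
        rep = apply_abstention(pset, labels, table)
        r = rep.tasks["site"]
        assert r.accuracy is None or r.accuracy >= 0.9


class TestRetainedCount:
    def test_truncation_matches_published_counts(self):
        # 34.52% and 36.33% of the 441 732 test reports
        assert retained_count(34.52, 441_732) == 152_485
        assert retained_count(36.33, 441_732) == 160_481

    def test_full_retention(self):
        assert retained_count(100.0, 12_345) == 12_345

    def test_truncates_not_rounds(self):
        assert retained_count(50.0, 3) == 1  # 1.5 truncates to 1


class TestWrongConfidenceHistogram:
    def test_no_wrong_predictions(self):
        pset, labels = _pset([(0.9, True), (0.8, True)])
        counts = wrong_confidence_histogram(pset, labels, "site", [0.0, 0.5, 1.0])
        assert counts.tolist() == [0, 0]

    def test_hand_binning(self):
        pset, labels = _pset([(0.5, False), (0.95, False), (0.99, True)])
        counts = wrong_confidence_histogram(pset, labels, "site", [0.0, 0.9, 1.0])
        assert counts.tolist() == [1, 1]

    def test_mass_conservation(self):
        rng = np.random.default_rng(1)
        pairs = [(c, bool(r < 0.6)) for c, r in zip(rng.random(50), rng.random(50))]
        pset, labels = _pset(pairs)
        counts = wrong_confidence_histogram(
            pset, labels, "site", np.linspace(0, 1, 11)
        )
        n_wrong = int((pset.argmax("site") != labels["site"]).sum())
        assert counts.sum() == n_wrong

    def test_bad_edges(self):
        pset, labels = _pset([(0.5, True)])
        with pytest.raises(ValueError):
            wrong_confidence_histogram(pset, labels, "site", [0.1, 0.5, 1.0])


class TestCountOverconfidentWrong:
    def test_strict_inequality_boundary(self):
        pset, labels = _pset([(0.97, False), (0.971, False), (0.5, False)])
        assert count_overconfident_wrong(pset, labels, "site", 0.97) == 1

    def test_no_wrong_predictions(self):
        pset, labels = _pset([(0.99, True)])
        assert count_overconfident_wrong(pset, labels, "site") == 0

    def test_correct_predictions_excluded(self):
        pset, labels = _pset([(0.98, False), (0.99, False), (0.999, True)])
        assert count_overconfident_wrong(pset, labels, "site") == 2


class TestEnsembleSizeCurve:
    def _members(self, T=6, n=40, K=5, seed=0):
        rng = np.random.default_rng(seed)
        labels = {"site": rng.integers(0, K, n)}
        members = []
        for _ in range(T):
            p = rng.dirichlet(np.full(K, 0.3), size=n)
            members.append(
                PredictionSet(ids=[f"d{i}" for i in range(n)], probs={"site": p})
            )
        return members, labels

    def test_full_pool_size_has_zero_spread(self):
        members, labels = self._members()
        curve = ensemble_size_curve(members, labels, sizes=[6], replicates=10)
        assert curve.stds["site"][0] == 0.0

    def test_exhaustive_singletons_mean(self):
        members, labels = self._members()
        curve = ensemble_size_curve(
            members, labels, sizes=[1], exhaustive_singletons=True
        )
        singles = [
            count_overconfident_wrong(m, labels, "site", 0.97) for m in members
        ]
        assert curve.means["site"][0] == pytest.approx(np.mean(singles))

    def test_seed_determinism(self):
        members, labels = self._members()
        a = ensemble_size_curve(members, labels, [2, 4], replicates=7, seed=3)
        b = ensemble_size_curve(members, labels, [2, 4], replicates=7, seed=3)
        assert a.means == b.means

    def test_size_exceeding_pool_rejected(self):
        members, labels = self._members()
        with pytest.raises(ValueError):
            ensemble_size_curve(members, labels, sizes=[7])


def quantile_oracle(values, q):
    """Independent linear-interpolation quantile (Hyndman-Fan type 7)."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestPercentileCI:
    def test_constant_values(self):
        assert percentile_ci([3.3] * 10) == (3.3, 3.3)

    def test_matches_quantile_oracle(self):
        values = np.arange(1, 101, dtype=float)
        lo, hi = percentile_ci(values, 0.95)
        assert lo == pytest.approx(quantile_oracle(values, 0.025))
        assert hi == pytest.approx(quantile_oracle(values, 0.975))

    def test_contained_in_sample_range(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=37)
        lo, hi = percentile_ci(v)
        assert v.min() <= lo <= hi <= v.max()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0])

    def test_bootstrap_ci_brackets_accuracy(self):
        rng = np.random.default_rng(2)
        correct = rng.random(400) < 0.9
        lo, hi = bootstrap_accuracy_ci(correct, seed=1)
        assert lo <= correct.mean() <= hi
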
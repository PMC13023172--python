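import numpy as np
import pandas as pd
import pytest
from scipy import stats

from screenbias.bias_diagnostics import equal_count_bins
from screenbias.fp_estimation import (
    ThresholdCurve,
    detect_elbow,
    ecdf_ks,
    estimate,
    per_bin_fp_fn,
    threshold_curve,
)


def _genes(n):
    return pd.Index([f"G{i:04d}" for i in range(n)], name="gene")


class TestThresholdCurve:
    def test_lowest_four_essential(self):
        idx = _genes(10)
        pdna = pd.Series(np.arange(1.0, 11.0), index=idx)
        flags = pd.Series([True] * 4 + [False] * 6, index=idx)
        curve = threshold_curve(pdna, flags, fraction=0.15)
        i = np.searchsorted(curve.thresholds, 4.0)
        assert curve.n_below[i] == 4
        assert curve.ratio[i] == pytest.approx(1.0)
        assert curve.expected[i] == pytest.approx(0.6)
        assert curve.predicted_fp[i] == pytest.approx(3.4)

    def test_interleaved_flags_near_zero_fp(self):
        idx = _genes(20)
        pdna = pd.Series(np.arange(20.0), index=idx)
        flags = pd.Series([(i + 1) % 4 == 0 for i in range(20)], index=idx)
        curve = threshold_curve(pdna, flags, fraction=0.25)
        assert np.all(np.abs(curve.predicted_fp) < 1.0)

    def test_monotone_counts(self):
        rng = np.random.default_rng(5)
        idx = _genes(200)
        pdna = pd.Series(rng.lognormal(size=200), index=idx)
        flags = pd.Series(rng.random(200) < 0.15, index=idx)
        flags.iloc[0] = True
        curve = threshold_curve(pdna, flags)
        assert (np.diff(curve.n_below) > 0).all()
        assert (np.diff(curve.ess_below) >= 0).all()

    def test_no_essentials_errors(self):
        idx = _genes(5)
        with pytest.raises(ValueError, match="no essential"):
            threshold_curve(pd.Series(np.arange(5.0), index=idx),
                            pd.Series(False, index=idx))

    def test_duplicate_pdna_values_collapse(self):
        idx = _genes(4)
        pdna = pd.Series([1.0, 1.0, 2.0, 3.0], index=idx)
        flags = pd.Series([True, False, True, False], index=idx)
        curve = threshold_curve(pdna, flags)
        assert curve.thresholds.tolist() == [1.0, 2.0, 3.0]
        assert curve.n_below.tolist() == [2, 3, 4]

    def test_predicted_fp_at_max_threshold_is_floor_residual(self):
        rng = np.random.default_rng(11)
        n = 173
        idx = _genes(n)
        pdna = pd.Series(rng.lognormal(size=n), index=idx)
        k = int(np.floor(0.15 * n))
        flags = pd.Series(False, index=idx)
        flags.iloc[rng.choice(n, size=k, replace=False)] = True
        curve = threshold_curve(pdna, flags, fraction=0.15)
        assert curve.predicted_fp[-1] == pytest.approx(k - 0.15 * n)
        assert abs(curve.predicted_fp[-1]) < 1.0


def _brute_elbow(x, y):
    """Enumerate every point's perpendicular distance to the endpoint chord."""
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    best_i, best_d = 0, -1.0
    for i in range(len(x)):
        d = abs((y1 - y0) * (x[i] - x0) - (x1 - x0) * (y[i] - y0)) / norm
        if d > best_d + 1e-15:
            best_d, best_i = d, i
    return x[best_i]


def _curve_from_xy(x, y, n_below=None):
    n_below = np.arange(1, len(x) + 1) * 200 if n_below is None else n_below
    return ThresholdCurve(thresholds=np.asarray(x, dtype=float),
                          n_below=np.asarray(n_below),
                          ess_below=np.asarray(y, dtype=float) * np.asarray(n_below),
                          fraction=0.15)


class TestDetectElbow:
    def test_worked_three_point_fixture(self):
        curve = _curve_from_xy([0.0, 1.0, 2.0], [0.0, 0.9, 1.0])
        res = detect_elbow(curve, min_genes_below=0)
        assert res.threshold == 1.0
        # frozen from brute-force distance of (1, 0.9) to chord (0,0)-(2,1)
        assert res.distances[1] == pytest.approx(0.8 / np.sqrt(5.0))

    def test_collinear_degenerate(self):
        curve = _curve_from_xy([0.0, 1.0, 2.0, 3.0], [0.0, 1 / 3, 2 / 3, 1.0])
        res = detect_elbow(curve, min_genes_below=0)
        assert res.degenerate
        assert res.threshold == 0.0

    def test_tie_resolves_to_smallest_threshold(self):
        curve = _curve_from_xy([0.0, 1.0, 2.0, 3.0], [0.0, 0.5, 0.5, 0.0])
        res = detect_elbow(curve, min_genes_below=0)
        assert res.threshold == 1.0

    def test_restriction_excludes_low_thresholds(self):
        x = np.array([0.1, 0.5, 1.0, 2.0, 3.0])
        y = np.array([1.0, 0.9, 0.2, 0.15, 0.1])
        n_below = np.array([5, 150, 300, 600, 1000])
        curve = _curve_from_xy(x, y, n_below)
        res = detect_elbow(curve, min_genes_below=100)
        assert res.threshold == _brute_elbow(x[1:], y[1:])

    def test_too_few_points_errors(self):
        curve = _curve_from_xy([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(ValueError, match="at least 3"):
            detect_elbow(curve, min_genes_below=0)

    def test_zero_length_chord_errors(self):
        curve = ThresholdCurve(thresholds=np.array([1.0, 1.0, 1.0]),
                               n_below=np.array([10, 20, 30]),
                               ess_below=np.array([5.0, 10.0, 15.0]),
                               fraction=0.15)
        with pytest.raises(ValueError, match="chord"):
            detect_elbow(curve, min_genes_below=0)

    def test_oracle_equivalence_on_random_monotone_curves(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 60)
            x = np.sort(rng.uniform(0, 100, size=n))
            x += np.arange(n) * 1e-6  # ensure strictly increasing
            y = np.sort(rng.uniform(0, 1, size=n))[::-1] if rng.random() < 0.5 \
                else np.sort(rng.uniform(0, 1, size=n))
            if np.hypot(x[-1] - x[0], y[-1] - y[0]) == 0:
                continue
            curve = _curve_from_xy(x, y)
            res = detect_elbow(curve, min_genes_below=0)
            assert res.threshold == _brute_elbow(x, y)


class TestPerBinFpFn:
    def _partitioned_flags(self, bin_sizes, observed):
        n = sum(bin_sizes)
        idx = _genes(n)
        pdna = pd.Series(np.arange(n, dtype=float), index=idx)
        part = equal_count_bins(pdna, n_bins=len(bin_sizes))
        flags = pd.Series(False, index=idx)
        start = 0
        for size, obs in zip(bin_sizes, observed):
            flags.iloc[start:start + obs] = True
            start += size
        return pdna, flags, part

    def test_worked_three_bin_example(self):
        pdna, flags, part = self._partitioned_flags([100, 100, 100], [30, 15, 0])
        est = per_bin_fp_fn(pdna, flags, part, fraction=0.15)
        assert est.bins["expected"].tolist() == [15, 15, 15]
        assert est.bins["fp"].tolist() == [15, 0, 0]
        assert est.bins["fn"].tolist() == [0, 0, 15]
        assert est.total_fp == 15
        assert est.total_fn == 15
        assert est.total_misclassified == 30

    def test_observed_equals_expected_all_zero(self):
        pdna, flags, part = self._partitioned_flags([100, 100], [15, 15])
        est = per_bin_fp_fn(pdna, flags, part, fraction=0.15)
        assert est.total_fp == 0.0
        assert est.total_fn == 0.0

    def test_fractional_conservation(self):
        pdna, flags, part = self._partitioned_flags([10, 10], [3, 0])
        est = per_bin_fp_fn(pdna, flags, part, fraction=0.15)
        assert est.bins["fp"].tolist() == [1.5, 0.0]
        assert est.bins["fn"].tolist() == [0.0, 1.5]
        assert est.total_fp == est.total_fn

    def test_conservation_exact_when_fraction_exact(self):
        # 300 genes, fraction 0.15 -> essential set of exactly 45
        rng = np.random.default_rng(9)
        idx = _genes(300)
        pdna = pd.Series(rng.lognormal(size=300), index=idx)
        flags = pd.Series(False, index=idx)
        flags.iloc[rng.choice(300, size=45, replace=False)] = True
        part = equal_count_bins(pdna, n_bins=20)
        est = per_bin_fp_fn(pdna, flags, part, fraction=0.15)
        assert est.total_fp == pytest.approx(est.total_fn, abs=1e-9)
        assert est.total_misclassified == pytest.approx(2 * est.total_fp)

    def test_bad_fraction_errors(self):
        pdna, flags, part = self._partitioned_flags([10, 10], [3, 0])
        with pytest.raises(ValueError, match="fraction"):
            per_bin_fp_fn(pdna, flags, part, fraction=1.5)


class TestEcdfKs:
    def test_identical_multisets_d_zero(self):
        idx = _genes(20)
        pdna = pd.Series(list(range(10)) * 2, index=idx, dtype=float)
        flags = pd.Series([True] * 10 + [False] * 10, index=idx)
        out = ecdf_ks(pdna, flags)
        assert out["ks_stat"] == pytest.approx(0.0)

    def test_separated_supports_d_one(self):
        idx = _genes(20)
        pdna = pd.Series(list(range(10)) + list(range(100, 110)), index=idx, dtype=float)
        flags = pd.Series([True] * 10 + [False] * 10, index=idx)
        assert ecdf_ks(pdna, flags)["ks_stat"] == pytest.approx(1.0)

    def test_shift_detected_and_matches_independent_ks(self):
        rng = np.random.default_rng(1)
        n = 1000
        non = rng.lognormal(size=n)
        ess = rng.lognormal(size=n) * 0.7  # constant shift in log space
        idx = _genes(2 * n)
        pdna = pd.Series(np.concatenate([ess, non]), index=idx)
        flags = pd.Series([True] * n + [False] * n, index=idx)
        out = ecdf_ks(pdna, flags)
        assert out["ks_stat"] > 0
        assert out["ks_p"] < 0.05
        # independent oracle: sup over pooled values of |ECDF difference|
        pooled = np.sort(np.concatenate([ess, non]))
        d = np.max(np.abs(np.searchsorted(np.sort(ess), pooled, side="right") / n
                          - np.searchsorted(np.sort(non), pooled, side="right") / n))
        assert out["ks_stat"] == pytest.approx(d)

    def test_empty_group_errors(self):
        idx = _genes(5)
        pdna = pd.Series(np.arange(5.0), index=idx)
        with pytest.raises(ValueError, match="non-empty"):
            ecdf_ks(pdna, pd.Series(True, index=idx))


def test_full_estimate_includes_elbow_and_ks():
    rng = np.random.default_rng(2)
    n = 600
    idx = _genes(n)
    pdna = pd.Series(rng.lognormal(sigma=1.2, size=n) * 100, index=idx)
    # essentials skewed toward low representation
    prob = 1.0 / (1.0 + pdna.rank().to_numpy())
    flags_idx = rng.choice(n, size=90, replace=False, p=prob / prob.sum())
    flags = pd.Series(False, index=idx)
    flags.iloc[flags_idx] = True
    part = equal_count_bins(pdna, 20)
    est = estimate(pdna, flags, part, fraction=0.15, min_genes_below=50)
    assert est.elbow_threshold is not None
    assert 0 <= est.ks_stat <= 1
    assert est.total_fp > 0
    d = est.to_dict()
    assert set(d) >= {"fraction", "total_fp", "total_fn", "elbow_threshold", "ks", "bins"}
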
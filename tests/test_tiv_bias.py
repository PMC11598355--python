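"""TIV bias audit: tertile mechanics, KDE overlap vs a dense-grid oracle,
and the balanced correctly-classified subset."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainsexmap.errors import DegenerateInputError
from brainsexmap.evaluation import make_predictions
from brainsexmap.tiv_bias import (balanced_correct_subset, kde_overlap,
                                  tertile_performance, tiv_tertiles)


def brute_force_overlap(f, m, threshold, grid_points=4096):
    """Independent oracle: evaluate both Gaussian KDEs by the explicit
    sum-of-kernels formula on a very dense grid."""
    def kde(x, data):
        n = len(data)
        h = data.std(ddof=1) * n ** (-1 / 5)          # Scott's rule, 1D
        return np.mean(np.exp(-0.5 * ((x[:, None] - data) / h) ** 2), axis=1) \
            / (h * np.sqrt(2 * np.pi)), h
    pad = 3 * max(np.std(f, ddof=1), np.std(m, ddof=1))
    grid = np.linspace(min(f.min(), m.min()) - pad,
                       max(f.max(), m.max()) + pad, grid_points)
    bounds = []
    for data in (f, m):
        d, _ = kde(grid, data)
        idx = np.flatnonzero(d >= threshold * d.max())
        bounds.append((grid[idx[0]], grid[idx[-1]]))
    return max(bounds[0][0], bounds[1][0]), min(bounds[0][1], bounds[1][1])


class TestTertiles:
    @pytest.mark.parametrize("n,sizes", [(210, (70, 70, 70)),
                                         (3, (1, 1, 1)),
                                         (211, (71, 70, 70))])
    def test_sizes(self, rng, n, sizes):
        assignment, _ = tiv_tertiles(rng.normal(1500, 100, n))
        assert tuple(np.bincount(assignment)) == sizes

    def test_matches_sorting_oracle(self, rng):
        tivs = rng.normal(1500, 100, 211)
        assignment, ranges = tiv_tertiles(tivs)
        order = sorted(range(211), key=lambda i: tivs[i])
        expect = np.empty(211, dtype=int)
        for k, lo in enumerate((0, 71, 141)):
            hi = (71, 141, 211)[k]
            for i in order[lo:hi]:
                expect[i] = k
        assert np.array_equal(assignment, expect)
        assert ranges[0][1] <= ranges[1][0] and ranges[1][1] <= ranges[2][0]

    def test_too_few_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            tiv_tertiles([1400.0, 1500.0])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(500, 2500), min_size=3, max_size=200))
    def test_partition_property(self, tivs):
        """Tertiles partition the sample, sizes within one of each other,
        and the value ranges are ordered."""
        assignment, ranges = tiv_tertiles(tivs)
        sizes = np.bincount(assignment, minlength=3)
        assert sizes.sum() == len(tivs)
        assert sizes.max() - sizes.min() <= 1
        assert ranges[0][1] <= ranges[1][0] and ranges[1][1] <= ranges[2][0]


class TestTertilePerformance:
    def test_perfect_classifier_all_ones(self, rng):
        true = np.where(rng.random(90) > 0.5, "M", "F")
        prob = np.where(true == "M", 0.9, 0.1)
        preds = make_predictions(range(90), prob, true)
        table = tertile_performance(preds, rng.normal(1500, 100, 90))
        assert (table["balanced_accuracy"] == 1.0).all()

    def test_missing_sex_flagged_undefined(self):
        true = ["F"] * 30 + ["M"] * 60
        prob = [0.1] * 30 + [0.9] * 60
        tivs = np.concatenate([np.linspace(1000, 1100, 30),
                               np.linspace(1400, 1900, 60)])
        table = tertile_performance(
            make_predictions(range(90), prob, true), tivs)
        first = table.iloc[0]
        assert math.isnan(first["recall_male"])
        assert math.isnan(first["balanced_accuracy"])
        assert first["flag"]

    def test_rows_aggregate_to_global_confusion(self, rng):
        preds = make_predictions(range(210), rng.random(210),
                                 np.where(rng.random(210) > 0.5, "M", "F"))
        tivs = rng.normal(1500, 100, 210)
        table = tertile_performance(preds, tivs)
        assert table["n"].sum() == 210
        assert table["n_female"].sum() == (preds["true"] == "F").sum()
        # recompose correct-classification counts
        correct = ((preds["pred"] == preds["true"])).sum()
        recomposed = (table["recall_female"] * table["n_female"]
                      + table["recall_male"] * table["n_male"]).sum()
        assert recomposed == pytest.approx(correct)


class TestKdeOverlap:
    def test_identical_samples_return_own_support(self, rng):
        x = rng.normal(1500, 80, 105)
        iv = kde_overlap(x, x)
        lo, hi = brute_force_overlap(x, x, 0.2)
        step = (np.ptp(x) + 6 * 80) / 512
        assert iv.lo == pytest.approx(lo, abs=2 * step)
        assert iv.hi == pytest.approx(hi, abs=2 * step)

    def test_matches_dense_grid_oracle(self, rng):
        f = rng.normal(1300, 60, 105)
        m = rng.normal(1500, 60, 105)
        iv = kde_overlap(f, m)
        lo, hi = brute_force_overlap(f, m, 0.2)
        span = max(f.max(), m.max()) - min(f.min(), m.min()) + 6 * 60
        step = span / 512
        assert iv.lo == pytest.approx(lo, abs=2 * step)
        assert iv.hi == pytest.approx(hi, abs=2 * step)
        assert iv.bandwidth_f > 0 and iv.bandwidth_m > 0

    def test_disjoint_distributions_empty(self, rng):
        f = rng.normal(1000, 10, 50)
        m = rng.normal(2000, 10, 50)
        iv = kde_overlap(f, m)
        assert iv.empty

    def test_threshold_monotonicity(self, rng):
        f = rng.normal(1300, 80, 105)
        m = rng.normal(1450, 80, 105)
        widths = []
        for thr in (0.1, 0.2, 0.4, 0.6):
            iv = kde_overlap(f, m, threshold=thr)
            widths.append(-1.0 if iv.empty else iv.hi - iv.lo)
        assert all(a >= b for a, b in zip(widths, widths[1:]))


class TestBalancedSubset:
    def _interval(self):
        from brainsexmap.tiv_bias import OverlapInterval
        return OverlapInterval(1300.0, 1700.0, 0.2, 50.0, 50.0)

    def test_all_correct_balanced_kept(self, rng):
        true = ["F"] * 5 + ["M"] * 5
        prob = [0.1] * 5 + [0.9] * 5
        preds = make_predictions(range(10), prob, true)
        ids = balanced_correct_subset(preds, [1500.0] * 10, self._interval(), rng)
        assert len(ids) == 10

    def test_downsampling_reproducible(self):
        true = ["F"] * 10 + ["M"] * 6
        prob = [0.1] * 10 + [0.9] * 6
        preds = make_predictions(range(16), prob, true)
        tivs = [1500.0] * 16
        a = balanced_correct_subset(preds, tivs, self._interval(),
                                    np.random.default_rng(3))
        b = balanced_correct_subset(preds, tivs, self._interval(),
                                    np.random.default_rng(3))
        assert a == b and len(a) == 12
        f = [s for s in a if int(s) < 10]
        assert len(f) == 6

    def test_missing_sex_empty(self, rng):
        true = ["F"] * 5 + ["M"] * 3
        prob = [0.1] * 5 + [0.1] * 3           # all males misclassified
        preds = make_predictions(range(8), prob, true)
        ids = balanced_correct_subset(preds, [1500.0] * 8, self._interval(), rng)
        assert ids == []
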
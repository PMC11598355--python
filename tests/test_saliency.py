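"""Saliency maps: normalisation contract, aggregation arithmetic, rank
correlation, and gradient correctness."""

import numpy as np
import pytest
from scipy import stats

from brainsexmap.errors import DegenerateInputError
from brainsexmap.evaluation import make_predictions
from brainsexmap.saliency import (SaliencyMap, average_maps,
                                  gradient_saliency, minmax_normalize,
                                  sexwise_average, spearman_maps)
from brainsexmap.sfcn import build_sfcn

TINY = (2, 2, 2, 2, 2, 2)


@pytest.fixture(scope="module")
def tiny_model():
    return build_sfcn((32, 32, 32), channels=TINY, seed=3)


class TestGradientSaliency:
    def test_normalization_contract(self, tiny_model, rng):
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        mask = np.zeros((32, 32, 32), dtype=bool)
        mask[4:28, 4:28, 4:28] = True
        smap = gradient_saliency(tiny_model, x, mask)
        assert smap.state == "minmax"
        assert smap.values[mask].min() == 0.0
        assert smap.values[mask].max() == pytest.approx(1.0)
        assert np.all(smap.values[~mask] == 0.0)

    def test_class_sign_invariance(self, tiny_model, rng):
        """A single-logit model gives identical magnitude maps whichever
        class is targeted: negating the head flips only the sign."""
        x = rng.normal(size=(1, 32, 32, 32)).astype(np.float32)
        g_male = tiny_model.input_gradient(x)
        head = tiny_model.net.layers[-1]
        head.w *= -1.0
        head.b *= -1.0
        try:
            g_female = tiny_model.input_gradient(x)
        finally:
            head.w *= -1.0
            head.b *= -1.0
        assert np.allclose(np.abs(g_male), np.abs(g_female), atol=1e-6)

    def test_gradient_matches_finite_differences(self, tiny_model, rng):
        x = rng.normal(size=(32, 32, 32)).astype(np.float32)
        g = tiny_model.input_gradient(x[None])[0]
        eps = 0.05          # float32 logits: a large step beats roundoff
        for _ in range(10):
            idx = tuple(int(rng.integers(32)) for _ in range(3))
            xp, xm = x.copy(), x.copy()
            xp[idx] += eps
            xm[idx] -= eps
            fd = (tiny_model.logits(xp[None])[0]
                  - tiny_model.logits(xm[None])[0]) / (2 * eps)
            assert g[idx] == pytest.approx(fd, abs=5e-3)


class TestAveraging:
    def _mask(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:5, 1:5, 1:5] = True
        return m

    def test_identical_maps_idempotent(self, rng):
        mask = self._mask()
        m = SaliencyMap(minmax_normalize(
            rng.random((6, 6, 6)).astype(np.float32), mask), "minmax")
        out = average_maps([m, m, m], mask)
        assert np.allclose(out.values, m.values, atol=1e-6)

    def test_two_one_hot_maps_mean_half_before_renorm(self):
        mask = self._mask()
        a = np.zeros((6, 6, 6), dtype=np.float32)
        b = np.zeros((6, 6, 6), dtype=np.float32)
        a[2, 2, 2] = 1.0
        b[3, 3, 3] = 1.0
        out = average_maps([SaliencyMap(a, "minmax"), SaliencyMap(b, "minmax")],
                           mask, renormalize=False)
        assert out.values[2, 2, 2] == 0.5 and out.values[3, 3, 3] == 0.5

    def test_matches_elementwise_mean_oracle(self, rng):
        mask = self._mask()
        maps = [rng.random((6, 6, 6)).astype(np.float32) for _ in range(50)]
        out = average_maps([SaliencyMap(m, "minmax") for m in maps],
                           mask, renormalize=False)
        assert np.allclose(out.values, np.mean(maps, axis=0), atol=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            average_maps([], self._mask())

    def test_averaging_commutes_with_masking(self, rng):
        mask = self._mask()
        maps = [rng.random((6, 6, 6)).astype(np.float32) for _ in range(5)]
        mean_then_mask = np.mean(maps, axis=0) * mask
        masked_then_mean = np.mean([m * mask for m in maps], axis=0)
        assert np.allclose(mean_then_mask, masked_then_mean, atol=1e-7)


class TestSexwiseAverage:
    def test_misclassified_subject_excluded(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        ids = ["f1", "f2", "f3", "m1"]
        maps = {s: SaliencyMap(minmax_normalize(
            rng.random((4, 4, 4)).astype(np.float32), mask), "minmax")
            for s in ids}
        # f3 misclassified as male
        preds = make_predictions(ids, [0.1, 0.2, 0.9, 0.8],
                                 ["F", "F", "F", "M"])
        map_f, map_m = sexwise_average(maps, preds, mask, renormalize=False)
        expect_f = np.mean([maps["f1"].values, maps["f2"].values], axis=0)
        assert np.allclose(map_f.values, expect_f, atol=1e-6)
        assert np.allclose(map_m.values, maps["m1"].values, atol=1e-6)

    def test_sex_without_correct_predictions_absent(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        maps = {"f1": SaliencyMap(minmax_normalize(
            rng.random((4, 4, 4)).astype(np.float32), mask), "minmax")}
        preds = make_predictions(["f1"], [0.9], ["F"])   # wrong
        map_f, map_m = sexwise_average(maps, preds, mask)
        assert map_f is None and map_m is None


class TestSpearman:
    def test_identical_and_reversed(self, rng):
        mask = np.ones((10, 10, 10), dtype=bool)
        a = rng.random((10, 10, 10))
        assert spearman_maps(a, a, mask) == pytest.approx(1.0)
        assert spearman_maps(a, -a, mask) == pytest.approx(-1.0)

    def test_matches_pearson_of_ranks(self, rng):
        mask = np.ones((10, 10, 10), dtype=bool)
        a = rng.random((10, 10, 10))
        b = rng.random((10, 10, 10))
        rho = spearman_maps(a, b, mask)
        ra = stats.rankdata(a.ravel())
        rb = stats.rankdata(b.ravel())
        expect = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(expect, abs=1e-12)

    def test_constant_map_rejected(self):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(DegenerateInputError):
            spearman_maps(np.ones((4, 4, 4)), np.random.rand(4, 4, 4), mask)


class TestEndToEndRecovery:
    def test_planted_regions_carry_more_saliency(self, effect_runs):
        """The composite map must concentrate saliency inside the planted
        effect regions relative to the rest of the brain, in every seed."""
        for run in effect_runs:
            atlas = run["atlas"]
            comp = run["composite"].values
            mask = run["mask"]
            planted = np.isin(atlas.labels, (1, 2, 3))
            rest = mask & ~planted
            assert comp[planted & mask].mean() > comp[rest].mean()

    def test_per_sex_maps_strongly_rank_correlated(self, effect_runs):
        """Female- and male-derived maps of one model rank voxels similarly
        (the single-logit gradient differs across subjects only through the
        input)."""
        run = effect_runs[0]
        map_f, map_m = sexwise_average(run["maps"], run["preds"], run["mask"])
        if map_f is None or map_m is None:
            pytest.skip("a sex had no correctly classified subjects")
        rho = spearman_maps(map_f, map_m, run["mask"])
        assert rho > 0.5
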
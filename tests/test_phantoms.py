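"""Synthetic cohort generator: determinism, TIV fidelity, signal isolation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from brainsexmap.errors import SizingError
from brainsexmap.phantoms import (PhantomConfig, STUDY_DEMOGRAPHICS,
                                  generate_cohort, make_atlas, make_phantom,
                                  simulate_metadata)


class TestMakeAtlas:
    def test_regions_disjoint_and_labeled(self):
        atlas = make_atlas((32, 32, 32), 2, seed=1, envelope_tiv_ml=80.0)
        assert sorted(np.unique(atlas.labels)) == [0, 1, 2]
        # disjointness is implied by a single label per voxel; check both
        # regions are nonempty and named
        assert all((atlas.labels == r).sum() > 0 for r in (1, 2))
        assert set(atlas.names) == {1, 2}

    def test_deterministic(self):
        a = make_atlas((32, 32, 32), 3, seed=7, envelope_tiv_ml=80.0)
        b = make_atlas((32, 32, 32), 3, seed=7, envelope_tiv_ml=80.0)
        assert np.array_equal(a.labels, b.labels)

    def test_region_volumes_by_voxel_count(self):
        atlas = make_atlas((32, 32, 32), 4, seed=3, envelope_tiv_ml=80.0)
        for r in range(1, 5):
            # brute-force voxel count per label
            count = int(np.sum(atlas.labels == r))
            assert count >= 4, f"region {r} implausibly small ({count} voxels)"

    def test_regions_inside_smallest_brain(self, small_atlas, small_cohort):
        _, _, volumes = small_cohort
        region = small_atlas.labels > 0
        for vol, mask in volumes.values():
            assert np.all(mask[region]), "atlas region left the brain mask"


class TestGenerateCohort:
    def test_empty_cohort(self):
        cfg = PhantomConfig(n_subjects=0)
        table, volumes = generate_cohort(cfg, None)
        assert table.empty and volumes == {}

    def test_negative_n_rejected(self):
        with pytest.raises(ValueError, match="n_subjects"):
            PhantomConfig(n_subjects=-1).validate()

    def test_deterministic_tables_and_grids(self, small_atlas):
        cfg = PhantomConfig(n_subjects=4, grid_shape=(32, 32, 32),
                            tiv_mean_male=120.0, tiv_sd=8.0, seed=3)
        t1, v1 = generate_cohort(cfg, small_atlas)
        t2, v2 = generate_cohort(cfg, small_atlas)
        pd.testing.assert_frame_equal(t1, t2)
        for sid in t1["subject_id"]:
            assert np.array_equal(v1[sid][0].data, v2[sid][0].data)

    def test_tiv_ratio_calibrated_against_monte_carlo_band(self):
        """The female/male TIV mean ratio at n=400 must be distributed
        around (1 - deficit) = 0.875: the generator's own Monte-Carlo 95%
        band covers 0.875, and fresh draws fall inside that band at roughly
        the nominal rate."""
        ratios = []
        for s in range(200):
            t = simulate_metadata(PhantomConfig(n_subjects=400, seed=10_000 + s))
            ratios.append(t.loc[t.sex == "F", "tiv_ml"].mean()
                          / t.loc[t.sex == "M", "tiv_ml"].mean())
        lo, hi = np.percentile(ratios, [2.5, 97.5])
        assert lo < 0.875 < hi
        fresh = []
        for s in range(40):
            t = simulate_metadata(PhantomConfig(n_subjects=400, seed=77_000 + s))
            fresh.append(t.loc[t.sex == "F", "tiv_ml"].mean()
                         / t.loc[t.sex == "M", "tiv_ml"].mean())
        inside = np.mean([(lo <= r <= hi) for r in fresh])
        assert inside >= 0.8

    def test_pooled_demographics_female_share(self):
        cfg = PhantomConfig(n_subjects=STUDY_DEMOGRAPHICS["n_subjects"],
                            female_fraction=STUDY_DEMOGRAPHICS["female_fraction"],
                            seed=0)
        table = simulate_metadata(cfg)
        share = (table.sex == "F").mean()
        assert round(100 * share) == 53


class TestMakePhantom:
    def test_mask_inside_grid(self, small_cohort):
        _, _, volumes = small_cohort
        for vol, mask in volumes.values():
            assert mask.any()
            # no mask voxel on any grid face
            assert not mask[0].any() and not mask[-1].any()
            assert not mask[:, 0].any() and not mask[:, -1].any()
            assert not mask[:, :, 0].any() and not mask[:, :, -1].any()

    def test_background_exactly_zero(self, small_cohort):
        _, _, volumes = small_cohort
        vol, mask = next(iter(volumes.values()))
        assert np.all(vol.data[~mask] == 0.0)

    def test_tiv_fidelity_large_brain_coarse_grid(self):
        cfg = PhantomConfig(grid_shape=(48, 48, 48), voxel_mm=4.0)
        rng = np.random.default_rng(0)
        vol, mask = make_phantom("M", 1200.0, None, cfg, rng)
        counted = mask.sum() * cfg.voxel_mm ** 3 / 1000.0
        assert abs(counted - 1200.0) / 1200.0 <= 0.02

    def test_mask_volume_fidelity_across_cohort(self, small_cohort):
        cfg, table, volumes = small_cohort
        for row in table.itertuples():
            _, mask = volumes[row.subject_id]
            counted = mask.sum() * cfg.voxel_mm ** 3 / 1000.0
            assert abs(counted - row.tiv_ml) / row.tiv_ml <= 0.02

    def test_oversized_brain_rejected(self):
        cfg = PhantomConfig(grid_shape=(32, 32, 32), voxel_mm=3.0)
        with pytest.raises(SizingError):
            make_phantom("F", 2000.0, None, cfg, np.random.default_rng(0))

    def test_no_effect_means_no_regional_sex_difference(self, small_atlas):
        """With effect_size 0 the sexes differ only by TIV scaling and
        noise: paired region means are statistically indistinguishable."""
        cfg = PhantomConfig(grid_shape=(32, 32, 32), tiv_mean_male=120.0,
                            effect_regions=(1,), effect_size=0.0,
                            noise_sd=0.05)
        rng = np.random.default_rng(1)
        region = small_atlas.region_mask(1)
        f_means, m_means = [], []
        for _ in range(50):
            vf, _ = make_phantom("F", 110.0, small_atlas, cfg, rng)
            vm, _ = make_phantom("M", 110.0, small_atlas, cfg, rng)
            f_means.append(vf.data[region].mean())
            m_means.append(vm.data[region].mean())
        p = stats.ttest_ind(f_means, m_means).pvalue
        assert p > 0.01

    def test_effect_shifts_only_target_sex(self, small_atlas):
        cfg = PhantomConfig(grid_shape=(32, 32, 32), tiv_mean_male=120.0,
                            effect_regions=(1,), effect_size=0.3,
                            effect_sex="F", noise_sd=0.0)
        rng = np.random.default_rng(2)
        region = small_atlas.region_mask(1)
        vf, _ = make_phantom("F", 110.0, small_atlas, cfg, rng)
        vm, _ = make_phantom("M", 110.0, small_atlas, cfg, rng)
        assert vf.data[region].mean() - vm.data[region].mean() \
            == pytest.approx(0.3, abs=1e-5)


class TestConfoundControl:
    def test_tiv_exchangeable_when_deficit_zero(self):
        """With no deficit the sexes' TIV distributions coincide: KS p-values
        over repeated seeds behave like draws from a uniform, not piling up
        near zero."""
        pvals = []
        for s in range(20):
            t = simulate_metadata(PhantomConfig(
                n_subjects=200, tiv_deficit_female=0.0, seed=500 + s))
            pvals.append(stats.ks_2samp(t.loc[t.sex == "F", "tiv_ml"],
                                        t.loc[t.sex == "M", "tiv_ml"]).pvalue)
        assert np.mean(np.asarray(pvals) < 0.05) <= 0.25
        assert max(pvals) > 0.5

    def test_deficit_separates_tiv(self):
        t = simulate_metadata(PhantomConfig(n_subjects=200,
                                            tiv_deficit_female=0.125, seed=6))
        p = stats.ks_2samp(t.loc[t.sex == "F", "tiv_ml"],
                           t.loc[t.sex == "M", "tiv_ml"]).pvalue
        assert p < 1e-6
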
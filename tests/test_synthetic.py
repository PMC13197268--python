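"""Atlas geometry, resection growth, image signal model and outcome model."""

import numpy as np
import pandas as pd
import pytest

import lesionmap as lm
from lesionmap.errors import AtlasSizingError, ConfigurationError
from lesionmap.synthetic import (
    DEFAULT_TISSUE_MEANS,
    CohortConfig,
    EffectSpec,
    generate_cohort,
    generate_cohort_arrays,
    outcome_probabilities,
    simulate_outcomes,
    substream,
)
from lesionmap.volumes import REQUIRED_REGIONS


class TestMakeAtlas:
    def test_mirror_symmetric_counts_and_minimum_sizes(self, atlas):
        counts = np.bincount(atlas.labels.ravel())
        for i, name in enumerate(REQUIRED_REGIONS):
            left, right = counts[i + 1], counts[i + 1 + len(REQUIRED_REGIONS)]
            assert left == right, name
            assert left >= 20, name

    def test_mirror_symmetric_voxelwise(self, atlas):
        nx = atlas.shape[0]
        left = atlas.labels[: nx // 2]
        right = atlas.labels[nx // 2 :][::-1]
        assert np.array_equal(left > 0, right > 0)
        assert np.array_equal(
            np.where(left > 0, left + len(REQUIRED_REGIONS), 0), right
        )

    def test_deterministic(self):
        a = lm.make_atlas((48, 56, 48), seed=1)
        b = lm.make_atlas((48, 56, 48), seed=1)
        assert np.array_equal(a.labels, b.labels)
        assert a.label_table == b.label_table

    def test_minimum_grid_and_sizing_errors(self):
        # the smallest allowed grid still hosts every region
        small = lm.make_atlas((24, 24, 24), seed=1)
        counts = np.bincount(small.labels.ravel())
        assert all(counts[lab] >= 20 for lab in small.label_table)
        with pytest.raises(AtlasSizingError):
            lm.make_atlas((22, 24, 24), seed=1)
        with pytest.raises(AtlasSizingError, match="even"):
            lm.make_atlas((47, 56, 48), seed=1)


class TestSimulateResection:
    def test_full_extent_atlr_covers_mesial_targets(self, atlas):
        mask = lm.simulate_resection(atlas, "left", "ATLR", 1.0, seed=3)
        assert mask.dtype == np.uint8 and set(np.unique(mask)) <= {0, 1}
        for region in ("amygdala", "hippocampus_head"):
            roi = atlas.region_mask(region, "left")
            assert mask[roi].all(), region

    def test_extent_monotone_growth(self, atlas):
        sizes = [
            lm.simulate_resection(atlas, "left", "SAHE", e, seed=3).sum()
            for e in (0.05, 0.4, 1.0)
        ]
        assert sizes[0] < sizes[1] < sizes[2]

    def test_atlr_larger_than_sahe_at_equal_extent(self, atlas):
        vols_a = [lm.simulate_resection(atlas, "left", "ATLR", 0.7, seed=s).sum() for s in range(5)]
        vols_s = [lm.simulate_resection(atlas, "left", "SAHE", 0.7, seed=s).sum() for s in range(5)]
        assert np.mean(vols_a) > np.mean(vols_s)

    def test_respects_hemisphere(self, atlas):
        nx = atlas.shape[0]
        right = lm.simulate_resection(atlas, "right", "ATLR", 0.9, seed=4)
        assert right[: nx // 2].sum() == 0
        left = lm.simulate_resection(atlas, "left", "lesionectomy", 0.9, seed=4)
        assert left[nx // 2 :].sum() == 0

    def test_single_connected_component(self, atlas):
        from scipy import ndimage

        for surgery in ("ATLR", "SAHE", "tailored", "lesionectomy"):
            mask = lm.simulate_resection(atlas, "left", surgery, 0.6, seed=9)
            assert ndimage.label(mask > 0, np.ones((3, 3, 3), bool))[1] == 1

    def test_extent_domain_error(self, atlas):
        for bad in (0.0, -0.2, 1.2):
            with pytest.raises(ValueError):
                lm.simulate_resection(atlas, "left", "ATLR", bad, seed=1)


class TestSimulateImages:
    def test_noise_free_difference_is_exact(self, atlas):
        mask = lm.simulate_resection(atlas, "left", "SAHE", 0.5, seed=2)
        pre, post = lm.simulate_images(atlas, mask, drop=40.0, noise_sd=0.0, seed=0)
        diff = post - pre
        assert np.allclose(diff[mask > 0], -40.0)
        assert np.allclose(diff[mask == 0], 0.0)

    def test_noisy_difference_mean(self, atlas):
        mask = lm.simulate_resection(atlas, "left", "ATLR", 1.0, seed=2)
        n_res = int(mask.sum())
        pre, post = lm.simulate_images(atlas, mask, drop=40.0, noise_sd=5.0, seed=0)
        diffs = (post - pre)[mask > 0]
        se = np.sqrt(2 * 5.0**2 / n_res)
        assert abs(diffs.mean() + 40.0) < 3 * se

    def test_empty_mask_null_case(self, atlas):
        empty = np.zeros(atlas.shape, dtype=np.uint8)
        pre, post = lm.simulate_images(atlas, empty, drop=40.0, noise_sd=0.0, seed=0)
        assert np.array_equal(pre, post)
        est = lm.delineate_resection(
            lm.normalize_intensity(pre, atlas.brain_mask()),
            lm.normalize_intensity(post, atlas.brain_mask()),
            atlas,
        )
        assert est.sum() == 0

    def test_missing_tissue_mean_raises(self, atlas):
        means = {k: v for k, v in DEFAULT_TISSUE_MEANS.items() if k != "amygdala"}
        mask = np.zeros(atlas.shape, dtype=np.uint8)
        with pytest.raises(ConfigurationError, match="amygdala"):
            lm.simulate_images(atlas, mask, tissue_means=means)

    def test_low_contrast_warns(self, atlas):
        mask = np.zeros(atlas.shape, dtype=np.uint8)
        with pytest.warns(UserWarning, match="drop"):
            lm.simulate_images(atlas, mask, drop=5.0, noise_sd=5.0, seed=0)


class TestSimulateOutcomes:
    @staticmethod
    def _null_inputs(n, rng):
        cov = pd.DataFrame(
            {
                "sex": rng.choice(["male", "female"], n),
                "surgery": rng.choice(["ATLR", "SAHE"], n),
                "lesion": rng.choice(["HS", "other"], n),
                "total_resection_volume": rng.random(n) * 1e4,
            }
        )
        frac = pd.DataFrame({"hippocampus": rng.random(n)})
        return cov, frac

    def test_null_rate_half(self, rng):
        cov, frac = self._null_inputs(10_000, rng)
        ilae = simulate_outcomes(cov, frac, EffectSpec(intercept=0.0), seed=0)
        assert set(np.unique(ilae)) <= {1, 2}
        assert abs((ilae == 1).mean() - 0.5) < 0.015

    def test_discovery_marginal_rate(self, rng):
        # intercept = logit(0.429) reproduces the 42.9% seizure-free marginal
        cov, frac = self._null_inputs(10_000, rng)
        spec = EffectSpec(intercept=float(np.log(0.429 / 0.571)))
        ilae = simulate_outcomes(cov, frac, spec, seed=1)
        assert abs((ilae == 1).mean() - 0.429) < 0.015

    def test_saturating_effect(self, rng):
        cov, frac = self._null_inputs(2000, rng)
        frac["hippocampus"] = (frac["hippocampus"] > 0.5).astype(float)
        spec = EffectSpec(intercept=-10.0, region_effects={"hippocampus": 20.0})
        ilae = simulate_outcomes(cov, frac, spec, seed=2)
        agree = (ilae == 1) == (frac["hippocampus"] > 0.5)
        assert agree.mean() > 0.995

    def test_region_missing_from_table_raises(self, rng):
        cov, frac = self._null_inputs(10, rng)
        spec = EffectSpec(region_effects={"amygdala": 1.0})
        with pytest.raises(ConfigurationError, match="amygdala"):
            outcome_probabilities(cov, frac, spec)

    def test_deterministic_for_seed(self, rng):
        cov, frac = self._null_inputs(200, rng)
        a = simulate_outcomes(cov, frac, EffectSpec(), seed=5)
        b = simulate_outcomes(cov, frac, EffectSpec(), seed=5)
        assert np.array_equal(a, b)


class TestGenerateCohort:
    def test_discovery_mixture_tally(self, tmp_path):
        cfg = CohortConfig(
            n=28,
            surgery_mix={"SAHE": 22 / 28, "ATLR": 3 / 28, "tailored": 3 / 28},
            grid_shape=(32, 32, 32),
        )
        cohort = generate_cohort(cfg, seed=11, out_dir=tmp_path / "d")
        tally = cohort.table["surgery"].value_counts().to_dict()
        assert tally == {"SAHE": 22, "ATLR": 3, "tailored": 3}
        assert len(cohort) == 28

    def test_zero_subjects_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_cohort(CohortConfig(n=0), seed=1, out_dir=tmp_path)

    def test_reproducible_tsv_and_masks(self, tmp_path):
        cfg = CohortConfig(n=6, grid_shape=(32, 32, 32))
        c1 = generate_cohort(cfg, seed=3, out_dir=tmp_path / "a")
        c2 = generate_cohort(cfg, seed=3, out_dir=tmp_path / "b")
        tsv1 = (tmp_path / "a" / "cohort.tsv").read_bytes()
        tsv2 = (tmp_path / "b" / "cohort.tsv").read_bytes()
        assert tsv1 == tsv2
        m1, _ = c1.load_masks()
        m2, _ = c2.load_masks()
        assert np.array_equal(m1, m2)

    def test_substreams_are_order_independent(self):
        a = substream(5, "subject", "sub-0001").integers(2**31)
        substream(5, "other", "op")
        b = substream(5, "subject", "sub-0001").integers(2**31)
        assert a == b


def test_marginal_rate_matches_analytic_expectation():
    """Outcome marginal converges to the mean of the analytic probabilities."""
    cfg = CohortConfig(n=1000, grid_shape=(32, 32, 32))
    table, masks, atlas = generate_cohort_arrays(cfg, seed=21)
    from lesionmap.volumetrics import percent_resected_table

    frac = percent_resected_table(masks, atlas, table["laterality"]) / 100.0
    p = outcome_probabilities(table, frac, cfg.effects)
    rate = (table["ilae_class"] == 1).mean()
    se = np.sqrt((p * (1 - p)).sum()) / len(p)
    assert abs(rate - p.mean()) < 4 * max(se, 1e-3)
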
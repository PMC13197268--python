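"""Voxelwise logistic mapping: design encoding, fits, clusters, permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import lesionmap as lm
from lesionmap.synthetic import generate_cohort_arrays
from lesionmap.vlom import (
    DesignMatrix,
    _batched_logistic,
    build_design,
    cluster_mass_permutation,
    fit_voxel_logistic,
    flip_right_to_left,
    label_clusters,
    voxel_inclusion_mask,
)

from .oracles import flood_fill_clusters, logit_2x2_beta


def _table(n, rng, balanced=True):
    t = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "sex": rng.choice(["male", "female"], n),
            "laterality": ["left"] * n,
            "surgery": rng.choice(["ATLR", "lesionectomy"], n),
            "lesion": rng.choice(["HS", "other"], n),
            "ilae_class": rng.choice([1, 2], n),
            "follow_up_years": np.round(rng.uniform(1, 8, n), 1),
        }
    )
    if balanced:
        t.loc[0, "ilae_class"] = 1
        t.loc[1, "ilae_class"] = 2
    return t


class TestBuildDesign:
    def test_outcome_and_encodings(self, rng):
        t = _table(40, rng)
        masks = rng.random((40, 6, 6, 6)) < 0.3
        d = build_design(t, masks, np.diag([2.0, 2.0, 2.0, 1.0]))
        assert d.outcome.sum() == (t["ilae_class"] == 1).sum()
        vol_col = d.names.index("resection_volume")
        assert abs(d.covariates[:, vol_col].mean()) < 1e-12
        assert abs(d.covariates[:, vol_col].std() - 1.0) < 1e-12
        assert set(np.unique(d.covariates[:, d.names.index("sex_female")])) <= {0.0, 1.0}

    def test_constant_column_dropped_with_warning(self, rng):
        t = _table(30, rng)
        t["sex"] = "female"
        masks = rng.random((30, 5, 5, 5)) < 0.4
        with pytest.warns(UserWarning, match="sex_female"):
            d = build_design(t, masks, np.eye(4))
        assert "sex_female" in d.dropped and "sex_female" not in d.names

    def test_single_class_outcome_rejected(self, rng):
        t = _table(20, rng, balanced=False)
        t["ilae_class"] = 2
        with pytest.raises(ValueError, match="single class"):
            build_design(t, np.zeros((20, 4, 4, 4), bool), np.eye(4))


class TestVoxelInclusion:
    def test_no_contrast_voxels_excluded(self):
        masks = np.zeros((30, 4, 4, 4), bool)
        masks[:, 0, 0, 0] = True  # resected in everyone
        masks[:15, 1, 1, 1] = True  # balanced 15/15
        tested = voxel_inclusion_mask(masks, min_per_cell=10)
        assert not tested[0, 0, 0]
        assert tested[1, 1, 1]
        assert not tested[2, 2, 2]  # resected in nobody

    def test_tested_subset_of_union_minus_intersection(self, rng):
        masks = rng.random((60, 8, 8, 8)) < rng.uniform(0.1, 0.9, (60, 1, 1, 1))
        tested = voxel_inclusion_mask(masks, min_per_cell=10)
        union = masks.any(0)
        inter = masks.all(0)
        assert not np.any(tested & ~union)
        assert not np.any(tested & inter)


class TestFitVoxelLogistic:
    def test_closed_form_2x2(self):
        # a=20 resected&ILAE I, b=10 resected&not, c=10, d=20
        resected = np.r_[np.ones(30), np.zeros(30)]
        outcome = np.r_[np.ones(20), np.zeros(10), np.ones(10), np.zeros(20)]
        design = DesignMatrix(outcome=outcome, covariates=np.empty((60, 0)), names=[])
        out = fit_voxel_logistic(resected, design)
        assert out["converged"]
        assert out["beta"] == pytest.approx(np.log(4.0), abs=1e-8)
        assert np.exp(out["beta"]) == pytest.approx(4.0, abs=1e-6)

    def test_random_2x2_tables_match_closed_form(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(3, 30, size=4)
            resected = np.r_[np.ones(a + b), np.zeros(c + d)]
            outcome = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
            design = DesignMatrix(outcome=outcome, covariates=np.empty((a + b + c + d, 0)), names=[])
            out = fit_voxel_logistic(resected, design)
            assert out["beta"] == pytest.approx(logit_2x2_beta(a, b, c, d), abs=1e-6)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 90
        Z = rng.normal(size=(n, 2))
        resected = (rng.random(n) < 0.5).astype(float)
        eta = 0.2 + Z @ [0.5, -0.4] + 0.8 * resected
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        design = DesignMatrix(outcome=y, covariates=Z, names=["c1", "c2"])
        out = fit_voxel_logistic(resected, design)
        ref = sm.Logit(y, np.column_stack([np.ones(n), Z, resected])).fit(disp=0)
        assert out["beta"] == pytest.approx(ref.params[-1], abs=1e-6)
        assert out["se"] == pytest.approx(ref.bse[-1], abs=1e-6)

    def test_separation_flagged(self):
        resected = np.r_[np.ones(15), np.zeros(15)]
        design = DesignMatrix(outcome=resected.copy(), covariates=np.empty((30, 0)), names=[])
        out = fit_voxel_logistic(resected, design)
        assert not out["converged"]
        assert np.isnan(out["beta"])

    def test_rank_deficient_design_named(self, rng):
        n = 40
        col = rng.normal(size=n)
        design = DesignMatrix(
            outcome=(rng.random(n) < 0.5).astype(float),
            covariates=np.column_stack([col, col]),
            names=["vol", "vol_copy"],
        )
        resected = (rng.random(n) < 0.5).astype(float)
        with pytest.raises(ValueError, match="collinear"):
            fit_voxel_logistic(resected, design)

    def test_null_association_mean_z_near_zero(self, rng):
        n = 400
        design = DesignMatrix(
            outcome=(rng.random(n) < 0.5).astype(float),
            covariates=np.empty((n, 0)),
            names=[],
        )
        R = (rng.random((80, n)) < 0.5).astype(float)
        Z = np.ones((n, 1))
        beta, se, conv = _batched_logistic(Z, R, design.outcome[None, :])
        z = beta[0, :, -1] / se[0]
        assert abs(z[conv[0]].mean()) < 0.3


class TestLabelClusters:
    def test_two_blob_toy_map(self):
        z = np.zeros((8, 8, 8))
        z[1, 1, 1] = z[1, 1, 2] = 4.0
        z[5, 5, 5] = z[5, 5, 6] = -4.0
        tested = np.ones_like(z, bool)
        clusters = label_clusters(z, tested, cluster_forming_p=0.001, connectivity=26)
        assert len(clusters) == 2
        for c in clusters:
            assert c.size == 2
            assert c.mass == pytest.approx(8.0)
        assert {c.sign for c in clusters} == {"positive", "negative"}

    def test_all_subthreshold_empty(self, rng):
        z = rng.normal(size=(6, 6, 6)) * 0.5
        assert label_clusters(z, np.ones_like(z, bool)) == []

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError):
            label_clusters(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool), connectivity=10)

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity, rng):
        z_thr = float(norm.isf(0.001 / 2))
        for _ in range(8):
            z = rng.normal(size=(16, 16, 16)) * 2.0
            tested = rng.random((16, 16, 16)) < 0.9
            ours = label_clusters(z, tested, cluster_forming_p=0.001, connectivity=connectivity)
            ref = flood_fill_clusters(z, tested, z_thr, connectivity)
            ours_sets = {frozenset(zip(*c.indices)): c.mass for c in ours}
            ref_sets = {members: mass for _, members, mass in ref}
            assert set(ours_sets) == set(ref_sets)
            for members, mass in ref_sets.items():
                assert ours_sets[members] == pytest.approx(mass, abs=1e-9)


class TestClusterMassPermutation:
    def test_nperm1_counting_bound(self, rng):
        table = _table(40, rng)
        masks = rng.random((40, 8, 8, 8)) < rng.uniform(0.2, 0.8, (40, 1, 1, 1))
        design = build_design(table, masks, np.eye(4))
        result, clusters, null_max = cluster_mass_permutation(
            masks, design, n_perm=1, seed=0, min_per_cell=5
        )
        assert null_max.shape == (1,)
        for c in clusters:
            assert c.p_fwe in (0.5, 1.0)

    def test_no_testable_voxels_structured_empty(self, rng):
        table = _table(30, rng)
        masks = np.zeros((30, 6, 6, 6), bool)
        with pytest.warns(UserWarning, match="no testable"):
            design = build_design(table, np.ones((30, 6, 6, 6), bool), np.eye(4))
            result, clusters, null_max = cluster_mass_permutation(masks, design, n_perm=10)
        assert clusters == []
        assert result.tested_mask.sum() == 0

    def test_screened_equals_exhaustive(self, small_atlas):
        from lesionmap.calibration import FWER_NULL
        import dataclasses

        cfg = dataclasses.replace(FWER_NULL, n=60)
        table, masks, _ = generate_cohort_arrays(cfg, seed=42, atlas=small_atlas)
        design = build_design(table, masks, small_atlas.affine)
        r_screen = cluster_mass_permutation(masks, design, n_perm=60, seed=9)
        r_full = cluster_mass_permutation(masks, design, n_perm=60, seed=9, screen=False)
        assert np.allclose(r_screen[2], r_full[2], atol=1e-9)

    def test_or_map_consistency_and_determinism(self, small_atlas):
        from lesionmap.calibration import FWER_NULL

        table, masks, _ = generate_cohort_arrays(FWER_NULL, seed=8, atlas=small_atlas)
        model = lm.VoxelOutcomeModel.from_arrays(masks, table, small_atlas.affine)
        res1 = model.fit(n_perm=30, seed=4)
        res2 = model.fit(n_perm=30, seed=4)
        pd.testing.assert_frame_equal(res1.cluster_table(), res2.cluster_table())
        maps = res1.maps
        t = maps.tested_mask.astype(bool)
        assert np.all(maps.or_map[t] > 0)
        assert np.allclose(np.log(maps.or_map[t]), maps.beta[t], atol=1e-10)


class TestFlip:
    def test_involution_and_conservation(self, rng):
        mask = rng.random((10, 7, 5)) < 0.4
        flipped = flip_right_to_left(mask)
        assert flipped.sum() == mask.sum()
        assert np.array_equal(flip_right_to_left(flipped), mask)

    def test_hemisphere_exchange(self):
        mask = np.zeros((8, 4, 4), bool)
        mask[:4] = True  # left half
        flipped = flip_right_to_left(mask)
        assert flipped[:4].sum() == 0 and flipped[4:].all()

    def test_odd_grid_rejected(self):
        with pytest.raises(ValueError, match="resample"):
            flip_right_to_left(np.zeros((7, 4, 4), bool))


class TestVlomPipeline:
    @pytest.fixture(scope="class")
    def mixed_cohort(self, tmp_path_factory):
        from lesionmap.synthetic import CohortConfig, generate_cohort

        cfg = CohortConfig(
            n=40,
            laterality_mix={"left": 0.5, "right": 0.5},
            surgery_mix={"ATLR": 0.6, "SAHE": 0.4},
            grid_shape=(32, 32, 32),
        )
        return generate_cohort(cfg, seed=17, out_dir=tmp_path_factory.mktemp("cohort"))

    def test_split_mode_bundles_per_laterality(self, mixed_cohort):
        results = lm.vlom_pipeline(mixed_cohort, mode="split_by_laterality",
                                   n_perm=5, min_per_cell=5, seed=1)
        assert set(results) == {"left", "right"}
        ns = {k: r.model.design.n for k, r in results.items()}
        assert ns["left"] + ns["right"] == 40

    def test_flip_and_pool_confined_to_left(self, mixed_cohort, tmp_path):
        results = lm.vlom_pipeline(mixed_cohort, mode="flip_and_pool",
                                   n_perm=5, min_per_cell=5, seed=1, out_dir=tmp_path)
        assert set(results) == {"pooled_left"}
        res = results["pooled_left"]
        assert res.model.design.n == 40
        tested = res.maps.tested_mask
        nx = tested.shape[0]
        assert tested[nx // 2 :].sum() == 0  # only left-hemisphere voxels
        assert (tmp_path / "pooled_left" / "clusters.tsv").exists()
        assert (tmp_path / "pooled_left" / "or.nii.gz").exists()
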
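"""Simulation studies that validate the pipeline end to end.

These are the package's own evidence that its inference is calibrated:
type-I error of the regional permutation t-test under the null generator,
family-wise error of the cluster-mass permutation procedure, power/recovery
for a planted focal effect, and segmentation accuracy of the delineation
stage. The same routines back the test suite and the acceptance script.

Problem sizes are desk-scale by design: the null/FWER studies run on the
generator's default or a 32^3 grid with cohorts of 28-300 subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .delineation import DelineationParams, delineate_resection, normalize_intensity
from .stats import permutation_t_test
from .synthetic import (
    CohortConfig,
    EffectSpec,
    generate_cohort_arrays,
    make_atlas,
    simulate_images,
    simulate_resection,
    substream,
)
from .vlom import VoxelOutcomeModel, build_design
from .volumetrics import DEFAULT_REGION_FAMILY, RegionOutcomeModel

#: Discovery-style cohort: n=28, SAHE-dominant (22 SAHE / 3 ATLR / 3 tailored).
DISCOVERY_LIKE = CohortConfig(
    n=28,
    surgery_mix={"SAHE": 22 / 28, "ATLR": 3 / 28, "tailored": 3 / 28},
    lesion_mix={"HS": 12 / 28, "other": 16 / 28},
    laterality_mix={"left": 18 / 28, "right": 10 / 28},
    sex_mix={"female": 15 / 28, "male": 13 / 28},
    effects=EffectSpec(intercept=float(np.log(12 / 16))),
)

#: Null cohort on a 32^3 grid for the scaled-down FWER study.
FWER_NULL = CohortConfig(
    n=100,
    surgery_mix={"ATLR": 0.7, "lesionectomy": 0.3},
    lesion_mix={"HS": 0.6, "other": 0.4},
    laterality_mix={"left": 1.0},
    sex_mix={"female": 0.5, "male": 0.5},
    effects=EffectSpec(intercept=0.0),
    grid_shape=(32, 32, 32),
)

#: Planted-effect cohort: resecting more than half the posterior hippocampus
#: (body + tail, ~100 voxels on the 32^3 grid) carries a log-odds contrast of
#: -3; the intercept offsets the effect at its mean so the outcome marginal
#: stays near one half.
RECOVERY_EFFECT = -3.0
RECOVERY_REGION = "hippocampus_posterior"
RECOVERY_COHORT = CohortConfig(
    n=300,
    surgery_mix={"ATLR": 0.5, "SAHE": 0.5},
    lesion_mix={"HS": 0.5, "other": 0.5},
    laterality_mix={"left": 1.0},
    sex_mix={"female": 0.5, "male": 0.5},
    # U-shaped extents: subjects either spare or take the posterior
    # hippocampus, the dichotomy between selective and extended resections
    extent_params={
        "ATLR": (0.3, 0.3),
        "SAHE": (0.3, 0.3),
        "lesionectomy": (0.3, 0.3),
        "tailored": (0.3, 0.3),
    },
    effects=EffectSpec(
        intercept=1.5,
        region_effects={"hippocampus_posterior": RECOVERY_EFFECT},
        region_threshold=0.5,
    ),
    grid_shape=(32, 32, 32),
    # strong directional variability of growth: heterogeneous surgical
    # trajectories decouple regional coverage from overall volume
    growth_anisotropy_sd=0.9,
)


def most_significant_region(table):
    """Region with the smallest raw permutation p; ties at the attainable
    floor are broken by the larger |t| (the statistic the p is computed
    from)."""
    t = table.copy()
    t["_key"] = list(zip(t["p_raw"], -t["t"].abs()))
    return t.loc[t["_key"].idxmin(), "region"]


@dataclass
class NullCalibration:
    rejection_rate: float
    n_tests: int
    n_cohorts: int


def null_rejection_rate(
    n_cohorts: int = 500,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    config: CohortConfig | None = None,
) -> NullCalibration:
    """Type-I calibration of the regional permutation t-test.

    Regenerates ``n_cohorts`` cohorts under the all-zero effect spec (outcome
    independent of resection topography) and pools the per-region raw-p
    rejections at level ``alpha`` across the default region family plus
    overall volume. Degenerate quantities (zero variance in both groups,
    where the test is vacuous with p = 1 by convention) are not counted.
    """
    config = replace(config or DISCOVERY_LIKE, effects=EffectSpec(intercept=(config or DISCOVERY_LIKE).effects.intercept))
    atlas = make_atlas(config.grid_shape, seed=substream(seed, "atlas").integers(2**31))
    rejections = 0
    total = 0
    for c in range(n_cohorts):
        cseed = int(substream(seed, "null_cohort", c).integers(2**31))
        table, masks, _ = generate_cohort_arrays(config, cseed, atlas=atlas)
        model = RegionOutcomeModel.from_arrays(masks, atlas, table)
        g1 = model.outcome == 1
        if g1.sum() < 2 or (~g1).sum() < 2:
            continue
        res = model.fit(n_perm=n_perm, seed=cseed % (2**31))
        informative = res.table["t"] != 0.0
        rejections += int((res.table.loc[informative, "p_raw"] <= alpha).sum())
        total += int(informative.sum())
    return NullCalibration(rejection_rate=rejections / total, n_tests=total, n_cohorts=n_cohorts)


@dataclass
class FwerCalibration:
    fwer: float
    n_reps: int
    mean_tested_voxels: float


def fwer_calibration(
    n_reps: int = 200,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    config: CohortConfig | None = None,
    min_per_cell: int = 10,
) -> FwerCalibration:
    """Family-wise error of the cluster-mass permutation under the null.

    Each repetition regenerates a null cohort, runs the full voxel mapping,
    and records whether any cluster reaches FWE-corrected p <= alpha.
    """
    config = config or FWER_NULL
    atlas = make_atlas(config.grid_shape, seed=substream(seed, "atlas").integers(2**31))
    hits = 0
    tested = []
    for r in range(n_reps):
        rseed = int(substream(seed, "fwer_rep", r).integers(2**31))
        table, masks, _ = generate_cohort_arrays(config, rseed, atlas=atlas)
        if table["ilae_class"].nunique() < 2:
            continue
        model = VoxelOutcomeModel.from_arrays(masks, table, atlas.affine, min_per_cell=min_per_cell)
        res = model.fit(n_perm=n_perm, seed=rseed % (2**31))
        tested.append(float(res.maps.tested_mask.sum()))
        if any((c.p_fwe or 1.0) <= alpha for c in res.clusters):
            hits += 1
    return FwerCalibration(fwer=hits / n_reps, n_reps=n_reps,
                           mean_tested_voxels=float(np.mean(tested)))


@dataclass
class RecoveryStudy:
    cluster_recovery_rate: float
    volumetric_min_p_rate: float
    n_runs: int
    mean_overlap: float


def recovery_study(
    n_runs: int = 50,
    n_perm_vlom: int = 250,
    n_perm_volumetrics: int = 1000,
    seed: int = 0,
    config: CohortConfig | None = None,
    overlap_threshold: float = 0.5,
) -> RecoveryStudy:
    """Power/recovery for a planted focal effect on the hippocampus.

    Per run: fraction of runs where significant clusters (FWE p <= 0.05)
    cover at least half the planted region, and fraction where the
    hippocampus attains the smallest raw p in the volumetric family.
    """
    config = config or RECOVERY_COHORT
    atlas = make_atlas(config.grid_shape, seed=substream(seed, "atlas").integers(2**31))
    planted = atlas.region_mask(RECOVERY_REGION, "left")
    n_planted = int(planted.sum())

    cluster_hits = 0
    volumetric_hits = 0
    overlaps = []
    for r in range(n_runs):
        rseed = int(substream(seed, "recovery_run", r).integers(2**31))
        table, masks, _ = generate_cohort_arrays(config, rseed, atlas=atlas)

        vmodel = RegionOutcomeModel.from_arrays(masks, atlas, table)
        vres = vmodel.fit(n_perm=n_perm_volumetrics, seed=rseed % (2**31))
        regions_only = vres.table[vres.table["region"].isin(DEFAULT_REGION_FAMILY)]
        if most_significant_region(regions_only) == "hippocampus":
            volumetric_hits += 1

        model = VoxelOutcomeModel.from_arrays(masks, table, atlas.affine)
        res = model.fit(n_perm=n_perm_vlom, seed=rseed % (2**31))
        covered = np.zeros(atlas.shape, dtype=bool)
        for c in res.clusters:
            if (c.p_fwe or 1.0) <= 0.05:
                covered[c.indices] = True
        overlap = float((covered & planted).sum()) / n_planted
        overlaps.append(overlap)
        if overlap >= overlap_threshold:
            cluster_hits += 1
    return RecoveryStudy(
        cluster_recovery_rate=cluster_hits / n_runs,
        volumetric_min_p_rate=volumetric_hits / n_runs,
        n_runs=n_runs,
        mean_overlap=float(np.mean(overlaps)),
    )


@dataclass
class DelineationScores:
    dice_noise_free: float
    dice_default_noise: float


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a) > 0
    b = np.asarray(b) > 0
    denom = a.sum() + b.sum()
    return 2.0 * float((a & b).sum()) / denom if denom else 1.0


def delineation_scores(seed: int = 0, drop: float = 40.0) -> DelineationScores:
    """Delineation accuracy on the default synthetic subject.

    Noise-free recovery uses cleanup-free parameters (no closing, minimum
    component 1) where exact recovery holds by construction; the noisy case
    uses the default noise level noise_sd = drop / 8 with default cleanup.
    """
    atlas = make_atlas((48, 56, 48), seed=substream(seed, "atlas").integers(2**31))
    truth = simulate_resection(atlas, "left", "ATLR", extent=0.8,
                               seed=int(substream(seed, "truth").integers(2**31)))
    scores = []
    for noise_sd, params in (
        (0.0, DelineationParams(gm_threshold=drop / 2, wm_threshold=drop / 2,
                                min_component_voxels=1, closing_radius=0)),
        (drop / 8.0, DelineationParams(gm_threshold=drop / 2, wm_threshold=drop / 2)),
    ):
        pre, post = simulate_images(atlas, truth, drop=drop, noise_sd=noise_sd,
                                    seed=int(substream(seed, "img", noise_sd).integers(2**31)))
        brain = atlas.brain_mask()
        pre_n = normalize_intensity(pre, brain, params.normalization_target)
        post_n = normalize_intensity(post, brain, params.normalization_target)
        est = delineate_resection(pre_n, post_n, atlas, params)
        scores.append(_dice(est, truth))
    return DelineationScores(dice_noise_free=scores[0], dice_default_noise=scores[1])
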
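"""Synthetic surgical cohorts with the statistical structure of a real one.

The generator emits, on one shared voxel grid, a bilaterally symmetric
geometric atlas of mesiotemporal parcels, per-subject binary resection masks
grown from a mesial seed, optional pre/post T1-like image pairs, and a cohort
table with clinical covariates and binary ILAE outcomes drawn from a logistic
model. An all-zero set of region effects gives an exact null in which outcome
is independent of resection topography.

Randomness policy: one master seed; every subject and operation uses an
independent substream derived by hashing ``(master_seed, *keys)``, so results
do not depend on generation order.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import expit

from .errors import AtlasSizingError, ConfigurationError
from .volumes import (
    HEMISPHERES,
    REQUIRED_REGIONS,
    AtlasVolume,
    save_atlas,
    save_mask,
    save_volume,
)

SURGERIES = ("ATLR", "SAHE", "lesionectomy", "tailored")
LESIONS = ("HS", "other")
SEXES = ("male", "female")

#: Default tissue intensities (arbitrary T1-like units) per region base name.
DEFAULT_TISSUE_MEANS = {
    "background": 15.0,
    "white_matter": 110.0,
    "temporal_neocortex": 80.0,
    "hippocampus_head": 80.0,
    "hippocampus_body": 80.0,
    "hippocampus_tail": 80.0,
    "amygdala": 80.0,
    "entorhinal": 80.0,
    "frontal_piriform": 80.0,
    "anterior_piriform": 80.0,
    "dorsotemporal_piriform": 80.0,
}


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Independent generator derived from a master seed and a key tuple."""
    tag = "|".join(str(k) for k in (master_seed, *keys))
    digest = hashlib.sha256(tag.encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------

# (center, radii) of each left-hemisphere parcel in voxel units of the
# reference 48 x 56 x 48 grid (2 mm nominal spacing). Painted in order, later
# entries overwrite earlier ones so small parcels survive.
_REFERENCE_SHAPE = np.array([48, 56, 48], dtype=float)
_PARCEL_GEOMETRY = [
    ("white_matter", (12.0, 28.0, 26.0), (8.0, 20.0, 14.0)),
    ("temporal_neocortex", (5.0, 24.0, 14.0), (4.5, 14.0, 8.0)),
    ("entorhinal", (12.0, 21.0, 8.0), (3.5, 4.5, 2.4)),
    ("hippocampus_tail", (15.0, 34.0, 15.0), (2.8, 3.0, 2.6)),
    ("hippocampus_body", (14.0, 28.0, 13.0), (3.0, 3.2, 2.8)),
    ("hippocampus_head", (14.0, 22.0, 12.0), (3.2, 3.0, 3.0)),
    ("amygdala", (14.0, 17.0, 15.0), (3.2, 3.0, 3.0)),
    ("frontal_piriform", (20.0, 9.0, 19.0), (2.2, 2.2, 2.2)),
    ("anterior_piriform", (19.0, 12.0, 13.0), (2.2, 2.5, 2.2)),
    ("dorsotemporal_piriform", (18.5, 22.0, 19.0), (2.2, 2.5, 2.0)),
]
_MIN_RADIUS = 2.3  # floor so every parcel keeps >= ~20 voxels on small grids
_MIN_REGION_VOXELS = 20


def make_atlas(grid_shape: tuple[int, int, int], seed: int) -> AtlasVolume:
    """Bilaterally mirror-symmetric atlas of geometric parcels.

    The first grid dimension must be even so a mid-sagittal plane lies between
    voxel columns; the left hemisphere occupies ``i < nx/2`` and the right
    hemisphere is its exact mirror. Left-hemisphere parcels carry label ids
    1..10 (order of :data:`lesionmap.volumes.REQUIRED_REGIONS`), right ids
    11..20.
    """
    nx, ny, nz = (int(s) for s in grid_shape)
    if min(nx, ny, nz) < 24:
        raise AtlasSizingError("each grid dimension must be >= 24")
    if nx % 2:
        raise AtlasSizingError("first grid dimension must be even (mid-sagittal plane)")

    rng = substream(seed, "make_atlas", nx, ny, nz)
    scale = np.array([nx, ny, nz], dtype=float) / _REFERENCE_SHAPE

    half = np.zeros((nx // 2, ny, nz), dtype=np.int32)
    ii, jj, kk = np.meshgrid(
        np.arange(nx // 2), np.arange(ny), np.arange(nz), indexing="ij"
    )
    base_id = {name: i + 1 for i, name in enumerate(REQUIRED_REGIONS)}
    for name, center, radii in _PARCEL_GEOMETRY:
        c = np.asarray(center) * scale + rng.uniform(-0.5, 0.5, size=3)
        r = np.maximum(np.asarray(radii) * scale, _MIN_RADIUS)
        r = r * rng.uniform(0.99, 1.06, size=3)
        inside = (
            ((ii - c[0]) / r[0]) ** 2 + ((jj - c[1]) / r[1]) ** 2 + ((kk - c[2]) / r[2]) ** 2
        ) <= 1.0
        half[inside] = base_id[name]

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    labels[: nx // 2] = half
    mirrored = half[::-1]
    labels[nx // 2 :] = np.where(mirrored > 0, mirrored + len(REQUIRED_REGIONS), 0)

    label_table = {}
    for name, bid in base_id.items():
        label_table[bid] = f"left_{name}"
        label_table[bid + len(REQUIRED_REGIONS)] = f"right_{name}"

    counts = np.bincount(labels.ravel(), minlength=2 * len(REQUIRED_REGIONS) + 1)
    for name in REQUIRED_REGIONS:
        for hemi in HEMISPHERES:
            lab = base_id[name] + (0 if hemi == "left" else len(REQUIRED_REGIONS))
            if counts[lab] < _MIN_REGION_VOXELS:
                raise AtlasSizingError(
                    f"grid {grid_shape} too small: region {hemi}_{name} has "
                    f"{counts[lab]} voxels (< {_MIN_REGION_VOXELS})"
                )

    spacing = 2.0  # nominal mm
    affine = np.diag([spacing, spacing, spacing, 1.0])
    affine[:3, 3] = -spacing * (np.array([nx, ny, nz]) - 1) / 2.0
    return AtlasVolume(labels=labels, affine=affine, label_table=label_table)


# ---------------------------------------------------------------------------
# Resection simulation
# ---------------------------------------------------------------------------

_MESIAL_SET = (
    "amygdala",
    "hippocampus_head",
    "hippocampus_body",
    "hippocampus_tail",
    "entorhinal",
    "anterior_piriform",
    "dorsotemporal_piriform",
)
# accessible base regions and white-matter margin (voxels) per approach
_SURGERY_REACH = {
    "ATLR": (_MESIAL_SET + ("temporal_neocortex", "frontal_piriform"), 3),
    "SAHE": (_MESIAL_SET, 1),
    "lesionectomy": (("amygdala", "hippocampus_head", "anterior_piriform"), 1),
    "tailored": (_MESIAL_SET, 2),
}


def _hemisphere_mask(atlas: AtlasVolume, hemisphere: str) -> np.ndarray:
    nx = atlas.shape[0]
    m = np.zeros(atlas.shape, dtype=bool)
    if hemisphere == "left":
        m[: nx // 2] = True
    else:
        m[nx // 2 :] = True
    return m


def simulate_resection(
    atlas: AtlasVolume,
    laterality: str,
    surgery: str,
    extent: float,
    seed: int,
    anisotropy_sd: float = 0.35,
) -> np.ndarray:
    """Grow a connected resection mask from a mesiotemporal seed.

    The accessible territory depends on the surgical approach (ATLR reaches
    the temporal neocortex, selective approaches stay mesial), voxels are
    rank-ordered by distance from the seed, and ``extent`` is the distance
    quantile retained, so masks for one subject are nested in ``extent`` and
    ATLR masks are larger than SAHE masks in expectation at equal extent.

    The distance metric is randomly anisotropic per subject and the seed
    point jitters by a couple of voxels, mimicking surgical variability in
    the direction of spread: two subjects with the same overall resection
    volume then differ in which voxels are covered, so regional coverage is
    not a deterministic function of overall volume.
    """
    if surgery not in SURGERIES:
        raise ValueError(f"unknown surgery {surgery!r}; expected one of {SURGERIES}")
    if laterality not in HEMISPHERES:
        raise ValueError(f"laterality must be 'left' or 'right', got {laterality!r}")
    if not (0.0 < extent <= 1.0):
        raise ValueError(f"extent must lie in (0, 1], got {extent}")

    rng = substream(seed, "simulate_resection", laterality, surgery)
    hemi = _hemisphere_mask(atlas, laterality)
    regions, wm_margin = _SURGERY_REACH[surgery]

    structures = np.zeros(atlas.shape, dtype=bool)
    for name in regions:
        structures |= atlas.region_mask(name, laterality)
    wm = atlas.region_mask("white_matter", laterality)
    bridge = ndimage.binary_dilation(structures, iterations=wm_margin) & wm
    accessible = (structures | bridge) & hemi

    # seed at the amygdala: mesial resections start anteriorly and spread
    # posteriorly, so distal (posterior) structures are reached last
    seed_region = atlas.region_mask("amygdala", laterality)
    seed_point = np.array(np.nonzero(seed_region)).mean(axis=1) + rng.uniform(-2, 2, 3)
    axis_weights = np.exp(rng.normal(0.0, anisotropy_sd, size=3))

    idx = np.array(np.nonzero(accessible))
    dist = np.sqrt((((idx - seed_point[:, None]) / axis_weights[:, None]) ** 2).sum(axis=0))
    thr = np.quantile(dist, extent)
    keep = dist <= thr

    mask = np.zeros(atlas.shape, dtype=bool)
    mask[tuple(idx[:, keep])] = True

    # retain the connected component containing the voxel nearest the seed
    lab, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    nearest = tuple(idx[:, np.argmin(dist)])
    mask = lab == lab[nearest]
    return mask.astype(np.uint8)


# ---------------------------------------------------------------------------
# Image simulation
# ---------------------------------------------------------------------------


def simulate_images(
    atlas: AtlasVolume,
    resection_mask: np.ndarray,
    tissue_means: dict[str, float] | None = None,
    drop: float = 40.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pre/postoperative T1-like pair: tissue means plus Gaussian noise.

    The noiseless post image equals the noiseless pre image minus ``drop``
    inside the resection mask; pre and post receive independent noise. With
    ``noise_sd == 0`` the voxelwise difference is exactly ``-drop`` on
    resected voxels and 0 elsewhere.
    """
    tissue_means = dict(DEFAULT_TISSUE_MEANS if tissue_means is None else tissue_means)
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0 and drop <= 2 * noise_sd:
        warnings.warn(
            f"intensity drop {drop} is <= 2 * noise_sd ({noise_sd}); delineation "
            "may be unreliable",
            stacklevel=2,
        )

    labels = atlas.labels
    lut = np.empty(labels.max() + 1, dtype=float)
    lut[0] = tissue_means.get("background", 0.0)
    for lab, name in atlas.label_table.items():
        base = name.split("_", 1)[1]
        if base not in tissue_means:
            raise ConfigurationError(f"tissue_means missing region {base!r} present in atlas")
        lut[lab] = tissue_means[base]
    clean = lut[labels]

    rng = substream(seed, "simulate_images")
    mask = np.asarray(resection_mask) > 0
    pre = clean + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd else 0.0)
    post = clean - drop * mask + (rng.normal(0.0, noise_sd, clean.shape) if noise_sd else 0.0)
    return pre, post


# ---------------------------------------------------------------------------
# Outcome simulation
# ---------------------------------------------------------------------------


@dataclass
class EffectSpec:
    """Logistic outcome model: ILAE I probability from resection topography.

    ``region_effects`` are log-odds per unit fraction resected of a named
    region; with ``region_threshold`` set they instead apply to the binary
    split ``fraction > threshold`` (the log-odds contrast between subjects
    whose region was and was not substantially resected). An all-zero map is
    the global null (outcome independent of resection topography).
    ``covariate_effects`` may name ``sex`` (female=1),
    ``total_resection_volume`` (z-scored within cohort), ``surgery_type``
    (ATLR=1) and ``lesion_type`` (HS=1).
    """

    intercept: float = 0.0
    region_effects: dict[str, float] = field(default_factory=dict)
    covariate_effects: dict[str, float] = field(default_factory=dict)
    region_threshold: float | None = None

    @property
    def is_null(self) -> bool:
        return all(v == 0 for v in self.region_effects.values())


_COVARIATE_ENCODERS = {
    "sex": lambda df: (df["sex"] == "female").astype(float).to_numpy(),
    "surgery_type": lambda df: (df["surgery"] == "ATLR").astype(float).to_numpy(),
    "lesion_type": lambda df: (df["lesion"] == "HS").astype(float).to_numpy(),
}


def _encode_covariate(name: str, covariates: pd.DataFrame) -> np.ndarray:
    if name == "total_resection_volume":
        v = covariates["total_resection_volume"].to_numpy(dtype=float)
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
    if name in _COVARIATE_ENCODERS:
        return _COVARIATE_ENCODERS[name](covariates)
    raise ConfigurationError(f"unknown covariate {name!r} in EffectSpec")


def outcome_probabilities(
    covariates: pd.DataFrame,
    percent_resected_table: pd.DataFrame,
    spec: EffectSpec,
) -> np.ndarray:
    """Per-subject ILAE-I probability under the logistic outcome model."""
    missing = [r for r in spec.region_effects if r not in percent_resected_table.columns]
    if missing:
        raise ConfigurationError(f"region_effects name regions absent from table: {missing}")
    eta = np.full(len(percent_resected_table), spec.intercept, dtype=float)
    for region, beta in spec.region_effects.items():
        frac = percent_resected_table[region].to_numpy(dtype=float)
        if spec.region_threshold is not None:
            frac = (frac > spec.region_threshold).astype(float)
        eta += beta * frac
    for name, beta in spec.covariate_effects.items():
        eta += beta * _encode_covariate(name, covariates)
    return expit(eta)


def simulate_outcomes(
    covariates: pd.DataFrame,
    percent_resected_table: pd.DataFrame,
    spec: EffectSpec,
    seed: int,
) -> np.ndarray:
    """Draw binary ILAE outcomes; returns ilae_class 1 (free) or 2 (not free)."""
    p = outcome_probabilities(covariates, percent_resected_table, spec)
    rng = substream(seed, "simulate_outcomes")
    return np.where(rng.random(len(p)) < p, 1, 2)


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults emulate the published validation cohort: n=305 with 205
    hippocampal-sclerosis ATLR subjects and 100 others, laterality 170 left /
    135 right, marginal seizure-freedom rate 188/305, and larger resections
    for ATLR than for selective approaches.
    """

    n: int = 305
    surgery_mix: dict[str, float] = field(
        default_factory=lambda: {"ATLR": 279 / 305, "lesionectomy": 26 / 305}
    )
    lesion_mix: dict[str, float] = field(
        default_factory=lambda: {"HS": 205 / 305, "other": 100 / 305}
    )
    laterality_mix: dict[str, float] = field(
        default_factory=lambda: {"left": 170 / 305, "right": 135 / 305}
    )
    sex_mix: dict[str, float] = field(
        default_factory=lambda: {"female": 172 / 305, "male": 133 / 305}
    )
    # Beta(a, b) parameters of the resection-extent quantile per approach
    extent_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ATLR": (5.0, 3.0),
            "SAHE": (3.0, 4.0),
            "lesionectomy": (3.5, 4.0),
            "tailored": (3.0, 3.5),
        }
    )
    effects: EffectSpec = field(default_factory=lambda: EffectSpec(intercept=float(np.log(188 / 117))))
    grid_shape: tuple[int, int, int] = (48, 56, 48)
    include_images: bool = False
    drop: float = 40.0
    noise_sd: float = 5.0
    follow_up_mean: float = 4.4
    follow_up_sd: float = 1.5
    follow_up_min: float = 1.0
    # per-subject log-normal SD of the growth metric's axis weights
    growth_anisotropy_sd: float = 0.35


def _apportion(n: int, mix: dict[str, float], rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n among categories,
    then a random permutation of the resulting assignment vector."""
    names = list(mix)
    probs = np.array([mix[k] for k in names], dtype=float)
    probs = probs / probs.sum()
    raw = probs * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    assignment = np.repeat(np.array(names, dtype=object), counts)
    return rng.permutation(assignment)


def _percent_table(masks: np.ndarray, atlas: AtlasVolume, lateralities: np.ndarray) -> pd.DataFrame:
    """Subject x region fractions resected (ipsilateral), over every base
    region and composite so any region effect can be referenced."""
    from .volumes import REGION_COMPOSITES
    from .volumetrics import percent_resected_table  # local import avoids a cycle

    regions = tuple(REQUIRED_REGIONS) + tuple(REGION_COMPOSITES)
    table = percent_resected_table(masks, atlas, lateralities, regions=regions)
    return table / 100.0


def generate_cohort_arrays(
    config: CohortConfig, seed: int, atlas: AtlasVolume | None = None
) -> tuple[pd.DataFrame, np.ndarray, AtlasVolume]:
    """In-memory cohort: (table, subject masks, atlas).

    The table carries subject covariates, ilae_class and follow-up; masks is
    a boolean array of shape ``(n, *grid_shape)``.
    """
    if config.n <= 0:
        raise ValueError("cohort size n must be positive")
    if atlas is None:
        atlas = make_atlas(config.grid_shape, seed)
    elif atlas.shape != tuple(config.grid_shape):
        raise ConfigurationError("supplied atlas does not match config.grid_shape")

    rng = substream(seed, "cohort_mixture")
    surgery = _apportion(config.n, config.surgery_mix, rng)
    lesion = _apportion(config.n, config.lesion_mix, rng)
    laterality = _apportion(config.n, config.laterality_mix, rng)
    sex = _apportion(config.n, config.sex_mix, rng)
    subject_ids = [f"sub-{i + 1:04d}" for i in range(config.n)]

    masks = np.zeros((config.n, *atlas.shape), dtype=bool)
    extents = np.empty(config.n)
    for i, sid in enumerate(subject_ids):
        srng = substream(seed, "subject", sid)
        a, b = config.extent_params[surgery[i]]
        extents[i] = srng.beta(a, b)
        masks[i] = simulate_resection(
            atlas, laterality[i], surgery[i], float(extents[i]),
            seed=int(srng.integers(2**31)),
            anisotropy_sd=config.growth_anisotropy_sd,
        ) > 0

    vox_ul = atlas.voxel_volume_ul
    table = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "sex": sex,
            "laterality": laterality,
            "surgery": surgery,
            "lesion": lesion,
        }
    )
    table["total_resection_volume"] = masks.reshape(config.n, -1).sum(axis=1) * vox_ul

    fractions = _percent_table(masks, atlas, laterality)
    table["ilae_class"] = simulate_outcomes(table, fractions, config.effects, seed)

    frng = substream(seed, "follow_up")
    fu = frng.normal(config.follow_up_mean, config.follow_up_sd, config.n)
    table["follow_up_years"] = np.round(np.maximum(fu, config.follow_up_min), 1)
    return table, masks, atlas


COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "laterality",
    "surgery",
    "lesion",
    "ilae_class",
    "follow_up_years",
    "mask_path",
    "pre_path",
    "post_path",
]


def generate_cohort(config: CohortConfig, seed: int, out_dir: str | Path):
    """Write a cohort to disk: NIfTI masks (and optional images), atlas and
    ``cohort.tsv``. Re-running with the same config and seed reproduces a
    byte-identical TSV and voxel-identical masks."""
    from .cohort import Cohort  # local import avoids a cycle

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"output directory {out} not writable: {exc}") from exc

    table, masks, atlas = generate_cohort_arrays(config, seed)
    save_atlas(atlas, out / "atlas.nii.gz", out / "atlas_labels.tsv")

    rows = []
    for i, row in table.iterrows():
        sid = row["subject_id"]
        mask_path = f"masks/{sid}_mask.nii.gz"
        save_mask(masks[i], atlas.affine, out / mask_path)
        pre_path = post_path = ""
        if config.include_images:
            pre, post = simulate_images(
                atlas, masks[i], drop=config.drop, noise_sd=config.noise_sd,
                seed=int(substream(seed, "subject_images", sid).integers(2**31)),
            )
            pre_path = f"images/{sid}_pre.nii.gz"
            post_path = f"images/{sid}_post.nii.gz"
            save_volume(pre, atlas.affine, out / pre_path)
            save_volume(post, atlas.affine, out / post_path)
        rows.append(
            {
                "subject_id": sid,
                "sex": row["sex"],
                "laterality": row["laterality"],
                "surgery": row["surgery"],
                "lesion": row["lesion"],
                "ilae_class": int(row["ilae_class"]),
                "follow_up_years": f"{row['follow_up_years']:.1f}",
                "mask_path": mask_path,
                "pre_path": pre_path,
                "post_path": post_path,
            }
        )
    tsv = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    tsv.to_csv(out / "cohort.tsv", sep="\t", index=False, lineterminator="\n")
    return Cohort.from_tsv(out / "cohort.tsv", root=out)
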
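"""Semi-automated resection-zone delineation from pre/post T1-like images.

Aligned pre- and postoperative images are intensity-normalized to a common
brain-median target, and voxels whose normalized intensity drops by more than
a tissue-dependent cutoff (one for white matter, one for grey matter) are
labelled resected. A morphological closing plus a minimum connected-component
size stand in for the manual mask correction used in interactive practice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .errors import InvalidImageError
from .volumes import AtlasVolume, check_same_grid, voxel_volume_ul


@dataclass
class DelineationParams:
    """Tunables of the intensity-drop segmentation.

    ``gm_threshold``/``wm_threshold`` are minimum normalized intensity drops
    (pre - post) for grey- and white-matter parcels. Defaults assume images
    normalized to a brain median of 100 and an expected cavity drop of ~40
    units, with cutoffs at half the drop.
    """

    normalization_target: float = 100.0
    gm_threshold: float = 20.0
    wm_threshold: float = 20.0
    min_component_voxels: int = 10
    closing_radius: int = 1

    def __post_init__(self) -> None:
        if self.gm_threshold <= 0 or self.wm_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_component_voxels < 1:
            raise ValueError("min_component_voxels must be >= 1")
        if self.closing_radius < 0:
            raise ValueError("closing_radius must be nonnegative")


def normalize_intensity(
    volume: np.ndarray, brain_mask: np.ndarray, target: float = 100.0
) -> np.ndarray:
    """Rescale so the median intensity over the brain mask equals ``target``."""
    volume = np.asarray(volume, dtype=float)
    brain_mask = np.asarray(brain_mask) > 0
    check_same_grid(volume, brain_mask)
    if not brain_mask.any():
        raise InvalidImageError("brain mask is empty")
    med = float(np.median(volume[brain_mask]))
    if med <= 0:
        raise InvalidImageError(f"non-positive brain median intensity ({med})")
    return volume * (target / med)


def parcel_mean_table(volume: np.ndarray, atlas: AtlasVolume) -> pd.DataFrame:
    """Mean intensity per nonzero atlas parcel.

    Labels listed in the label table but absent from the grid are kept as
    rows with ``undefined_mean=True`` rather than silently dropped.
    """
    volume = np.asarray(volume, dtype=float)
    check_same_grid(volume, atlas.labels)
    labels = atlas.labels.ravel()
    vals = volume.ravel()
    nmax = max(atlas.label_table) + 1
    counts = np.bincount(labels, minlength=nmax)
    sums = np.bincount(labels, weights=vals, minlength=nmax)
    rows = []
    for lab in sorted(atlas.label_table):
        n = int(counts[lab])
        rows.append(
            {
                "label_id": lab,
                "region": atlas.label_table[lab],
                "n_voxels": n,
                "mean": sums[lab] / n if n else np.nan,
                "undefined_mean": n == 0,
            }
        )
    return pd.DataFrame(rows)


def _ball(radius: int) -> np.ndarray:
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return (xx**2 + yy**2 + zz**2) <= r**2


def delineate_resection(
    pre: np.ndarray,
    post: np.ndarray,
    atlas: AtlasVolume,
    params: DelineationParams | None = None,
    return_qc: bool = False,
):
    """Binary resection mask from normalized pre/post images.

    Candidate voxels satisfy ``pre - post > threshold`` with the white-matter
    cutoff on white-matter parcels and the grey-matter cutoff on every other
    labelled parcel; background voxels are never candidates. Candidates are
    then closed morphologically and components smaller than
    ``min_component_voxels`` discarded.
    """
    params = params or DelineationParams()
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    check_same_grid(pre, post, atlas.labels)
    if not (atlas.labels > 0).any():
        raise InvalidImageError("atlas has no labelled voxels; tissue class unknown")

    wm = atlas.region_mask("white_matter")
    brain = atlas.brain_mask()
    threshold = np.where(wm, params.wm_threshold, params.gm_threshold)
    candidates = ((pre - post) > threshold) & brain
    n_candidates = int(candidates.sum())

    mask = candidates
    if params.closing_radius > 0:
        mask = ndimage.binary_closing(mask, structure=_ball(params.closing_radius))
        mask &= brain

    lab, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    if n_comp:
        sizes = np.bincount(lab.ravel())
        keep = np.flatnonzero(sizes >= params.min_component_voxels)
        keep = keep[keep > 0]
        mask = np.isin(lab, keep)
    n_retained = int(ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))[1])

    mask = mask.astype(np.uint8)
    if not return_qc:
        return mask
    qc = {
        "candidate_voxels": n_candidates,
        "retained_components": n_retained,
        "final_voxels": int(mask.sum()),
        "final_volume_ul": float(mask.sum() * voxel_volume_ul(atlas.affine)),
    }
    return mask, qc


def propose_threshold(pre: np.ndarray, post: np.ndarray, brain_mask: np.ndarray) -> float | None:
    """Data-driven drop cutoff: midpoint between the two most prominent modes
    of the within-brain (pre - post) histogram.

    Returns ``None`` when the difference histogram has a single mode (no
    visible cavity).
    """
    diff = (np.asarray(pre, float) - np.asarray(post, float))[np.asarray(brain_mask) > 0]
    hist, edges = np.histogram(diff, bins=128)
    smooth = gaussian_filter1d(hist.astype(float), sigma=2.0)
    peaks, props = find_peaks(smooth, prominence=smooth.max() * 0.02)
    if peaks.size < 2:
        return None
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    centers = (edges[:-1] + edges[1:]) / 2.0
    return float(centers[top2].mean())


def delineate_cohort_qc(qc_rows: list[dict], subject_ids: list[str]) -> pd.DataFrame:
    """Assemble per-subject QC rows into the report table."""
    df = pd.DataFrame(qc_rows)
    df.insert(0, "subject_id", subject_ids)
    return df
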
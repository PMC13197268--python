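"""Grid-aligned volume containers and NIfTI input/output.

All stages of the pipeline operate on volumes sharing a single voxel grid and
world affine, so no registration step is needed. Masks are stored as unsigned
8-bit, label volumes as signed 32-bit NIfTI-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GridMismatchError

#: Region base names every atlas must contain, once per hemisphere.
REQUIRED_REGIONS = (
    "frontal_piriform",
    "anterior_piriform",
    "dorsotemporal_piriform",
    "hippocampus_head",
    "hippocampus_body",
    "hippocampus_tail",
    "amygdala",
    "entorhinal",
    "temporal_neocortex",
    "white_matter",
)

#: Composite regions used by the volumetric family (unions of base labels).
REGION_COMPOSITES = {
    "hippocampus": ("hippocampus_head", "hippocampus_body", "hippocampus_tail"),
    "hippocampus_posterior": ("hippocampus_body", "hippocampus_tail"),
    "whole_piriform": ("frontal_piriform", "anterior_piriform", "dorsotemporal_piriform"),
}

HEMISPHERES = ("left", "right")


def voxel_volume_ul(affine: np.ndarray) -> float:
    """Volume of one voxel in microliters (1 mm^3 == 1 ul)."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


@dataclass
class AtlasVolume:
    """Integer-labelled parcellation on a world-aligned grid.

    ``labels`` holds non-negative integers (0 = background); ``label_table``
    maps every nonzero label id to a hemisphere-tagged region name such as
    ``left_hippocampus_head``.
    """

    labels: np.ndarray
    affine: np.ndarray
    label_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("atlas labels must be a 3D array")
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.label_table)
        if missing:
            raise ValueError(f"labels present but absent from label_table: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def voxel_volume_ul(self) -> float:
        return voxel_volume_ul(self.affine)

    def label_id(self, region: str, hemisphere: str) -> int:
        """Label id of a base region in one hemisphere."""
        name = f"{hemisphere}_{region}"
        for lab, nm in self.label_table.items():
            if nm == name:
                return lab
        raise KeyError(f"region {name!r} not in atlas label table")

    def region_mask(self, region: str, hemisphere: str | None = None) -> np.ndarray:
        """Boolean mask of a region (base or composite), optionally one hemisphere.

        With ``hemisphere=None`` both hemispheres are included.
        """
        bases = REGION_COMPOSITES.get(region, (region,))
        hemis = HEMISPHERES if hemisphere is None else (hemisphere,)
        ids = [self.label_id(b, h) for b in bases for h in hemis]
        return np.isin(self.labels, ids)

    def brain_mask(self) -> np.ndarray:
        return self.labels > 0

    def region_names(self) -> list[str]:
        return sorted(set(self.label_table.values()))


def check_same_grid(*volumes: np.ndarray) -> None:
    shapes = {np.asarray(v).shape for v in volumes}
    if len(shapes) > 1:
        raise GridMismatchError(f"volumes disagree in shape: {sorted(shapes)}")


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a NIfTI volume; returns ``(data, affine)`` with data as float64."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary mask; any nonzero voxel is True."""
    data, affine = load_volume(path)
    return data > 0, affine


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path, dtype=np.float32) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), np.asarray(affine))
    nib.save(img, str(path))


def save_mask(mask: np.ndarray, affine: np.ndarray, path: str | Path) -> None:
    save_volume(np.asarray(mask) > 0, affine, path, dtype=np.uint8)


def save_atlas(atlas: AtlasVolume, path: str | Path, label_table_path: str | Path | None = None) -> None:
    """Write atlas labels (int32 NIfTI) and its label table (two-column TSV)."""
    save_volume(atlas.labels, atlas.affine, path, dtype=np.int32)
    if label_table_path is not None:
        lines = ["label_id\tregion_name"]
        lines += [f"{lab}\t{name}" for lab, name in sorted(atlas.label_table.items())]
        Path(label_table_path).write_text("\n".join(lines) + "\n")


def load_atlas(path: str | Path, label_table_path: str | Path) -> AtlasVolume:
    data, affine = load_volume(path)
    table: dict[int, str] = {}
    for line in Path(label_table_path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        lab, name = line.split("\t")
        table[int(lab)] = name
    return AtlasVolume(labels=np.rint(data).astype(np.int32), affine=affine, label_table=table)
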
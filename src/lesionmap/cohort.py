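"""Cohort table: clinical covariates, ILAE outcome and volume paths.

A cohort is a TSV with one row per subject (columns ``subject_id, sex,
laterality, surgery, lesion, ilae_class, follow_up_years, mask_path,
pre_path, post_path``) plus NIfTI volumes on one shared grid. The binary
outcome of interest is complete seizure freedom: ILAE class I versus II-VI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, GridMismatchError
from .synthetic import LESIONS, SEXES, SURGERIES
from .volumes import HEMISPHERES, load_mask

logger = logging.getLogger(__name__)

AFFINE_TOL = 1e-4

_CATEGORY_DOMAINS = {
    "sex": set(SEXES),
    "laterality": set(HEMISPHERES),
    "surgery": set(SURGERIES),
    "lesion": set(LESIONS),
}


@dataclass
class SubjectRecord:
    subject_id: str
    sex: str
    laterality: str
    surgery: str
    lesion: str
    ilae_class: int
    follow_up_years: float
    mask_path: str = ""
    pre_path: str = ""
    post_path: str = ""

    @property
    def seizure_free(self) -> bool:
        return self.ilae_class == 1


@dataclass
class Cohort:
    """Validated cohort table plus the directory its volume paths are
    relative to."""

    table: pd.DataFrame
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def outcome(self) -> np.ndarray:
        """Binary seizure-freedom vector (ILAE I -> 1)."""
        return (self.table["ilae_class"].to_numpy() == 1).astype(int)

    def subjects(self) -> list[SubjectRecord]:
        return [
            SubjectRecord(**{k: row[k] for k in row.index if k in SubjectRecord.__annotations__})
            for _, row in self.table.iterrows()
        ]

    @classmethod
    def from_tsv(cls, tsv_path: str | Path, root: str | Path | None = None) -> "Cohort":
        tsv_path = Path(tsv_path)
        root = Path(root) if root is not None else tsv_path.parent
        table = pd.read_csv(tsv_path, sep="\t", dtype={"subject_id": str}, keep_default_na=False)
        return cls(table=table, root=root)

    def load_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack all resection masks; returns ``(masks (n,x,y,z), affine)``.

        Raises on any grid or affine mismatch across subjects.
        """
        masks, affine, shape = [], None, None
        for _, row in self.table.iterrows():
            m, aff = load_mask(self.root / row["mask_path"])
            if affine is None:
                affine, shape = aff, m.shape
            else:
                if m.shape != shape:
                    raise GridMismatchError(f"{row['subject_id']}: mask shape {m.shape} != {shape}")
                if np.max(np.abs(aff - affine)) > AFFINE_TOL:
                    raise GridMismatchError(f"{row['subject_id']}: affine differs beyond {AFFINE_TOL}")
            masks.append(m)
        return np.stack(masks), affine

    def filter(self, **criteria) -> "Cohort":
        return filter_cohort(self, **criteria)


def _validate_table(table: pd.DataFrame, root: Path, check_files: bool = True) -> list[str]:
    problems: list[str] = []
    from .synthetic import COHORT_COLUMNS

    missing_cols = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing_cols:
        return [f"missing columns: {missing_cols}"]
    for i, row in table.iterrows():
        sid = row["subject_id"]
        for col, domain in _CATEGORY_DOMAINS.items():
            if row[col] not in domain:
                problems.append(f"row {i} ({sid}): {col}={row[col]!r} not in {sorted(domain)}")
        try:
            ilae = int(row["ilae_class"])
            if not 1 <= ilae <= 6:
                problems.append(f"row {i} ({sid}): ilae_class={ilae} outside 1..6")
        except (TypeError, ValueError):
            problems.append(f"row {i} ({sid}): ilae_class={row['ilae_class']!r} not an integer")
        if float(row["follow_up_years"]) < 0:
            problems.append(f"row {i} ({sid}): negative follow_up_years")
        if check_files:
            for col in ("mask_path", "pre_path", "post_path"):
                rel = str(row[col])
                if rel and not (root / rel).exists():
                    problems.append(f"row {i} ({sid}): missing file {rel}")
    return problems


def load_cohort(tsv_path: str | Path, volume_root: str | Path | None = None) -> Cohort:
    """Load and validate a cohort; checks categories, ILAE range, referenced
    files and (via :meth:`Cohort.load_masks`) the shared grid."""
    cohort = Cohort.from_tsv(tsv_path, root=volume_root)
    problems = _validate_table(cohort.table, cohort.root)
    if problems:
        raise CohortValidationError("cohort validation failed:\n" + "\n".join(problems))
    if (cohort.table["mask_path"] != "").any():
        cohort.load_masks()  # raises GridMismatchError on affine/shape drift
    logger.info("loaded cohort with %d subjects from %s", len(cohort), tsv_path)
    return cohort


def filter_cohort(
    cohort: Cohort,
    laterality: str | None = None,
    lesion: str | None = None,
    surgery: str | None = None,
    exact_follow_up_years: float | None = None,
) -> Cohort:
    """Subset a cohort on clinical criteria; empty results warn, not raise."""
    keep = pd.Series(True, index=cohort.table.index)
    if laterality is not None:
        keep &= cohort.table["laterality"] == laterality
    if lesion is not None:
        keep &= cohort.table["lesion"] == lesion
    if surgery is not None:
        keep &= cohort.table["surgery"] == surgery
    if exact_follow_up_years is not None:
        keep &= np.isclose(
            cohort.table["follow_up_years"].astype(float), exact_follow_up_years
        )
    out = Cohort(table=cohort.table[keep].reset_index(drop=True), root=cohort.root)
    logger.info("filter_cohort: %d -> %d subjects", len(cohort), len(out))
    if len(out) == 0:
        import warnings

        warnings.warn("filter_cohort produced an empty cohort", stacklevel=2)
    return out
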
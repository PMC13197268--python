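"""Regional percent-of-ROI-resected volumetry and group comparison.

For each subject the percent of each ipsilateral region of interest covered
by the resection mask is computed; seizure-free (ILAE I) and non-seizure-free
(ILAE II-VI) groups are then compared per region with a permutation t-test,
and p-values are corrected across the tested family with Benjamini-Hochberg
FDR. The tested family mirrors the eight-comparison design used in practice:
three piriform subregions, the whole piriform cortex, hippocampus, entorhinal
cortex, amygdala, plus overall resection volume in microliters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortCompositionError, EmptyROIError
from .stats import bh_fdr, cohens_d, permutation_t_test
from .volumes import AtlasVolume, check_same_grid

#: Region family tested by default (overall resection volume is appended).
DEFAULT_REGION_FAMILY = (
    "frontal_piriform",
    "dorsotemporal_piriform",
    "anterior_piriform",
    "whole_piriform",
    "hippocampus",
    "entorhinal",
    "amygdala",
)

VOLUME_ROW = "overall_resection"


def percent_resected(resection_mask: np.ndarray, roi_mask: np.ndarray) -> float:
    """Percent of the ROI inside the resection mask: 100 * |R ∩ ROI| / |ROI|."""
    resection_mask = np.asarray(resection_mask) > 0
    roi_mask = np.asarray(roi_mask) > 0
    check_same_grid(resection_mask, roi_mask)
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise EmptyROIError("percent resected is undefined for an empty ROI")
    return 100.0 * float((resection_mask & roi_mask).sum()) / n_roi


def percent_resected_table(
    masks: np.ndarray,
    atlas: AtlasVolume,
    lateralities,
    regions=None,
) -> pd.DataFrame:
    """Subject x region percent-resected table, ipsilateral to each surgery.

    ``masks`` has shape ``(n, x, y, z)``; ``lateralities`` gives each
    subject's operated hemisphere.
    """
    regions = tuple(regions) if regions is not None else DEFAULT_REGION_FAMILY
    lateralities = np.asarray(lateralities)
    roi = {
        (r, h): atlas.region_mask(r, h) for r in regions for h in ("left", "right")
    }
    rows = np.empty((len(masks), len(regions)))
    for i, mask in enumerate(masks):
        for j, r in enumerate(regions):
            rows[i, j] = percent_resected(mask, roi[(r, lateralities[i])])
    return pd.DataFrame(rows, columns=list(regions))


def _quiet_cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohens_d(x, y)


def _median_iqr(v: np.ndarray) -> str:
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return f"{med:.1f} [{q1:.1f}-{q3:.1f}]"


@dataclass
class RegionOutcomeModel:
    """Group-comparison model for regional resection extents.

    Built from a subject x region percent table, the binary seizure-freedom
    outcome, and per-subject overall resection volumes; :meth:`fit` runs one
    permutation t-test per region (plus overall volume) and corrects the
    family with BH-FDR.
    """

    percent: pd.DataFrame
    outcome: np.ndarray
    volumes_ul: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome).astype(int)
        if len(self.outcome) != len(self.percent):
            raise ValueError("outcome length must match percent table")

    @classmethod
    def from_arrays(
        cls, masks: np.ndarray, atlas: AtlasVolume, table: pd.DataFrame, regions=None
    ) -> "RegionOutcomeModel":
        percent = percent_resected_table(masks, atlas, table["laterality"], regions)
        volumes = np.asarray(masks).reshape(len(masks), -1).sum(axis=1) * atlas.voxel_volume_ul
        outcome = (table["ilae_class"].to_numpy() == 1).astype(int)
        return cls(percent=percent, outcome=outcome, volumes_ul=volumes)

    @classmethod
    def from_cohort(cls, cohort, atlas: AtlasVolume, regions=None) -> "RegionOutcomeModel":
        masks, _ = cohort.load_masks()
        return cls.from_arrays(masks, atlas, cohort.table, regions)

    def fit(
        self,
        n_perm: int = 100_000,
        seed: int | None = None,
        q: float = 0.05,
        equal_var: bool = True,
    ) -> "RegionOutcomeResults":
        g1 = self.outcome == 1  # ILAE I
        g2 = self.outcome == 0
        if g1.sum() < 2 or g2.sum() < 2:
            raise CohortCompositionError(
                f"both outcome groups need >= 2 subjects (ILAE I: {g1.sum()}, II-VI: {g2.sum()})"
            )
        quantities = {name: self.percent[name].to_numpy(float) for name in self.percent.columns}
        if self.volumes_ul is not None:
            quantities[VOLUME_ROW] = np.asarray(self.volumes_ul, dtype=float)

        rows = []
        for k, (name, values) in enumerate(quantities.items()):
            x, y = values[g1], values[g2]
            res = permutation_t_test(
                x, y, n_perm=n_perm, equal_var=equal_var,
                seed=None if seed is None else (int(seed) * 1000 + k) % (2**31),
            )
            rows.append(
                {
                    "region": name,
                    "n1": int(g1.sum()),
                    "n2": int(g2.sum()),
                    "median_iqr_g1": _median_iqr(x),
                    "median_iqr_g2": _median_iqr(y),
                    "t": res.t,
                    # NaN flags an undefined effect (zero pooled SD)
                    "d": _quiet_cohens_d(x, y),
                    "p_raw": res.p,
                }
            )
        table = pd.DataFrame(rows)
        p_adj, reject = bh_fdr(table["p_raw"].to_numpy(), q=q)
        table["p_fdr"] = p_adj
        table["reject"] = reject
        return RegionOutcomeResults(table=table, q=q, n_perm=n_perm, model=self)


@dataclass
class RegionOutcomeResults:
    """Per-region statistics from :meth:`RegionOutcomeModel.fit`."""

    table: pd.DataFrame
    q: float
    n_perm: int
    model: RegionOutcomeModel = field(repr=False)

    def summary(self) -> str:
        lines = [
            "Regional resection extent vs seizure freedom (permutation t-test, "
            f"{self.n_perm} permutations, BH-FDR q={self.q})",
            f"{'region':<26}{'ILAE I':>18}{'ILAE II-VI':>18}{'t':>8}{'d':>8}"
            f"{'p':>9}{'p_FDR':>9}",
        ]
        for _, r in self.table.iterrows():
            lines.append(
                f"{r['region']:<26}{r['median_iqr_g1']:>18}{r['median_iqr_g2']:>18}"
                f"{r['t']:>8.2f}{r['d']:>8.2f}{r['p_raw']:>9.4g}{r['p_fdr']:>9.4g}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        cols = [
            "region", "n1", "n2", "median_iqr_g1", "median_iqr_g2",
            "t", "d", "p_raw", "p_fdr",
        ]
        self.table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


def region_outcome_analysis(
    cohort,
    atlas: AtlasVolume,
    regions=None,
    n_perm: int = 100_000,
    seed: int | None = None,
    q: float = 0.05,
) -> RegionOutcomeResults:
    """One-call regional analysis: build the model from a cohort and fit it."""
    model = RegionOutcomeModel.from_cohort(cohort, atlas, regions)
    return model.fit(n_perm=n_perm, seed=seed, q=q)
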
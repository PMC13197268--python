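"""Presentation of volumetric results: per-region boxplots and summary TSV."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import seaborn as sns

from .errors import LesionmapError


def write_report(results_dir: str | Path, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Figures and a merged summary from a volumetrics results directory.

    Expects ``regions.tsv`` (per-region statistics) and
    ``percent_by_subject.tsv`` (per-subject percent table with an
    ``ilae_class`` column) as written by the ``volumetrics`` CLI command.
    Boxplots show percent resected by outcome group per region; output is
    deterministic (fixed style, no timestamps).
    """
    results = Path(results_dir)
    out = Path(out_dir) if out_dir is not None else results
    regions_tsv = results / "regions.tsv"
    subjects_tsv = results / "percent_by_subject.tsv"
    if not regions_tsv.exists() or not subjects_tsv.exists():
        raise LesionmapError(f"no volumetrics results found under {results}")
    out.mkdir(parents=True, exist_ok=True)

    regions = pd.read_csv(regions_tsv, sep="\t")
    subjects = pd.read_csv(subjects_tsv, sep="\t")
    subjects["outcome"] = subjects["ilae_class"].map(lambda c: "ILAE I" if c == 1 else "ILAE II-VI")

    sns.set_theme(style="whitegrid")
    region_cols = [c for c in subjects.columns if c not in ("subject_id", "ilae_class", "outcome")]
    for region in region_cols:
        fig, ax = plt.subplots(figsize=(3.2, 3.6))
        sns.boxplot(data=subjects, x="outcome", y=region, hue="outcome",
                    order=["ILAE I", "ILAE II-VI"], legend=False, ax=ax)
        ax.set_ylabel("percent resected" if region != "overall_resection" else "volume (ul)")
        ax.set_title(region.replace("_", " "))
        fig.tight_layout()
        fig.savefig(out / f"boxplot_{region}.png", dpi=120)
        plt.close(fig)

    regions.to_csv(out / "summary.tsv", sep="\t", index=False, lineterminator="\n")
    return regions
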
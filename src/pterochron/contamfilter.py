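"""Cross-contamination filtering of multiplexed transcript expression tables.

Multiplexed libraries sequenced on a shared Illumina lane can exchange reads
through index hopping, so a highly expressed transcript of one sample shows
up at low level in its lane-mates.  The filter works on relative expression:
for each transcript of a focal dataset it computes the worst-case TPM
enrichment across lane-mate datasets carrying the same transcript id, and
excludes transcripts that are (1) more than ``fold_threshold``-fold enriched
in a lane-mate, or (2) supported by fewer than ``min_count`` estimated reads
in the focal dataset.  The two criteria are applied independently (union
exclusion); a transcript failing both is attributed to criterion 1 in the
report, so per-criterion exclusion fractions can be summarised separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TranscriptTable:
    """Per-dataset transcript counts and TPMs across sequencing lanes."""

    df: pd.DataFrame

    REQUIRED = ("transcript_id", "dataset_id", "lane_id", "est_count", "tpm")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"transcript table missing columns {missing}")
        if (self.df["est_count"] < 0).any() or (self.df["tpm"] < 0).any():
            raise ValueError("est_count and tpm must be non-negative")
        dup = self.df.duplicated(subset=["transcript_id", "dataset_id"])
        if dup.any():
            raise ValueError("(transcript_id, dataset_id) pairs must be unique")
        lanes = self.df.groupby("dataset_id")["lane_id"].nunique()
        if (lanes > 1).any():
            raise ValueError("each dataset must belong to exactly one lane")

    @property
    def datasets(self) -> list:
        return sorted(self.df["dataset_id"].unique().tolist())

    def lane_of(self, dataset) -> object:
        return self.df.loc[self.df["dataset_id"] == dataset, "lane_id"].iloc[0]


@dataclass
class FilterReport:
    """Per-dataset partition of transcripts into kept / excluded lists."""

    dataset_id: object
    kept: list
    excluded_by_enrichment: list
    excluded_by_count: list

    @property
    def n_total(self) -> int:
        return len(self.kept) + len(self.excluded_by_enrichment) + len(
            self.excluded_by_count
        )

    @property
    def frac_enrichment(self) -> float:
        return len(self.excluded_by_enrichment) / self.n_total if self.n_total else 0.0

    @property
    def frac_count(self) -> float:
        return len(self.excluded_by_count) / self.n_total if self.n_total else 0.0


def enrichment_ratio(transcript_id, dataset_id, table: TranscriptTable) -> float:
    """Worst-case TPM enrichment of a transcript in lane-mate datasets.

    Returns ``max`` over lane-mates of (lane-mate TPM / focal TPM); lane-mates
    lacking the transcript contribute 0, and a focal TPM of 0 with any
    positive lane-mate TPM yields ``inf``.
    """
    ratios = _enrichment_ratios(table)
    key = (transcript_id, dataset_id)
    if key not in ratios.index:
        raise KeyError(
            f"transcript {transcript_id!r} absent from dataset {dataset_id!r}"
        )
    return float(ratios.loc[key])


def _enrichment_ratios(table: TranscriptTable) -> pd.Series:
    """Enrichment ratio for every (transcript, dataset) row, vectorised."""
    df = table.df
    # sum of lane-mate TPM per (lane, transcript) minus own contribution is
    # wrong for max; instead compute max over mates via groupby on lane+id
    lane_groups = df.groupby(["lane_id", "transcript_id"])["tpm"]
    lane_max = lane_groups.transform("max")
    lane_sum = lane_groups.transform("sum")
    lane_n = lane_groups.transform("size")
    own = df["tpm"]
    # max over *other* datasets in the lane:
    # if own is the unique max, the mate max is the second largest; handle via
    # a direct second-max computation
    second = lane_groups.transform(
        lambda s: s.sort_values(ascending=False).iloc[1] if len(s) > 1 else np.nan
    )
    mate_max = np.where(own < lane_max, lane_max, np.where(lane_n > 1, second, 0.0))
    mate_max = np.nan_to_num(mate_max, nan=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            own > 0,
            mate_max / own,
            np.where(mate_max > 0, np.inf, 0.0),
        )
    out = pd.Series(ratio, index=pd.MultiIndex.from_frame(
        df[["transcript_id", "dataset_id"]]))
    return out


def apply_filter(
    table: TranscriptTable | pd.DataFrame,
    fold_threshold: float = 2.0,
    min_count: float = 2.0,
) -> list[FilterReport]:
    """Partition every dataset's transcripts into kept / excluded lists.

    Criterion 1 excludes transcripts with enrichment ratio strictly greater
    than ``fold_threshold``; criterion 2 excludes transcripts with estimated
    count strictly lower than ``min_count`` (counts are fractional estimates
    and compared as real numbers).  A transcript failing both criteria is
    attributed to criterion 1.
    """
    if isinstance(table, pd.DataFrame):
        table = TranscriptTable(table)
    df = table.df.reset_index(drop=True)
    ratio = _enrichment_ratios(table).to_numpy()
    excl1 = ratio > fold_threshold
    excl2 = (df["est_count"].to_numpy() < min_count) & ~excl1
    reports = []
    for ds, idx in df.groupby("dataset_id").groups.items():
        idx = np.asarray(idx)
        tid = df.loc[idx, "transcript_id"]
        e1 = excl1[idx]
        e2 = excl2[idx]
        reports.append(
            FilterReport(
                dataset_id=ds,
                kept=tid[~(e1 | e2)].tolist(),
                excluded_by_enrichment=tid[e1].tolist(),
                excluded_by_count=tid[e2].tolist(),
            )
        )
    return reports


def summarize_exclusions(reports: list[FilterReport]) -> tuple[float, float]:
    """Median per-dataset exclusion fractions, one per criterion."""
    if not reports:
        raise ValueError("no filter reports to summarise")
    f1 = float(np.median([r.frac_enrichment for r in reports]))
    f2 = float(np.median([r.frac_count for r in reports]))
    return f1, f2


def report_to_frame(
    reports: list[FilterReport], table: TranscriptTable | None = None
) -> pd.DataFrame:
    """Flat per-transcript decision table (CLI report format)."""
    rows = []
    ratios = _enrichment_ratios(table).to_dict() if table is not None else {}
    for r in reports:
        for tid in r.kept:
            rows.append((tid, r.dataset_id, "kept", "", ratios.get((tid, r.dataset_id))))
        for tid in r.excluded_by_enrichment:
            rows.append((tid, r.dataset_id, "excluded", "enrichment",
                         ratios.get((tid, r.dataset_id))))
        for tid in r.excluded_by_count:
            rows.append((tid, r.dataset_id, "excluded", "low_count",
                         ratios.get((tid, r.dataset_id))))
    return pd.DataFrame(
        rows, columns=["transcript_id", "dataset_id", "decision", "criterion", "ratio"]
    )
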
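"""Fossil diversity through time on a stage-resolved geologic timescale.

Observed (sampled-in-bin) diversity counts, per stage, the distinct accepted
species with at least one occurrence in that stage; range-through diversity
counts every species in all stages between its oldest and youngest
occurrence.  Occurrences citing a span of stages ("Chattian–Burdigalian")
are expanded to one record per spanned stage before counting.  Synonym and
doubtful records never contribute.

A default timescale with stage bounds in Ma ships with the package and can
be replaced by any CSV with columns stage, older_ma, younger_ma ordered from
old to young, ending in a "Recent" bin reaching 0 Ma.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BinningError

VALID_STATUSES = {"accepted", "synonym", "doubtful"}


@dataclass
class GeologicTimescale:
    """Ordered stage bins (old to young) with bounds in Ma."""

    table: pd.DataFrame  # stage, older_ma, younger_ma

    def __post_init__(self) -> None:
        df = self.table
        need = {"stage", "older_ma", "younger_ma"}
        if not need <= set(df.columns):
            raise ValueError(f"timescale needs columns {sorted(need)}")
        if df["stage"].duplicated().any():
            raise ValueError("duplicate stage names")
        older = df["older_ma"].to_numpy(dtype=float)
        younger = df["younger_ma"].to_numpy(dtype=float)
        if not np.all(older > younger):
            raise ValueError("each stage needs older_ma > younger_ma")
        if not np.all(older[1:] == younger[:-1]):
            raise ValueError("stages must tile time without gaps or overlap")
        if younger[-1] != 0.0:
            raise ValueError("the youngest (Recent) bin must reach 0 Ma")
        self._index = {s: i for i, s in enumerate(df["stage"])}

    @property
    def stage_names(self) -> list[str]:
        return self.table["stage"].tolist()

    @property
    def recent_stage(self) -> str:
        return self.table["stage"].iloc[-1]

    def position(self, stage: str) -> int:
        if stage not in self._index:
            raise BinningError(f"unknown stage {stage!r}")
        return self._index[stage]

    def midpoint(self, stage: str) -> float:
        row = self.table.iloc[self.position(stage)]
        return (row["older_ma"] + row["younger_ma"]) / 2.0

    def span(self, first: str, last: str) -> list[str]:
        i, j = self.position(first), self.position(last)
        if i > j:
            i, j = j, i
        return self.stage_names[i : j + 1]


def default_timescale() -> GeologicTimescale:
    """The bundled stage table (Tithonian to Recent)."""
    ref = importlib.resources.files("pterochron.data") / "timescale.csv"
    with ref.open() as fh:
        return GeologicTimescale(pd.read_csv(fh))


# ---------------------------------------------------------------------------
# Record preparation
# ---------------------------------------------------------------------------

def _expand_records(table: pd.DataFrame, ts: GeologicTimescale) -> pd.DataFrame:
    """Accepted records only, with stage spans expanded one row per stage."""
    df = table.copy()
    df["species"] = df["species"].astype(str).str.strip()
    df["status"] = df["status"].astype(str).str.strip().str.lower()
    bad_status = set(df["status"]) - VALID_STATUSES
    if bad_status:
        raise ValueError(f"unknown status values {sorted(bad_status)}")
    df = df[df["status"] == "accepted"]
    rows = []
    bad_rows = []
    for idx, rec in df.iterrows():
        stage = str(rec["stage"]).strip()
        parts = [p.strip() for p in stage.replace("–", "-").split("-")]
        try:
            if len(parts) == 2 and parts[1]:
                stages = ts.span(parts[0], parts[1])
            else:
                ts.position(stage)
                stages = [stage]
        except BinningError:
            bad_rows.append(idx)
            continue
        for s in stages:
            rows.append((rec["species"], rec.get("clade", ""), s))
    if bad_rows:
        raise BinningError(
            f"unresolvable stages in rows {bad_rows[:10]}"
            + ("..." if len(bad_rows) > 10 else "")
        )
    return pd.DataFrame(rows, columns=["species", "clade", "stage"]).drop_duplicates()


def _filter_clades(df: pd.DataFrame, clades) -> pd.DataFrame:
    if clades is None or clades == "all":
        return df
    clades = {clades} if isinstance(clades, str) else set(clades)
    return df[df["clade"].isin(clades)]


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def observed_diversity(
    table: pd.DataFrame, ts: GeologicTimescale, clades=None
) -> pd.Series:
    """Distinct accepted species with >= 1 occurrence per stage."""
    df = _filter_clades(_expand_records(table, ts), clades)
    counts = df.groupby("stage")["species"].nunique()
    return counts.reindex(ts.stage_names, fill_value=0).astype(int)


def range_through_diversity(
    table: pd.DataFrame, ts: GeologicTimescale, clades=None
) -> pd.Series:
    """Each species counted in every stage between its first and last
    occurrence inclusive."""
    df = _filter_clades(_expand_records(table, ts), clades)
    out = pd.Series(0, index=ts.stage_names, dtype=int)
    pos = {s: i for i, s in enumerate(ts.stage_names)}
    for _, grp in df.groupby("species"):
        idx = [pos[s] for s in grp["stage"]]
        lo, hi = min(idx), max(idx)
        out.iloc[lo : hi + 1] += 1
    return out


def interval_summary(counts: pd.Series, interval: list[str], statistic: str = "median"):
    """A named statistic of per-stage counts over an interval of stages."""
    if not interval:
        raise ValueError("empty stage interval")
    missing = [s for s in interval if s not in counts.index]
    if missing:
        raise ValueError(f"stages not in the curve: {missing}")
    vals = counts.loc[interval].to_numpy(dtype=float)
    if statistic == "median":
        return float(np.median(vals))
    if statistic == "total":
        return float(vals.sum())
    if statistic == "mean":
        return float(vals.mean())
    raise ValueError(f"unknown statistic {statistic!r}")


def diversity_report(
    table: pd.DataFrame, ts: GeologicTimescale, plot_path=None
) -> pd.DataFrame:
    """Observed and range-through curves per clade and pooled.

    Returns a long table (clade_group, stage, stage_mid_ma, observed,
    range_through) with one "all" group pooling every clade; the report's
    ``attrs`` carry the Thanetian->Ypresian step of the pooled observed
    curve when both stages exist in the timescale.
    """
    groups: dict[str, object] = {"all": None}
    for clade in sorted(set(table["clade"].astype(str))):
        groups[clade] = clade
    frames = []
    for name, flt in groups.items():
        obs = observed_diversity(table, ts, clades=flt)
        rng = range_through_diversity(table, ts, clades=flt)
        frames.append(pd.DataFrame({
            "clade_group": name,
            "stage": ts.stage_names,
            "stage_mid_ma": [ts.midpoint(s) for s in ts.stage_names],
            "observed": obs.to_numpy(),
            "range_through": rng.to_numpy(),
        }))
    report = pd.concat(frames, ignore_index=True)
    pooled = report[report["clade_group"] == "all"].set_index("stage")
    if {"Thanetian", "Ypresian"} <= set(ts.stage_names):
        report.attrs["thanetian_observed"] = int(pooled.loc["Thanetian", "observed"])
        report.attrs["ypresian_observed"] = int(pooled.loc["Ypresian", "observed"])
    if plot_path is not None:
        _plot_report(report, plot_path)
    return report


def _plot_report(report: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4.5))
    for name, grp in report.groupby("clade_group"):
        lw = 2.5 if name == "all" else 1.2
        ax.step(grp["stage_mid_ma"], grp["observed"], where="mid", label=name, lw=lw)
    ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("observed species")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


#: Neogene stages preceding the Pleistocene, oldest first
NEOGENE_STAGES = [
    "Aquitanian", "Burdigalian", "Langhian", "Serravallian",
    "Tortonian", "Messinian", "Zanclean", "Piacenzian",
]
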
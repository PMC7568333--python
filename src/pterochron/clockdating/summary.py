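"""Posterior summaries of dating chains: means, credibility intervals, ESS."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..formats import DatedTree
from .mcmc import Chain


@dataclass
class PosteriorSummary:
    """Per-node and per-parameter posterior summaries of one chain."""

    nodes: pd.DataFrame  # node, mean, lower, upper, ess
    params: pd.DataFrame  # name, mean, lower, upper, ess
    tree: DatedTree
    internal_nodes: list[int]

    def node_row(self, node: int) -> pd.Series:
        return self.nodes.set_index("node").loc[node]

    def mean_age_tree(self) -> DatedTree:
        """Chronogram annotated with posterior-mean ages.

        Posterior means need not respect parent > child; children are nudged
        just below their parent where they would not (the annotated tree is a
        summary, not a sampled state).
        """
        ages = self.tree.ages.copy()
        means = self.nodes.set_index("node")["mean"]
        for n in self.internal_nodes:
            ages[n] = means.loc[n]
        for n in self.tree.preorder:
            par = self.tree.parent[n]
            if par >= 0 and n >= self.tree.n_tips and ages[n] >= ages[par]:
                ages[n] = ages[par] * (1 - 1e-9)
        return self.tree.with_ages(ages)


def effective_sample_size(x: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation-time estimate."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 4 or np.allclose(x, x[0]):
        return 0.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(x))


def summarize(chain: Chain, burn_in_fraction: float = 0.25) -> PosteriorSummary:
    """Summarise a chain: per-node mean, 95% CrI and ESS.

    ``burn_in_fraction`` discards an additional leading share of the retained
    samples (the sampler already dropped its configured burn-in).
    """
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    df = chain.samples
    start = int(len(df) * burn_in_fraction)
    df = df.iloc[start:]
    if df.empty:
        raise ValueError("no samples left after burn-in")

    def stats_for(x: np.ndarray):
        return (
            float(np.mean(x)),
            float(np.percentile(x, 2.5)),
            float(np.percentile(x, 97.5)),
            effective_sample_size(x),
        )

    node_rows = []
    for n in chain.internal_nodes:
        m, lo, hi, ess = stats_for(df[f"age_{n}"].to_numpy())
        node_rows.append((n, m, lo, hi, ess))
    nodes = pd.DataFrame(node_rows, columns=["node", "mean", "lower", "upper", "ess"])

    param_rows = []
    for col in df.columns:
        if col.startswith("age_") or col == "iteration":
            continue
        m, lo, hi, ess = stats_for(df[col].to_numpy())
        param_rows.append((col, m, lo, hi, ess))
    params = pd.DataFrame(param_rows, columns=["name", "mean", "lower", "upper", "ess"])

    root_ess = nodes.set_index("node").loc[chain.tree.root, "ess"]
    if root_ess < 50:
        warnings.warn(
            f"root-age ESS {root_ess:.0f} < 50: chain may not have converged"
        )
    return PosteriorSummary(
        nodes=nodes, params=params, tree=chain.tree,
        internal_nodes=list(chain.internal_nodes),
    )


def annotated_newick(summary: PosteriorSummary) -> str:
    """Newick of the posterior-mean chronogram with CrI comments on nodes."""
    tree = summary.mean_age_tree()
    labels = {}
    for _, row in summary.nodes.iterrows():
        n = int(row["node"])
        labels[n] = f"[&mean={row['mean']:.2f},CrI={{{row['lower']:.2f},{row['upper']:.2f}}}]"
    return tree.to_newick(labels=labels)
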
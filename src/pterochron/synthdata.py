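"""Synthetic data generators for every pipeline stage.

The generators emulate, at desk scale, the statistical structure of the real
study inputs: birth–death chronograms of extant taxa, relaxed-clock rate
variation, amino-acid gene alignments with per-gene taxon occupancy,
multi-lane transcript expression tables with index-hopping style
cross-contamination, and stage-binned fossil occurrence records with
preservation bias.  Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clockdating.models import BranchRateSet, ClockModelSpec
from .formats import GeneAlignment, DatedTree
from .subst import AA_ORDER, discrete_gamma_rates, get_model


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class SimulationSpec:
    """Conditions of one chronogram + alignment simulation."""

    seed: int
    n_extant_taxa: int = 28
    birth_rate: float = 0.05  # events / lineage / Myr
    death_rate: float = 0.02
    root_age: float = 140.0  # Ma
    clock: ClockModelSpec = field(default_factory=lambda: ClockModelSpec("CIR"))
    n_genes: int = 20
    gene_length_min: int = 200
    gene_length_max: int = 400
    missing_prob: float = 0.2
    subst_model: str = "poisson"
    gamma_shape: float | None = 0.8
    gamma_categories: int = 4

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.birth_rate > self.death_rate >= 0:
            raise ValueError("need birth_rate > death_rate >= 0")
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ValueError("missing_prob must be in [0, 1]")
        if self.n_extant_taxa < 2:
            raise ValueError("need at least 2 extant taxa")


@dataclass
class ContaminationSpec:
    """Conditions of one multi-lane expression-table simulation.

    ``lanes`` partitions dataset indices into sequencing lanes; only datasets
    sharing a lane can contaminate each other.  ``contamination`` is the
    fraction of a dataset's reads leaked into each lane-mate.
    """

    seed: int
    n_datasets: int = 6
    lanes: list[list[int]] | None = None
    n_transcripts: int = 2000
    contamination: float = 0.05
    library_size: int = 2_000_000
    abundance_log_mean: float = 1.0
    abundance_log_sd: float = 1.5
    length_log_mean: float = 7.0
    length_log_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.contamination < 1.0:
            raise ValueError("contamination fraction must be in [0, 1)")
        if self.lanes is None:
            # default: lanes of 2 datasets each
            ids = list(range(self.n_datasets))
            self.lanes = [ids[i : i + 2] for i in range(0, self.n_datasets, 2)]
        seen = [d for lane in self.lanes for d in lane]
        if sorted(seen) != list(range(self.n_datasets)):
            raise ValueError("lanes must partition the dataset indices")


# ---------------------------------------------------------------------------
# Chronogram
# ---------------------------------------------------------------------------

def gen_chronogram(spec: SimulationSpec) -> DatedTree:
    """Birth–death tree conditioned on the extant tip count by rejection,
    rescaled so the root (MRCA of extant tips) age equals ``spec.root_age``."""
    rng = np.random.default_rng(spec.seed)
    raw = simulate_bd_forward(
        rng, spec.n_extant_taxa, spec.birth_rate, spec.death_rate
    )
    taxa, parent, children, ages = raw
    tree = DatedTree(taxa, parent, children, ages)
    scale = spec.root_age / tree.root_age
    return tree.with_ages(tree.ages * scale)


def simulate_bd_forward(
    rng: np.random.Generator,
    n: int,
    lam: float,
    mu: float,
    max_attempts: int = 100_000,
):
    """Forward birth–death simulation from two lineages, stopped at the moment
    the extant lineage count first reaches ``n``; extinct subtrees are pruned
    and unifurcations suppressed.  Returns (taxa, parent, children, ages)."""
    for _ in range(max_attempts):
        out = _bd_once(rng, n, lam, mu)
        if out is not None:
            return out
    raise RuntimeError("birth–death simulation failed to reach the tip count")


def _bd_once(rng, n, lam, mu):
    # node records: time of birth, parent, children list, death time
    btime = [0.0, 0.0, 0.0]  # root and its two children
    parent = [-1, 0, 0]
    kids: list[list[int]] = [[1, 2], [], []]
    extant = [1, 2]
    t = 0.0
    while len(extant) < n:
        k = len(extant)
        if k == 0:
            return None
        t += rng.exponential(1.0 / (k * (lam + mu)))
        idx = extant[rng.integers(k)]
        if rng.random() < lam / (lam + mu):
            a, b = len(btime), len(btime) + 1
            btime += [t, t]
            parent += [idx, idx]
            kids[idx] = [a, b]
            kids += [[], []]
            extant.remove(idx)
            extant += [a, b]
        else:
            extant.remove(idx)
    # stop inside the holding interval at n tips, before the next event,
    # so the final cherry has a strictly positive pendant branch
    t_stop = t + rng.exponential(1.0 / (n * (lam + mu)))

    # prune extinct lineages: keep nodes with extant descendants
    extant_set = set(extant)
    keep = set()
    for tip in extant:
        node = tip
        while node >= 0 and node not in keep:
            keep.add(node)
            node = parent[node]

    def surviving_children(node):
        return [c for c in kids[node] if c in keep]

    # build pruned binary tree with unifurcations suppressed
    taxa = [f"t{i+1}" for i in range(n)]
    tip_of = {tip: i for i, tip in enumerate(sorted(extant_set))}
    new_parent = [-1] * (2 * n - 1)
    new_children: dict[int, tuple[int, int]] = {}
    new_age = [0.0] * (2 * n - 1)
    counter = [n]  # next internal index

    def build(node):
        """Return new index for the pruned subtree rooted at `node`."""
        while True:
            sc = surviving_children(node)
            if len(sc) == 1:
                node = sc[0]  # suppress unifurcation
            else:
                break
        sc = surviving_children(node)
        if not sc:  # extant tip
            i = tip_of[node]
            new_age[i] = 0.0
            return i
        i = counter[0]
        counter[0] += 1
        new_age[i] = t_stop - btime[kids[node][0]]  # split time of this node
        a = build(sc[0])
        b = build(sc[1])
        new_children[i] = (a, b)
        new_parent[a] = i
        new_parent[b] = i
        return i

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10 * n + 100))
    try:
        root = build(0)
    finally:
        sys.setrecursionlimit(old_limit)
    new_parent[root] = -1
    if new_age[root] <= 0:
        return None
    return taxa, np.array(new_parent), new_children, np.array(new_age)


# ---------------------------------------------------------------------------
# Branch rates
# ---------------------------------------------------------------------------

def gen_branch_rates(
    tree: DatedTree, clock: ClockModelSpec, seed: int
) -> BranchRateSet:
    """Draw per-branch rates under the requested relaxed clock."""
    rng = np.random.default_rng(seed)
    n = tree.n_nodes
    if clock.kind == "UGAM":
        if clock.nu == 0:
            rates = np.full(n, clock.mean_rate)
        else:
            shape = 1.0 / clock.nu
            rates = rng.gamma(shape, clock.mean_rate / shape, size=n)
        rates[tree.root] = np.nan
        return BranchRateSet(branch_rates=rates)

    node_rates = np.empty(n)
    if clock.kind == "LOGNORMAL_AC":
        node_rates[tree.root] = clock.mean_rate
        for node in tree.preorder:
            if node == tree.root:
                continue
            par = tree.parent[node]
            dt = tree.ages[par] - tree.ages[node]
            drift = -0.5 * clock.sigma2 * dt
            if clock.sigma2 == 0:
                node_rates[node] = node_rates[par]
            else:
                node_rates[node] = node_rates[par] * np.exp(
                    drift + rng.normal(0.0, np.sqrt(clock.sigma2 * dt))
                )
    elif clock.kind == "CIR":
        ClockModelSpec.check_feller(clock.theta, clock.mean_rate, clock.sigma2)
        stat_shape = 2.0 * clock.theta * clock.mean_rate / clock.sigma2
        node_rates[tree.root] = rng.gamma(
            stat_shape, clock.sigma2 / (2.0 * clock.theta)
        )
        for node in tree.preorder:
            if node == tree.root:
                continue
            par = tree.parent[node]
            dt = tree.ages[par] - tree.ages[node]
            node_rates[node] = _cir_step(
                rng, node_rates[par], dt, clock.theta, clock.mean_rate, clock.sigma2
            )
    else:
        raise ValueError(clock.kind)
    branch = np.full(n, np.nan)
    for node in range(n):
        par = tree.parent[node]
        if par >= 0:
            branch[node] = 0.5 * (node_rates[node] + node_rates[par])
    return BranchRateSet(branch_rates=branch, node_rates=node_rates)


def _cir_step(rng, r0, dt, theta, mean_rate, sigma2):
    """Exact CIR transition draw (noncentral chi-square representation)."""
    if sigma2 == 0 or dt == 0:
        return mean_rate + (r0 - mean_rate) * np.exp(-theta * dt)
    e = np.exp(-theta * dt)
    c = 4.0 * theta / (sigma2 * (1.0 - e))
    df = 4.0 * theta * mean_rate / sigma2
    nc = c * r0 * e
    return rng.noncentral_chisquare(df, nc) / c


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def gen_alignments(
    tree: DatedTree, rates: BranchRateSet, spec: SimulationSpec
) -> list[GeneAlignment]:
    """Evolve ``spec.n_genes`` alignments on the chronogram.

    Branch expected substitutions are rate x duration; sites evolve under the
    chosen substitution model with optional discrete-gamma rate heterogeneity.
    Whole taxa are deleted per gene with ``spec.missing_prob`` (occupancy is
    resampled whenever a draw would delete every taxon).
    """
    rng = np.random.default_rng(spec.seed + 1)
    model = get_model(spec.subst_model)
    if spec.gamma_shape is not None and spec.gamma_categories > 1:
        cat_rates = discrete_gamma_rates(spec.gamma_shape, spec.gamma_categories)
    else:
        cat_rates = np.ones(1)
    durations = tree.durations()
    nu = rates.branch_rates * durations  # expected substitutions per branch
    aa = np.frombuffer(AA_ORDER.encode(), dtype="S1").astype("U1")

    genes = []
    for g in range(spec.n_genes):
        length = int(rng.integers(spec.gene_length_min, spec.gene_length_max + 1))
        site_cat = rng.integers(len(cat_rates), size=length)
        seqs = np.empty((tree.n_nodes, length), dtype=np.int8)
        seqs[tree.root] = rng.choice(20, size=length, p=model.freqs)
        for node in tree.preorder:
            if node == tree.root:
                continue
            Ps = model.transition_matrices(nu[node] * cat_rates)
            cums = Ps.cumsum(axis=2)
            parent_states = seqs[tree.parent[node]]
            u = rng.random(length)
            rowcum = cums[site_cat, parent_states, :]  # (length, 20)
            seqs[node] = (u[:, None] > rowcum).sum(axis=1)
        while True:
            present = rng.random(tree.n_tips) >= spec.missing_prob
            if present.any():
                break
        rows = {
            tree.taxa[i]: "".join(aa[seqs[i]])
            for i in range(tree.n_tips)
            if present[i]
        }
        genes.append(GeneAlignment(gene_id=f"gene{g+1:04d}", rows=rows))
    return genes


# ---------------------------------------------------------------------------
# Contaminated expression tables
# ---------------------------------------------------------------------------

def gen_contaminated_expression(spec: ContaminationSpec) -> pd.DataFrame:
    """Simulate per-dataset transcript counts with cross-lane leakage.

    True abundances are log-normal; counts are multinomial reads over
    transcripts weighted by abundance x length; a fraction ``contamination``
    of every transcript's reads leaks into each lane-mate as a distinct row
    (same transcript id, recipient dataset).  TPMs are recomputed per dataset
    from the final counts.  Ground-truth columns ``origin_dataset`` and
    ``is_contaminant`` are retained for scoring.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    native = {}
    lengths = {}
    lane_of = {}
    for lane_id, lane in enumerate(spec.lanes):
        for d in lane:
            lane_of[d] = lane_id
    for d in range(spec.n_datasets):
        tids = [f"d{d}_t{i}" for i in range(spec.n_transcripts)]
        abund = rng.lognormal(spec.abundance_log_mean, spec.abundance_log_sd,
                              size=spec.n_transcripts)
        tlen = rng.lognormal(spec.length_log_mean, spec.length_log_sd,
                             size=spec.n_transcripts)
        w = abund * tlen
        counts = rng.multinomial(spec.library_size, w / w.sum())
        native[d] = (tids, counts)
        lengths[d] = tlen

    for lane_id, lane in enumerate(spec.lanes):
        for d in lane:
            tids, counts = native[d]
            tlen = lengths[d]
            recs = [
                (tids[i], d, lane_id, float(counts[i]), tlen[i], d, False)
                for i in range(len(tids))
                if counts[i] > 0
            ]
            for mate in lane:
                if mate == d or spec.contamination == 0:
                    continue
                src_tids, src_counts = native[mate]
                leak = rng.binomial(src_counts, spec.contamination)
                src_len = lengths[mate]
                recs += [
                    (src_tids[i], d, lane_id, float(leak[i]), src_len[i], mate, True)
                    for i in range(len(src_tids))
                    if leak[i] > 0
                ]
            df = pd.DataFrame(
                recs,
                columns=["transcript_id", "dataset_id", "lane_id", "est_count",
                         "length", "origin_dataset", "is_contaminant"],
            )
            rpk = df["est_count"] / df["length"]
            df["tpm"] = rpk / rpk.sum() * 1e6
            rows.append(df)
    out = pd.concat(rows, ignore_index=True)
    cols = ["transcript_id", "dataset_id", "lane_id", "est_count", "tpm",
            "length", "origin_dataset", "is_contaminant"]
    return out[cols]


# ---------------------------------------------------------------------------
# Fossil record
# ---------------------------------------------------------------------------

def gen_fossil_record(
    clades: list[str],
    timescale,
    preservation,
    richness: dict[str, int],
    seed: int,
    mean_range_stages: float = 3.0,
    recent_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a species-level occurrence table with preservation bias.

    Each clade carries ``richness[clade]`` true species; every species lives
    through a contiguous run of stages (geometric duration, mean
    ``mean_range_stages``), a fraction ``recent_fraction`` of species ranging
    to the Recent.  Within each lived-through stage the species is recorded
    with that stage's preservation probability; Recent occurrences are always
    recorded.  Returns ``(occurrences, truth)`` where ``truth`` lists the full
    true ranges for scoring.

    ``preservation`` maps stage name -> probability (or a scalar applied to
    all pre-Recent stages); ``timescale`` is a GeologicTimescale.
    """
    rng = np.random.default_rng(seed)
    stages = [s for s in timescale.stage_names]
    recent = timescale.recent_stage
    pre_recent = [s for s in stages if s != recent]
    if np.isscalar(preservation):
        pres = {s: float(preservation) for s in pre_recent}
    else:
        pres = dict(preservation)
    occ_rows = []
    truth_rows = []
    for clade in clades:
        for k in range(richness.get(clade, 0)):
            sp = f"{clade}_sp{k+1}"
            to_recent = rng.random() < recent_fraction
            dur = int(rng.geometric(1.0 / mean_range_stages))
            if to_recent:
                first = max(0, len(stages) - dur)
                lived = stages[first:]
            else:
                last = int(rng.integers(len(pre_recent)))
                first = max(0, last - dur + 1)
                lived = pre_recent[first : last + 1]
            for st in lived:
                truth_rows.append((sp, clade, st))
                if st == recent:
                    recorded = True
                else:
                    recorded = rng.random() < pres.get(st, 0.0)
                if recorded:
                    occ_rows.append((sp, clade, st, "accepted"))
    occ = pd.DataFrame(occ_rows, columns=["species", "clade", "stage", "status"])
    truth = pd.DataFrame(truth_rows, columns=["species", "clade", "stage"])
    return occ, truth
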
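"""Ortholog selection, trimming, concatenation and gene informativeness.

The selection rules mirror common phylogenomic practice: keep single-copy
genes that are represented in at least one outgroup taxon and at least half
of the ingroup; trim alignment columns that are mostly gaps or essentially
unconserved; concatenate into a partitioned supermatrix whose missing-data
fraction counts both internal gaps and the padding of absent taxa.

Gene informativeness is ranked by mean bootstrap support of the gene's own
tree.  Trees are built by neighbor joining on pairwise distances corrected
under the 20-state equal-rates model — a deliberately cheap proxy for
per-gene maximum-likelihood trees that preserves the selection procedure
(rank genes by mean support, take the top k).  Externally computed per-gene
scores can be supplied instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .errors import ConfigError, RosterError
from .formats import GeneAlignment


@dataclass
class OrthologSet:
    """Per-gene alignments plus the ingroup/outgroup taxon roster."""

    genes: dict[str, GeneAlignment]
    ingroup: list[str]
    outgroup: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.ingroup) & set(self.outgroup)
        if overlap:
            raise ConfigError(f"taxa in both rosters: {sorted(overlap)}")
        roster = set(self.ingroup) | set(self.outgroup)
        for gid, aln in self.genes.items():
            extra = set(aln.taxa) - roster
            if extra:
                raise RosterError(f"{gid}: taxa not in roster: {sorted(extra)}")


@dataclass
class Supermatrix:
    """Concatenated alignment with a partition map and missing-data share."""

    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]  # gene_id -> [start, end)
    missing_fraction: float

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))


@dataclass
class GeneScore:
    gene_id: str
    support: float | None  # mean bootstrap percentage, None if unscored
    n_taxa: int


# ---------------------------------------------------------------------------
# Selection & trimming
# ---------------------------------------------------------------------------

def select_single_copy(
    ortho: OrthologSet,
    min_outgroup: int = 1,
    min_ingroup_frac: float = 0.5,
) -> list[str]:
    """Genes with >= min_outgroup outgroup taxa and >= ceil(frac * |ingroup|)
    ingroup taxa present."""
    if not ortho.ingroup and not ortho.outgroup:
        raise ConfigError("empty taxon roster")
    need_in = math.ceil(min_ingroup_frac * len(ortho.ingroup))
    ingroup = set(ortho.ingroup)
    outgroup = set(ortho.outgroup)
    kept = []
    for gid in sorted(ortho.genes):
        taxa = set(ortho.genes[gid].taxa)
        if len(taxa & outgroup) >= min_outgroup and len(taxa & ingroup) >= need_in:
            kept.append(gid)
    return kept


def trim_columns(
    aln: GeneAlignment,
    min_nongap_frac: float = 0.15,
    min_similarity: float = 0.001,
) -> GeneAlignment:
    """Drop mostly-gap columns, then columns below a conservation floor.

    Similarity of a column is the frequency of its modal residue among
    non-gap residues (gaps and X excluded); all-gap columns have similarity 0.
    Column order is preserved; an empty result is returned with a warning.
    """
    taxa = aln.taxa
    mat = np.array([list(aln.rows[t]) for t in taxa])
    nongap = (mat != "-") & (mat != "X")
    frac = nongap.mean(axis=0)
    keep = frac >= min_nongap_frac
    sim = np.zeros(aln.length)
    for j in np.flatnonzero(keep):
        col = mat[nongap[:, j], j]
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            sim[j] = counts.max() / col.size
    keep &= sim >= min_similarity
    if not keep.any():
        warnings.warn(f"{aln.gene_id}: all columns removed by trimming")
        return _empty_alignment(aln)
    rows = {t: "".join(mat[i, keep]) for i, t in enumerate(taxa)}
    return GeneAlignment(gene_id=aln.gene_id, rows=rows)


def _empty_alignment(aln: GeneAlignment) -> GeneAlignment:
    out = GeneAlignment.__new__(GeneAlignment)
    out.gene_id = aln.gene_id
    out.rows = {t: "" for t in aln.taxa}
    out.length = 0
    return out


def concatenate(genes: list[GeneAlignment], taxa: list[str]) -> Supermatrix:
    """Concatenate gene alignments over a roster, padding absent taxa with '-'.

    The missing fraction counts padded cells and internal gaps ('-' and 'X')
    over the full taxa x columns grid.
    """
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids")
    roster = set(taxa)
    for g in genes:
        extra = set(g.taxa) - roster
        if extra:
            raise RosterError(f"{g.gene_id}: taxa not in roster: {sorted(extra)}")
    partitions: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    pos = 0
    for g in genes:
        partitions[g.gene_id] = (pos, pos + g.length)
        pos += g.length
        pad = "-" * g.length
        for t in taxa:
            chunks[t].append(g.rows.get(t, pad))
    rows = {t: "".join(chunks[t]) for t in taxa}
    total = len(taxa) * pos
    missing = sum(s.count("-") + s.count("X") for s in rows.values())
    return Supermatrix(
        taxa=list(taxa),
        rows=rows,
        partitions=partitions,
        missing_fraction=missing / total if total else 0.0,
    )


def missing_fraction(sm: Supermatrix) -> float:
    """Recompute the missing-data proportion from the residue matrix."""
    total = len(sm.taxa) * sm.length
    if total == 0:
        return 0.0
    missing = sum(s.count("-") + s.count("X") for s in sm.rows.values())
    return missing / total


# ---------------------------------------------------------------------------
# Gene informativeness
# ---------------------------------------------------------------------------

def _pairwise_distances(mat: np.ndarray) -> np.ndarray:
    """Distances corrected under the 20-state equal-rates model.

    p is the mismatch proportion over mutually non-missing sites and
    d = -(19/20) ln(1 - 20 p / 19); saturated or non-overlapping pairs get a
    large finite cap.
    """
    n = mat.shape[0]
    ok = (mat != "-") & (mat != "X")
    cap = 10.0
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = both.sum()
            if m == 0:
                d = cap
            else:
                p = (mat[i, both] != mat[j, both]).mean()
                arg = 1.0 - 20.0 * p / 19.0
                d = cap if arg <= 0 else min(cap, -(19.0 / 20.0) * math.log(arg))
            D[i, j] = D[j, i] = d
    return D


def _nj_bipartitions(D: np.ndarray, names: list[str]) -> set[frozenset]:
    """Non-trivial bipartitions (as smaller-side tip sets) of the NJ tree."""
    dm = DistanceMatrix(D, ids=names)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tree = nj(dm)
    allnames = frozenset(names)
    bips = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(names) - 1:
            other = allnames - side
            bips.add(min(side, other, key=lambda s: (len(s), sorted(s))))
    return bips


def gene_support_scores(
    genes: list[GeneAlignment], n_boot: int = 100, seed: int = 0
) -> list[GeneScore]:
    """Mean bootstrap support of each gene's NJ tree.

    For each gene with >= 4 taxa: build the NJ tree on corrected distances,
    resample columns ``n_boot`` times, and score the mean percentage of
    bootstrap trees containing each internal bipartition of the original
    tree.  Genes with < 4 taxa are returned unscored (support None).
    """
    rng = np.random.default_rng(seed)
    scores = []
    for g in genes:
        if g.n_taxa < 4:
            scores.append(GeneScore(g.gene_id, None, g.n_taxa))
            continue
        names = g.taxa
        mat = np.array([list(g.rows[t]) for t in names])
        ref = _nj_bipartitions(_pairwise_distances(mat), names)
        if not ref:
            scores.append(GeneScore(g.gene_id, None, g.n_taxa))
            continue
        hits = {b: 0 for b in ref}
        for _ in range(n_boot):
            cols = rng.integers(g.length, size=g.length)
            boot = _nj_bipartitions(_pairwise_distances(mat[:, cols]), names)
            for b in ref:
                if b in boot:
                    hits[b] += 1
        support = 100.0 * np.mean([hits[b] / n_boot for b in ref])
        scores.append(GeneScore(g.gene_id, float(support), g.n_taxa))
    return scores


def select_top_genes(scores: list[GeneScore], k: int = 200) -> list[str]:
    """Top-k gene ids by support; ties broken by larger n_taxa then id.

    The result is deterministic and independent of input order.  If fewer
    than k genes are scored, all scored genes are returned with a warning.
    """
    scored = [s for s in scores if s.support is not None]
    if len(scored) < k:
        warnings.warn(f"only {len(scored)} scored genes for k={k}")
    ranked = sorted(scored, key=lambda s: (-s.support, -s.n_taxa, s.gene_id))
    return [s.gene_id for s in ranked[:k]]


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_supermatrix_phylip(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.length}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.rows[t]}\n")


def partitions_frame(sm: Supermatrix) -> pd.DataFrame:
    """Partition map with 1-based inclusive coordinates for reports."""
    rows = [
        (gid, start + 1, end) for gid, (start, end) in sm.partitions.items()
    ]
    return pd.DataFrame(rows, columns=["gene_id", "first_col", "last_col"])
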
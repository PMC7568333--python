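"""Readers and writers for alignments, dated trees, tables and run configs.

Conventions
-----------
* Alignments are amino-acid only: the 20 IUPAC residues, ``-`` for gaps and
  ``X`` for unknowns.  Residues are upper-cased on input and ``.`` is
  normalised to ``-``.
* Trees are rooted, binary and ultrametric.  Newick branch lengths are
  durations in Myr; node ages are always derived from the durations (root age
  = maximal tip-to-root path) and never stored as labels, so files stay
  standard-Newick compatible.
* Tables are plain CSV with fixed header names; unknown columns are carried
  along untouched.
* Alignment columns are 0-based half-open internally; user-facing reports are
  1-based inclusive.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    FormatError,
    SchemaError,
    TreeError,
)

AA_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
VALID_CHARS = frozenset(AA_RESIDUES + "-X")

#: relative tolerance on tip depths for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-9


# ---------------------------------------------------------------------------
# GeneAlignment
# ---------------------------------------------------------------------------

@dataclass
class GeneAlignment:
    """A single gene's amino-acid alignment.

    Parameters
    ----------
    gene_id : str
        Identifier of the gene (ortholog group).
    rows : dict of str -> str
        Mapping taxon name -> aligned sequence.  All sequences must have
        equal length; taxon names are unique by construction of the dict,
        and readers raise :class:`FormatError` on duplicated names.
    """

    gene_id: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError(f"{self.gene_id}: alignment has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"{self.gene_id}: ragged rows (lengths {sorted(lengths)})"
            )
        self.length = lengths.pop()
        if self.length < 1:
            raise AlignmentError(f"{self.gene_id}: zero-length alignment")
        for taxon, seq in self.rows.items():
            bad = set(seq) - VALID_CHARS
            if bad:
                raise FormatError(
                    f"{self.gene_id}/{taxon}: invalid residues {sorted(bad)}"
                )

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        return "".join(seq[i] for seq in self.rows.values())


def _normalise(seq: str) -> str:
    return seq.upper().replace(".", "-")


def read_alignment(path: str | os.PathLike, dialect: str = "fasta") -> GeneAlignment:
    """Read one gene alignment from FASTA or relaxed sequential PHYLIP.

    The gene id is the file's base name without extension.
    """
    gene_id = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    with open(path) as fh:
        text = fh.read()
    if dialect == "fasta":
        rows = _parse_fasta(text)
    elif dialect == "phylip":
        rows = _parse_phylip(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return GeneAlignment(gene_id=gene_id, rows=rows)


def _parse_fasta(text: str) -> dict[str, str]:
    rows: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None:
                rows[name] = _normalise("".join(chunks))
            name = line[1:].split()[0]
            if name in rows:
                raise FormatError(f"duplicate taxon {name!r}")
            chunks = []
        else:
            if name is None:
                raise FormatError("sequence data before first FASTA header")
            chunks.append(line)
    if name is not None:
        rows[name] = _normalise("".join(chunks))
    if not rows:
        raise FormatError("empty FASTA file")
    return rows


def _parse_phylip(text: str) -> dict[str, str]:
    """Relaxed sequential PHYLIP: header `ntax nchar`, then `name  sequence`
    one taxon per line (whitespace inside the sequence allowed)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty PHYLIP file")
    try:
        ntax, nchar = (int(tok) for tok in lines[0].split()[:2])
    except (ValueError, IndexError) as exc:
        raise FormatError("bad PHYLIP header") from exc
    rows: dict[str, str] = {}
    for ln in lines[1 : 1 + ntax]:
        parts = ln.split()
        if len(parts) < 2:
            raise FormatError(f"bad PHYLIP row: {ln!r}")
        name, seq = parts[0], _normalise("".join(parts[1:]))
        if name in rows:
            raise FormatError(f"duplicate taxon {name!r}")
        if len(seq) != nchar:
            raise AlignmentError(
                f"{name}: sequence length {len(seq)} != header nchar {nchar}"
            )
        rows[name] = seq
    if len(rows) != ntax:
        raise FormatError(f"expected {ntax} rows, found {len(rows)}")
    return rows


def write_alignment(
    aln: GeneAlignment, path: str | os.PathLike, dialect: str = "fasta"
) -> None:
    with open(path, "w") as fh:
        if dialect == "fasta":
            for taxon, seq in aln.rows.items():
                fh.write(f">{taxon}\n{seq}\n")
        elif dialect == "phylip":
            fh.write(f"{aln.n_taxa} {aln.length}\n")
            for taxon, seq in aln.rows.items():
                fh.write(f"{taxon}  {seq}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# DatedTree
# ---------------------------------------------------------------------------

class DatedTree:
    """Rooted binary ultrametric tree with node ages in Ma.

    Nodes are indexed ``0 .. 2n-2`` with the ``n`` tips first (in ``taxa``
    order) and the root last in postorder.  Ages are measured back from the
    present: every tip has age 0 and every parent is strictly older than its
    children.  Branch durations are ``age[parent] - age[child]``.
    """

    def __init__(
        self,
        taxa: list[str],
        parent: np.ndarray,
        children: dict[int, tuple[int, int]],
        ages: np.ndarray,
    ):
        self.taxa = list(taxa)
        self.parent = np.asarray(parent, dtype=int)
        self.children = dict(children)
        self.ages = np.asarray(ages, dtype=float)
        self.n_tips = len(self.taxa)
        self.n_nodes = len(self.ages)
        if len(set(self.taxa)) != self.n_tips:
            raise TreeError("duplicate tip names")
        if self.n_nodes != 2 * self.n_tips - 1:
            raise TreeError("tree is not binary")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise TreeError("tree must have exactly one root")
        self.root = int(roots[0])
        self._validate()
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1]
        self.tip_index = {name: i for i, name in enumerate(self.taxa)}

    def _validate(self) -> None:
        if self.root_age <= 0:
            raise TreeError("root age must be positive")
        for child, par in enumerate(self.parent):
            if par < 0:
                continue
            if not self.ages[par] > self.ages[child]:
                raise TreeError(
                    f"parent {par} (age {self.ages[par]}) not older than "
                    f"child {child} (age {self.ages[child]})"
                )
        tips = self.ages[: self.n_tips]
        if np.any(np.abs(tips) > ULTRAMETRIC_RTOL * self.root_age):
            raise TreeError("tip ages must all be 0 (extant taxa)")

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def _postorder(self) -> list[int]:
        order: list[int] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if node < self.n_tips:
                order.append(node)
            elif expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return order

    @property
    def internal_nodes(self) -> list[int]:
        return [n for n in self.postorder if n >= self.n_tips]

    def durations(self) -> np.ndarray:
        """Branch duration above each node (root entry is 0)."""
        d = np.zeros(self.n_nodes)
        mask = self.parent >= 0
        d[mask] = self.ages[self.parent[mask]] - self.ages[np.flatnonzero(mask)]
        return d

    def mrca(self, taxa) -> int:
        """Least common ancestor node of a nonempty set of tip names."""
        taxa = list(taxa)
        if not taxa:
            raise ValueError("empty taxon set")
        try:
            nodes = [self.tip_index[t] for t in taxa]
        except KeyError as exc:
            raise KeyError(f"unknown taxon {exc.args[0]!r}") from exc
        paths = []
        for n in nodes:
            path = []
            while n >= 0:
                path.append(n)
                n = self.parent[n]
            paths.append(path[::-1])
        mrca = paths[0][0]
        for depth in range(min(len(p) for p in paths)):
            vals = {p[depth] for p in paths}
            if len(vals) == 1:
                mrca = vals.pop()
            else:
                break
        return mrca

    def clade_tips(self, node: int) -> set[str]:
        """Tip names descending from (and including) a node."""
        out: set[str] = set()
        stack = [node]
        while stack:
            n = stack.pop()
            if n < self.n_tips:
                out.add(self.taxa[n])
            else:
                stack.extend(self.children[n])
        return out

    def copy(self) -> "DatedTree":
        return DatedTree(self.taxa, self.parent.copy(), self.children, self.ages.copy())

    def with_ages(self, ages: np.ndarray) -> "DatedTree":
        return DatedTree(self.taxa, self.parent.copy(), self.children, np.asarray(ages))

    # -- Newick ------------------------------------------------------------

    def to_newick(self, labels: dict[int, str] | None = None) -> str:
        def emit(node: int) -> str:
            if node < self.n_tips:
                s = self.taxa[node]
            else:
                a, b = self.children[node]
                s = f"({emit(a)},{emit(b)})"
                if labels and node in labels:
                    s += labels[node]
            par = self.parent[node]
            if par >= 0:
                s += f":{self.ages[par] - self.ages[node]:.12g}"
            return s

        return emit(self.root) + ";"


def _tree_from_dendropy(dtree: dendropy.Tree) -> DatedTree:
    dtree.is_rooted = True
    leaves = [lf for lf in dtree.leaf_node_iter()]
    taxa = [lf.taxon.label for lf in leaves]
    if len(set(taxa)) != len(taxa):
        raise TreeError("duplicate tip names")
    for nd in dtree.preorder_node_iter():
        nchild = len(nd.child_nodes())
        if nchild not in (0, 2):
            raise TreeError("tree must be binary and rooted (no polytomies)")
    # depths from root, then ages = root_age - depth
    depth = {dtree.seed_node: 0.0}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            continue
        if nd.edge.length is None:
            raise TreeError("missing branch length")
        depth[nd] = depth[nd.parent_node] + float(nd.edge.length)
    tip_depths = np.array([depth[lf] for lf in leaves])
    root_age = float(tip_depths.max())
    if root_age <= 0:
        raise TreeError("root age must be positive")
    if np.any(np.abs(tip_depths - root_age) > ULTRAMETRIC_RTOL * root_age):
        raise TreeError(
            "tree is not ultrametric: tip depths span "
            f"[{tip_depths.min():.6g}, {tip_depths.max():.6g}]"
        )
    n = len(taxa)
    index: dict = {lf: i for i, lf in enumerate(leaves)}
    nxt = n
    for nd in dtree.postorder_internal_node_iter():
        index[nd] = nxt
        nxt += 1
    parent = np.full(2 * n - 1, -1, dtype=int)
    children: dict[int, tuple[int, int]] = {}
    ages = np.zeros(2 * n - 1)
    for nd, i in index.items():
        ages[i] = 0.0 if nd.is_leaf() else root_age - depth[nd]
        if nd.parent_node is not None:
            parent[i] = index[nd.parent_node]
        if not nd.is_leaf():
            a, b = nd.child_nodes()
            children[i] = (index[a], index[b])
    # snap tip ages to exactly zero
    ages[:n] = 0.0
    return DatedTree(taxa, parent, children, ages)


def read_newick_dated(source: str | os.PathLike) -> DatedTree:
    """Parse a Newick chronogram whose branch lengths are durations in Myr.

    `source` may be a path or a literal Newick string.
    """
    text = None
    src = os.fspath(source) if not isinstance(source, str) else source
    if isinstance(src, str) and src.lstrip().startswith("("):
        text = src
    else:
        with open(src) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises many flavours
        raise TreeError(f"unparseable Newick: {exc}") from exc
    return _tree_from_dendropy(dtree)


def write_newick_dated(
    tree: DatedTree, path: str | os.PathLike, labels: dict[int, str] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(labels=labels) + "\n")


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

TABLE_SCHEMAS: dict[str, dict] = {
    "transcript": {
        "columns": ["transcript_id", "dataset_id", "lane_id", "est_count", "tpm"],
        "numeric": ["est_count", "tpm"],
        "nonnegative": ["est_count", "tpm"],
    },
    "occurrence": {
        "columns": ["species", "clade", "stage", "status"],
        "numeric": [],
        "nonnegative": [],
    },
    "ortholog_presence": {
        "columns": ["gene_id", "taxon", "copy_number"],
        "numeric": ["copy_number"],
        "nonnegative": ["copy_number"],
    },
}


def read_table(path: str | os.PathLike | io.TextIOBase, schema: str) -> pd.DataFrame:
    """Read a CSV table and validate it against a named schema.

    Unknown columns are preserved; mandatory columns are type-checked.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = TABLE_SCHEMAS[schema]
    df = pd.read_csv(path)
    missing = [c for c in spec["columns"] if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing mandatory columns {missing}")
    for col in spec["numeric"]:
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in spec["nonnegative"]:
        if (df[col] < 0).any():
            raise ValueError(f"{schema}: negative values in column {col!r}")
    return df


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

CLOCK_MODELS = ("UGAM", "LOGNORMAL_AC", "CIR")
AGE_PRIORS = ("uniform", "birth_death", "dirichlet")
SUBST_MODELS = ("poisson", "lg")


@dataclass
class RunConfig:
    """Fully resolved configuration of one dating run."""

    seed: int
    clock_model: str = "CIR"
    age_prior: str = "birth_death"
    calibration_scheme: str = "s4"
    iterations: int = 20000
    burn_in: int = 5000
    thinning: int = 10
    subst_model: str = "poisson"
    gamma_categories: int = 4
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        self.seed = int(self.seed)
        if self.iterations <= self.burn_in:
            raise ConfigError("iterations must exceed burn_in")
        if self.clock_model not in CLOCK_MODELS:
            raise ConfigError(f"unknown clock model {self.clock_model!r}")
        if self.age_prior not in AGE_PRIORS:
            raise ConfigError(f"unknown age prior {self.age_prior!r}")
        if self.subst_model not in SUBST_MODELS:
            raise ConfigError(f"unknown substitution model {self.subst_model!r}")
        if self.gamma_categories < 1:
            raise ConfigError("gamma_categories must be >= 1")


def read_config(path: str | os.PathLike) -> RunConfig:
    """Read a flat key = value config file (TOML subset)."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = {f for f in RunConfig.__dataclass_fields__ if f != "extra"}
    kwargs = {k: v for k, v in data.items() if k in known}
    extra = {k: v for k, v in data.items() if k not in known}
    if "seed" not in kwargs:
        raise ConfigError("seed is mandatory")
    return RunConfig(extra=extra, **kwargs)


def write_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    """Echo a fully resolved config (for reproducibility of stochastic runs)."""
    with open(path, "w") as fh:
        for key in RunConfig.__dataclass_fields__:
            if key == "extra":
                continue
            val = getattr(cfg, key)
            if isinstance(val, str):
                fh.write(f'{key} = "{val}"\n')
            else:
                fh.write(f"{key} = {val}\n")
        for key, val in cfg.extra.items():
            if isinstance(val, str):
                fh.write(f'{key} = "{val}"\n')
            else:
                fh.write(f"{key} = {val}\n")
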
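"""Felsenstein pruning likelihood over unique site patterns.

The engine evaluates the log-likelihood of amino-acid data on a fixed
topology given per-branch expected substitutions (rate x duration), with an
optional discrete-gamma mixture over site rates.  It supports transactional
partial updates: when a move changes a handful of branch lengths, only the
partials on the path from the affected branches to the root are recomputed,
and a rejected proposal restores them.
"""

from __future__ import annotations

import math

import numpy as np

from ..formats import DatedTree, GeneAlignment
from ..subst import AA_ORDER, SubstModel, discrete_gamma_rates, get_model
from .models import BranchRateSet

MISSING = 20
_CODE = {aa: i for i, aa in enumerate(AA_ORDER)}
_CODE["-"] = MISSING
_CODE["X"] = MISSING

#: per-pattern rescaling threshold for underflow protection
_SCALE_FLOOR = 1e-240


def encode_genes(genes: list[GeneAlignment], taxa: list[str]) -> np.ndarray:
    """Concatenate genes into an integer matrix (n_taxa, n_sites);
    gaps, X and absent taxa are coded as missing."""
    chunks = []
    for g in genes:
        block = np.full((len(taxa), g.length), MISSING, dtype=np.int8)
        for i, t in enumerate(taxa):
            if t in g.rows:
                block[i] = [_CODE[ch] for ch in g.rows[t]]
        chunks.append(block)
    return np.concatenate(chunks, axis=1)


class PruningEngine:
    """Pruning likelihood with pattern compression and path updates."""

    def __init__(
        self,
        tree: DatedTree,
        codes: np.ndarray,
        model: SubstModel | str,
        gamma_categories: int = 1,
        gamma_shape: float = 0.8,
    ):
        self.tree = tree
        self.model = get_model(model) if isinstance(model, str) else model
        self.K = int(gamma_categories)
        self.gamma_shape = float(gamma_shape)
        self.cat_rates = discrete_gamma_rates(self.gamma_shape, self.K)

        patterns, counts = np.unique(codes.T, axis=0, return_counts=True)
        self.patterns = patterns.T  # (n_taxa, n_pat)
        self.counts = counts.astype(float)
        self.n_pat = patterns.shape[0]
        # per-tip observed-site masks and codes, fixed for the run
        self._tip_obs = {}
        for t in range(tree.n_tips):
            obs = self.patterns[t] < MISSING
            self._tip_obs[t] = (
                obs, self.patterns[t][obs].astype(np.intp), bool(obs.all())
            )

        self.partials: dict[int, np.ndarray] = {}
        self.scale_log: dict[int, np.ndarray] = {}
        self.bl = np.zeros(tree.n_nodes)
        self._saved: dict | None = None
        self._loglik = -np.inf

    # -- core recomputation -------------------------------------------------

    def _node_partial(self, node: int) -> tuple[np.ndarray, np.ndarray | None]:
        """Partial likelihood array (K, n_pat, 20) of one internal node."""
        tree = self.tree
        c1, c2 = tree.children[node]
        # both children's transition matrices in one spectral evaluation
        lens = np.concatenate([self.bl[c1] * self.cat_rates,
                               self.bl[c2] * self.cat_rates])
        Pall = self.model.transition_matrices(lens)
        out = None
        for i, c in enumerate((c1, c2)):
            Ps = Pall[i * self.K : (i + 1) * self.K]
            if c < tree.n_tips:
                obs, codes_obs, all_obs = self._tip_obs[c]
                sel = Ps[:, :, codes_obs].transpose(0, 2, 1)  # (K, n_obs, 20)
                if all_obs:
                    contrib = sel
                else:
                    contrib = np.ones((self.K, self.n_pat, 20))
                    contrib[:, obs, :] = sel
            else:
                child = self.partials[c]  # (K, n_pat, 20)
                contrib = child @ Ps.transpose(0, 2, 1)
            out = contrib if out is None else out * contrib
        if out.min() < _SCALE_FLOOR:
            mx = out.max(axis=2)
            safe = np.where(mx > 0.0, mx, 1.0)
            out = out / safe[:, :, None]
            return out, np.log(safe)
        return out, None

    def _root_loglik(self) -> float:
        root = self.tree.root
        site = self.partials[root] @ self.model.freqs  # (K, n_pat)
        scales = [s for s in self.scale_log.values() if s is not None]
        if not scales:
            if self.K == 1:
                return float(
                    (self.counts * np.log(np.maximum(site[0], 1e-300))).sum()
                )
            persite = np.log(np.maximum(site.mean(axis=0), 1e-300))
            return float((self.counts * persite).sum())
        total_scale = scales[0].copy()
        for s in scales[1:]:
            total_scale += s
        # mix categories in log space to respect per-category scaling
        logmix = np.log(np.maximum(site, 1e-300)) + total_scale
        m = logmix.max(axis=0)
        persite = m + np.log(np.exp(logmix - m).mean(axis=0))
        return float((self.counts * persite).sum())

    def set_lengths(self, branch_lengths: np.ndarray) -> float:
        """Full recompute with new branch lengths (indexed by child node)."""
        self.bl = np.asarray(branch_lengths, dtype=float).copy()
        if np.any(self.bl[np.arange(self.tree.n_nodes) != self.tree.root] < 0):
            raise ValueError("negative branch length")
        for node in self.tree.postorder:
            if node >= self.tree.n_tips:
                self.partials[node], self.scale_log[node] = self._node_partial(node)
        self._loglik = self._root_loglik()
        return self._loglik

    def set_gamma_shape(self, shape: float) -> float:
        self.gamma_shape = float(shape)
        self.cat_rates = discrete_gamma_rates(self.gamma_shape, self.K)
        return self.set_lengths(self.bl)

    @property
    def loglik(self) -> float:
        return self._loglik

    # -- transactional path updates -----------------------------------------

    def propose(self, new_lengths: dict[int, float]) -> float:
        """Tentatively change the branches above the given nodes.

        Recomputes only the partials on the paths to the root and returns the
        new log-likelihood; follow with :meth:`accept` or :meth:`reject`.
        """
        tree = self.tree
        affected: list[int] = []
        seen = set()
        for c in new_lengths:
            node = tree.parent[c] if c != tree.root else c
            while node >= 0 and node not in seen:
                seen.add(node)
                node = tree.parent[node]
        for node in tree.postorder:
            if node in seen and node >= tree.n_tips:
                affected.append(node)
        saved_bl = {c: self.bl[c] for c in new_lengths}
        saved_parts = {n: (self.partials[n], self.scale_log[n]) for n in affected}
        for c, v in new_lengths.items():
            if v < 0:
                raise ValueError("negative branch length")
            self.bl[c] = v
        for n in affected:
            self.partials[n], self.scale_log[n] = self._node_partial(n)
        self._saved = {
            "bl": saved_bl,
            "parts": saved_parts,
            "loglik": self._loglik,
        }
        self._loglik = self._root_loglik()
        return self._loglik

    def accept(self) -> None:
        self._saved = None

    def reject(self) -> None:
        if self._saved is None:
            raise RuntimeError("nothing to reject")
        for c, v in self._saved["bl"].items():
            self.bl[c] = v
        for n, (p, s) in self._saved["parts"].items():
            self.partials[n] = p
            self.scale_log[n] = s
        self._loglik = self._saved["loglik"]
        self._saved = None


def branch_lengths_from(
    tree: DatedTree, ages: np.ndarray, rates: BranchRateSet
) -> np.ndarray:
    """Expected substitutions per branch: rate x duration, indexed by child."""
    bl = np.zeros(tree.n_nodes)
    for node in range(tree.n_nodes):
        par = tree.parent[node]
        if par >= 0:
            bl[node] = rates.branch_rates[node] * (ages[par] - ages[node])
    return bl


def log_likelihood(
    genes: list[GeneAlignment] | np.ndarray,
    tree: DatedTree,
    rates: BranchRateSet,
    subst_model: str = "poisson",
    gamma_categories: int = 4,
    gamma_shape: float = 0.8,
    ages: np.ndarray | None = None,
) -> float:
    """One-shot pruning log-likelihood of data on a dated tree.

    ``genes`` may be a list of alignments or a pre-encoded integer matrix in
    ``tree.taxa`` order.  Branch expected substitutions are branch rate times
    branch duration.
    """
    ages = tree.ages if ages is None else ages
    codes = genes if isinstance(genes, np.ndarray) else encode_genes(genes, tree.taxa)
    engine = PruningEngine(
        tree, codes, subst_model, gamma_categories=gamma_categories,
        gamma_shape=gamma_shape,
    )
    return engine.set_lengths(branch_lengths_from(tree, ages, rates))
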
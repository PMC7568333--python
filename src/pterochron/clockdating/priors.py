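"""Node-age and branch-rate priors for the dating MCMC.

Age priors
----------
The root age always carries a gamma prior (moment-matched from a mean and SD,
default 150 +- 70 Ma).  Interior ages follow one of three priors:

* ``uniform`` — flat over the order-constrained age simplex given the root;
* ``birth_death`` — the reconstructed birth–death process density given the
  root age: interior node ages are i.i.d. draws from the standard
  speciation-time kernel with speciation rate lam, extinction rate mu and
  sampling fraction rho, conditioned to lie below the root age;
* ``dirichlet`` — a symmetric Dirichlet on the proportions of the internode
  gaps obtained by sorting all internal ages (concentration 1 makes it
  coincide with the uniform prior).

Calibrations enter in one of two modes:

* ``conditional`` (the default with a uniform interior prior): the joint age
  prior is built top-down — every calibrated node's age has the two-piece
  soft-bound density conditional on its nearest calibrated ancestor's age,
  and every uncalibrated node is uniform between the oldest calibrated age in
  its subtree and its parent's age.  Under this construction the prior
  probability that any calibrated node violates its minimum is exactly the
  calibration's ``soft_mass``.
* ``factor`` (birth–death and Dirichlet priors): the soft-bound densities
  multiply the base prior, the standard approach in dating software; the
  realised prior mass below each bound is then approximate, distorted by the
  interaction with the base prior and the tree's order constraints.

Rate priors follow the three relaxed clocks (see
:mod:`pterochron.clockdating.models`); autocorrelated rates live on nodes and
each branch's rate is the mean of its endpoint rates.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import special, stats

from ..formats import DatedTree
from .calibrations import (
    DEFAULT_AGE_CAP,
    MIN_RAMP_EXPONENT,
    Calibration,
    calibration_log_factor,
    nearest_calibrated_ancestor,
)
from .models import BranchRateSet, ClockModelSpec, NodeAgePriorSpec

LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Birth–death speciation-time kernel (reconstructed process, given root age)
# ---------------------------------------------------------------------------

def bd_kernel_logpdf(t, lam: float, mu: float, rho: float = 1.0):
    """Log of the unconditioned speciation-time kernel f(t)."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) < 1e-12:
        # critical-process limit (lam == mu), complete sampling form
        denom = 1.0 + lam * rho * t
        return np.log(lam * rho) - 2.0 * np.log(denom)
    e = np.exp(-r * t)
    denom = rho * lam + (lam * (1.0 - rho) - mu) * e
    return np.log(rho * lam) + 2.0 * np.log(r / denom) - r * t


def bd_kernel_logcdf(t, lam: float, mu: float, rho: float = 1.0):
    """Log CDF F(t) of the speciation-time kernel."""
    t = np.asarray(t, dtype=float)
    r = lam - mu
    if abs(r) < 1e-12:
        return np.log(lam * rho * t) - np.log(1.0 + lam * rho * t)
    e = np.exp(-r * t)
    denom = rho * lam + (lam * (1.0 - rho) - mu) * e
    return np.log(rho * lam) + np.log1p(-e) - np.log(denom)


# ---------------------------------------------------------------------------
# AgePrior
# ---------------------------------------------------------------------------

class AgePrior:
    """Joint log-prior over internal node ages, with optional calibrations.

    Parameters
    ----------
    tree : DatedTree
        Supplies the topology (ages are passed per evaluation).
    spec : NodeAgePriorSpec
    placed : dict node -> Calibration, optional
    mode : {"conditional", "factor", "auto"}
        Calibration mode; "auto" picks "conditional" for the uniform interior
        prior and "factor" otherwise.
    age_cap : float
        Upper reference age (Ma) for calibrations without a calibrated
        ancestor when the root itself is calibrated.
    """

    def __init__(
        self,
        tree: DatedTree,
        spec: NodeAgePriorSpec,
        placed: dict[int, Calibration] | None = None,
        mode: str = "auto",
        age_cap: float = DEFAULT_AGE_CAP,
    ):
        self.tree = tree
        self.spec = spec
        self.placed = dict(placed or {})
        self.age_cap = float(age_cap)
        if mode == "auto":
            mode = "conditional" if spec.kind == "uniform" else "factor"
        if mode == "conditional" and spec.kind != "uniform":
            raise ValueError("conditional calibration mode requires the uniform prior")
        self.mode = mode

        self.root = tree.root
        self.internal = np.array(
            [n for n in tree.postorder if n >= tree.n_tips and n != self.root],
            dtype=int,
        )
        self.parents = tree.parent
        self.root_calibrated = self.root in self.placed

        cal_nodes = sorted(n for n in self.placed if n != self.root)
        self.cal_idx = np.array(cal_nodes, dtype=int)
        self.cal_min = np.array([self.placed[n].min_age for n in cal_nodes])
        self.cal_soft = np.array([self.placed[n].soft_mass for n in cal_nodes])
        nca = nearest_calibrated_ancestor(tree, self.placed)
        # upper reference node per calibration: nearest calibrated ancestor,
        # or the fixed age cap (index sentinel -1) for top-level calibrations.
        # Conditioning top-level calibrations on the cap rather than on the
        # root age keeps their marginal soft mass exact: the root (and every
        # other uncalibrated node) is drawn afterwards from a normalised
        # conditional above the calibrated skeleton.
        self.cal_upper_idx = np.array(
            [nca[n] if nca[n] is not None else -1 for n in cal_nodes], dtype=int
        )
        self.top_cal_idx = np.array(
            [n for n in cal_nodes if nca[n] is None], dtype=int
        )
        for n in list(cal_nodes) + ([self.root] if self.root_calibrated else []):
            if nca.get(n) is None and self.placed[n].min_age >= self.age_cap:
                from ..errors import InitError

                raise InitError(
                    f"calibration {self.placed[n].label!r}: minimum age "
                    f"{self.placed[n].min_age} is not below the age cap "
                    f"{self.age_cap}"
                )

        self.uncal_idx = np.array(
            [n for n in self.internal if n not in self.placed], dtype=int
        )
        # mask of "calibrated node c is a descendant of uncalibrated node j"
        self.uncal_floor_mask = np.zeros(
            (len(self.uncal_idx), len(self.cal_idx)), dtype=bool
        )
        for cj, c in enumerate(self.cal_idx):
            anc = tree.parent[c]
            while anc >= 0:
                hits = np.flatnonzero(self.uncal_idx == anc)
                if hits.size:
                    self.uncal_floor_mask[hits[0], cj] = True
                anc = tree.parent[anc]
        self.uncal_parent = self.parents[self.uncal_idx]
        self._int_par = self.parents[self.internal]
        # constants of the root gamma log-density
        a, b = self.spec.root_shape, self.spec.root_rate
        self._root_gamma_const = a * math.log(b) - math.lgamma(a)
        self._root_gamma_a = a
        self._root_gamma_b = b
        # calibrated root: gamma reweighted so mass soft_mass sits below the
        # minimum and the gamma tail (which anchors the time scale) sits above
        if self.root_calibrated:
            cal = self.placed[self.root]
            F_m = float(stats.gamma.cdf(cal.min_age, a=a, scale=1.0 / b))
            self._root_cdf_at_min = F_m
            self._root_log_below = math.log(cal.soft_mass / F_m)
            self._root_log_above = math.log((1.0 - cal.soft_mass) / (1.0 - F_m))
        # nested calibrations: the conditional soft mass is adjusted so the
        # *marginal* mass below each minimum equals the nominal soft mass
        # despite truncation by the calibrated ancestor (see _adjust_masses)
        self._nca = nca
        self._adj_soft = {n: self.placed[n].soft_mass for n in cal_nodes}
        if self.mode == "conditional" and cal_nodes:
            self._adjust_masses(cal_nodes)
        self._cal_list = [
            (int(n), int(u), float(self.placed[n].min_age),
             float(self._adj_soft[n]))
            for n, u in zip(self.cal_idx, self.cal_upper_idx)
        ]

    def _adjust_masses(self, cal_nodes, n_mc: int = 300_000) -> None:
        """Monte-Carlo calibration of the conditional soft masses.

        A nested calibration conditioned on its ancestor's age spends all its
        mass below the minimum whenever the ancestor happens to be younger
        than that minimum.  Setting the conditional mass to
        (s - p) / (1 - p), with p the probability of that event under the
        ancestor's exact marginal, makes the marginal mass below the minimum
        exactly s.  The skeleton marginals are simulated once, top-down, with
        a fixed generator that is part of the prior's definition.
        """
        rng = np.random.default_rng(987654321)
        samples: dict[int, np.ndarray] = {}
        if self.root_calibrated:
            cal = self.placed[self.root]
            u = rng.random(n_mc)
            ramp = rng.random(n_mc) < cal.soft_mass
            F_m = self._root_cdf_at_min
            q = np.where(ramp, u * F_m, F_m + u * (1.0 - F_m))
            samples[self.root] = stats.gamma.ppf(
                np.minimum(q, 1.0 - 1e-16), a=self._root_gamma_a,
                scale=1.0 / self._root_gamma_b,
            )
        order = sorted(cal_nodes, key=lambda n: -self.tree.ages[n])
        for n in order:
            cal = self.placed[n]
            anc = self._nca[n]
            if anc is None:
                upper = np.full(n_mc, self.age_cap)
                s_adj = cal.soft_mass
            else:
                upper = samples[anc]
                p = float((upper <= cal.min_age).mean())
                if p >= cal.soft_mass:
                    import warnings

                    warnings.warn(
                        f"calibration {cal.label!r}: ancestor younger than the "
                        f"minimum with probability {p:.3f} >= soft mass; the "
                        "marginal soft-mass contract cannot be met"
                    )
                    s_adj = 1e-4
                else:
                    s_adj = (cal.soft_mass - p) / (1.0 - p)
            self._adj_soft[n] = s_adj
            samples[n] = _two_piece_draws(rng, cal.min_age, s_adj, upper)

    # -- pieces ------------------------------------------------------------

    def _root_term(self, ages: np.ndarray) -> float:
        t = ages[self.root]
        if self.root_calibrated and self.mode in ("conditional", "factor"):
            cal = self.placed[self.root]
            lp = calibration_log_factor(t, cal, upper=self.age_cap)
            if self.mode == "factor":
                lp += stats.gamma.logpdf(
                    t, a=self.spec.root_shape, scale=1.0 / self.spec.root_rate
                )
            return lp
        return float(
            stats.gamma.logpdf(t, a=self.spec.root_shape, scale=1.0 / self.spec.root_rate)
        )

    def _root_trunc_log_sf(self, floor: float) -> float:
        """log P(root gamma > floor), the truncation normaliser."""
        if floor <= 0.0:
            return 0.0
        return float(
            np.log(special.gammaincc(self._root_gamma_a, self._root_gamma_b * floor))
        )

    def _calibration_terms(self, ages: np.ndarray) -> float:
        if self.cal_idx.size == 0:
            return 0.0
        t = ages[self.cal_idx]
        upper = np.where(
            self.cal_upper_idx >= 0, ages[self.cal_upper_idx], self.age_cap
        )
        m, s = self.cal_min, self.cal_soft
        if np.any(t <= 0.0) or np.any(t > upper):
            return -np.inf
        out = np.empty_like(t)
        deg = upper <= m
        if np.any(deg):
            u = upper[deg]
            out[deg] = np.log(2.0 / u) + np.log(t[deg] / u)
        ok = ~deg
        if np.any(ok):
            theta = np.maximum(
                m[ok] * (1.0 - s[ok]) / (s[ok] * (upper[ok] - m[ok])),
                MIN_RAMP_EXPONENT,
            )
            plateau = t[ok] >= m[ok]
            val = np.where(
                plateau,
                np.log((1.0 - s[ok]) / (upper[ok] - m[ok])),
                np.log(s[ok] * theta / m[ok])
                + (theta - 1.0) * np.log(np.maximum(t[ok], 1e-300) / m[ok]),
            )
            out[ok] = val
        return float(out.sum())

    # -- full log prior ----------------------------------------------------

    def log_prior(self, ages: np.ndarray, lam: float | None = None,
                  mu: float | None = None) -> float:
        """Joint log-density of all internal node ages."""
        ai = ages[self.internal]
        if (ai <= 0.0).any() or (ai >= ages[self._int_par]).any():
            return -np.inf
        if ages[self.root] <= 0.0:
            return -np.inf

        if self.mode == "conditional":
            # root: soft-bounded gamma when calibrated; gamma truncated above
            # the tallest top-level calibrated age otherwise
            t_root = ages[self.root]
            if self.root_calibrated:
                if t_root <= 0.0:
                    return -np.inf
                lp = (
                    self._root_gamma_const
                    + (self._root_gamma_a - 1.0) * math.log(t_root)
                    - self._root_gamma_b * t_root
                    + (
                        self._root_log_below
                        if t_root < self.placed[self.root].min_age
                        else self._root_log_above
                    )
                )
            else:
                lp = (
                    self._root_gamma_const
                    + (self._root_gamma_a - 1.0) * math.log(t_root)
                    - self._root_gamma_b * t_root
                )
                if self.top_cal_idx.size:
                    floor = float(ages[self.top_cal_idx].max())
                    if t_root <= floor:
                        return -np.inf
                    lp -= self._root_trunc_log_sf(floor)
            if lp == -math.inf:
                return -np.inf
            # calibrated skeleton, scalar arithmetic (few calibrations)
            for n, u, m, s in self._cal_list:
                t = ages[n]
                upper = ages[u] if u >= 0 else self.age_cap
                if t >= upper:
                    return -np.inf
                if upper <= m:
                    lp += math.log(2.0 / upper) + math.log(t / upper)
                elif t >= m:
                    lp += math.log((1.0 - s) / (upper - m))
                else:
                    theta = max(
                        m * (1.0 - s) / (s * (upper - m)), MIN_RAMP_EXPONENT
                    )
                    lp += math.log(s * theta / m) + (theta - 1.0) * math.log(t / m)
            if self.uncal_idx.size:
                t = ages[self.uncal_idx]
                upper = ages[self.uncal_parent]
                if self.cal_idx.size:
                    floors = np.where(
                        self.uncal_floor_mask, ages[self.cal_idx][None, :], 0.0
                    ).max(axis=1, initial=0.0)
                    if (t <= floors).any():
                        return -np.inf
                    lp += -np.log(upper - floors).sum()
                else:
                    lp += -np.log(upper).sum()
            return float(lp)

        # factor mode: base interior prior x multiplicative soft-bound factors
        lp = self._root_term(ages)
        if not np.isfinite(lp):
            return -np.inf
        lam = self.spec.lam if lam is None else lam
        mu = self.spec.mu if mu is None else mu
        root_age = ages[self.root]
        t = ages[self.internal]
        kind = self.spec.kind
        if kind == "uniform":
            lp += -len(t) * math.log(root_age)
        elif kind == "birth_death":
            if not lam > 0 or mu < 0:
                return -np.inf
            lp += float(bd_kernel_logpdf(t, lam, mu, self.spec.rho).sum())
            lp -= len(t) * float(bd_kernel_logcdf(root_age, lam, mu, self.spec.rho))
        elif kind == "dirichlet":
            gaps = np.diff(np.sort(np.concatenate([[0.0], t, [root_age]])))
            props = gaps / root_age
            if np.any(props <= 0):
                return -np.inf
            conc = 1.0
            lp += float(stats.dirichlet.logpdf(props / props.sum(),
                                               np.full(len(props), conc)))
            lp += -len(t) * math.log(root_age)  # Jacobian of gaps -> props
        else:  # pragma: no cover
            raise ValueError(kind)
        lp += self._calibration_terms(ages)
        return lp

    # -- generative sampling (initialisation and prior-only checks) --------

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Draw ages from the conditional calibrated construction.

        Used to initialise the MCMC for every mode (a valid state under the
        calibrations is a valid state under the factor-mode priors too).
        """
        tree = self.tree
        ages = np.zeros(tree.n_nodes)
        if self.root_calibrated:
            cal = self.placed[self.root]
            u = rng.random()
            F_m = self._root_cdf_at_min
            q = u * F_m if rng.random() < cal.soft_mass else F_m + u * (1.0 - F_m)
            ages[self.root] = float(stats.gamma.ppf(
                min(q, 1.0 - 1e-16), a=self._root_gamma_a,
                scale=1.0 / self._root_gamma_b,
            ))
        # calibrated skeleton, top-down; top-level calibrations draw against
        # the fixed age cap
        order = sorted(
            (n for n in self.placed if n != self.root),
            key=lambda n: -tree.ages[n],
        )
        nca = self._nca
        for n in order:
            upper = ages[nca[n]] if nca[n] is not None else self.age_cap
            ages[n] = float(_two_piece_draws(
                rng, self.placed[n].min_age, self._adj_soft[n],
                np.array([upper]),
            )[0])
        if not self.root_calibrated:
            # gamma truncated above the calibrated skeleton (inverse CDF)
            floor = float(ages[self.top_cal_idx].max()) if self.top_cal_idx.size else 0.0
            lo = float(stats.gamma.cdf(
                floor, a=self._root_gamma_a, scale=1.0 / self._root_gamma_b
            ))
            u = lo + rng.random() * (1.0 - lo)
            ages[self.root] = float(stats.gamma.ppf(
                min(u, 1.0 - 1e-16), a=self._root_gamma_a,
                scale=1.0 / self._root_gamma_b,
            ))
        # uncalibrated nodes, preorder
        floors = {}
        for j, node in enumerate(self.uncal_idx):
            if self.cal_idx.size:
                f = (
                    np.where(self.uncal_floor_mask[j], ages[self.cal_idx], 0.0)
                    .max(initial=0.0)
                )
            else:
                f = 0.0
            floors[node] = f
        for node in tree.preorder:
            if node == self.root or node < tree.n_tips or node in self.placed:
                continue
            lo = floors[node]
            hi = ages[tree.parent[node]]
            ages[node] = rng.uniform(lo, hi)
        return ages


def _two_piece_draws(
    rng: np.random.Generator, m: float, s: float, upper: np.ndarray
) -> np.ndarray:
    """Vectorised draws from the two-piece soft-bound density on (0, upper].

    Where ``upper <= m`` the whole range is a quadratic ramp; elsewhere a
    power ramp below ``m`` carries mass ``s`` and the plateau carries the
    rest, with the continuity-matched exponent floored at MIN_RAMP_EXPONENT.
    """
    n = len(upper)
    u = rng.random(n)
    pick_ramp = rng.random(n) < s
    out = np.empty(n)
    deg = upper <= m
    if deg.any():
        out[deg] = upper[deg] * np.sqrt(u[deg])
    ok = ~deg
    if ok.any():
        theta = np.maximum(
            m * (1.0 - s) / (s * (upper[ok] - m)), MIN_RAMP_EXPONENT
        )
        ramp_vals = m * u[ok] ** (1.0 / theta)
        flat_vals = m + u[ok] * (upper[ok] - m)
        out[ok] = np.where(pick_ramp[ok], ramp_vals, flat_vals)
    return out


# ---------------------------------------------------------------------------
# Rate priors
# ---------------------------------------------------------------------------

def cir_transition_logpdf(
    r1, r0, dt, theta: float, mean_rate: float, sigma2: float
):
    """Exact CIR transition log-density (noncentral chi-square form).

    Written with the exponentially scaled Bessel function for numerical
    stability:  f(r1|r0) = c' e^{-u-v} (v/u)^{q/2} I_q(2 sqrt(uv)).
    """
    r1 = np.asarray(r1, dtype=float)
    r0 = np.asarray(r0, dtype=float)
    dt = np.asarray(dt, dtype=float)
    e = np.exp(-theta * dt)
    cp = 2.0 * theta / (sigma2 * (1.0 - e))
    q = 2.0 * theta * mean_rate / sigma2 - 1.0
    u = cp * r0 * e
    v = cp * r1
    x = 2.0 * np.sqrt(u * v)
    # log I_q(x) = log(ive(q, x)) + x; where ive underflows (large order q,
    # extreme hyperparameter proposals) fall back on the leading term of the
    # ascending series, log I_q(x) ~ q log(x/2) - lgamma(q+1), valid there
    with np.errstate(divide="ignore", invalid="ignore"):
        iv = special.ive(q, x)
        ok = np.isfinite(iv) & (iv > 0.0)
        log_bessel = np.where(
            ok,
            np.log(np.where(ok, iv, 1.0)) + x,
            q * np.log(np.maximum(x, 1e-300) / 2.0) - special.gammaln(q + 1.0),
        )
    return (
        np.log(cp) - u - v + 0.5 * q * (np.log(v) - np.log(u)) + log_bessel
    )


def log_prior_rates(
    rates: BranchRateSet, tree: DatedTree, clock: ClockModelSpec,
    ages: np.ndarray | None = None,
) -> float:
    """Joint log-density of a rate configuration under a relaxed clock."""
    ages = tree.ages if ages is None else ages
    if clock.kind == "UGAM":
        br = np.array([
            rates.branch_rates[n] for n in range(tree.n_nodes) if n != tree.root
        ])
        if np.any(br <= 0):
            return -np.inf
        if clock.nu == 0:
            raise ValueError("UGAM density undefined at nu = 0 (point mass)")
        shape = 1.0 / clock.nu
        return float(
            stats.gamma.logpdf(br, a=shape, scale=clock.mean_rate / shape).sum()
        )
    if rates.node_rates is None:
        raise ValueError("autocorrelated clocks need node rates")
    nr = rates.node_rates
    if np.any(nr <= 0):
        return -np.inf
    nonroot = np.array([n for n in range(tree.n_nodes) if n != tree.root])
    dt = ages[tree.parent[nonroot]] - ages[nonroot]
    rp = nr[tree.parent[nonroot]]
    rc = nr[nonroot]
    if clock.kind == "LOGNORMAL_AC":
        if clock.sigma2 == 0:
            return 0.0 if np.allclose(rc, rp) else -np.inf
        v = clock.sigma2 * dt
        z = np.log(rc) - np.log(rp) + 0.5 * v
        lp = (-np.log(rc) - 0.5 * np.log(v) - 0.5 * LOG2PI - z * z / (2.0 * v)).sum()
        lp += root_rate_logpdf(nr[tree.root], clock)
        return float(lp)
    if clock.kind == "CIR":
        ClockModelSpec.check_feller(clock.theta, clock.mean_rate, clock.sigma2)
        lp = cir_transition_logpdf(
            rc, rp, dt, clock.theta, clock.mean_rate, clock.sigma2
        ).sum()
        lp += root_rate_logpdf(nr[tree.root], clock)
        return float(lp)
    raise ValueError(clock.kind)


def root_rate_logpdf(r: float, clock: ClockModelSpec) -> float:
    """Prior on the rate at the root node.

    CIR uses its stationary gamma distribution; the lognormal clock (which
    has no stationary law) uses a moderately concentrated gamma centred on
    the clock's mean rate.
    """
    if r <= 0:
        return -np.inf
    if clock.kind == "CIR":
        shape = 2.0 * clock.theta * clock.mean_rate / clock.sigma2
        scale = clock.sigma2 / (2.0 * clock.theta)
        return float(stats.gamma.logpdf(r, a=shape, scale=scale))
    return float(stats.gamma.logpdf(r, a=2.0, scale=clock.mean_rate / 2.0))


def log_prior_node_ages(
    tree: DatedTree, spec: NodeAgePriorSpec, ages: np.ndarray | None = None
) -> float:
    """Log-prior of a node-age configuration without calibrations."""
    ages = tree.ages if ages is None else ages
    return AgePrior(tree, spec, placed=None, mode="factor").log_prior(ages)
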
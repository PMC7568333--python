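"""Relaxed-clock model and node-age prior specifications.

Three relaxed clocks are supported, following the standard conventions for
rate processes on a dated tree:

* ``UGAM`` — uncorrelated gamma multipliers: every branch draws an i.i.d.
  gamma rate with mean ``mean_rate`` and shape ``1/nu`` (variance
  ``mean_rate**2 * nu``); ``nu = 0`` degenerates to a strict clock.
* ``LOGNORMAL_AC`` — geometric Brownian motion of the rate along root-to-tip
  paths with infinitesimal variance ``sigma2`` per Myr and drift
  ``-sigma2/2`` so the expectation of the rate is preserved
  (the Thorne–Kishino convention).  Rates live on nodes; a branch's rate is
  the arithmetic mean of its endpoint rates.
* ``CIR`` — the Cox–Ingersoll–Ross mean-reverting square-root diffusion
  ``dr = theta (mean_rate - r) dt + sigma sqrt(r) dW`` with stationary
  distribution Gamma(2 theta mean_rate / sigma2, scale sigma2 / (2 theta)).
  The Feller condition ``2 theta mean_rate >= sigma2`` is enforced so the
  process cannot reach zero.  Rates live on nodes as for the lognormal clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLOCK_KINDS = ("UGAM", "LOGNORMAL_AC", "CIR")


@dataclass
class ClockModelSpec:
    """Parameters of one relaxed-clock rate process.

    mean_rate is in substitutions/site/Myr; nu is the UGAM relative variance;
    sigma2 the diffusion variance per Myr (lognormal and CIR); theta the CIR
    reversion rate per Myr.

    The CIR defaults give a stationary rate CV of ~32% and an autocorrelation
    (relaxation) time 1/theta of ~33 Myr — rate variation that persists over
    tens of Myr, comparable to typical relaxed-clock fits on phylogenies of
    this depth.  A much larger theta would make branch rates effectively
    independent, erasing the identifiability of node ages that autocorrelated
    clocks provide.
    """

    kind: str
    mean_rate: float = 0.01
    nu: float = 0.5
    sigma2: float = 6e-5
    theta: float = 0.03

    def __post_init__(self) -> None:
        if self.kind not in CLOCK_KINDS:
            raise ValueError(f"unknown clock model {self.kind!r}")
        if self.mean_rate <= 0:
            raise ValueError("mean_rate must be positive")
        if self.kind == "UGAM" and self.nu < 0:
            raise ValueError("UGAM variance nu must be >= 0")
        if self.kind in ("LOGNORMAL_AC", "CIR") and self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.kind == "CIR":
            self.check_feller(self.theta, self.mean_rate, self.sigma2)

    @staticmethod
    def check_feller(theta: float, mean_rate: float, sigma2: float) -> None:
        if theta <= 0:
            raise ValueError("CIR reversion theta must be positive")
        if 2.0 * theta * mean_rate < sigma2:
            raise ValueError(
                "CIR parameters violate the Feller condition "
                f"2*theta*mean_rate >= sigma2 ({2*theta*mean_rate:.4g} < {sigma2:.4g}); "
                "the rate process could hit zero"
            )

    def stationary_variance(self) -> float:
        if self.kind == "UGAM":
            return self.mean_rate**2 * self.nu
        if self.kind == "CIR":
            return self.sigma2 * self.mean_rate / (2.0 * self.theta)
        raise ValueError("stationary variance undefined for LOGNORMAL_AC")


@dataclass
class BranchRateSet:
    """Per-branch substitution rates on a dated tree.

    ``branch_rates[i]`` is the rate of the branch above node ``i`` (the root
    entry is unused and kept at nan).  For the autocorrelated clocks the
    underlying node-wise process values are retained in ``node_rates``.
    """

    branch_rates: np.ndarray
    node_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.branch_rates = np.asarray(self.branch_rates, dtype=float)


@dataclass
class NodeAgePriorSpec:
    """Prior on node ages: a gamma root prior plus one of three interior priors.

    * ``uniform`` — flat over the order-constrained age simplex given the root.
    * ``birth_death`` — reconstructed birth–death process density given the
      root age, speciation rate ``lam``, extinction rate ``mu`` and sampling
      fraction ``rho``.
    * ``dirichlet`` — symmetric Dirichlet (concentration 1) on internode
      proportions along the root-to-tip depth.
    """

    kind: str = "birth_death"
    root_mean: float = 150.0
    root_sd: float = 70.0
    lam: float = 0.05
    mu: float = 0.02
    rho: float = 1.0
    sample_bd_hyperparams: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "birth_death", "dirichlet"):
            raise ValueError(f"unknown age prior {self.kind!r}")
        if self.root_mean <= 0 or self.root_sd <= 0:
            raise ValueError("root gamma mean and SD must be positive")
        if not (0.0 < self.rho <= 1.0):
            raise ValueError("sampling fraction rho must be in (0, 1]")

    @property
    def root_shape(self) -> float:
        return (self.root_mean / self.root_sd) ** 2

    @property
    def root_rate(self) -> float:
        return self.root_mean / self.root_sd**2
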
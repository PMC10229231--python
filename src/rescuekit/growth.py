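"""Density-regulated growth laws, model parameters and mean-field trajectories.

The wild-type population lives under a carrying capacity ``K`` enforced through a
density-dependent per-capita birth rate ``b * g(N/K)``: ``g`` is the density
factor of the chosen growth law (logistic, Gompertz or Richards) and vanishes at
``N = K``, while the per-capita death rate is density-independent.  The
environment only modulates the intrinsic birth rate ``b``: it equals ``b_WF`` in
a favourable phase (``b_WF > d_W``, the population grows towards its equilibrium
size ``N*``) and ``b_WH`` in a harsh phase (``b_WH < d_W``, the population
declines).  A generalist mutant has environment-independent rates ``b_M``/``d_M``
and arises at wild-type birth events with probability ``mu``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "GrowthKind",
    "GrowthLaw",
    "ModelParams",
    "Phase",
    "per_capita_birth_rate",
    "density_factor",
    "equilibrium_size",
    "mean_trajectory",
]


class GrowthKind(str, Enum):
    LOGISTIC = "logistic"
    GOMPERTZ = "gompertz"
    RICHARDS = "richards"


class Phase(str, Enum):
    HARSH = "H"
    FAVOURABLE = "F"


@dataclass(frozen=True)
class GrowthLaw:
    """A density-dependence law for the per-capita birth rate.

    Parameters
    ----------
    kind:
        One of ``logistic`` (factor ``1 - N/K``), ``gompertz`` (``log(K/N)``)
        or ``richards`` (``1 - (N/K)**beta``, the theta-logistic).
    beta:
        Shape exponent of the Richards law; ignored for the other two kinds.
    """

    kind: GrowthKind = GrowthKind.LOGISTIC
    beta: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", GrowthKind(self.kind))
        if self.kind is GrowthKind.RICHARDS and not self.beta > 0:
            raise ValueError("Richards growth requires beta > 0")

    def label(self) -> str:
        if self.kind is GrowthKind.RICHARDS:
            return f"richards(beta={self.beta:g})"
        return self.kind.value


def density_factor(growth: GrowthLaw, N, K: float):
    """Density factor ``g(N/K)`` of the per-capita birth rate.

    Accepts scalar or array ``N`` with ``0 <= N <= K``.  For the Gompertz law
    the factor ``log(K/N)`` diverges as ``N -> 0``; in deterministic (mean
    field) use it is capped at its value for a single individual, ``log(K)``.
    In the stochastic process a birth only ever happens with ``N >= 1``, so the
    cap is inert there.
    """
    N = np.asarray(N, dtype=float)
    if np.any(N < 0) or np.any(N > K):
        raise ValueError(f"population size must lie in [0, K={K}]")
    x = N / K
    if growth.kind is GrowthKind.LOGISTIC:
        g = 1.0 - x
    elif growth.kind is GrowthKind.GOMPERTZ:
        with np.errstate(divide="ignore"):
            g = np.where(N >= 1.0, -np.log(np.maximum(x, 1e-300)), math.log(K))
    else:  # richards
        g = 1.0 - x**growth.beta
    g = np.maximum(g, 0.0)
    return g if g.ndim else float(g)


def per_capita_birth_rate(growth: GrowthLaw, b: float, N, K: float):
    """Per-capita birth rate ``b * g(N/K)`` at population size ``N``."""
    if b < 0:
        raise ValueError("birth rate must be non-negative")
    g = density_factor(growth, N, K)
    return b * g


def equilibrium_size(growth: GrowthLaw, b: float, d: float, K: float) -> float:
    """Positive equilibrium ``N*`` solving ``b * g(N*/K) = d``.

    ``K (1 - d/b)`` for logistic, ``K (1 - d/b)^(1/beta)`` for Richards and
    ``K exp(-d/b)`` for Gompertz.  Requires ``b > d``.
    """
    if not b > d:
        raise ValueError("no positive equilibrium: requires b > d")
    if growth.kind is GrowthKind.LOGISTIC:
        return K * (1.0 - d / b)
    if growth.kind is GrowthKind.GOMPERTZ:
        return K * math.exp(-d / b)
    return K * (1.0 - d / b) ** (1.0 / growth.beta)


@dataclass(frozen=True)
class ModelParams:
    """Demographic and mutational parameters of the two-genotype model.

    Rates are per unit time; ``mu`` is a probability per wild-type birth event.
    ``validate=False`` disables the favourable-growth / harsh-decline sanity
    checks for exploratory parameterizations.
    """

    b_WF: float = 1.0
    b_WH: float = 0.0
    d_W: float = 0.1
    b_M: float = 1.0
    d_M: float = 0.1
    mu: float = 1e-3
    K: int = 100
    growth: GrowthLaw = field(default_factory=GrowthLaw)
    validate: bool = True

    def __post_init__(self) -> None:
        for name in ("b_WF", "b_WH", "d_W", "b_M", "d_M"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.validate:
            if not self.b_WF > self.d_W:
                raise ValueError(
                    "favourable growth requires b_WF > d_W (validate=False to override)"
                )
            if not self.b_WH < self.d_W:
                raise ValueError(
                    "harsh decline requires b_WH < d_W (validate=False to override)"
                )

    # -- convenience -------------------------------------------------------
    def birth_rate(self, phase: Phase | str) -> float:
        return self.b_WH if Phase(phase) is Phase.HARSH else self.b_WF

    @property
    def n_star(self) -> float:
        """Wild-type equilibrium size in the favourable environment."""
        return equilibrium_size(self.growth, self.b_WF, self.d_W, self.K)

    @property
    def n_star_mutant(self) -> float:
        """Mutant equilibrium size (environment-independent rates)."""
        return equilibrium_size(self.growth, self.b_M, self.d_M, self.K)

    @property
    def tau_0H(self) -> float:
        """Mean wild-type survival time in an uninterrupted harsh
        environment, ``log(N*)/d_W``."""
        return math.log(self.n_star) / self.d_W

    def with_growth(self, growth: GrowthLaw) -> "ModelParams":
        return replace(self, growth=growth)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "b_WF": self.b_WF,
            "b_WH": self.b_WH,
            "d_W": self.d_W,
            "b_M": self.b_M,
            "d_M": self.d_M,
            "mu": self.mu,
            "K": self.K,
            "growth": self.growth.kind.value,
            "beta": self.growth.beta,
        }

    @classmethod
    def from_dict(cls, mapping: Mapping) -> "ModelParams":
        m = dict(mapping)
        growth = GrowthLaw(kind=m.pop("growth", "logistic"), beta=m.pop("beta", 1.0))
        return cls(growth=growth, **m)


def mean_trajectory(params: ModelParams, phase: Phase | str, N0: float, t):
    """Deterministic mean-field wild-type trajectory ``<N_W>(t)``.

    Solves ``dN/dt = (b_phase * g(N/K) - d_W) N`` from ``N(0) = N0``.  Closed
    forms are used for the pure-death case (``b_phase = 0``) and for the
    logistic law; other laws are integrated numerically (adaptive stepping,
    relative tolerance 1e-8).  ``t`` may be a scalar or an array.
    """
    b = params.birth_rate(phase)
    d, K = params.d_W, params.K
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if not 0 <= N0 <= K:
        raise ValueError("N0 must lie in [0, K]")

    if N0 == 0 or b == 0:
        out = N0 * np.exp(-d * t_arr)
    elif params.growth.kind is GrowthKind.LOGISTIC:
        r = b - d
        if r == 0.0:
            out = N0 / (1.0 + b * N0 * t_arr / K)
        else:
            # dN/dt = r N (1 - N/K_eff) with K_eff = K r / b
            K_eff = K * r / b
            e = np.exp(r * t_arr)
            out = K_eff * N0 * e / (K_eff + N0 * (e - 1.0))
    else:
        def rhs(_t, y):
            return (b * density_factor(params.growth, min(y[0], K), K) - d) * y[0]

        sol = solve_ivp(
            rhs,
            (0.0, float(t_arr.max()) if t_arr.max() > 0 else 1e-12),
            [float(N0)],
            method="RK45",
            rtol=1e-10,
            atol=1e-12,
            dense_output=True,
        )
        out = np.clip(sol.sol(t_arr)[0], 0.0, K)
    return out if np.ndim(t) else float(out[0])
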
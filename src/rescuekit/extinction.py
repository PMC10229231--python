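"""Extinction analytics for the rescue-free wild-type process.

The wild-type population is a density-regulated birth-death chain on
``{0, ..., K}`` with birth rates ``n b_W,alpha g(n/K)`` and death rates
``n d_W``, absorbing at 0.  This module computes

* the transient master-equation solution of a harsh phase (``harsh_phase_solution``),
* the probability ``p0_H`` of dying within one harsh phase, averaged over the
  phase-duration law,
* the population-size distribution at the end of a survived harsh phase,
* the probability ``p0_F`` of *rapid* extinction early in the following
  favourable phase (first passage to 0 before recovery to the equilibrium
  size), conditional on having survived the harsh phase,
* the geometric law of the number ``q_F`` of favourable phases a population
  completes before extinction, and
* the mean total extinction time ``T0``.

With both extinction routes, a full cycle (one harsh then one favourable
phase) is survived with probability ``s = (1 - p0_H)(1 - p0_F)``; the cycle
count to absorption is geometric, giving ``<q_F> = s / (1 - s)`` and

    T0 = 2 <q_F> tau + (1 - omega_F) tau_0H + omega_F tau_0F,

where ``omega_F = p0_F / (p0_F + p0_H)`` is the proportion of extinctions
happening in a favourable phase, ``tau_0F ~ 1/d_W`` and ``tau_0H`` is
``log(N*)/d_W`` capped at ``tau`` for short phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy import stats

from .environment import DurationDistribution
from .growth import GrowthLaw, ModelParams, Phase, density_factor

__all__ = [
    "MasterEquationSolution",
    "ExtinctionPrediction",
    "harsh_phase_solution",
    "p0_H",
    "end_of_harsh_distribution",
    "rapid_extinction_prob",
    "rapid_extinction_sensitivity",
    "p0_F",
    "qF_distribution",
    "mean_qF",
    "total_extinction_time",
    "pure_death_mean_extinction_time",
    "mean_extinction_time_constant",
]

_N_QUAD = 96  # Gauss-Legendre nodes for duration averaging


@dataclass(frozen=True)
class MasterEquationSolution:
    """Time-indexed probability vectors over population sizes ``0..K``."""

    grid: np.ndarray  # (T,)
    P: np.ndarray  # (T, K+1); rows sum to 1

    @property
    def extinction_mass(self) -> np.ndarray:
        return self.P[:, 0]


@dataclass(frozen=True)
class ExtinctionPrediction:
    p0_H: float
    p0_F: float
    omega_F: float
    mean_qF: float
    tau_0H: float
    tau_0F: float
    T0: float

    def to_dict(self) -> dict:
        return {
            "p0_H": self.p0_H,
            "p0_F": self.p0_F,
            "omega_F": self.omega_F,
            "mean_qF": self.mean_qF,
            "tau_0H": self.tau_0H,
            "tau_0F": self.tau_0F,
            "T0": self.T0,
        }


def _birth_death_rates(params: ModelParams, phase: Phase | str):
    """Per-state total birth and death rates on ``0..K``."""
    K = params.K
    n = np.arange(K + 1, dtype=float)
    b = params.birth_rate(phase)
    g = np.zeros(K + 1)
    if b > 0:
        g[1:] = density_factor(params.growth, n[1:], K)
    lam = n * b * g
    mu = n * params.d_W
    return lam, mu


def _generator(params: ModelParams, phase: Phase | str) -> np.ndarray:
    """Dense master-equation generator ``A`` with ``dP/dt = A P``."""
    lam, mu = _birth_death_rates(params, phase)
    K = params.K
    A = np.zeros((K + 1, K + 1))
    idx = np.arange(K + 1)
    A[idx, idx] = -(lam + mu)
    A[idx[1:], idx[:-1]] = lam[:-1]  # inflow from n-1 by birth
    A[idx[:-1], idx[1:]] = mu[1:]  # inflow from n+1 by death
    return A


def _phase_marginals(
    params: ModelParams,
    phase: Phase | str,
    N0: int,
    times: np.ndarray,
    method: str = "auto",
) -> np.ndarray:
    """Size distributions ``P(n, t | N0)`` at the requested times.

    With ``method="auto"``, pure-death phases (``b = 0``) use the exact
    binomial law ``n ~ Binomial(N0, exp(-d_W t))``; otherwise (and always for
    ``method="generic"``) the master equation is propagated by matrix
    exponentials between consecutive times.
    """
    times = np.asarray(times, dtype=float)
    K = params.K
    if method == "auto" and params.birth_rate(phase) == 0.0:
        p_surv = np.exp(-params.d_W * times)
        n = np.arange(K + 1)
        out = stats.binom.pmf(n[None, :], N0, p_surv[:, None])
        return out
    A = _generator(params, phase)
    order = np.argsort(times)
    sorted_t = times[order]
    P = np.zeros((times.size, K + 1))
    p = np.zeros(K + 1)
    p[N0] = 1.0
    t_prev = 0.0
    for j, t in enumerate(sorted_t):
        dt = t - t_prev
        if dt > 0:
            p = expm(A * dt) @ p
        P[order[j]] = p
        t_prev = t
    # clip tiny negative round-off and renormalize
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    return P


def harsh_phase_solution(
    params: ModelParams,
    N0: int,
    t_max: float,
    n_times: int = 201,
    method: str = "auto",
) -> MasterEquationSolution:
    """Transient harsh-phase master-equation solution on ``[0, t_max]``.

    ``method="generic"`` forces the numerical generator propagation even when
    a closed form exists (useful to validate the solver itself).
    """
    if not t_max > 0:
        raise ValueError("t_max must be positive")
    if not 0 <= N0 <= params.K:
        raise ValueError("N0 must lie in [0, K]")
    grid = np.linspace(0.0, t_max, n_times)
    P = _phase_marginals(params, Phase.HARSH, N0, grid, method=method)
    return MasterEquationSolution(grid=grid, P=P)


def _duration_nodes(dist: DurationDistribution):
    """Gauss-Legendre nodes/weights against the duration density."""
    lo, hi = dist.support(8.0)
    x, w = np.polynomial.legendre.leggauss(_N_QUAD)
    t = 0.5 * (hi - lo) * x + 0.5 * (hi + lo)
    w = 0.5 * (hi - lo) * w * dist.pdf(t)
    return t, w


def p0_H(params: ModelParams, dist: DurationDistribution) -> float:
    """Probability of extinction within a single harsh phase.

    ``p0_H = \\int F_tau(t) P_H(0, t | N*) dt``; for deterministic durations
    this is the extinction mass at exactly ``tau``.
    """
    N0 = int(round(params.n_star))
    if dist.deterministic:
        P = _phase_marginals(params, Phase.HARSH, N0, np.array([dist.mean_tau]))
        return float(P[0, 0])
    t, w = _duration_nodes(dist)
    if params.b_WH == 0.0:
        cdf = (-np.expm1(-params.d_W * t)) ** N0
    else:
        cdf = _phase_marginals(params, Phase.HARSH, N0, t)[:, 0]
    return float(np.sum(w * cdf))


def end_of_harsh_distribution(
    params: ModelParams, dist: DurationDistribution
) -> np.ndarray:
    """Size distribution over ``1..K`` at the end of a survived harsh phase.

    Index ``i`` of the returned vector is the probability of size ``i + 1``,
    conditional on not having gone extinct during the phase.
    """
    N0 = int(round(params.n_star))
    if dist.deterministic:
        marg = _phase_marginals(
            params, Phase.HARSH, N0, np.array([dist.mean_tau])
        )[0]
    else:
        t, w = _duration_nodes(dist)
        marg = np.sum(w[:, None] * _phase_marginals(params, Phase.HARSH, N0, t), axis=0)
    survival = marg[1:].sum()
    if survival < 1e-12:
        raise ValueError("conditioning on null event: survival probability < 1e-12")
    return marg[1:] / survival


def conditional_mean_after_harsh(params: ModelParams, tau: float) -> float:
    """Mean population size after a harsh phase of length ``tau``,
    conditional on survival: ``E[N | N > 0]``.

    Closed binomial form for perfectly harsh phases (``b_WH = 0``), master
    equation otherwise.  This is the natural initial size of the favourable
    phases that a surviving population actually experiences; the
    unconditional mean underestimates it badly once ``tau`` approaches the
    harsh-phase survival time.
    """
    N0 = int(round(params.n_star))
    if params.b_WH == 0.0:
        p = math.exp(-params.d_W * tau)
        dead = (1.0 - p) ** N0
        if 1.0 - dead < 1e-300:
            raise ValueError("conditioning on null event: survival impossible")
        return N0 * p / (1.0 - dead)
    marg = _phase_marginals(params, Phase.HARSH, N0, np.array([tau]))[0]
    surv = marg[1:].sum()
    if surv < 1e-300:
        raise ValueError("conditioning on null event: survival impossible")
    n = np.arange(1, params.K + 1)
    return float(np.sum(n * marg[1:]) / surv)


def rapid_extinction_prob(
    params: ModelParams, n: int, barrier: int | None = None
) -> float:
    """Probability of hitting 0 before the equilibrium size in a favourable phase.

    Gambler's-ruin first-passage probability for the favourable-environment
    chain started at ``n``, with absorbing barrier at ``ceil(N*)`` (recovery).
    For ``n`` well below ``N*`` this approaches the classic branching result
    ``(d_W / b_WF)^n`` (logistic/Richards) or ``(d_W / (b_WF log K))^n``
    (Gompertz).
    """
    if not 0 <= n <= params.K:
        raise ValueError("n must lie in [0, K]")
    B = int(math.ceil(params.n_star)) if barrier is None else int(barrier)
    if n == 0:
        return 1.0
    if n >= B:
        return 0.0
    j = np.arange(1, B, dtype=float)
    g = density_factor(params.growth, j, params.K)
    ratios = params.d_W / (params.b_WF * g)
    rho = np.concatenate([[1.0], np.cumprod(ratios)])  # rho_0 .. rho_{B-1}
    return float(rho[n:].sum() / rho.sum())


def rapid_extinction_sensitivity(params: ModelParams, n: int) -> dict:
    """Diagnostic: sensitivity of the rapid-extinction barrier (+/- 10% of N*)."""
    base = int(math.ceil(params.n_star))
    out = {}
    for label, b in [
        ("barrier-10%", int(math.ceil(0.9 * params.n_star))),
        ("barrier", base),
        ("barrier+10%", int(math.ceil(min(1.1 * params.n_star, params.K)))),
    ]:
        out[label] = rapid_extinction_prob(params, n, barrier=b)
    return out


def p0_F(params: ModelParams, dist: DurationDistribution) -> float:
    """Rapid favourable-phase extinction probability, conditional on having
    survived the preceding harsh phase."""
    try:
        weights = end_of_harsh_distribution(params, dist)
    except ValueError:
        return 0.0  # survival essentially impossible; the harsh phase kills
    B = int(math.ceil(params.n_star))
    probs = np.array(
        [rapid_extinction_prob(params, n) for n in range(1, min(B, params.K) + 1)]
    )
    out = float(np.sum(weights[: probs.size] * probs))
    return out


def qF_distribution(p0_H_val: float, p0_F_val: float, k: int) -> float:
    """Probability of completing exactly ``k`` favourable phases before
    extinction: geometric with per-cycle survival
    ``s = (1 - p0_H)(1 - p0_F)``."""
    if p0_H_val + p0_F_val <= 0:
        raise ValueError("no absorption: p0_H + p0_F must be positive")
    if k < 0:
        return 0.0
    s = (1.0 - p0_H_val) * (1.0 - p0_F_val)
    return s**k * (1.0 - s)


def mean_qF(p0_H_val: float, p0_F_val: float) -> float:
    """Mean number of completed favourable phases, ``s / (1 - s)``."""
    if p0_H_val + p0_F_val <= 0:
        raise ValueError("no absorption: p0_H + p0_F must be positive")
    s = (1.0 - p0_H_val) * (1.0 - p0_F_val)
    if s >= 1.0:
        raise ValueError("no absorption: per-cycle survival is 1 to machine precision")
    return s / (1.0 - s)


def pure_death_mean_extinction_time(N0: int, d: float) -> float:
    """Exact mean absorption time of a pure-death process:
    ``(1/d) * H_N0`` (harmonic number).  Exceeds the large-``N0``
    approximation ``log(N0)/d`` by about ``gamma/d``."""
    return float(np.sum(1.0 / np.arange(1, N0 + 1)) / d)


def mean_extinction_time_constant(
    growth: GrowthLaw, b: float, d: float, K: int, n0: int
) -> float:
    """Mean extinction time of the constant-environment chain from ``n0``.

    Solves the first-step linear system on the transient states ``1..K``.
    """
    n = np.arange(K + 1, dtype=float)
    g = np.zeros(K + 1)
    g[1:] = density_factor(growth, n[1:], K)
    lam = n * b * g
    mu = n * d
    A = np.zeros((K, K))
    for i in range(1, K + 1):
        A[i - 1, i - 1] = -(lam[i] + mu[i])
        if i + 1 <= K:
            A[i - 1, i] = lam[i]
        if i - 1 >= 1:
            A[i - 1, i - 2] = mu[i]
    t = np.linalg.solve(A, -np.ones(K))
    return float(t[n0 - 1])


def conditional_harsh_extinction_time(params: ModelParams, tau: float) -> float:
    """Mean extinction time within a harsh phase of length ``tau``,
    conditional on extinction happening in it: ``E[T | T <= tau]``.

    This is the harsh-phase term of the total-extinction-time decomposition.
    As ``tau -> inf`` it converges to the unconditional mean survival time
    (``(1/d_W) H_{N*}`` for pure death, i.e. ``log(N*)/d_W`` plus the
    Euler-gamma correction); for ``tau`` below the survival time it is
    slightly less than ``tau``.  Computed from the extinction-time CDF by
    ``tau - int_0^tau P0(t) dt / P0(tau)``.
    """
    N0 = int(round(params.n_star))
    t = np.linspace(0.0, tau, 401)
    if params.b_WH == 0.0:
        P0 = (-np.expm1(-params.d_W * t)) ** N0
    else:
        P0 = _phase_marginals(params, Phase.HARSH, N0, t)[:, 0]
    if P0[-1] < 1e-300:
        return tau  # extinction this early is beyond float resolution
    return float(tau - np.trapezoid(P0, t) / P0[-1])


def total_extinction_time(
    params: ModelParams, dist: DurationDistribution
) -> ExtinctionPrediction:
    """Assemble the full extinction prediction (Eq. for ``T0`` above)."""
    ph = p0_H(params, dist)
    pf = p0_F(params, dist)
    if ph + pf <= 0:
        raise ValueError("no absorption: p0_H + p0_F must be positive")
    omega_f = pf / (pf + ph)
    qf = mean_qF(ph, pf)
    tau = dist.mean_tau
    tau_0h = conditional_harsh_extinction_time(params, tau)
    tau_0f = 1.0 / params.d_W
    T0 = 2.0 * qf * tau + (1.0 - omega_f) * tau_0h + omega_f * tau_0f
    return ExtinctionPrediction(
        p0_H=ph,
        p0_F=pf,
        omega_F=omega_f,
        mean_qF=qf,
        tau_0H=tau_0h,
        tau_0F=tau_0f,
        T0=T0,
    )
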
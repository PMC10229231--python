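"""Rescue analytics: mutant fixation, supply integrals and rescue probability.

A mutant lineage that appears at cycle time ``t0`` is approximated by a
time-inhomogeneous linear birth-death process with per-capita birth rate
``beta(s) = b_M g(<N_W>(s)/K)`` along the periodic mean-field wild-type orbit
(harsh phase from ``N*`` on ``[0, tau)``, favourable phase from
``<N_W>_H(tau)`` on ``[tau, 2 tau)``), and constant death rate ``d_M``.  Its
escape-from-loss probability is the classic time-inhomogeneous branching
result

    pfix(t0) = 1 / (1 + int_{t0}^inf d_M exp(rho(u)) du),
    rho(u)   = int_{t0}^u (d_M - beta(s)) ds,

evaluated exactly through the 2-tau periodicity of ``beta`` (geometric
resummation across periods).  Mutants are produced at rate
``mu b_W(t) g(<N_W>(t)/K) <N_W>(t)``, giving the per-cycle fixing-mutant
supplies ``Sigma_H`` (harsh part) and ``Sigma_F`` (favourable part).
Combining the supplies with the geometric law of the number of favourable
phases before extinction yields the de novo rescue probability; a single
pre-existing mutant adds ``p_r,SGV = pfix(0)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid

from . import extinction
from .environment import DurationDistribution
from .growth import ModelParams, Phase, density_factor, equilibrium_size, mean_trajectory

__all__ = [
    "RescuePrediction",
    "FastLimit",
    "RescueAnalytics",
    "pfix",
    "mutant_supply_integrals",
    "p_rescue_dn",
    "p_rescue_total",
    "appearance_time",
    "fast_limit",
    "harsh_mutant_supply",
]


@dataclass(frozen=True)
class RescuePrediction:
    """Bundle of analytic rescue quantities for one parameter set."""

    Sigma_H: float
    Sigma_F: float
    p_r_DN: float
    p_r_SGV: float
    p_r: float
    q_af_F: float
    t_af: float
    tau_af: float

    def to_dict(self) -> dict:
        return {
            "Sigma_H": self.Sigma_H,
            "Sigma_F": self.Sigma_F,
            "p_r_DN": self.p_r_DN,
            "p_r_SGV": self.p_r_SGV,
            "p_r": self.p_r,
            "q_af_F": self.q_af_F,
            "t_af": self.t_af,
            "tau_af": self.tau_af,
        }


@dataclass(frozen=True)
class FastLimit:
    """Effective constant-environment description of very fast fluctuations."""

    b_tilde: float
    N_tilde_star: float
    s_tilde: float
    tau_af_tilde: Optional[float]
    T0_tilde: float


class RescueAnalytics:
    """Precomputed rescue analytics on a fixed cycle-time grid.

    The fixation probability is always computed under the *mean-duration*
    periodic environment; stochastic durations enter only through the
    extinction probabilities ``p0_H``/``p0_F`` and the cycle-count law.
    """

    def __init__(
        self,
        params: ModelParams,
        dist: DurationDistribution,
        n_grid: int = 4096,
    ) -> None:
        if n_grid % 2:
            n_grid += 1
        self.params = params
        self.dist = dist
        self.tau = dist.mean_tau
        self.n_grid = n_grid
        self._build()

    # ------------------------------------------------------------------
    def _build(self) -> None:
        p, tau, n = self.params, self.tau, self.n_grid
        self.t_grid = np.linspace(0.0, 2.0 * tau, n + 1)
        half = n // 2
        th = self.t_grid[: half + 1]  # harsh phase times [0, tau]
        n_harsh = mean_trajectory(p, Phase.HARSH, p.n_star, th)
        # favourable phases only happen in cycles whose harsh phase was
        # survived: start from the survival-conditioned mean E[N]/P(N > 0)
        # (equals the plain mean while survival is near-certain, tau << tau_0H)
        n0 = int(round(p.n_star))
        if p.b_WH == 0.0:
            surv = -math.expm1(n0 * math.log1p(-math.exp(-p.d_W * tau)))
        else:
            surv = (
                1.0
                - extinction._phase_marginals(p, Phase.HARSH, n0, np.array([tau]))[0, 0]
            )
        if surv <= 0.0:
            raise ValueError("conditioning on null event: harsh phase is always fatal")
        n0_fav = min(float(n_harsh[-1]) / surv, float(p.K))
        n_fav = mean_trajectory(p, Phase.FAVOURABLE, n0_fav, th)
        self.N_orbit = np.concatenate([n_harsh, n_fav[1:]])
        self._half = half
        g = density_factor(p.growth, np.minimum(self.N_orbit, p.K), p.K)
        self.g_orbit = g
        beta = p.b_M * g
        # rho along [0, 2 tau] and its per-period increment
        integrand = p.d_M - beta
        rho = np.concatenate(
            [[0.0], cumulative_trapezoid(integrand, self.t_grid)]
        )
        self.delta_rho = float(rho[-1])
        if self.delta_rho >= -1e-12:
            # non-positive per-period lineage growth: certain eventual loss
            self.pfix_grid = np.zeros_like(self.t_grid)
            return
        # J(t0) = int_{t0}^inf d_M exp(rho(u) - rho(t0)) du, assembled from a
        # backward recurrence over one period using only local rho increments
        # (a global cumulative integral of exp(rho) loses the far-below-zero
        # excursions of rho to floating-point cancellation):
        #   A_i = seg_i + exp(drho_i) A_{i+1},  A_n = 0
        # with seg_i the trapezoid of d_M exp(rho(u) - rho(t_i)) over one step,
        # then J_i = A_i + exp(rho_n - rho_i) * J(2 tau) and periodicity gives
        # J(2 tau) = J(0) = A_0 / (1 - exp(delta_rho)).
        h = self.t_grid[1] - self.t_grid[0]
        drho = np.diff(rho)
        f = np.exp(drho)
        seg = 0.5 * h * p.d_M * (1.0 + f)
        A = np.zeros(n + 1)
        for i in range(n - 1, -1, -1):
            A[i] = seg[i] + f[i] * A[i + 1]
        J_period = A[0] / -np.expm1(self.delta_rho)
        J = A + np.exp(self.delta_rho - rho) * J_period
        self.pfix_grid = 1.0 / (1.0 + J)

    # ------------------------------------------------------------------
    def pfix(self, t0):
        """Fixation probability of a single mutant appearing at cycle time
        ``t0`` (harsh phase ``[0, tau)``, favourable ``[tau, 2 tau)``)."""
        t0 = np.asarray(t0, dtype=float)
        if np.any(t0 < 0) or np.any(t0 >= 2.0 * self.tau + 1e-9):
            raise ValueError("t0 must lie in [0, 2 tau)")
        out = np.interp(t0, self.t_grid, self.pfix_grid)
        return out if out.ndim else float(out)

    @cached_property
    def _cycle_survival(self) -> float:
        """Per-cycle survival ``s = (1 - p0_H)(1 - p0_F)`` (1.0 when
        extinction is beyond floating-point resolution)."""
        ph = extinction.p0_H(self.params, self.dist)
        pf = extinction.p0_F(self.params, self.dist)
        return (1.0 - ph) * (1.0 - pf)

    @cached_property
    def supply_integrals(self) -> tuple[float, float]:
        """Per-cycle expected numbers of *fixing* mutants (Sigma_H, Sigma_F)."""
        p, half = self.params, self._half
        th = self.t_grid[: half + 1]
        if p.mu == 0.0:
            return 0.0, 0.0
        wh = (
            p.mu
            * p.b_WH
            * self.N_orbit[: half + 1]
            * self.g_orbit[: half + 1]
            * self.pfix_grid[: half + 1]
        )
        wf = (
            p.mu
            * p.b_WF
            * self.N_orbit[half:]
            * self.g_orbit[half:]
            * self.pfix_grid[half:]
        )
        sigma_h = float(trapezoid(wh, th)) if p.b_WH > 0 else 0.0
        sigma_f = float(trapezoid(wf, th))
        return sigma_h, sigma_f

    @property
    def p_r_SGV(self) -> float:
        return float(self.pfix_grid[0])

    @cached_property
    def p_r_DN(self) -> float:
        """De novo rescue probability.

        Geometric resummation of
        ``sum_k P_qF(k) (1 - exp(-(k+1) Sigma_H - k Sigma_F))``.
        """
        if self.params.mu == 0.0:
            return 0.0
        sh, sf = self.supply_integrals
        s = self._cycle_survival
        denom = 1.0 - s * math.exp(-(sh + sf))
        if denom <= 0.0:  # no absorption of any kind: nothing to rescue from
            raise ValueError("no absorption: extinction and rescue both impossible")
        return float(1.0 - (1.0 - s) * math.exp(-sh) / denom)

    @cached_property
    def p_r_total(self) -> float:
        """Total rescue probability with one pre-existing mutant."""
        sgv = self.p_r_SGV
        return sgv + (1.0 - sgv) * self.p_r_DN

    @cached_property
    def appearance(self) -> tuple[float, float, float]:
        """``(q_af_F, t_af, tau_af)`` for the fixing de novo mutant.

        ``q_af_F`` is the mean index of the favourable environment in which
        the fixing mutant appears, conditioned on de novo rescue; ``t_af`` the
        fixation-weighted mean appearance time within a favourable phase;
        ``tau_af = (2 q_af_F - 1) tau + t_af``.
        """
        p, half = self.params, self._half
        pr = self.p_r_DN
        if pr <= 0.0:
            raise ValueError("conditioning on null event: p_r_DN = 0")
        sh, sf = self.supply_integrals
        s = self._cycle_survival
        a = math.exp(-sf)
        if 1.0 - s < 1e-12:
            # extinction beyond floating-point resolution: the fixing mutant's
            # favourable-environment index is plain geometric
            q_af = 1.0 / (1.0 - a)
        else:
            # truncate the geometric outer sum at relative tail mass 1e-12
            k_max = int(
                min(5_000_000, max(64, math.ceil(math.log(1e-12) / math.log(s))))
            )
            q = np.arange(0, k_max + 1, dtype=float)
            term_q = q * a ** (q - 1.0) * (1.0 - a)
            inner = np.cumsum(term_q)
            pqf = s**q * (1.0 - s)
            q_af = float(np.sum(pqf * inner) / pr)
        # fixation-weighted mean appearance time within a favourable phase
        th = self.t_grid[: half + 1]
        w = (
            p.b_WF
            * self.N_orbit[half:]
            * self.g_orbit[half:]
            * self.pfix_grid[half:]
        )
        denom = trapezoid(w, th)
        t_af = float(trapezoid(th * w, th) / denom) if denom > 0 else math.nan
        tau_af = (2.0 * q_af - 1.0) * self.tau + t_af
        return q_af, t_af, tau_af

    def predict(self) -> RescuePrediction:
        sh, sf = self.supply_integrals
        try:
            q_af, t_af, tau_af = self.appearance
        except ValueError:
            q_af = t_af = tau_af = math.nan
        return RescuePrediction(
            Sigma_H=sh,
            Sigma_F=sf,
            p_r_DN=self.p_r_DN,
            p_r_SGV=self.p_r_SGV,
            p_r=self.p_r_total,
            q_af_F=q_af,
            t_af=t_af,
            tau_af=tau_af,
        )


# ---------------------------------------------------------------------------
# functional wrappers


def pfix(params: ModelParams, dist: DurationDistribution, t0, n_grid: int = 4096):
    return RescueAnalytics(params, dist, n_grid).pfix(t0)


def mutant_supply_integrals(
    params: ModelParams, dist: DurationDistribution, n_grid: int = 4096
) -> tuple[float, float]:
    return RescueAnalytics(params, dist, n_grid).supply_integrals


def p_rescue_dn(
    params: ModelParams, dist: DurationDistribution, n_grid: int = 4096
) -> float:
    return RescueAnalytics(params, dist, n_grid).p_r_DN


def p_rescue_total(
    params: ModelParams, dist: DurationDistribution, n_grid: int = 4096
) -> float:
    return RescueAnalytics(params, dist, n_grid).p_r_total


def appearance_time(
    params: ModelParams, dist: DurationDistribution, n_grid: int = 4096
) -> tuple[float, float, float]:
    return RescueAnalytics(params, dist, n_grid).appearance


def fast_limit(params: ModelParams) -> FastLimit:
    """Effective constant environment for very fast fluctuations.

    Averaged birth rate ``b~ = (b_WF + b_WH)/2``, effective equilibrium size
    ``N~* = equilibrium_size(b~)``, selection coefficient
    ``s~ = b_M d_W / (b~ d_M) - 1``, and mean fixing-mutant appearance time
    ``tau~_af = 1 / (mu N~* d_W s~)`` when ``s~ > 0`` (None otherwise).
    ``T0~`` is the mean extinction time of the effective chain.
    """
    b_tilde = 0.5 * (params.b_WF + params.b_WH)
    n_tilde = equilibrium_size(params.growth, b_tilde, params.d_W, params.K)
    s_tilde = params.b_M * params.d_W / (b_tilde * params.d_M) - 1.0
    if s_tilde > 0 and params.mu > 0:
        tau_af_tilde = 1.0 / (params.mu * n_tilde * params.d_W * s_tilde)
    else:
        tau_af_tilde = None
    T0_tilde = extinction.mean_extinction_time_constant(
        params.growth, b_tilde, params.d_W, params.K, int(round(n_tilde))
    )
    return FastLimit(
        b_tilde=b_tilde,
        N_tilde_star=n_tilde,
        s_tilde=s_tilde,
        tau_af_tilde=tau_af_tilde,
        T0_tilde=T0_tilde,
    )


def harsh_mutant_supply(params: ModelParams) -> tuple[float, float]:
    """Births per harsh phase and probability that at least one mutant appears.

    ``N_birth ~ b_WH N* (2K - N*) / (2 d_W K)`` and
    ``P(>=1 mutant) = 1 - (1 - mu)^N_birth``.
    """
    if params.b_WH == 0.0:
        return 0.0, 0.0
    n_star = params.n_star
    n_birth = (
        params.b_WH * n_star * (2.0 * params.K - n_star) / (2.0 * params.d_W * params.K)
    )
    p_one = 1.0 - (1.0 - params.mu) ** n_birth
    return float(n_birth), float(p_one)
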
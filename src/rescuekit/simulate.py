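"""Exact stochastic simulation of the two-genotype rescue process.

A realization starts from the wild-type favourable-environment equilibrium
(rounded to the nearest integer) plus ``init_mutants`` pre-existing mutants,
and evolves under an alternating harsh/favourable schedule (harsh first) with
phase durations drawn from a :class:`~rescuekit.environment.DurationDistribution`.
Event rates in environment ``alpha`` are::

    wild-type birth  N_W * b_W,alpha * g(N_tot / K)
    wild-type death  N_W * d_W
    mutant birth     N_M * b_M * g(N_tot / K)
    mutant death     N_M * d_M

with the density factor evaluated at the *total* population size (both
genotypes compete for the same resources).  Each wild-type birth yields a
mutant offspring with probability ``mu`` (no back-mutation).  A realization
absorbs either at extinction (``N_W + N_M = 0``) or at rescue, declared when
the mutant count reaches ``ceil(rescue_fraction * N_M*)`` with ``N_M*`` the
mutant equilibrium size; from that size the residual extinction probability is
astronomically small (about ``(d_M/b_M)**threshold``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import _ssa
from .environment import DurationDistribution
from .growth import GrowthKind, ModelParams

__all__ = [
    "SimOutcome",
    "EnsembleSummary",
    "simulate_realization",
    "run_ensemble",
    "ensemble_records",
    "simulate_trajectory",
    "rescue_threshold",
]

_GROWTH_CODE = {GrowthKind.LOGISTIC: 0, GrowthKind.GOMPERTZ: 1, GrowthKind.RICHARDS: 2}
_MAX_EVENTS = 10**9
_INITIAL_PHASES = 512


@dataclass(frozen=True)
class SimOutcome:
    """Fate and event record of a single realization."""

    fate: str  # "extinct" | "rescued"
    T0: Optional[float]  # extinction time (extinct only)
    rescue_time: Optional[float]  # rescue-declaration time (rescued only)
    q_F: int  # completed favourable phases before absorption
    extinct_phase: Optional[str]  # "H" | "F" (extinct only)
    first_success_mutant_time: Optional[float]  # oldest surviving lineage origin
    n_mutation_events: int
    max_ntot: int  # largest total population observed

    @property
    def rescued(self) -> bool:
        return self.fate == "rescued"


@dataclass(frozen=True)
class EnsembleSummary:
    """Replicate-averaged statistics with 95% confidence intervals."""

    n_reps: int
    p_rescue_hat: float
    p_rescue_ci: tuple[float, float]
    mean_T0_given_extinct: float
    T0_ci: tuple[float, float]
    mean_qF: float
    qF_ci: tuple[float, float]
    mean_appearance_time_given_rescue: float
    appearance_ci: tuple[float, float]
    omega_F_hat: float
    seed: Optional[int] = None


def rescue_threshold(params: ModelParams, rescue_fraction: float = 0.9) -> int:
    """Mutant count at which rescue is declared."""
    return int(math.ceil(rescue_fraction * params.n_star_mutant))


def _initial_wildtype(params: ModelParams) -> int:
    return int(round(params.n_star))


def _kernel_args(params: ModelParams, rescue_fraction: float):
    return (
        _GROWTH_CODE[params.growth.kind],
        float(params.growth.beta),
        params.b_WF,
        params.b_WH,
        params.d_W,
        params.b_M,
        params.d_M,
        params.mu,
        float(params.K),
        _initial_wildtype(params),
    )


def _phase_hint(params: ModelParams, dist: DurationDistribution) -> int:
    """Initial schedule length generous enough to avoid replays.

    The number of cycles to extinction is roughly geometric with per-cycle
    death probability of order the harsh-phase extinction probability; a
    pure-death estimate with net rate ``d_W - b_WH`` bounds it well enough for
    a first guess (a realization whose schedule still runs out is replayed on
    a longer one).
    """
    n0 = _initial_wildtype(params)
    d_eff = max(params.d_W - params.b_WH, 1e-12)
    ts = dist.mean_tau + dist.sigma * np.array([-1.0, 0.0, 1.0, 2.0])
    ts = ts[ts > 0]
    p_die = max(
        float(np.mean((-np.expm1(-d_eff * ts)) ** n0)), 1e-5
    )
    cycles = 8.0 / p_die
    cap = 2**18 if params.mu == 0 else 2**16
    return int(min(max(_INITIAL_PHASES, 2 * cycles), cap))


def _run_one(
    params: ModelParams,
    dist: DurationDistribution,
    init_mutants: int,
    child: np.random.SeedSequence,
    rescue_fraction: float,
    max_events: int,
    n_phase_hint: int | None = None,
) -> SimOutcome:
    kernel_seed = int(child.generate_state(1, dtype=np.uint32)[0])
    base = _kernel_args(params, rescue_fraction)
    threshold = rescue_threshold(params, rescue_fraction)
    n_phases = n_phase_hint or _phase_hint(params, dist)
    while True:
        sched_rng = np.random.default_rng(child)
        durations = np.asarray(dist.sample(sched_rng, n_phases), dtype=float)
        out = _ssa._ssa_realization(
            kernel_seed, *base, int(init_mutants), threshold, durations, max_events
        )
        status = out[0]
        if status == _ssa.SCHEDULE_EXHAUSTED:
            # same kernel seed + identical duration prefix: the trajectory is
            # replayed exactly and continues past the old schedule end
            n_phases *= 8
            if n_phases > 2**25:
                raise RuntimeError("no absorption reached within schedule budget")
            continue
        if status == _ssa.MAX_EVENTS_REACHED:
            raise RuntimeError(
                f"no absorption reached within {max_events} events; "
                "check that the parameterization admits extinction or rescue"
            )
        break
    _, fate, t_abs, q_f, extinct_in_f, first_mut, n_mut, max_ntot = out
    if fate == _ssa.EXTINCT:
        return SimOutcome(
            fate="extinct",
            T0=float(t_abs),
            rescue_time=None,
            q_F=int(q_f),
            extinct_phase="F" if extinct_in_f else "H",
            first_success_mutant_time=None,
            n_mutation_events=int(n_mut),
            max_ntot=int(max_ntot),
        )
    return SimOutcome(
        fate="rescued",
        T0=None,
        rescue_time=float(t_abs),
        q_F=int(q_f),
        extinct_phase=None,
        first_success_mutant_time=None if math.isnan(first_mut) else float(first_mut),
        n_mutation_events=int(n_mut),
        max_ntot=int(max_ntot),
    )


def simulate_realization(
    params: ModelParams,
    dist: DurationDistribution,
    init_mutants: int = 0,
    seed: int | np.random.SeedSequence = 0,
    rescue_fraction: float = 0.9,
    max_events: int = _MAX_EVENTS,
) -> SimOutcome:
    """Simulate one realization to absorption (extinction or rescue)."""
    if init_mutants not in (0, 1):
        raise ValueError("init_mutants must be 0 or 1")
    child = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    return _run_one(params, dist, init_mutants, child, rescue_fraction, max_events)


def _mean_ci(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return math.nan, (math.nan, math.nan)
    m = float(np.mean(x))
    if x.size == 1 or np.ptp(x) == 0:
        return m, (m, m)
    half = stats.t.ppf(0.975, x.size - 1) * stats.sem(x)
    return m, (m - half, m + half)


def ensemble_records(
    params: ModelParams,
    dist: DurationDistribution,
    init_mutants: int = 0,
    n_reps: int = 1000,
    seed: int = 0,
    rescue_fraction: float = 0.9,
    max_events: int = _MAX_EVENTS,
) -> pd.DataFrame:
    """Per-replicate outcomes as a data frame (one row per realization)."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if init_mutants not in (0, 1):
        raise ValueError("init_mutants must be 0 or 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    hint = _phase_hint(params, dist)
    rows = []
    for rep, child in enumerate(children):
        o = _run_one(
            params, dist, init_mutants, child, rescue_fraction, max_events, hint
        )
        rows.append(
            {
                "rep": rep,
                "fate": o.fate,
                "T0": o.T0,
                "rescue_time": o.rescue_time,
                "q_F": o.q_F,
                "extinct_phase": o.extinct_phase,
                "first_success_mutant_time": o.first_success_mutant_time,
                "n_mutation_events": o.n_mutation_events,
            }
        )
    return pd.DataFrame(rows)


def summarize(records: pd.DataFrame, seed: int | None = None) -> EnsembleSummary:
    """Reduce per-replicate records to an :class:`EnsembleSummary`."""
    n = len(records)
    rescued = records["fate"] == "rescued"
    k = int(rescued.sum())
    ci = stats.binomtest(k, n).proportion_ci(0.95, method="wilson")
    t0 = records.loc[~rescued, "T0"].to_numpy(dtype=float)
    mean_t0, t0_ci = _mean_ci(t0)
    mean_qf, qf_ci = _mean_ci(records["q_F"].to_numpy(dtype=float))
    app = records.loc[rescued, "first_success_mutant_time"].dropna().to_numpy(float)
    mean_app, app_ci = _mean_ci(app)
    extinct = records.loc[~rescued, "extinct_phase"]
    omega_f = float((extinct == "F").mean()) if len(extinct) else math.nan
    return EnsembleSummary(
        n_reps=n,
        p_rescue_hat=k / n,
        p_rescue_ci=(float(ci.low), float(ci.high)),
        mean_T0_given_extinct=mean_t0,
        T0_ci=t0_ci,
        mean_qF=mean_qf,
        qF_ci=qf_ci,
        mean_appearance_time_given_rescue=mean_app,
        appearance_ci=app_ci,
        omega_F_hat=omega_f,
        seed=seed,
    )


def run_ensemble(
    params: ModelParams,
    dist: DurationDistribution,
    init_mutants: int = 0,
    n_reps: int = 1000,
    seed: int = 0,
    rescue_fraction: float = 0.9,
    max_events: int = _MAX_EVENTS,
) -> EnsembleSummary:
    """Replicate ensemble with independent per-replicate seed streams.

    Bit-identical output for identical ``(params, dist, init_mutants, n_reps,
    seed)``.
    """
    records = ensemble_records(
        params, dist, init_mutants, n_reps, seed, rescue_fraction, max_events
    )
    return summarize(records, seed=seed)


def lineage_fixation_mc(
    params: ModelParams,
    dist: DurationDistribution,
    t0: float,
    n_reps: int = 10_000,
    seed: int = 0,
    n_establish: int = 50,
    t_max_periods: float = 400.0,
) -> float:
    """Monte-Carlo fixation probability of a single mutant lineage.

    Direct simulation of the time-inhomogeneous linear birth-death lineage
    used by the branching approximation: one mutant appears at cycle time
    ``t0`` against the periodic mean-field wild-type background; the lineage
    is followed until it dies out or reaches ``n_establish`` individuals
    (from which eventual loss is negligible).  Serves as an independent check
    of :meth:`rescuekit.rescue.RescueAnalytics.pfix`.
    """
    from .rescue import RescueAnalytics

    ra = RescueAnalytics(params, dist)
    beta_grid = params.b_M * ra.g_orbit
    b_max = float(beta_grid.max())
    period = 2.0 * ra.tau
    grid_dt = float(ra.t_grid[1] - ra.t_grid[0])
    seeds = np.random.SeedSequence(seed).generate_state(n_reps, np.uint32)
    wins = 0
    for s in seeds:
        wins += _ssa._lineage_realization(
            int(s),
            float(t0),
            period,
            beta_grid,
            grid_dt,
            b_max,
            params.d_M,
            n_establish,
            float(t0) + t_max_periods * period,
        )
    return wins / n_reps


def simulate_trajectory(
    params: ModelParams,
    dist: DurationDistribution,
    horizon: float,
    init_mutants: int = 0,
    seed: int = 0,
    rescue_fraction: float = 0.9,
) -> pd.DataFrame:
    """Record a single trajectory (t, N_W, N_M, phase) up to ``horizon``.

    Convenience for illustration; stops early at extinction or rescue.  Plain
    Python event loop, intended for short horizons.
    """
    rng = np.random.default_rng(seed)
    from .environment import generate_schedule
    from .growth import density_factor

    schedule = generate_schedule(dist, horizon, rng)
    threshold = rescue_threshold(params, rescue_fraction)
    n_w, n_m = _initial_wildtype(params), int(init_mutants)
    t = 0.0
    rows = [(0.0, n_w, n_m, "H")]
    switches = np.cumsum([d for _, d in schedule.phases])
    phase_idx = 0
    while t < horizon and n_w + n_m > 0 and n_m < threshold:
        phase, _ = schedule.phases[phase_idx]
        bw = params.birth_rate(phase)
        ntot = n_w + n_m
        g = density_factor(params.growth, ntot, params.K) if ntot >= 1 else 0.0
        rates = np.array(
            [n_w * bw * g, n_w * params.d_W, n_m * params.b_M * g, n_m * params.d_M]
        )
        total = rates.sum()
        t_switch = switches[phase_idx]
        if total <= 0:
            t = t_switch
            phase_idx += 1
            continue
        dt = rng.exponential(1.0 / total)
        if t + dt >= t_switch:
            t = t_switch
            phase_idx += 1
            if phase_idx >= len(schedule.phases):
                break
            continue
        t += dt
        ev = rng.choice(4, p=rates / total)
        if ev == 0:
            if rng.random() < params.mu:
                n_m += 1
            else:
                n_w += 1
        elif ev == 1:
            n_w -= 1
        elif ev == 2:
            n_m += 1
        else:
            n_m -= 1
        rows.append((t, n_w, n_m, phase))
    return pd.DataFrame(rows, columns=["t", "N_W", "N_M", "phase"])
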
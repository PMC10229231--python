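"""Low-level event-driven (Gillespie) kernels.

These kernels are written in a numba-compilable subset of Python and are
jitted when numba is importable; otherwise they run as plain Python (correct
but slow).  All randomness comes from numba/numpy's legacy global generator,
seeded per call, so a (seed, arguments) pair fully determines a realization.

Time-inhomogeneity is handled exactly: rates are constant within an
environmental phase, so an exponential waiting time that would cross the next
switch epoch is discarded and the clock advanced to the switch (the memoryless
property makes the redraw valid).
"""

from __future__ import annotations

import math

import numpy as np

try:  # optional acceleration
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


# status codes
OK = 0
SCHEDULE_EXHAUSTED = 1
MAX_EVENTS_REACHED = 2

# fate codes
EXTINCT = 0
RESCUED = 1

_LINEAGE_CAP = 1024


@njit(cache=False)
def _density_factor(code: int, beta: float, ntot: float, K: float) -> float:
    x = ntot / K
    if code == 0:  # logistic
        g = 1.0 - x
    elif code == 1:  # gompertz; births only occur with ntot >= 1
        g = math.log(K / ntot)
    else:  # richards
        g = 1.0 - x**beta
    if g < 0.0:
        g = 0.0
    return g


@njit(cache=False, fastmath=True)
def _ssa_realization(
    seed: int,
    growth_code: int,
    growth_beta: float,
    b_wf: float,
    b_wh: float,
    d_w: float,
    b_m: float,
    d_m: float,
    mu: float,
    K: float,
    n_w0: int,
    n_m0: int,
    rescue_threshold: int,
    durations: np.ndarray,
    max_events: int,
):
    """One realization of the two-genotype birth-death process.

    Returns (status, fate, t_abs, q_f, extinct_in_F, first_success_mutant_time,
    n_mutation_events, max_ntot).  fate is -1 when no absorption was reached
    (status != OK).
    """
    np.random.seed(seed)

    n_w = n_w0
    n_m = n_m0
    t = 0.0
    phase_idx = 0
    n_phases = durations.shape[0]
    t_switch = durations[0]
    q_f = 0
    events = 0
    n_mut_events = 0
    max_ntot = n_w + n_m

    # mutant lineage bookkeeping: origin time and current size per lineage
    origins = np.zeros(_LINEAGE_CAP)
    sizes = np.zeros(_LINEAGE_CAP, dtype=np.int64)
    n_lin = 0
    overflow = False
    if n_m0 > 0:
        origins[0] = 0.0
        sizes[0] = n_m0
        n_lin = 1

    status = OK
    fate = -1
    t_abs = np.nan
    extinct_in_f = False
    first_mut_time = np.nan

    while True:
        if n_w + n_m == 0:
            fate = EXTINCT
            t_abs = t
            extinct_in_f = phase_idx % 2 == 1
            break
        if n_m >= rescue_threshold:
            fate = RESCUED
            t_abs = t
            if not overflow:
                best = np.inf
                for i in range(n_lin):
                    if sizes[i] > 0 and origins[i] < best:
                        best = origins[i]
                first_mut_time = best
            break
        if events >= max_events:
            status = MAX_EVENTS_REACHED
            break

        harsh = phase_idx % 2 == 0
        bw = b_wh if harsh else b_wf
        ntot = float(n_w + n_m)
        g = _density_factor(growth_code, growth_beta, ntot, K)
        r_wb = n_w * bw * g
        r_wd = n_w * d_w
        r_mb = n_m * b_m * g
        r_md = n_m * d_m
        total = r_wb + r_wd + r_mb + r_md

        advance_phase = False
        if total <= 0.0:
            advance_phase = True
        else:
            dt = np.random.exponential(1.0 / total)
            if t + dt >= t_switch:
                advance_phase = True
        if advance_phase:
            if phase_idx + 1 >= n_phases:
                status = SCHEDULE_EXHAUSTED
                break
            if not harsh:
                q_f += 1
            t = t_switch
            phase_idx += 1
            t_switch += durations[phase_idx]
            continue

        t += dt
        events += 1
        u = np.random.random() * total
        if u < r_wb:
            if mu > 0.0 and np.random.random() < mu:
                # mutant offspring: new lineage
                n_m += 1
                n_mut_events += 1
                if n_lin >= _LINEAGE_CAP:
                    # recycle extinct lineage slots
                    k = 0
                    for i in range(n_lin):
                        if sizes[i] > 0:
                            sizes[k] = sizes[i]
                            origins[k] = origins[i]
                            k += 1
                    n_lin = k
                if n_lin < _LINEAGE_CAP:
                    origins[n_lin] = t
                    sizes[n_lin] = 1
                    n_lin += 1
                else:  # pathologically many live lineages
                    overflow = True
            else:
                n_w += 1
        elif u < r_wb + r_wd:
            n_w -= 1
        elif u < r_wb + r_wd + r_mb:
            n_m += 1
            if not overflow:
                pick = np.random.random() * (n_m - 1)
                acc = 0.0
                for i in range(n_lin):
                    acc += sizes[i]
                    if pick < acc:
                        sizes[i] += 1
                        break
        else:
            n_m -= 1
            if not overflow:
                pick = np.random.random() * (n_m + 1)
                acc = 0.0
                for i in range(n_lin):
                    acc += sizes[i]
                    if pick < acc:
                        sizes[i] -= 1
                        break
        if n_w + n_m > max_ntot:
            max_ntot = n_w + n_m

    return (
        status,
        fate,
        t_abs,
        q_f,
        extinct_in_f,
        first_mut_time,
        n_mut_events,
        max_ntot,
    )


@njit(cache=False)
def _lineage_realization(
    seed: int,
    t0: float,
    period: float,
    beta_grid: np.ndarray,
    grid_dt: float,
    b_max: float,
    d_m: float,
    n_establish: int,
    t_max: float,
):
    """Single mutant lineage in the periodic mean-field background.

    Linear birth-death process with time-dependent per-capita birth rate
    ``beta(t)`` (piecewise-linear interpolation of ``beta_grid`` over one
    period), simulated exactly by thinning with bound ``b_max >= beta``.
    Returns 1 if the lineage reaches ``n_establish`` before hitting 0.
    """
    np.random.seed(seed)
    n = 1
    t = t0
    top = b_max + d_m
    while 0 < n < n_establish and t < t_max:
        t += np.random.exponential(1.0 / (n * top))
        tm = t % period
        idx = int(tm / grid_dt)
        if idx >= beta_grid.shape[0] - 1:
            idx = beta_grid.shape[0] - 2
        frac = tm / grid_dt - idx
        beta = beta_grid[idx] * (1.0 - frac) + beta_grid[idx + 1] * frac
        u = np.random.random() * top
        if u < beta:
            n += 1
        elif u > b_max:
            n -= 1
        # else: phantom event (thinning rejection)
    return 1 if n >= n_establish else 0
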
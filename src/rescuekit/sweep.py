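"""Config-driven sweeps: analytic curves plus simulation points on a tau grid.

A sweep evaluates, for every (parameter variant, tau, sigma) grid point, the
full analytic extinction and rescue predictions and (optionally) a simulated
replicate ensemble, and collects everything into one long-format table --
the same protocol the model's validation figures follow (analytic solid
lines, simulated points with confidence intervals).

Tau grids are specified in units of each variant's harsh-environment survival
time ``tau_0H = log(N*)/d_W`` so presets transfer across carrying capacities;
sigma values are fractions of tau.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import extinction, rescue
from .environment import DurationDistribution
from .growth import GrowthLaw, ModelParams
from .simulate import ensemble_records, summarize

__all__ = ["SweepConfig", "run_sweep", "presets", "preset_names"]

_BASE = ModelParams()  # b_WF=1, b_WH=0, d_W=0.1, b_M=1, d_M=0.1, mu=1e-3, K=100


@dataclass(frozen=True)
class SweepConfig:
    """One sweep: parameter variants crossed with a (tau, sigma) grid."""

    name: str
    variants: tuple[tuple[str, ModelParams], ...]
    tau_over_tau0H: tuple[float, ...] = (0.5, 0.75, 1.0, 1.5, 2.0, 3.0)
    sigma_fracs: tuple[float, ...] = (0.0,)
    init_mutants: int = 0
    n_reps: int = 1000
    seed: int = 0
    simulate: bool = True

    def __post_init__(self) -> None:
        if not self.variants or not self.tau_over_tau0H or not self.sigma_fracs:
            raise ValueError("variants and grids must be non-empty")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    def grid_size(self) -> int:
        return len(self.variants) * len(self.tau_over_tau0H) * len(self.sigma_fracs)


def _analytic_row(params: ModelParams, dist: DurationDistribution) -> dict:
    row: dict = {}
    ext = extinction.total_extinction_time(params, dist)
    row.update(ext.to_dict())
    if params.mu > 0:
        row.update(rescue.RescueAnalytics(params, dist).predict().to_dict())
    return row


def run_sweep(
    config: SweepConfig,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run a sweep; optionally write ``<name>.csv`` and ``<name>.meta.json``.

    Grid points whose evaluation fails record the error message instead of
    aborting the sweep.  Deterministic for a fixed config (the replicate seed
    is derived from the config seed and the grid position).
    """
    rows = []
    for iv, (label, params) in enumerate(config.variants):
        tau0h = params.tau_0H
        for it, mult in enumerate(config.tau_over_tau0H):
            tau = mult * tau0h
            for isig, frac in enumerate(config.sigma_fracs):
                dist = DurationDistribution(tau, frac * tau)
                row = {
                    "experiment": config.name,
                    "variant": label,
                    "tau_over_tau0H": mult,
                    "tau": tau,
                    "sigma": frac * tau,
                    "n_reps": config.n_reps if config.simulate else 0,
                }
                try:
                    row.update(_analytic_row(params, dist))
                    if config.simulate:
                        point_seed = (
                            config.seed + 1_000_003 * iv + 1009 * it + 101 * isig
                        )
                        rec = ensemble_records(
                            params,
                            dist,
                            init_mutants=config.init_mutants,
                            n_reps=config.n_reps,
                            seed=point_seed,
                        )
                        s = summarize(rec, seed=point_seed)
                        row.update(
                            {
                                "sim_p_rescue": s.p_rescue_hat,
                                "sim_p_rescue_lo": s.p_rescue_ci[0],
                                "sim_p_rescue_hi": s.p_rescue_ci[1],
                                "sim_T0": s.mean_T0_given_extinct,
                                "sim_T0_lo": s.T0_ci[0],
                                "sim_T0_hi": s.T0_ci[1],
                                "sim_qF": s.mean_qF,
                                "sim_tau_af": s.mean_appearance_time_given_rescue,
                                "sim_tau_af_lo": s.appearance_ci[0],
                                "sim_tau_af_hi": s.appearance_ci[1],
                                "sim_omega_F": s.omega_F_hat,
                                "seed": point_seed,
                            }
                        )
                except Exception as err:  # record, keep sweeping
                    row["error"] = f"{type(err).__name__}: {err}"
                rows.append(row)
    result = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_csv(out / f"{config.name}.csv", index=False)
        meta = dataclasses.asdict(
            replace(config, variants=tuple((l, p.to_dict()) for l, p in config.variants))
        )
        meta["version"] = _version
        with open(out / f"{config.name}.meta.json", "w") as fh:
            json.dump(meta, fh, indent=2, default=str)
    return result


def _growth_variants() -> tuple[tuple[str, ModelParams], ...]:
    return (
        ("logistic", _BASE),
        ("gompertz", _BASE.with_growth(GrowthLaw("gompertz"))),
        ("richards_b2", _BASE.with_growth(GrowthLaw("richards", 2.0))),
        ("richards_b05", _BASE.with_growth(GrowthLaw("richards", 0.5))),
    )


def presets() -> dict[str, SweepConfig]:
    """Named sweep configurations mirroring the model's validation figures.

    All use the baseline parameters (``b_WF = 1``, ``b_WH = 0``, ``d_W = 0.1``,
    ``b_M = 1``, ``d_M = 0.1``, ``K = 100``, ``mu = 1e-3`` where mutation is
    on, equilibrium size 90) and a default of 1000 replicates per point.
    Extinction-only presets (no mutation) keep ``tau >= 0.5 tau_0H``: below
    that the extinction time grows beyond any reasonable simulation budget.
    """
    mu0 = replace(_BASE, mu=0.0)
    harsh_variants = tuple(
        (f"b_WH={b}", replace(_BASE, b_WH=b)) for b in (0.0, 0.001, 0.01)
    )
    harsh_variants_mu0 = tuple(
        (f"b_WH={b}", replace(mu0, b_WH=b)) for b in (0.0, 0.001, 0.01)
    )
    kmu_variants = tuple(
        (f"Kmu={_BASE.K * m:g}", replace(_BASE, mu=m)) for m in (1e-3, 1e-2, 1e-1)
    )
    rescue_grid = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0)
    return {
        "fig1c": SweepConfig(
            "fig1c",
            tuple((l, replace(p, mu=0.0)) for l, p in _growth_variants()),
            tau_over_tau0H=(0.5,),
        ),
        "fig2a": SweepConfig(
            "fig2a", (("logistic", mu0),), sigma_fracs=(0.0, 0.1, 0.3)
        ),
        "fig2b": SweepConfig(
            "fig2b", tuple((l, replace(p, mu=0.0)) for l, p in _growth_variants())
        ),
        "fig2c": SweepConfig("fig2c", harsh_variants_mu0),
        "fig3a": SweepConfig(
            "fig3a", kmu_variants, tau_over_tau0H=rescue_grid
        ),
        "fig3b": SweepConfig(
            "fig3b",
            (("logistic", _BASE),),
            tau_over_tau0H=rescue_grid,
            sigma_fracs=(0.0, 0.1, 0.3),
        ),
        "fig3c": SweepConfig(
            "fig3c", _growth_variants(), tau_over_tau0H=rescue_grid
        ),
        "fig3d": SweepConfig(
            "fig3d", harsh_variants, tau_over_tau0H=rescue_grid
        ),
        "fig4a": SweepConfig(
            "fig4a", kmu_variants[:2], tau_over_tau0H=rescue_grid
        ),
        "fig4b": SweepConfig(
            "fig4b",
            (("logistic", _BASE),),
            tau_over_tau0H=rescue_grid,
            sigma_fracs=(0.0, 0.1, 0.3),
        ),
    }


def preset_names() -> list[str]:
    return sorted(presets())


def get_preset(name: str) -> SweepConfig:
    try:
        return presets()[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(preset_names())}"
        ) from None
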
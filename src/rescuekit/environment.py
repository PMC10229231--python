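"""Phase-duration distributions and alternating environment schedules.

Each environmental phase (harsh or favourable) lasts a random time drawn from
``F_tau``: a Dirac delta at ``tau`` for deterministic (periodic) fluctuations,
or a normal distribution of mean ``tau`` and standard deviation ``sigma``
truncated to non-negative values for stochastic (quasi-periodic) fluctuations.
Schedules always begin with a harsh phase: the population starts at its
favourable-environment equilibrium, so the first change it experiences is the
onset of harshness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DurationDistribution", "Schedule", "generate_schedule"]

_REJECTION_CHUNK = 4096  # fixed proposal chunk keeps sampled prefixes stable


@dataclass(frozen=True)
class DurationDistribution:
    """Law of a single environment-phase duration.

    ``sigma = 0`` denotes the degenerate (deterministic) case; ``sigma > 0``
    the zero-truncated normal with location ``mean_tau`` and scale ``sigma``.
    """

    mean_tau: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not self.mean_tau > 0:
            raise ValueError("mean_tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    @property
    def deterministic(self) -> bool:
        return self.sigma == 0.0

    def _truncnorm(self):
        a = -self.mean_tau / self.sigma  # truncate below at 0
        return stats.truncnorm(a, np.inf, loc=self.mean_tau, scale=self.sigma)

    def pdf(self, t):
        """Density of the zero-truncated normal at ``t`` (0 for ``t < 0``).

        Normalization ``Z = (1/2)(1 + erf(tau / (sigma sqrt(2))))`` makes the
        density integrate to one over ``[0, inf)``.
        """
        if self.deterministic:
            raise ValueError("degenerate distribution has no density")
        t = np.asarray(t, dtype=float)
        out = np.where(t >= 0, self._truncnorm().pdf(np.maximum(t, 0.0)), 0.0)
        return out if out.ndim else float(out)

    def mean(self) -> float:
        """Exact mean: ``tau`` if degenerate, else the truncated-normal
        moment ``tau + sigma * phi(tau/sigma) / Phi(tau/sigma)``."""
        if self.deterministic:
            return self.mean_tau
        z = self.mean_tau / self.sigma
        return self.mean_tau + self.sigma * stats.norm.pdf(z) / stats.norm.cdf(z)

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw durations by rejection from ``Normal(tau, sigma)``.

        Negative proposals are discarded (exact for this truncation; the
        acceptance rate is >= 1/2 since ``tau > 0``).  ``sigma = 0`` returns
        ``tau`` exactly.
        """
        n = 1 if size is None else int(size)
        if self.deterministic:
            out = np.full(n, self.mean_tau)
        else:
            parts: list[np.ndarray] = []
            have = 0
            while have < n:
                prop = rng.normal(self.mean_tau, self.sigma, _REJECTION_CHUNK)
                acc = prop[prop >= 0]
                parts.append(acc)
                have += acc.size
            out = np.concatenate(parts)[:n]
        return out if size is not None else float(out[0])

    def support(self, n_sigma: float = 8.0) -> tuple[float, float]:
        """Interval carrying essentially all mass (for quadrature)."""
        if self.deterministic:
            return self.mean_tau, self.mean_tau
        lo = max(0.0, self.mean_tau - n_sigma * self.sigma)
        return lo, self.mean_tau + n_sigma * self.sigma


@dataclass(frozen=True)
class Schedule:
    """Alternating harsh/favourable phases, harsh first."""

    durations: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.durations):
            raise ValueError("all durations must be positive")

    @property
    def phases(self) -> list[tuple[str, float]]:
        return [("H" if i % 2 == 0 else "F", d) for i, d in enumerate(self.durations)]

    @property
    def total(self) -> float:
        return float(sum(self.durations))

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("phase\tduration\n")
            for phase, d in self.phases:
                fh.write(f"{phase}\t{d:.12g}\n")


def generate_schedule(
    dist: DurationDistribution, horizon: float, rng: np.random.Generator
) -> Schedule:
    """Alternating schedule whose cumulative duration first exceeds ``horizon``."""
    if not horizon > 0:
        raise ValueError("horizon must be positive")
    n_guess = max(4, int(math.ceil(horizon / dist.mean_tau)) + 4)
    durations = list(dist.sample(rng, n_guess))
    while sum(durations) <= horizon:
        durations.extend(dist.sample(rng, n_guess))
    total, keep = 0.0, []
    for d in durations:
        keep.append(d)
        total += d
        if total > horizon:
            break
    return Schedule(tuple(keep))
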
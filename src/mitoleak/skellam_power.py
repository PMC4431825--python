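"""Detection power for a paternal mtDNA fraction via the Skellam distribution.

The discordant-read counts of mother and child over a motif are modelled
as independent Poisson variables with means N*lambda0 (background only)
and N*(lambda0 + f) (background plus a paternal fraction f), for equal
motif coverage N in both individuals.  Their difference D = C - M follows
a Skellam distribution, and the one-sided test "reject maternal-only
inheritance when D >= c" has its critical value c chosen conservatively on
the null Skellam(N*lambda0, N*lambda0).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import ConfigError


@dataclass(frozen=True)
class PowerSpec:
    """One power scenario: coverage, background rate, paternal fraction, alpha."""

    coverage: int
    background_rate: float
    paternal_fraction: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ConfigError("coverage must be >= 0")
        if self.background_rate < 0 or self.paternal_fraction < 0:
            raise ConfigError("rates must be >= 0")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")

    @property
    def mu_child(self) -> float:
        return self.coverage * (self.background_rate + self.paternal_fraction)

    @property
    def mu_mother(self) -> float:
        return self.coverage * self.background_rate


def skellam_pmf(d, mu1: float, mu2: float):
    """P(C - M = d) for independent C~Poisson(mu1), M~Poisson(mu2).

    Handles the degenerate limits mu1 == 0 and/or mu2 == 0 where the
    difference collapses to (minus) a single Poisson count.
    """
    if mu1 < 0 or mu2 < 0:
        raise ConfigError("Poisson means must be >= 0")
    d = np.asarray(d)
    if mu1 == 0 and mu2 == 0:
        out = np.where(d == 0, 1.0, 0.0)
    elif mu2 == 0:
        out = np.where(d >= 0, stats.poisson.pmf(np.maximum(d, 0), mu1), 0.0)
    elif mu1 == 0:
        out = np.where(d <= 0, stats.poisson.pmf(np.maximum(-d, 0), mu2), 0.0)
    else:
        out = stats.skellam.pmf(d, mu1, mu2)
    return float(out) if out.ndim == 0 else out


def _upper_tail(c: int, mu1: float, mu2: float) -> float:
    """P(D >= c) for D ~ Skellam(mu1, mu2), degenerate limits included."""
    if mu1 == 0 and mu2 == 0:
        return 1.0 if c <= 0 else 0.0
    if mu2 == 0:
        return float(stats.poisson.sf(c - 1, mu1)) if c > 0 else 1.0
    if mu1 == 0:
        return float(stats.poisson.cdf(-c, mu2)) if c <= 0 else 0.0
    return float(stats.skellam.sf(c - 1, mu1, mu2))


def critical_value(mu0: float, alpha: float) -> int:
    """Smallest integer c with P(D >= c) <= alpha under D ~ Skellam(mu0, mu0)."""
    if mu0 == 0:
        return 1
    c = int(stats.skellam.isf(alpha, mu0, mu0)) + 1
    while c > -10 * mu0 and _upper_tail(c - 1, mu0, mu0) <= alpha:
        c -= 1
    while _upper_tail(c, mu0, mu0) > alpha:
        c += 1
    return c


def detection_power(spec: PowerSpec) -> float:
    """Power of the one-sided child-excess test at the spec's alpha."""
    c = critical_value(spec.mu_mother, spec.alpha)
    return _upper_tail(c, spec.mu_child, spec.mu_mother)


def power_grid(
    coverages,
    backgrounds,
    fractions,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Evaluate detection power over the cross-product of the three grids."""
    coverages, backgrounds, fractions = list(coverages), list(backgrounds), list(fractions)
    if not (coverages and backgrounds and fractions):
        raise ConfigError("all three grids must be non-empty")
    rows = [
        {
            "coverage": n,
            "background_rate": lam,
            "paternal_fraction": f,
            "power": detection_power(PowerSpec(n, lam, f, alpha)),
        }
        for n, lam, f in product(coverages, backgrounds, fractions)
    ]
    return pd.DataFrame(rows)
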
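"""Two-sample t-test power and effect-size solver.

The design question behind the cohort: with 33 cases, how small an effect
(Cohen's d, the standardized mean difference) is detectable by a two-sided
two-sample t-test at a given alpha and power, and how much does enlarging
the control arm help? The exact engine uses the noncentral t distribution
with noncentrality delta = d * sqrt(n1*n2/(n1+n2)); a normal-approximation
mode (d = (z_{1-alpha/2} + z_power) * sqrt(1/n1 + 1/n2)) is provided as a
cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats

from .exceptions import ConfigurationError

__all__ = ["solve_power", "solve_effect_size"]


def _validate(n1: int, n2: int, alpha: float) -> None:
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("group sizes must be at least 2")
    if not 0 < alpha < 1:
        raise ConfigurationError("alpha must be in (0, 1)")


def solve_power(n1: int, n2: int, alpha: float, d: float, engine: str = "nct") -> float:
    """Power of the two-sided two-sample t-test at standardized effect size ``d``."""
    _validate(n1, n2, alpha)
    delta = d * np.sqrt(n1 * n2 / (n1 + n2))
    if engine == "nct":
        df = n1 + n2 - 2
        tcrit = stats.t.ppf(1 - alpha / 2, df)
        power = stats.nct.sf(tcrit, df, delta) + stats.nct.cdf(-tcrit, df, delta)
    elif engine == "normal":
        zcrit = stats.norm.ppf(1 - alpha / 2)
        power = stats.norm.sf(zcrit - delta) + stats.norm.cdf(-zcrit - delta)
    else:
        raise ConfigurationError(f"unknown engine {engine!r}; use 'nct' or 'normal'")
    return float(power)


def solve_effect_size(
    n1: int, n2: int, alpha: float, power: float, engine: str = "nct"
) -> float:
    """Smallest Cohen's d at which the two-sided t-test reaches ``power``.

    Root-found so that the achieved power matches the request to better than
    1e-8.
    """
    _validate(n1, n2, alpha)
    if not 0 < power < 1:
        raise ConfigurationError("power must be in (0, 1)")
    if power <= alpha:
        raise ConfigurationError("requested power must exceed alpha (power at d=0 is alpha)")

    def gap(d: float) -> float:
        return solve_power(n1, n2, alpha, d, engine=engine) - power

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e3:
            raise ConfigurationError("requested power is unreachable")
    d = optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    return float(d)
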
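"""Byar's-method confidence intervals for event counts.

Byar's approximation gives closed-form limits for a Poisson-distributed
count ``O``::

    lower = O       * (1 - 1/(9 O)     - z / (3 sqrt(O)))^3
    upper = (O + 1) * (1 - 1/(9 (O+1)) + z / (3 sqrt(O+1)))^3

with ``z`` the standard-normal quantile for the chosen two-sided level.
Intervals on counts are rescaled to rates or proportions by dividing by
the relevant denominator and multiplying by the reporting multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class CountInterval:
    """A confidence interval on the count scale."""

    count: int
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not self.lower <= self.count <= self.upper:
            raise ValueError(
                f"interval [{self.lower}, {self.upper}] does not bracket "
                f"count {self.count}"
            )


def _z(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def byar_interval(count: int, level: float = 0.95) -> CountInterval:
    """Byar's approximate Poisson confidence limits for an observed count.

    For ``count == 0`` the lower limit is 0 by convention; the upper limit
    uses the formula with ``O + 1 = 1``.
    """
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    z = _z(level)
    if count == 0:
        lower = 0.0
    else:
        lower = count * (1.0 - 1.0 / (9.0 * count) - z / (3.0 * math.sqrt(count))) ** 3
        lower = max(lower, 0.0)
    o1 = count + 1.0
    upper = o1 * (1.0 - 1.0 / (9.0 * o1) + z / (3.0 * math.sqrt(o1))) ** 3
    return CountInterval(count=count, lower=lower, upper=upper, level=level)


def exact_poisson_interval(count: int, level: float = 0.95) -> CountInterval:
    """Exact (Garwood) Poisson limits via gamma quantiles.

    Test oracle for :func:`byar_interval`; not used in the output path.
    """
    if count < 0:
        raise ValueError(f"count must be non-negative, got {count}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"ci_level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    lower = 0.0 if count == 0 else float(stats.gamma.ppf(alpha / 2.0, count))
    upper = float(stats.gamma.ppf(1.0 - alpha / 2.0, count + 1))
    return CountInterval(count=count, lower=lower, upper=upper, level=level)


def scale_interval(
    interval: CountInterval, denominator: float, multiplier: int = 100_000
) -> tuple[float, float, float]:
    """Rescale a count interval to the reporting scale.

    Returns ``(lower, estimate, upper)``, each equal to the corresponding
    count-scale quantity divided by ``denominator`` and multiplied by
    ``multiplier``. Ordering is preserved (positive linear map).
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if multiplier <= 0:
        raise ValueError(f"multiplier must be positive, got {multiplier}")
    factor = multiplier / denominator
    return (interval.lower * factor, interval.count * factor, interval.upper * factor)


def wilson_interval(
    numerator: int, denominator: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score interval for a proportion, on the [0, 1] scale.

    Optional sensitivity-check alternative to Byar scaling for
    prevalence proportions; never used by default.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    z = _z(level)
    n = denominator
    p = numerator / n
    centre = (p + z * z / (2 * n)) / (1 + z * z / n)
    half = (z / (1 + z * z / n)) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return (max(centre - half, 0.0), min(centre + half, 1.0))
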
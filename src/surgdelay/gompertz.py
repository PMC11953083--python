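"""Gompertz map from tumor diameter to 15-year breast-cancer mortality.

Fifteen-year BC-specific mortality (1 minus 15-year relative survival) as
a function of tumor diameter TD (mm) follows a Gompertz curve

    M(TD) = a * exp(-b * exp(-c * TD))      [percent]

with asymptote ``a`` (percent), displacement ``b`` and rate ``c`` (per
mm). The calibrated defaults a=58.4, b=4.46, c=0.071 give a basal
mortality of 19.57% at the 19.8 mm population-mean diameter and a turning
point (steepest mortality gain per mm) at ln(b)/c ~ 21.1 mm.

Internally mortality is carried as a fraction in [0, 1); the public
operations return percent, the paper-facing unit. ``round2`` implements
the "printed" rounding convention: national cohort tables are reproducible
only when mortalities are rounded to 2 decimal places (in percent) before
being multiplied by cohort sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "GompertzParams",
    "mortality_at_diameter",
    "mortality_fraction",
    "inflection_diameter",
    "mortality_slope",
    "mortality_delta",
    "round2",
]


@dataclass(frozen=True)
class GompertzParams:
    a: float = 58.4  # asymptote, percent
    b: float = 4.46  # displacement, dimensionless
    c: float = 0.071  # rate, per mm

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0 and self.c > 0):
            raise ValueError("Gompertz parameters a, b, c must all be positive")


DEFAULT_PARAMS = GompertzParams()


def mortality_at_diameter(td: float, params: GompertzParams = DEFAULT_PARAMS) -> float:
    """15-year BC-specific mortality (percent) at diameter ``td`` mm.

    Strictly increasing in ``td`` and bounded above by the asymptote
    ``params.a``.
    """
    if td < 0:
        raise ValueError("tumor diameter must be non-negative")
    return params.a * math.exp(-params.b * math.exp(-params.c * td))


def mortality_fraction(td: float, params: GompertzParams = DEFAULT_PARAMS) -> float:
    """Mortality as a fraction in [0, 1) — internal unit."""
    return mortality_at_diameter(td, params) / 100.0


def inflection_diameter(params: GompertzParams = DEFAULT_PARAMS) -> float:
    """Diameter (mm) of maximal mortality slope: ln(b)/c."""
    return math.log(params.b) / params.c


def mortality_slope(td: float, params: GompertzParams = DEFAULT_PARAMS) -> float:
    """Analytic derivative dM/dTD in percent per mm.

    Equals ``a*b*c*exp(-c*td)*exp(-b*exp(-c*td))``; positive everywhere,
    maximal (= a*c/e) at :func:`inflection_diameter`.
    """
    if td < 0:
        raise ValueError("tumor diameter must be non-negative")
    inner = math.exp(-params.c * td)
    return params.a * params.b * params.c * inner * math.exp(-params.b * inner)


def mortality_delta(
    td_from: float, td_to: float, params: GompertzParams = DEFAULT_PARAMS
) -> float:
    """Mortality increase (percentage points) growing from ``td_from`` to ``td_to``."""
    if td_to < td_from:
        raise ValueError("td_to must be >= td_from")
    return mortality_at_diameter(td_to, params) - mortality_at_diameter(td_from, params)


def round2(pct: float) -> float:
    """Round a percent value to 2 decimals, half away from zero.

    The half-up convention (not banker's rounding) matches the printed
    cohort tables.
    """
    return math.floor(pct * 100.0 + 0.5) / 100.0
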
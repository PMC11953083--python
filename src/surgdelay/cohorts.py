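"""Delay cohorts: partition a national incidence cohort and price the delay.

An annual incidence cohort is split into primary-metastatic (M1) cases and
M0 cases; the M0 population is split by hormone-receptor status (HR+/HR-)
and by binned diagnosis-to-surgery delay. Each (HR status, delay bin)
"delay cohort" starts at the population-mean diameter TD0, grows for the
bin's representative day count under the HR-appropriate VDT, and is
assigned the Gompertz 15-year mortality of the grown diameter. Excess
deaths are the cohort-size-weighted mortality difference against the
zero-delay baseline; relative risk (RR) is the ratio of the two
mortalities.

Week bins are represented by their middle day (week w -> day 7*(w-1)+4:
4, 11, 18, ...); open-ended bins carry an explicit representative day.

Two rounding conventions are supported. ``"full"`` keeps full floating
precision throughout. ``"printed"`` rounds each mortality to 2 decimal
places (percent) before multiplying by cohort sizes, which is the
convention under which the published national tables are arithmetically
reproducible (e.g. 40,864 x (20.31 - 19.57)/100 = 302).

M1 cases never enter delay cohorts; population summaries count them as
deaths within 15 years (a 100%-mortality convention forced by the
published totals), and delay does not modify their outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .gompertz import GompertzParams, mortality_at_diameter, round2
from .growth import HR_NEG, HR_POS, GrowthParams, grown_diameter, normalize_hr

__all__ = [
    "DelayBin",
    "DelayDistribution",
    "PopulationSpec",
    "CohortInput",
    "CohortOutcome",
    "AggregateTotals",
    "largest_remainder_apportion",
    "build_delay_cohorts",
    "cohort_outcome",
    "aggregate_outcomes",
    "population_mortality_summary",
    "mean_delay_days",
    "redistribute_early_mass",
]

RoundingMode = Literal["full", "printed"]

#: Representative (midweek) day for delay week w = 1, 2, ...
def midweek_day(week: int) -> int:
    return 7 * (week - 1) + 4


@dataclass(frozen=True)
class DelayBin:
    """One delay bin: a label, a mass and its representative day.

    ``mass`` is either a fraction of the M0 population or an absolute
    count of M0 patients, according to the parent distribution's
    ``mass_type``.
    """

    label: str
    mass: float
    representative_day: float

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"bin {self.label!r}: mass must be non-negative")
        if not self.representative_day > 0:
            raise ValueError(f"bin {self.label!r}: representative_day must be positive")


@dataclass(frozen=True)
class DelayDistribution:
    """Ordered delay bins with a common mass type."""

    bins: tuple[DelayBin, ...]
    mass_type: Literal["fraction", "count"] = "fraction"

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(self.bins))
        if not self.bins:
            raise ValueError("delay distribution must contain at least one bin")
        if self.mass_type not in ("fraction", "count"):
            raise ValueError(f"unknown mass_type: {self.mass_type!r}")
        if self.mass_type == "fraction":
            total = math.fsum(b.mass for b in self.bins)
            # published fractions are rounded; tolerate up to half a percent
            if abs(total - 1.0) > 0.005:
                raise ValueError(f"bin fractions must sum to 1 (got {total:.4f})")

    @property
    def total_mass(self) -> float:
        return math.fsum(b.mass for b in self.bins)

    def fractions(self) -> tuple[float, ...]:
        """Bin masses normalised to exact fractions."""
        total = self.total_mass
        return tuple(b.mass / total for b in self.bins)

    def with_representative_day(self, label: str, day: float) -> "DelayDistribution":
        """Copy of the distribution with one bin's representative day replaced."""
        new = tuple(
            replace(b, representative_day=day) if b.label == label else b
            for b in self.bins
        )
        if new == self.bins:
            raise ValueError(f"no bin labelled {label!r}")
        return DelayDistribution(new, self.mass_type)


@dataclass(frozen=True)
class PopulationSpec:
    """A national annual breast-cancer population.

    ``incidence`` counts all new invasive BCs in a year; ``m1_fraction``
    of them are primary metastatic, the rest (M0) are the delay-sensitive
    population, of which ``hr_pos_fraction`` are hormone-receptor
    positive. ``td0`` is the mean tumor diameter at diagnosis in mm.
    """

    incidence: float
    m1_fraction: float = 0.062
    hr_pos_fraction: float = 0.85
    td0: float = 19.8

    def __post_init__(self) -> None:
        if self.incidence < 0:
            raise ValueError("incidence must be non-negative")
        for name in ("m1_fraction", "hr_pos_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.td0 > 0:
            raise ValueError("td0 must be positive")

    @property
    def m0_count(self) -> float:
        return self.incidence * (1.0 - self.m1_fraction)

    @property
    def m1_count(self) -> float:
        return self.incidence * self.m1_fraction


@dataclass(frozen=True)
class CohortInput:
    """One delay cohort awaiting outcome computation."""

    hr_status: str
    n: float
    delay_day: float
    td0: float
    label: str = ""


@dataclass(frozen=True)
class CohortOutcome:
    """Computed outcome of one delay cohort."""

    hr_status: str
    n: float
    delay_day: float
    td_after: float  # mm
    mortality_base: float  # percent
    mortality_delayed: float  # percent
    rr: float
    baseline_deaths: float
    excess_deaths: float
    label: str = ""

    @property
    def delayed_deaths(self) -> float:
        return self.baseline_deaths + self.excess_deaths


def largest_remainder_apportion(total: int, weights: Sequence[float]) -> list[int]:
    """Apportion ``total`` integer units proportionally to ``weights``.

    Hamilton / largest-remainder method: floor the exact quotas, then hand
    the leftover units to the largest fractional remainders, ties broken
    by position. Conserves ``total`` exactly.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    wsum = math.fsum(weights)
    if wsum <= 0:
        raise ValueError("weights must have positive sum")
    quotas = [total * w / wsum for w in weights]
    counts = [math.floor(q) for q in quotas]
    short = total - sum(counts)
    order = sorted(range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def build_delay_cohorts(
    pop: PopulationSpec, dist: DelayDistribution
) -> list[CohortInput]:
    """Partition the M0 population into HR-status x delay-bin cohorts.

    Counts mode: each bin's mass is an absolute M0 count, split between
    HR strata by largest remainder at the population's HR+ fraction (the
    per-bin split under which the published per-stratum cohort sizes are
    regenerated exactly). Fractions mode: the M0 population is first
    apportioned into the two HR strata, then each stratum is apportioned
    across bins, so per-stratum cohort counts conserve the stratum totals
    exactly.
    """
    cohorts: list[CohortInput] = []
    if dist.mass_type == "count":
        for b in dist.bins:
            n_bin = int(round(b.mass))
            n_pos, n_neg = largest_remainder_apportion(
                n_bin, [pop.hr_pos_fraction, 1.0 - pop.hr_pos_fraction]
            )
            cohorts.append(CohortInput(HR_POS, n_pos, b.representative_day, pop.td0, b.label))
            cohorts.append(CohortInput(HR_NEG, n_neg, b.representative_day, pop.td0, b.label))
    else:
        m0 = int(round(pop.m0_count))
        n_pos_total, n_neg_total = largest_remainder_apportion(
            m0, [pop.hr_pos_fraction, 1.0 - pop.hr_pos_fraction]
        )
        fracs = dist.fractions()
        for hr, stratum_total in ((HR_POS, n_pos_total), (HR_NEG, n_neg_total)):
            per_bin = largest_remainder_apportion(stratum_total, fracs)
            for b, n in zip(dist.bins, per_bin):
                cohorts.append(CohortInput(hr, n, b.representative_day, pop.td0, b.label))
    return cohorts


def cohort_outcome(
    n: float,
    hr: str,
    delay_day: float,
    growth: GrowthParams | None = None,
    mort: GompertzParams | None = None,
    rounding: RoundingMode = "full",
    td0: float | None = None,
    label: str = "",
) -> CohortOutcome:
    """Outcome of a single delay cohort.

    Grows ``td0`` (default ``growth.td0``) for ``delay_day`` days with the
    HR-appropriate VDT, evaluates basal and delayed Gompertz mortalities
    (2-dp rounded first in ``"printed"`` mode) and derives RR, baseline
    and excess deaths. Deaths are real-valued; rounding to integers is a
    formatting concern.
    """
    if n < 0:
        raise ValueError("cohort size must be non-negative")
    if delay_day < 0:
        raise ValueError("delay must be non-negative")
    if rounding not in ("full", "printed"):
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    growth = growth or GrowthParams()
    mort = mort or GompertzParams()
    hr = normalize_hr(hr)
    start = growth.td0 if td0 is None else td0
    td_after = grown_diameter(start, delay_day, growth.vdt(hr), growth.diameter_factor)
    m_base = mortality_at_diameter(start, mort)
    m_delayed = mortality_at_diameter(td_after, mort)
    if rounding == "printed":
        m_base = round2(m_base)
        m_delayed = round2(m_delayed)
    baseline_deaths = n * m_base / 100.0
    excess_deaths = n * (m_delayed - m_base) / 100.0
    rr = m_delayed / m_base if m_base > 0 else float("nan")
    return CohortOutcome(
        hr_status=hr,
        n=n,
        delay_day=delay_day,
        td_after=td_after,
        mortality_base=m_base,
        mortality_delayed=m_delayed,
        rr=rr,
        baseline_deaths=baseline_deaths,
        excess_deaths=excess_deaths,
        label=label,
    )


@dataclass(frozen=True)
class AggregateTotals:
    """Per-stratum and overall totals over a set of delay cohorts.

    ``weighted_rr`` is total delayed deaths over total baseline deaths,
    i.e. the cohort-size-weighted mean RR.
    """

    n: float
    baseline_deaths: float
    excess_deaths: float
    weighted_rr: float
    by_hr: dict = field(default_factory=dict)

    @property
    def delayed_deaths(self) -> float:
        return self.baseline_deaths + self.excess_deaths


def aggregate_outcomes(cohorts: Iterable[CohortOutcome]) -> AggregateTotals:
    """Sum cohort outcomes overall and per HR stratum."""
    cohorts = list(cohorts)
    if not cohorts:
        raise ValueError("no cohorts to aggregate")

    def _totals(sub: list[CohortOutcome]) -> AggregateTotals:
        n = math.fsum(c.n for c in sub)
        base = math.fsum(c.baseline_deaths for c in sub)
        excess = math.fsum(c.excess_deaths for c in sub)
        rr = (base + excess) / base if base > 0 else float("nan")
        return AggregateTotals(n=n, baseline_deaths=base, excess_deaths=excess, weighted_rr=rr)

    by_hr = {
        hr: _totals([c for c in cohorts if c.hr_status == hr])
        for hr in (HR_POS, HR_NEG)
        if any(c.hr_status == hr for c in cohorts)
    }
    overall = _totals(cohorts)
    return AggregateTotals(
        n=overall.n,
        baseline_deaths=overall.baseline_deaths,
        excess_deaths=overall.excess_deaths,
        weighted_rr=overall.weighted_rr,
        by_hr=by_hr,
    )


def population_mortality_summary(
    pop: PopulationSpec, totals: AggregateTotals
) -> dict[str, float]:
    """National 15-year mortality with and without delay, including M1.

    Primary M1 cases contribute their full count as deaths (100%
    15-year-mortality convention); delay affects only M0 cohorts.
    Returns deaths without delay, deaths with delay, and the latter as a
    percent of incidence.
    """
    m0_n = totals.n
    if m0_n > pop.incidence + 0.5:
        raise ValueError("cohort totals exceed the population incidence")
    deaths_no_delay = totals.baseline_deaths + pop.m1_count
    deaths_with_delay = deaths_no_delay + totals.excess_deaths
    pct = 100.0 * deaths_with_delay / pop.incidence if pop.incidence > 0 else float("nan")
    return {
        "deaths_no_delay": deaths_no_delay,
        "deaths_with_delay": deaths_with_delay,
        "pct_of_incidence": pct,
    }


def mean_delay_days(dist: DelayDistribution) -> float:
    """Mass-weighted mean of the bins' representative days."""
    total = dist.total_mass
    if total <= 0:
        raise ValueError("distribution has zero mass")
    return math.fsum(b.mass * b.representative_day for b in dist.bins) / total


def redistribute_early_mass(
    target: DelayDistribution,
    reference: DelayDistribution,
    n_bins: int,
) -> DelayDistribution:
    """Split an aggregated leading bin of ``target`` by ``reference`` ratios.

    The first bin of ``target`` is assumed to pool the first ``n_bins``
    delay weeks (e.g. a source that reports weeks 1-4 only as a lump).
    Its mass is distributed over ``n_bins`` new bins proportionally to the
    leading-bin masses of ``reference``; labels and representative days
    are taken from ``reference``. Total mass is conserved exactly. With
    ``n_bins == 1`` the distribution is returned unchanged apart from the
    leading bin's label/day being preserved.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(reference.bins) < n_bins:
        raise ValueError("reference has fewer leading bins than n_bins")
    ref_masses = [b.mass for b in reference.bins[:n_bins]]
    ref_total = math.fsum(ref_masses)
    if ref_total <= 0:
        raise ValueError("reference leading bins carry no mass")
    pooled = target.bins[0].mass
    head = tuple(
        DelayBin(rb.label, pooled * m / ref_total, rb.representative_day)
        for rb, m in zip(reference.bins[:n_bins], ref_masses)
    )
    return DelayDistribution(head + target.bins[1:], target.mass_type)
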
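"""Model/Results front end for the surgical-delay mortality calculator.

:class:`TreatmentDelayModel` binds a national population and its delay
distribution to growth and mortality parameters; :meth:`fit` evaluates
the deterministic cohort pipeline and returns a
:class:`TreatmentDelayResults` carrying the per-cohort table, per-stratum
and overall totals, and the national mortality summary, with
``summary()`` producing a readable report. Monte-Carlo validation and
plotting hang off these objects.

Example
-------
>>> from surgdelay import TreatmentDelayModel
>>> res = TreatmentDelayModel.from_country("us", rounding="printed").fit()
>>> round(res.totals.excess_deaths)
4678
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .cohorts import (
    AggregateTotals,
    CohortOutcome,
    DelayDistribution,
    PopulationSpec,
    RoundingMode,
    aggregate_outcomes,
    build_delay_cohorts,
    cohort_outcome,
    mean_delay_days,
    population_mortality_summary,
)
from .datasets import country_population, load_delay_distribution, read_delay_csv
from .gompertz import GompertzParams, mortality_at_diameter
from .growth import HR_NEG, HR_POS, GrowthParams

__all__ = ["TreatmentDelayModel", "TreatmentDelayResults"]


class TreatmentDelayModel:
    """Deterministic delay-mortality model for one population.

    Parameters
    ----------
    population : PopulationSpec
        Incidence, M1 fraction, HR+ fraction and mean diameter at diagnosis.
    delay_distribution : DelayDistribution
        Week-binned diagnosis-to-surgery delays (fractions or counts).
    growth : GrowthParams, optional
        VDT growth law; defaults to TD0 19.8 mm, VDT 170/72 days.
    mortality : GompertzParams, optional
        Diameter -> 15-year-mortality curve; defaults to a=58.4, b=4.46,
        c=0.071.
    rounding : {"full", "printed"}
        Mortality rounding convention; "printed" reproduces the published
        table arithmetic.
    """

    def __init__(
        self,
        population: PopulationSpec,
        delay_distribution: DelayDistribution,
        growth: GrowthParams | None = None,
        mortality: GompertzParams | None = None,
        rounding: RoundingMode = "full",
    ) -> None:
        self.population = population
        self.delay_distribution = delay_distribution
        self.growth = growth or GrowthParams(td0=population.td0)
        self.mortality = mortality or GompertzParams()
        self.rounding = rounding

    @classmethod
    def from_country(
        cls,
        country: str,
        open_bin_day: float | None = None,
        rounding: RoundingMode = "full",
        growth: GrowthParams | None = None,
        mortality: GompertzParams | None = None,
        **population_overrides,
    ) -> "TreatmentDelayModel":
        """Model for a packaged country ("us" or "germany")."""
        pop = country_population(country, **population_overrides)
        dist = load_delay_distribution(country, open_bin_day=open_bin_day)
        return cls(pop, dist, growth=growth, mortality=mortality, rounding=rounding)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        population: PopulationSpec,
        **kwargs,
    ) -> "TreatmentDelayModel":
        """Model from a delay-distribution DataFrame.

        ``df`` needs columns ``label``, ``mass``, ``mass_type``,
        ``representative_day`` (the CSV schema).
        """
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        return cls(population, read_delay_csv(buf), **kwargs)

    def fit(self) -> "TreatmentDelayResults":
        """Evaluate the cohort pipeline; returns the results object."""
        inputs = build_delay_cohorts(self.population, self.delay_distribution)
        outcomes = [
            cohort_outcome(
                ci.n,
                ci.hr_status,
                ci.delay_day,
                growth=self.growth,
                mort=self.mortality,
                rounding=self.rounding,
                td0=self.population.td0,
                label=ci.label,
            )
            for ci in inputs
        ]
        return TreatmentDelayResults(self, outcomes)

    def simulate(self, n_patients: int, seed: int, n_reps: int = 1, **kwargs):
        """Patient-level Monte-Carlo run mirroring this model's configuration.

        Thin wrapper over :func:`surgdelay.simulate.simulate_excess_deaths`;
        see that function for the estimator and the keyword options.
        """
        from .simulate import SimulationConfig, simulate_excess_deaths

        config = SimulationConfig(
            n_patients=n_patients,
            seed=seed,
            population=self.population,
            delay_distribution=self.delay_distribution,
            growth=self.growth,
            mortality=self.mortality,
            **kwargs,
        )
        return simulate_excess_deaths(config, n_reps=n_reps)


class TreatmentDelayResults:
    """Fitted results: per-cohort outcomes plus aggregates."""

    def __init__(self, model: TreatmentDelayModel, outcomes: Sequence[CohortOutcome]):
        self.model = model
        self.cohort_outcomes: list[CohortOutcome] = list(outcomes)
        self.totals: AggregateTotals = aggregate_outcomes(self.cohort_outcomes)
        self.population_summary = population_mortality_summary(
            model.population, self.totals
        )
        self.mean_delay_days = mean_delay_days(model.delay_distribution)

    @property
    def cohorts(self) -> pd.DataFrame:
        """Per-cohort outcome table (one row per HR status x delay bin)."""
        return pd.DataFrame(
            {
                "label": c.label,
                "hr_status": c.hr_status,
                "n": c.n,
                "delay_day": c.delay_day,
                "td_after_mm": c.td_after,
                "mortality_base_pct": c.mortality_base,
                "mortality_delayed_pct": c.mortality_delayed,
                "rr": c.rr,
                "baseline_deaths": c.baseline_deaths,
                "excess_deaths": c.excess_deaths,
            }
            for c in self.cohort_outcomes
        )

    def summary(self) -> str:
        """Human-readable summary of the fitted population."""
        m = self.model
        t = self.totals
        ps = self.population_summary
        lines = [
            "Surgical-delay 15-year mortality model",
            "=" * 54,
            f"Incidence:            {m.population.incidence:>12,.0f}",
            f"M1 fraction:          {m.population.m1_fraction:>12.3f}",
            f"HR+ fraction:         {m.population.hr_pos_fraction:>12.3f}",
            f"TD0 (mm):             {m.population.td0:>12.1f}",
            f"VDT HR+/HR- (days):   {m.growth.vdt_hr_pos:>6.0f} / {m.growth.vdt_hr_neg:.0f}",
            f"Gompertz (a, b, c):   {m.mortality.a}, {m.mortality.b}, {m.mortality.c}",
            f"Rounding mode:        {m.rounding:>12}",
            f"Mean delay (days):    {self.mean_delay_days:>12.1f}",
            "-" * 54,
        ]
        for hr in (HR_POS, HR_NEG):
            if hr in t.by_hr:
                s = t.by_hr[hr]
                lines.append(
                    f"{hr}: n={s.n:>9,.0f}  baseline deaths={s.baseline_deaths:>9,.0f}  "
                    f"excess={s.excess_deaths:>7,.0f}  RR={s.weighted_rr:.3f}"
                )
        lines += [
            "-" * 54,
            f"Excess deaths (total):     {t.excess_deaths:>10,.0f}",
            f"Deaths without delay (+M1):{ps['deaths_no_delay']:>10,.0f}",
            f"Deaths with delay (+M1):   {ps['deaths_with_delay']:>10,.0f}",
            f"15-y mortality, % of incidence: {ps['pct_of_incidence']:>6.1f}",
        ]
        return "\n".join(lines)

    def plot_mortality_curve(self, ax=None, td_max: float = 60.0):
        """Gompertz mortality vs diameter, with TD0 and inflection marked."""
        import matplotlib.pyplot as plt
        import numpy as np

        from .gompertz import inflection_diameter

        if ax is None:
            _, ax = plt.subplots()
        td = np.linspace(0.0, td_max, 400)
        m = [mortality_at_diameter(x, self.model.mortality) for x in td]
        ax.plot(td, m)
        ax.axvline(self.model.population.td0, ls="--", lw=0.8, color="grey")
        ax.axvline(inflection_diameter(self.model.mortality), ls=":", lw=0.8, color="grey")
        ax.set_xlabel("tumor diameter (mm)")
        ax.set_ylabel("15-year BC-specific mortality (%)")
        return ax

    def plot_excess_by_delay(self, ax=None):
        """Per-bin excess deaths by HR stratum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.cohorts
        for hr, marker in ((HR_POS, "o"), (HR_NEG, "s")):
            sub = df[df.hr_status == hr]
            ax.plot(sub.delay_day, sub.excess_deaths, marker=marker, label=hr)
        ax.set_xlabel("delay (days)")
        ax.set_ylabel("excess deaths per cohort")
        ax.legend()
        return ax
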
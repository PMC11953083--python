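# Methods

## Model

`surgdelay` computes the expected 15-year breast-cancer-specific mortality
cost of the diagnosis-to-surgery interval. It is a deterministic cohort
calculator: no fitting happens at run time; the parameters are published
calibrations and the "data" are national incidence counts and week-binned
delay distributions.

The causal chain assumed is: delay → further exponential tumor growth →
larger diameter at surgery → higher probability that a distant metastasis
was seeded before removal → higher 15-year mortality. Tumor diameter (TD)
is the sole prognostic surrogate; all other prognostic structure (grade,
nodal status, subtype mix) is carried implicitly by the calibrated
diameter–mortality curve and by the HR stratification of growth speed.

**Growth.** Spherical volume doubling every VDT days gives
TD(d) = TD₀ · f^(d/VDT) with f the per-doubling diameter multiplier. The
literal published factor 1.26 is the default rather than 2^(1/3) ≈ 1.2599
(difference < 0.03% per VDT); `GrowthParams.diameter_factor` accepts
2^(1/3) when exact volume doubling is wanted. Growth of the *primary* is
treated as exponential throughout; decelerating (Gompertzian) primary
growth is out of scope.

**Mortality.** M(TD) = a·exp(−b·exp(−c·TD)) percent, a = 58.4, b = 4.46,
c = 0.071/mm. The model keeps mortality as a fraction internally and
exposes percent at the interfaces. Two published statements about this
curve (a 12→25 mm rise of 18.1 points and a "8.4–26.6%" range) are not
consistent with these parameter values, which give 18.7 points and
8.7–27.4%; they appear to derive from an earlier parameterisation. The
package computes from the parameters and documents the gap rather than
forcing agreement.

**Cohorts.** Incidence × (1 − 6.2% M1) is the delay-sensitive M0
population; 85% HR+. Week bins are represented by their middle day
(week w → day 7(w−1)+4). Per cohort: grow, re-score, difference. The
aggregate relative risk is total delayed deaths over total baseline
deaths. M1 cases are counted as deaths within 15 years in national
summaries (the convention under which the published national totals add
up) and are unaffected by delay.

**Rounding conventions.** `rounding="full"` (default) keeps full float
precision. `rounding="printed"` rounds each mortality to 2 decimal places
(percent, half-up) before multiplying by cohort sizes — the published
tables are arithmetically reproducible only under this convention, so it
is the mode used when comparing against them. Death counts stay
real-valued internally; integer rounding happens only in report
formatting.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| TD₀ | 19.8 (14 screening, 28 pT2) | mm | mean diameter at diagnosis |
| diameter_factor | 1.26 | – | diameter multiplier per VDT |
| VDT HR+ / HR− | 170 / 72 | days | volume doubling times |
| a, b, c | 58.4, 4.46, 0.071 | %, –, /mm | Gompertz mortality curve |
| m1_fraction | 0.062 | – | primary-metastatic share |
| hr_pos_fraction | 0.85 | – | HR+ share of M0 |
| PI₈₀ HR+ / HR− | (16.9, 60.4, 141.3) / (9.4, 25.2, 80.8) | months | MET-free-time percentile anchors |
| post_met_survival | 28 | months | median survival after MET diagnosis |

The weighted mean VDT at the default HR mix is 155.3 days; a rounded
"≈150 days" circulates in the literature but enters no computation here —
all cohort arithmetic uses the stratum-specific 170/72.

Post-MET survival defaults to 28 months because that value reproduces the
published 12.4/6.5-year medians to delay-attributable death; an
alternative 2.2-year (26.4-month) figure appears in discussion contexts
and is configurable.

## Packaged national inputs and their quirks

The US (2022) and German (2019) delay tables ship as CSVs of per-bin M0
counts. Per-stratum cohort sizes are recovered by a per-bin 85/15
largest-remainder split, which regenerates every published per-stratum
count exactly. Fractional distributions are instead apportioned
stratum-first (largest remainder, ties by bin order) so per-stratum sums
are conserved exactly.

Three source inconsistencies are surfaced rather than silently resolved:

- Germany's open-ended bin is labelled ">7 weeks / 46 days" in the table
  but the published excess-death totals (640/278) are reproducible only
  with a 48-day representative (as the methods text states). The packaged
  default is 46; `open_bin_day=48` selects the other convention.
- The published German mean delay of 26.0 days is not derivable from the
  printed bins and the midweek convention (which give 26.7 days).
- The per-1000 reference table's "3 month / 6 month" columns are
  numerically computed at days 88/179 (midweek of weeks 13/26), not
  90/180; the package reproduces the printed cells at 88/179.

Sources that pool the first weeks (the US data pool weeks 1–4) are split
with `redistribute_early_mass`, proportional to a reference country's
leading-bin masses, conserving total mass exactly.

## MET timing

Observed MET-free times mix metastases initiated long before diagnosis
(detected early) with late-initiated ones (detected late). A metastasis
seeded *during* the delay starts from a single cell, so its growth time to
detectability is taken as twice the median MET-free time (2 × 60.4 /
2 × 25.2 months), and adding the median post-MET survival gives the median
time from diagnosis to a delay-attributable death: 12.4 / 6.5 years for
HR+/HR−. The consistency of the median ratio (2.40) with the VDT ratio
(2.36) is exposed as a diagnostic. Elsewhere a 10.8-year HR+ figure
appears for the same 2×median quantity; 2 × 60.4/12 = 10.07 years, and the
package reports the computed value.

## Synthetic cohorts and Monte-Carlo validation

The simulator realises exactly the probabilistic model whose expectation
the deterministic calculator computes: Bernoulli HR and M1 status,
categorical delay bin at the representative day (optionally uniform ±3
days within the week), TD₀ fixed or lognormal with the configured mean and
relative SD (default 0 — the deterministic model works with a single mean
diameter per cohort; the dispersion knob exists to study Jensen-type
effects and is off by default), Bernoulli 15-year death at the Gompertz
probability of the at-surgery diameter, M1 deaths by convention.

Excess deaths are estimated with common random numbers: one death-uniform
per patient is compared against both the delayed and the zero-delay
probability, so a patient contributes exactly when the uniform falls
between the two. This pairing cuts the estimator variance by roughly an
order of magnitude versus independent arms (asserted > 2× in the tests)
and makes an n = 10⁵, 8-replicate validation run take well under a second.
With TD₀ dispersion enabled the deterministic reference is the
dispersion-free expectation, so a Jensen gap between the two is expected
and not treated as disagreement.

**MET-free-time sampler.** No standard two-parameter family fits all
three PI₈₀ anchors (their log-spacing is asymmetric), so times are drawn
by inverse transform from a piecewise quantile function: log-linear
between the anchors at probabilities 0.1/0.5/0.9; above p90 a shifted
exponential tail in time, density-matched at p90; below p10 a truncated
exponential piece on (0, p10], density-matched at p10 and carrying the
CDF continuously to zero, which guarantees strictly positive draws. The
empirical 10/50/90 quantiles of 10⁶ draws match the anchors within 2%.
Equal anchors degenerate to a point mass. MET times are attached only to
simulated deaths, mirroring the use of MET-free-time distributions among
patients who develop metastases; there is no cure or competing-risk
machinery beyond that.

What the simulator deliberately does not emulate about real data:
continuous within-week delay processes, screening detection, adjuvant or
neoadjuvant therapy eradicating delay-seeded METs, subtype structure
beyond HR, or correlation between TD₀ and delay. Passing validation shows
the deterministic arithmetic is an exact expectation of the stated
stochastic model — not that the stated model is biologically complete.

## Numerical choices

- Largest-remainder (Hamilton) apportionment everywhere fractions become
  integer cohorts; ties broken by bin order; conservation is exact and
  property-tested.
- Half-up rounding (not banker's) for printed-mode mortalities and for
  report-formatted death counts, matching the published arithmetic.
- Monotonicity, bounds and the inflection point of the Gompertz curve are
  tested against brute-force grids; beyond ~300 mm the curve is
  float-indistinguishable from its asymptote, so strict-inequality checks
  stop there.
- `days_to_diameter` inverts the growth law in closed form; round-trip
  error is < 10⁻⁶ days over the tested ranges.
- Degenerate inputs: zero delay gives RR exactly 1 and zero excess; empty
  distributions, negative masses, non-monotone anchors and out-of-range
  fractions raise validation errors before any computation.

## Problem sizes

The deterministic national runs involve 26 (US) or 14 (Germany) cohorts
and complete in milliseconds. Monte-Carlo validation defaults to
n = 10⁵ patients × 8 replicates (seeded, reproducible); the sampler
checks use 10⁶ draws. The full test suite runs in a few seconds.

## Known limitations

- The endpoint is the 15-year point estimate only; no survival curves.
- Delay is binned; within-bin timing is a point mass at the midweek day
  (uniform-within-week optional), because the sources publish no
  within-bin spread.
- VDT is dichotomised by HR status; HER2, Ki-67, grade and neoadjuvant
  pathways are not modelled.
- The Gompertz calibration is taken as given; refitting it to registry
  survival data is explicitly out of scope.
- National extrapolations inherit every limitation of the published
  inputs, including their internal rounding (the package reproduces the
  published totals to ~0.1–1.3% depending on the open-bin convention).
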
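# surgdelay

Deterministic modelling of the mortality cost of delaying breast-cancer
surgery, with a patient-level Monte-Carlo validator.

## The problem

Between the confirmed diagnosis of an invasive breast cancer (BC) and its
surgical removal, the primary tumor keeps growing, and a growing tumor
keeps seeding distant metastases. `surgdelay` quantifies what national
week-binned waiting-time distributions cost in 15-year BC-specific deaths.
It is aimed at epidemiologists and health-services researchers who want a
transparent, reproducible calculator rather than a black-box microsimulation.

The model rests on three published ingredients:

1. **Growth law.** A spherical tumor's volume doubles every VDT (volume
   doubling time) days, so its diameter grows as

   *TD(d) = TD₀ · 1.26^(d/VDT)*

   with TD₀ = 19.8 mm (population mean at diagnosis) and VDT = 170/72 days
   for hormone-receptor positive/negative (HR+/HR−) tumors (one volume
   doubling multiplies the diameter by 2^(1/3) ≈ 1.26).

2. **Mortality law.** 15-year BC-specific mortality (in %, 1 minus 15-year
   relative survival) is a Gompertz function of diameter,

   *M(TD) = a · exp(−b · exp(−c · TD))*,  a = 58.4, b = 4.46, c = 0.071,

   giving 19.57% at 19.8 mm and a turning point at ln(b)/c ≈ 21.1 mm.

3. **Population structure.** An annual incidence cohort (packaged: USA
   2022, 287,850 cases; Germany 2019, 71,375) of which 6.2% are primary
   metastatic (M1) and 85% of the M0 remainder are HR+, partitioned over
   the observed week-binned delay distribution, each week represented by
   its middle day (4, 11, 18, …).

Each (HR status × delay bin) cohort is grown, re-scored with the Gompertz
curve, and compared with the zero-delay baseline; the differences aggregate
to national excess deaths and relative risks. A metastasis-timing module
converts delay-attributable deaths into calendar time (median ≈ 12.4/6.5
years after diagnosis for HR+/HR−), and a synthetic patient simulator with
common random numbers verifies the deterministic arithmetic end to end.

## Worked example

```python
from surgdelay import TreatmentDelayModel

res = TreatmentDelayModel.from_country("us", rounding="printed").fit()
print(res.summary())
```

```
Surgical-delay 15-year mortality model
======================================================
Incidence:                 287,850
M1 fraction:                 0.062
HR+ fraction:                0.850
TD0 (mm):                     19.8
VDT HR+/HR- (days):      170 / 72
Gompertz (a, b, c):   58.4, 4.46, 0.071
Rounding mode:             printed
Mean delay (days):            33.7
------------------------------------------------------
HR+: n=  229,502  baseline deaths=   44,914  excess=  3,261  RR=1.073
HR-: n=   40,500  baseline deaths=    7,926  excess=  1,417  RR=1.179
------------------------------------------------------
Excess deaths (total):          4,678
Deaths without delay (+M1):    70,686
Deaths with delay (+M1):       75,364
15-y mortality, % of incidence:   26.2
```

Reading: the observed US delay distribution (mean 33.7 days) converts
roughly 4,700 of the year's 288k diagnoses into additional 15-year deaths —
a 1.6-point rise concentrated in the fast-growing HR− stratum (RR 1.179 vs
1.073) — and lifts the population's 15-year BC-specific mortality, M1
included, to 26.2% of incidence. `res.cohorts` holds the per-cohort table;
for instance the 40,864 HR+ patients waiting a third week (day 18) grow to
20.29 mm, mortality 19.57 → 20.31%, i.e. 302 extra deaths.

A command-line surface mirrors the library:

```bash
surgdelay cohorts --country germany
surgdelay mortality --td 14
surgdelay simulate --country us --n-patients 100000 --seed 1
```

`surgdelay.scenarios` sweeps VDT and TD₀ grids (screening populations at
TD₀ = 14 mm see *relative* mortality increases of ~12%/32% for HR+/HR−
after an 8-week delay), and `surgdelay.simulate` draws synthetic patient
tables for validation and method experiments.

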
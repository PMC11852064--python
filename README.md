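# dalbapk

Population pharmacokinetics of **dalbavancin** — a long-acting lipoglycopeptide
used off-label as multidose rescue therapy for difficult-to-treat Gram-positive
infections — built as a reusable pharmacometrics pipeline for people who model
therapeutic drug monitoring (TDM) data and need simulation-backed answers to
one clinical question: *how late can the next 1500 mg dose be given while the
pharmacodynamic target is still met in ≥ 90 % of patients of a given body
weight?*

## The model

Drug disposition follows a two-compartment model with first-order elimination
and zero-order (30-minute) IV infusion input, parameterised by clearance CL,
central volume V1, inter-compartmental clearance Q and peripheral volume V2.
Body weight enters through fixed allometric exponents,

    CL_i = CL_ref · (WT_i / 70)^0.75 · exp(η_CL,i),     V1_i = V1_ref · (WT_i / 70)^1.0 · exp(η_V1,i)

(and likewise Q, V2), with log-normal inter-individual random effects η and a
proportional residual error DV = f · (1 + ε), ε ~ N(0, b²).  The bundled adult
reference parameterisation is CL 0.0273 L/h, V1 3.6 L, Q 0.0225 L/h, V2 6.4 L,
inter-individual CVs of 22 / 17.3 / 55.9 / 30.1 %, b = 0.144 and a 7 % free
fraction — a typical terminal half-life of about 17 days.

The package has three layers:

* **Kinetics** (`dalbapk.pk`) — exact closed-form biexponential solutions with
  multidose superposition (the production path; an ODE integrator exists only
  as a test oracle).
* **Estimation** (`dalbapk.estimation`) — nonlinear mixed-effects fitting of
  sparse TDM event tables by a Laplace/FOCE-style approximate marginal
  likelihood, with CWRES-based outlier screening, stepwise covariate testing
  (ΔOFV thresholds 3.84 / 6.64), nonparametric bootstrap, η-shrinkage, and
  goodness-of-fit / prediction-corrected VPC diagnostics
  (`dalbapk.diagnostics`).
* **Simulation** (`dalbapk.pta`) — Monte Carlo probability of target
  attainment (PTA) for the time-dependent target **100 % fT > 4×MIC**: the
  free concentration (7 % of total) must exceed four times the MIC at every
  evaluated instant.  At the EUCAST/USCAST breakpoint MIC of 0.25 mg/L this is
  equivalent to keeping total dalbavancin above 4·0.25/0.07 ≈ **14.29 mg/L**.

Because the clinical dataset behind the reference estimates cannot be
redistributed, `dalbapk.study` generates synthetic cohorts with the same
design structure (30 adults, weights 44–179 kg, 2–10 doses 7–14 days apart,
trough + end-of-infusion sampling), so the whole pipeline is testable end to
end and estimation quality is demonstrated by parameter recovery.

## Worked example

```python
import numpy as np
from dalbapk import (dalbavancin_reference_model, sample_population, pta_by_week,
                     Regimen, SimulationConfig, PTAConfig,
                     total_threshold_from_mic, terminal_half_life)
from dalbapk.population import STANDARD_BANDS

model = dalbavancin_reference_model()
print(f"TDM threshold: {total_threshold_from_mic(0.25, 4, 0.07):.2f} mg/L")
print(f"typical terminal half-life: {terminal_half_life(model.theta)/24:.1f} days")

population = sample_population(model, STANDARD_BANDS,
                               SimulationConfig(n_per_band=2000, seed=1))
two_dose = Regimen.from_times([0.0, 168.0], 1500.0)   # 1500 mg at day 0 and day 7
weekly = pta_by_week(model, population, STANDARD_BANDS, two_dose,
                     PTAConfig(horizon_weeks=8))
for band in STANDARD_BANDS:
    f = weekly.fractions[band.label]
    print(f"{band.label:>11}: latest optimal week "
          f"{weekly.latest_optimal_week[band.label]}"
          f"  (PTA by week: {np.round(f, 3).tolist()})")
```

prints

```
TDM threshold: 14.29 mg/L
typical terminal half-life: 16.9 days
   40-80 kg: latest optimal week 5  (PTA by week: [1.0, 1.0, 0.996, 0.973, 0.928, 0.808, 0.624, 0.419])
  80-120 kg: latest optimal week 4  (PTA by week: [1.0, 1.0, 0.988, 0.939, 0.833, 0.636, 0.394, 0.227])
 120-200 kg: latest optimal week 3  (PTA by week: [1.0, 1.0, 0.958, 0.792, 0.599, 0.382, 0.195, 0.088])
```

Read: after 1500 mg at days 0 and 7, a 40–80 kg patient keeps PTA ≥ 90 % for
the 100 % fT > 4×MIC target through week 5 (92.8 % of simulated subjects stay
above the threshold for the full five weeks), an 80–120 kg patient through
week 4, and a 120–200 kg patient through week 3 — so the third dose should be
scheduled no later than those weeks.  `extend_regimen` appends that third dose
and the same call then gives the total weeks of coverage of the three-dose
regimen.

A command-line surface wraps the same functions: `dalbapk synth | fit |
simulate | pta | extend | vpc | bootstrap | covstep`, each taking a YAML
config plus `--seed`/`--out` and writing tidy CSV/JSON outputs with a
reproducibility log.

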
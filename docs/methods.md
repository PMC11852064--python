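# Methods

## Structural and statistical model

Disposition is a linear two-compartment system with first-order elimination
from the central compartment and zero-order infusion input.  With micro
constants k10 = CL/V1, k12 = Q/V1, k21 = Q/V2, the hybrid rate constants
α ≥ β are the roots of s² − (k10+k12+k21)s + k10·k21 = 0; β is computed as
k10·k21/α to avoid cancellation (β ≪ α for dalbavancin).  For one infusion at
rate R over [t₀, t₀+T], the central concentration at elapsed time τ uses the
single expression

    C(τ) = (R/V1) · [ A/α (1−e^{−αw}) e^{−αu} + B/β (1−e^{−βw}) e^{−βu} ],
    w = min(max(τ,0), T),  u = max(τ−T, 0),
    A = (α−k21)/(α−β),  B = (k21−β)/(α−β),

which covers the pre-dose, intra-infusion and post-infusion phases
continuously; doses superpose.  The closed form is the production path
everywhere, including the Monte Carlo engine; an adaptive ODE integrator
exists only in the test suite as an independent oracle (agreement better than
1e-6 relative error is asserted over random parameter/regimen draws).
Parameter sets with α ≈ β (discriminant < 1e-12) raise a degeneracy error in
the public API — they do not occur in the modelled clinical ranges — and are
penalised (not special-cased) inside the estimator's search.

Covariates: body weight scales clearances by (WT/70)^0.75 and volumes by
(WT/70)^1.0.  The 70 kg reference is the standard allometric convention and is
configurable; the simulated dosing recommendations are insensitive to moving
it to the cohort median of 72 kg.  Additional covariate effects (linear or
power, centred on the dataset median) can be attached to any parameter for
covariate testing.

Variability: independent log-normal random effects on the four structural
parameters.  Reported inter-individual variabilities are CVs; the default
conversion is ω = sqrt(ln(1+CV²)) so that the log-normal's true CV equals the
reported value, with the cruder ω = CV convention available as a switch for
sensitivity analysis (the two differ by < 2 % at the CVs involved and do not
change any dosing conclusion).  The omega matrix is diagonal.  Residual error
is proportional, DV = f·(1+ε) with ε ~ N(0, b²); simulated observations are
not truncated at zero, so synthetic datasets can contain (rare) negative
concentrations at low predictions and the estimator must tolerate them, as
real assay noise handling would require.

## Estimation

The marginal likelihood is approximated in the Laplace/FOCE-with-interaction
family.  Per subject, the joint −2 log density

    h(η) = Σ_j [ log(2π σ²_j(η)) + (y_j − f_j(η))²/σ²_j(η) ] + η'Ω⁻¹η + log det(2πΩ),

with σ² = (b·f)² + 1e-6 evaluated at the individual prediction (the
interaction; the 1e-6 mg²/L² floor is a numerical guard for near-zero
predictions), is minimised over η — the empirical Bayes estimate — and the
subject's contribution is the Laplace value

    −2 log L_i ≈ h(η̂) − 4·log 2π + log det(½ ∇²h(η̂)).

The OFV is the sum over subjects.  The 2π constants are *included*; OFV
differences, which drive every model-building decision, are independent of
this convention, and absolute OFVs are not comparable across tools.
A dense Gauss–Hermite quadrature oracle in the test suite pins the Laplace
approximation to within 2 % of exact integration on a fixture dataset (the
observed agreement is ~0.06 %).

Numerics: the inner MAP problem is solved by a damped Newton iteration whose
finite-difference gradient and Hessian come from one batched stencil
evaluation per iteration (step 1e-3 on the η scale), with a vectorised
backtracking line search and a BFGS fallback for stalls with a non-small
gradient; the Laplace value is second-order insensitive to the residual mode
error at the 1e-4 gradient tolerance used.  Inner solutions are warm-started
across outer iterations with a guarded restart from η = 0, because h can be
multimodal and a warm start may track the wrong mode.  The outer problem
optimises log-transformed typical values, log ω, log b (positivity by
construction) and raw covariate coefficients with L-BFGS-B under 2-point
finite differences; because the surface carries slight inner-optimisation
noise, the outer run is restarted from its incumbent until the OFV improves
by less than 0.1, which in practice takes two to three passes.  Degenerate or
overflowing parameter excursions return a large finite penalty.  `fit`
defaults to data-driven heuristic initial values (central volume from
dose/peak, clearance from the pooled terminal slope); `fit_multistart` fans
the start across the weakly identified Q/V2 axes (×{1, ¼–½, 2–4}) and keeps
the lowest OFV, the standard guard against the flat inter-compartmental ridge
in sparse designs.

Standard errors are reported as RSE % from the finite-difference Hessian of
the OFV in the log parameterisation (the SE of log p approximates the
relative SE of p); a sandwich estimator is out of scope.  CWRES are the
FOCE-linearised residuals: y minus the linearised marginal mean f(η̂) − G η̂,
decorrelated by the Cholesky factor of G Ω G' + diag(σ²(f(η̂))), with
G = ∂f/∂η at the mode.  Observations with |CWRES| > 3 are flagged as
outliers; `exclude_outliers` removes them, refits, and reports the ΔOFV and
parameter shifts as a sensitivity analysis.  Covariate search is forward
inclusion (ΔOFV > 3.84, χ²₁ at p < 0.05; each candidate adds exactly one
coefficient) followed by backward elimination (retained only if removal
raises the OFV by > 6.64, p < 0.01).  The bootstrap resamples subjects with
replacement to the original n, refits each replicate, reports the median and
5–95 % percentiles, and flags the summary unreliable if more than 20 % of
replicates fail.  η-shrinkage is 100·(1 − SD(η̂)/ω).

## Monte Carlo target attainment

The pharmacodynamic target is 100 % fT > 4×MIC with a free fraction of 0.07:
free concentration strictly above 4×MIC at every evaluated grid point.  At
MIC 0.25 mg/L this equals total dalbavancin > 14.29 mg/L.  Conventions, which
the engine declares rather than infers:

* evaluation grid: 1 h steps plus every infusion-end and pre-dose instant
  (for this model family the inter-dose minimum sits at a trough instant, so
  the grid captures the binding constraints exactly);
* the assessment window [0, 168·W] starts at the end of the first infusion —
  before the first dose has been delivered there is no exposure to assess;
* strict inequality at the threshold: a profile touching 4×MIC exactly does
  not attain (a measure-zero convention made testable by grid evaluation);
* PTA(W) is cumulative over the window, so it is non-increasing in W for a
  fixed regimen; the *latest optimal week* is the largest whole W with
  PTA(W) ≥ 0.90;
* PTA simulates true concentrations — residual (assay) error is excluded,
  since the target concerns exposure, not measurement;
* virtual subjects draw uniform weights within each band (40–80, 80–120,
  120–200 kg) and fresh etas; the defaults use 2000+ subjects per band.

With the reference parameters, two 1500 mg doses a week apart give latest
optimal weeks 5 / 4 / 3 for the three bands, robust to Monte Carlo error
(PTA at the critical weeks is 0.93 / 0.92 / 0.95 at large n).  Adding the
third 1500 mg dose at those band-specific weeks, the computed total coverage
is 8 / 7 / 5-6 weeks: the 80–120 kg band is stable at 7, while the other two
bands are knife-edge cases — the asymptotic PTA is 0.894 at week 9 (40–80 kg)
and 0.868 at week 6 (120–200 kg), within one to three points of the 90 %
criterion, so the reported week can move by one depending on the Monte Carlo
seed (40–80 kg) or on the within-band weight distribution (120–200 kg; a
uniform fill of 120–200 kg is heavier than any realistic clinical cohort, and
a right-skewed weight mix raises the band's PTA).  `pta_by_mic` evaluates the
same machinery across a MIC dilution series at a fixed treatment window; a
user-supplied MIC frequency table can be joined onto it for
distribution-weighted summaries (no frequency snapshot is bundled, since
breakpoint distributions are periodically revised).

## Synthetic cohorts

`generate_study` emulates the design structure of a multidose TDM cohort:
30 adults by default; weights log-normal around a 72 kg median (log-SD 0.22)
clipped by rejection to 44–179 kg; 2–10 doses of 1500 mg per subject (a
discrete distribution with median 3), 7–14 days apart; end-of-infusion peak
and pre-next-dose trough at every dose (a follow-up visit 7–14 days after the
last dose closes the final interval) with ±15 min sampling jitter; 0–2 extra
samples per subject at physician-convenience times, modelled as uniform over
the treatment span; creatinine clearance log-normal around 66.2 mL/min
clipped to 31.7–283 and generated *independently of the PK parameters*, so
covariate-selection calibration experiments have a true null; age and sex as
plain demographics, with a Cockcroft–Gault helper for deriving clearance from
serum creatinine.  The generator returns the truth record (per-subject etas
and parameters, injected-outlier row indices) alongside the event table, and
is byte-reproducible by seed.

The `rich_sampling` variant used for recovery experiments fixes 3 doses
7 days apart, adds 2 extra random samples per subject, and places the
washout visit 42–56 days after the last dose.  That washout is a design
necessity, not a tuning knob: the terminal half-life is ~17 days and the
peripheral equilibration time V2/Q ≈ 12 days, and terminal-slope estimation
requires observation over roughly three half-lives — with a follow-up of only
1–4 weeks the exact marginal likelihood itself is nearly flat along a Q–V2
ridge (equal-likelihood fits with V2 differing by tens of percent), so no
estimator could recover V2 reliably.  What passing recovery tests show is
that the estimator finds the generating values when the design identifies
them; they do not certify performance on designs that do not.

Synthetic cohorts reproduce the *structure* of real TDM data, not its
clinical correlations: no joint weight–age–renal-function dependence, no
infection-site effects, no informative sampling (sicker patients sampled
more often), and no assay quantitation limits.

## Diagnostics

`gof_table` emits DV, population prediction (η = 0), individual prediction
(at the EBEs), CWRES, time and time-after-dose per observation; plotting is
left to the caller.  The pcVPC multiplies each observed and simulated value
by (bin-median population prediction / own population prediction), using
equal-count bins on time after first dose (default 8; empty or duplicate
bins merge with a warning), and compares observed 5th/50th/95th percentiles
per bin with the 95 % envelope of the same percentiles over simulated
replicate studies (default 500; fresh etas and residual noise on the
original designs).  No censoring correction is applied since the pipeline
models none.  Self-simulated data stay inside the envelopes in ≥ 90 % of
bins, and a deliberately mis-specified (pseudo one-compartment) model breaks
coverage — both are asserted in the test suite.

## Problem sizes and defaults

Acceptance-scale runs use 2500 subjects per weight band for PTA (the
headline weeks are identical at 40000 per band, except the knife-edge cases
noted above) and a 50-subject rich-design cohort for parameter recovery;
the bootstrap default is 1000 replicates (tests exercise reduced counts).
Hours are the canonical time unit in all files and interfaces; concentrations
in files are always total plasma mg/L, and free concentrations are computed,
never stored, to prevent double application of the free fraction.

## Known limitations

* Laplace-family approximation, not exact ML: absolute OFVs differ from
  other tools' conventions; only ΔOFVs are meaningful.
* Inter-occasion variability, omega covariances, time-varying covariates and
  nonlinear elimination are out of scope.
* Q is estimated with wide uncertainty in every design considered (its
  generative CV is 55.9 %); it is not an acceptance-tested quantity.
* Simulation uses parameter point estimates; parameter uncertainty is not
  propagated into PTA.
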
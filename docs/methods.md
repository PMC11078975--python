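# Methods

## Model structure and assumptions

The maternal model is a simultaneous parent-metabolite system. Oral primaquine
doses are bolus inputs into a chain of five identical first-order compartments
(four transit compartments plus the absorption step), all with rate
k = (n+1)/MTT so that the mean transit time through the chain equals MTT;
setting the absorption rate equal to the transit rate follows the selected
structural model. The outflow of the last chain compartment splits: a fraction
F_M enters the carboxyprimaquine central compartment directly (first-pass
metabolism) and 1 − F_M enters the primaquine central compartment. Both
analytes have one-compartment disposition. All primaquine elimination is
assumed to form carboxyprimaquine mole-for-mole — the standard identifiability
assumption for an apparent-clearance metabolite model; it is consistent with
the metabolite exposures the parameter set implies and it makes total moles a
conserved quantity, which the tests exploit.

Each analyte exchanges with its own breast-milk compartment through a shared
apparent intercompartmental clearance Q, as a mass-conserving bidirectional
flux Q × (PC × C_central − C_milk). At equilibrium the milk concentration is
PC × C_plasma, so over a full dosing interval at periodic steady state the
milk:plasma AUC ratio equals PC exactly — this is why the typical-subject
ratio reproduces the partition fraction to three decimals, and why the
single-dose ratio falls slightly below it (the milk compartment lags a
decaying plasma signal). The milk-compartment volume is the volume of a single
feed, V_M = 0.15 L/kg/day × infant weight / feeds per day, carrying the
observed average intake of 150 mL/kg/day.

The maternal model as estimated (and as used for all milk:plasma and
infant-dose metrics) keeps the plasma-milk exchange open continuously. The
feeding square waves belong to the coupled mother-to-infant simulation: during
a feed the plasma→milk gate closes and the milk compartment empties into the
infant's absorption chain at MTINF = 100 h⁻¹, fast enough that >95 % of the
milk content transfers within the 24-minute window; between feeds the gates
reverse. The gates are implemented by exact modular arithmetic on the cycle
phase; a sine-threshold construction (a sinusoid at the cycle period compared
against the level cos(π·SH1/T_CYCLE), where SH1 is the off-time) is provided
as an alternative and tested for pointwise agreement away from the switching
instants. The printed square-root algebra that converts the sine pair into a
0/1 signal does not evaluate to {0, 1} as written, so the threshold form is
used.

Infant clearances and volumes are scaled from the mother's *individual*
parameters by infant body weight (exponents 0.75 and 1) and then fixed; no
infant-level random effects are drawn, so all infant variability derives from
the mother. The MAO-A-mediated primaquine clearance is additionally multiplied
by the maturation fraction MF = PMA/(PMA + TM50) of postmenstrual age
(gestation offset 9.2 months). TM50 defaults to the reported 7.6 months even
though inverting the maturation curve at 55 % newborn activity gives 7.53; the
reported value is retained and the 1 % difference is immaterial to any output.
Infant absorption uses a fixed two-transit chain with MTT 0.706 h. The
infant's first-pass metabolism is ignored; infant primaquine elimination forms
infant carboxyprimaquine, mirroring the mother.

## Parameters

The bundled parameter file (`lactokin/data/final_model_params.yaml`) carries
the final-model estimates: F 1 (fixed), MTT 1.44 h, F_M 0.282, CL/F_PQ
17.1 L/h, V/F_PQ 131 L, CL/F_CPQ 0.967 L/h, V/F_CPQ 22.7 L, CF_PQ 0.898,
CF_CPQ 1.06, Q/F 0.400 L/h, PC_PQ 0.376, PC_CPQ 0.00889. F_M is printed with
a percent label but treated as a fraction (28.2 %), the only reading
consistent with the exposure arithmetic. Variability is stored as variances;
reported %CVs are converted by ω² = ln(1 + (CV/100)²), the inverse of
CV = 100·√(exp(ω²) − 1). Residual variances are per analyte × matrix on the
log scale. The allometric reference weight is not stated with the estimates;
the study median of 51 kg is used and is configurable. Molar masses
(PQ 259.35, CPQ 274.32 g/mol) convert mg doses to the internal micromole unit
and amounts back to ng/mL.

Covariate hooks for the two effects rejected during backward elimination
(smoking −25.9 % on F; +1.29 %/year of age on V_PQ) exist but default to zero.

## Numerical method

The complete system is linear with piecewise-constant coefficients: the gates
are state-independent 0/1 switches and occasion-varying absorption parameters
change only at occasion boundaries. Trajectories are therefore advanced
exactly — segment by segment with cached matrix exponentials, doses as state
jumps — rather than by adaptive integration. Cumulative-AUC integrator rows
are appended to the system matrix, so AUC windows are exact too. An LSODA
route over the explicit right-hand side is retained and agrees with the
propagator to ~1e-10 relative; mass balance holds to ~1e-14. A binary-power
variant of the propagator (time steps as multiples of a 15-minute quantum)
accelerates the likelihood inner loops. Dose-time outputs are post-dose.

## Synthetic datasets

The generator emulates the study design: 21 mothers (weights uniform on
35–81 kg) on 0.5 mg/kg once daily × 14 days; 28 venous, 8 capillary and 10
breast-milk samples per mother on days 0/3/7/13 (milk collection windows
sampled at their midpoints); 11 infant capillary samples timed to the first
breastfeed after the maternal dose; lognormal IIV, occasion-level IOV on F and
MTT (occasions = dosing days 0, 3, 7, 13, the last κ persisting afterwards);
log-additive residual error per analyte × matrix; censoring at the assay
LLOQs (1.14/4.88 ng/mL maternal PQ/CPQ, 1.82/7.81 ng/mL infant capillary).
Infant ages are drawn uniformly on 1–22 months and weights from a bundled
approximate weight-for-age table (sex-averaged medians and ±3 SD at six ages,
log-linear interpolation, pinned to a 2–17 kg envelope). Datasets are
NONMEM-convention CSVs (ID, TIME, AMT, DV, EVID, MDV, CMT, BLQ, LLOQ, WT,
OCC, …), with BLQ values stored as missing.

What the generator does **not** emulate: assay-level drift or per-sample LLOQ
variation, dropout and missed visits (observed record counts are not matched
exactly), covariate correlations (weight-age, smoking), or departures from
the model's own structure. Passing recovery and VPC tests therefore
demonstrate internal consistency of the estimation machinery, not that the
model is correct for real data.

## Estimation

Observations are analysed on the log scale with Gaussian residuals per
analyte × matrix. `fit_population` maximises either the naive pooled
likelihood (all random effects zero) or a per-subject Laplace approximation to
the marginal likelihood: the conditional mode of each subject's random
effects is found by damped Gauss-Newton on the penalised least-squares
objective, and the Gauss-Newton information J'J + Ω⁻¹ stands in for the
Hessian in the Laplace determinant — the classical first-order-conditional
approximation. Variance components are held at their input values; the fixed
effects estimated by default are CL_PQ, V_PQ, CL_CPQ, V_CPQ and F_M, on log
(logit for fractions) scales, with Nelder-Mead outside. With all ω² = 0 the
marginal and pooled objectives coincide and the code routes to the pooled
path. BLQ records are discarded by default (only a handful of maternal plasma
records are censored under the study design); an M3-style cumulative-density
contribution is available via `blq_policy="m3"`.

The recovery experiment (analysis script 05, and the corresponding acceptance
test at n = 50) generates data from the estimation model itself — IIV plus
residual error, IOV variances zeroed — because the fit model does not carry
IOV; refitting data that deliberately contain unmodelled occasion-level
absorption variability measures robustness to misspecification rather than
recovery (F_M then absorbs early-phase misfit and biases low). Under the
self-consistent design all five structural fixed effects are recovered within
a few percent.

The prediction-corrected VPC scales each observation and simulated replicate
by (bin-median population prediction / record-level population prediction),
with bins at the nominal sampling times per analyte × matrix, and compares
observed 5th/50th/95th percentiles with their 95 % bands across simulated
trials (default n = 1000). Model-comparison helpers implement the χ² test on
OFV differences (drops of 3.84/6.63/10.83 at one degree of freedom for
p < 0.05/0.01/0.001).

## Dosing scenarios and metrics

Regimen presets: `standard` (0.5 mg base/kg OD × 14), `high-od` (1.0 OD × 7),
`high-bid` (0.5 BID × 7), `sld` (0.25 single dose), `weekly8` (0.75 weekly
× 8). Scenario mothers draw weights uniformly on 35–81 kg (the source range
without a stated distribution); the single-low-dose exposure threshold run
fixes 60 kg. The dose-metric AUC window is the last full 24-hour dosing day:
for once-daily or sparser regimens this is exactly 0–24 h after the last
dose, while for twice-daily dosing it spans the last two doses — the only
reading under which the twice-daily total infant daily dose equals the
once-daily high-dose value, as reported. C_ss,average is the venous AUC over
that window divided by 24 h; for the single dose the 0–24 h window plays the
role of the steady-state interval. Acceptance runs use 2000 virtual mothers
per scenario (Monte-Carlo error on the medians well under the 10 % comparison
band); the published simulations used 1000 replicates of 50 infants, and the
engine exposes `n_infants_per_mother` for coupled infant sampling at that
scale.

Sampled F_M values are clipped at 0.999 (a lognormal 42 %CV around 0.282
exceeds 1 with probability ~9e-4); clipping affects no reported median.

## Known limitations

- Estimation approximates FOCE-I by subject-level Laplace with a Gauss-Newton
  Hessian; OFV values are not comparable to other tools' at digit level.
- IOV is simulated but not estimable; variance components are not estimated.
- The weight-for-age table is an approximation adequate for weight sampling,
  not a replacement for the reference growth standards.
- Milk partitioning is constant over time (mature milk); composition or pH
  changes during early lactation, protein-binding differences in neonates,
  and any haemolysis pharmacodynamics are out of scope.
- The infant side is a prediction model by construction — infant
  concentrations below the assay LLOQ preclude estimating infant parameters,
  so infant predictions inherit the scaling and maturation assumptions.
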
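# Methods

This document records the modelling and numerical choices behind the
package, including the places where a published summary value admits more
than one reading and which reading the package adopts.

## Structural model

One-compartment disposition with zero-order infusion input. Every regimen
is expressed as a list of infusion segments `(start, end, rate)`; the
concentration is the exact closed-form superposition

```
C(t) = Σ_segments (R / CL) · [1 − e^{−k·(t − t0)}]  (during the segment)
       carried forward by e^{−k·Δt} afterwards,     k = CL / V1.
```

Steady state under q8h dosing is obtained analytically: over one interval
the concentration map is affine, `c ↦ A·c + B` with `A = e^{−k·τ}`, so the
pre-dose steady-state concentration is `B / (1 − A)`. No ODE solver is used
outside the test suite, where `scipy.integrate.solve_ivp` serves as an
oracle (relative agreement < 1e-6).

Covariate model:

```
CL = θ_CL · (BW / 12)^0.75 · (1 + (eCRCL − 150) · θ_slope)   [+ SC·Q_eff on CRRT]
V1 = θ_V1 · (BW / 12)
```

with θ_CL = 7.6 L/h, θ_V1 = 21.4 L, θ_slope = 0.0035 per ml/min/1.73 m²,
sieving coefficient SC = 0.257 and effluent flow Q_eff = 45 ml/kg/h.
The linear renal effect is floored at a small positive value so extreme
covariates cannot produce a non-positive clearance (a warning is emitted).
CRRT patients additionally get a 25-ml effluent measurement compartment fed
at rate `SC·Q_eff·C_plasma`; its closed-form solution allows effluent
concentrations to enter the likelihood with their own residual error.

## Interpretation of the published variability terms

The published inter-individual variabilities of CL and V1 are printed as
55.7% and 56.2%. Two readings are possible: the printed number is the
log-normal SD ω (so ω = 0.557), or it is the η-variance ω² expressed as a
percentage (so ω = √0.557 ≈ 0.746). The two readings were discriminated by
re-simulating the full published PTA tables under each: the direct-SD
reading over-predicts every printed PTA cell by +6 to +15 percentage points
(mean |error| 9.8 pp), while the variance reading reproduces the tables
with mean |error| 5.4 pp and no uniform bias. The package therefore adopts
the variance reading, `omega_cl = √0.557`, `omega_v1 = √0.562`, as its
default. The residual discrepancies that remain under either reading are
concentrated in the strictest cells (100% fT>MIC for the fastest-clearing,
smallest patients) and are documented as known reproduction gaps.

## Marginal likelihood

The population likelihood integrates the per-subject data density over two
log-normal random effects (η_CL, η_V1). The package uses a Laplace
approximation at the per-subject conditional modes; with the log-scale
additive residual model the η–ε interaction is carried automatically, so
the `foce_i` label maps to the same expansion.

Numerics, chosen for determinism and robustness:

- Inner gradients of the conditional objective are computed by the
  complex-step method (step 1e-30), which is exact to machine precision;
  the inner Hessian is Gauss–Newton.
- The conditional density can be multimodal (notably for subjects with
  censored records), so the mode search starts from a deterministic coarse
  grid over η-space and then runs a damped, vectorised Newton iteration on
  the still-active subjects only. Convergence near the mode can be linear
  rather than quadratic because the Gauss–Newton matrix only approximates
  the true curvature; the iteration budget is sized accordingly and a
  vanishing Newton step with a finite objective also counts as converged.
- No warm starting across outer iterations: a history-dependent mode
  search would make the outer objective non-deterministic.
- The outer optimizer is Nelder–Mead on log-transformed parameters, with
  deterministic restart rounds from the incumbent until an improvement
  round gains less than 0.05 OFV. This cures premature simplex collapse at
  a fraction of the cost of independent random multi-starts.

Correctness is arbitrated by an adaptive Gauss–Hermite quadrature oracle
(and, where feasible, brute-force 2-D integration). Note that agreement
with the exact integral is a property of the *regime*, not only of the
implementation: with sparse late-only sampling designs or η-SDs around
0.75, the conditional density is intrinsically skewed and every Laplace
variant (Gauss–Newton or true-Hessian) deviates from the exact integral by
O(1) OFV units. The oracle tests therefore use informative designs and
moderate variability, where the intrinsic approximation error is well
below the test tolerance and residual disagreement indicates a bug.

## BLQ handling

Observations below the 0.2 µg/ml quantification limit can be handled by
three conventions: **M1** drops them; **M3** replaces their likelihood
contribution with the censored-normal mass below log(LLOQ) (verified
against numeric integration to 1e-8); **M6** imputes the first BLQ record
of each subject at LLOQ/2 and drops the rest.

Known consequence of M6, measured on replicate synthetic trials at the
packaged parameters (25 subjects, sparse design): dropping the later BLQ
records removes exactly the evidence that concentrations fell low, which
flattens the apparent terminal slope and biases V1 = CL/k upward by
roughly +20–30% at this design, persisting with larger cohorts. Refitting
the same data with M3 recovers V1 to within ~1%. CL shows a smaller
(+10–15%) finite-sample bias that vanishes as the cohort grows. Users
estimating volumes from heavily censored data should prefer M3.

## Covariate screening

Forward step: a candidate effect enters if it reduces the OFV by at least
3.84 (χ², 1 df, p < 0.05). Backward step: each included effect is removed
in turn and retained only if its removal raises the OFV by at least 10.83
(χ², 1 df, p < 0.001). Thresholds are taken from `scipy.stats.chi2.ppf`
rather than hard-coded. The base model is re-polished before screening so
all ΔOFV values are measured from a converged reference.

## Diagnostics

- **GOF**: population and individual predictions, IWRES on the log scale,
  and CWRES from the FOCE linearisation; censored records are excluded.
- **VPC**: observed 5/50/95th percentiles per nominal time-since-dose bin
  against 95% bands from replicate simulations on the original design.
  BLQ-censored observations are excluded from the observed percentiles and
  simulated values below the LLOQ are excluded from the simulated bands in
  the same way — censoring must be applied symmetrically or the lower
  percentile bands sit far below anything observable. The censored
  fraction itself is checked by the categorical-BLQ VPC.
- **SIR**: importance weights `exp(−½ΔOFV)/q` under a multivariate normal
  proposal, resampling without replacement; validated against the analytic
  posterior of a conjugate linear-Gaussian toy.

## PTA simulation

PTA simulations draw log-normal η per subject, evaluate the steady-state
profile in closed form, and compute the fraction of the dosing interval
above the MIC from the analytic crossing times of each exponential piece
(no time grid). Scenario tables reuse common random numbers across
regimens, making dose–response monotonicity exact rather than statistical.
Renal-function scenarios below 90 ml/min/1.73 m² include CRRT clearance,
matching the simulation convention that impaired-renal-function patients
are the ones receiving CRRT. Unbound fraction defaults to 1 (meropenem
protein binding is ~2%).
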
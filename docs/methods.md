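# Methods

`mixpower` computes the statistical power of *mixed* population-pharmacokinetic
study designs — part densely, part sparsely sampled — to detect a binary
covariate effect, using Monte Carlo mapped power (MCMP): per-subject
likelihood-ratio contributions are computed once on large simulated
pseudo-populations and then resampled to score arbitrary design combinations
without refitting. Shortlisted designs are validated by expected parameter
precision (simulation/re-estimation) and by study cost.

## Models

Two single-oral-dose structural models, both with one-compartment disposition
and first-order elimination:

* **first-order absorption** — `C(t) = F·D·ka / (V·(ka−ke)) · (e^(−ke·t) − e^(−ka·t))`,
  `ke = CL/V`; evaluated through an `expm1` form stable as `ka → ke`, with the
  exact repeated-eigenvalue limit `F·D·ke·t·e^(−ke·t)/V` when
  `|ka − ke| < 1e−8·ke`;
* **transit-compartment absorption** — the dose traverses `n` transit
  compartments with rate `ktr = (n+1)/MTT`, an Erlang(n+1, ktr) input; the
  convolution with first-order elimination has the closed form
  `C(t) = F·D/V · (ktr/(ktr−ke))^(n+1) · e^(−ke·t) · P(n+1, (ktr−ke)·t)`
  with `P` the regularized lower incomplete gamma function. When
  `ktr − ke ≤ 1e−6·ktr` the convolution integral is evaluated instead by
  64-point Gauss–Legendre quadrature, which is exact to ~1e−10 for these
  smooth integrands.

Both forms agree with adaptive ODE integration to better than 1e−6 relative
error over wide parameter ranges (property-tested), and satisfy the mass
balance `CL·AUC = F·D`.

Random effects are lognormal: `p_i,occ = θ_p · exp(η_p + κ_p,occ) · (1 + β·X)`
with inter-individual η ~ N(0, ω²_IIV), inter-occasion κ redrawn per occasion,
and binary covariates acting as proportional shifts. Residual error is either
proportional (`y = c·(1 + σ_p·ε)`) or additive on the log scale
(`ln y = ln c + σ_log·ε`). The bundled dihydroartemisinin configuration reads
the published residual magnitude 0.58 as a *variance* on the log scale
(consistent with the variance convention of the random-effect table); a
`value_is_sd` flag selects the sd reading instead.

## Worked-example conditions

The bundled configurations are the study conditions, not tuning knobs:

* **hypothetical drug** — ka 0.8 h⁻¹ (IIV 0.1), CL 20 L/h (IIV 0.08,
  IOV 0.02), V 70 L (IIV 0.1), 30% covariate on CL, 10% proportional
  residual; 16-point dense schedule (0–24 h); sparse schedule of two samples,
  one drawn uniformly from each of two candidate-time windows
  ({0,…,4} and {5,…,24} h). Parallel pseudo-population: 1,000 subjects,
  500 per covariate stratum; cross-over: 500 subjects, covariate on
  occasion 1 only.
* **dihydroartemisinin** — 7 transit compartments, MTT 0.982 h (IOV 0.23),
  CL 78 L/h (20% pregnancy effect), V 129 L (IIV 0.0162), F fixed at 1 with
  IIV 0.0881, log-additive residual variance 0.58; 10-point dense schedule
  (0–12 h); 4-sample sparse windows that differ between pregnant and
  non-pregnant patients. The literature model's additional parasitemia-on-F
  covariate has no published magnitude and is omitted (see Limitations).

Dose amount is not part of either published model; the default is 100 units.
With multiplicative covariates and proportional (or log-additive) residual
error, the likelihood-ratio statistic is invariant to the dose scale
(verified by a unit test), so this choice only relabels volume-related
quantities.

**Paired strata.** For parallel pseudo-populations the two covariate strata
share common random numbers: subject *i* of each stratum receives identical
random effects, sampling-window draws and residual noise, differing only in
the covariate. Each stratum's marginal distribution is exactly the model's,
but the Monte-Carlo error of the realized between-stratum contrast — which
otherwise dominates the variability of the minimum-N estimate (several
patients across seeds) — is strongly reduced. Validation replicates
(`sse_rse`) deliberately use independent strata, since between-stratum noise
is the quantity being measured there.

## Estimation

Full (with covariate) and reduced (without) nonlinear mixed-effects models
are fitted by maximizing an approximate marginal likelihood. The inner
problem finds each subject's conditional mode η̂ of the joint density; the
outer objective is, by default, the **FOCE-I construction**: the model is
linearized in the random effects around η̂ with the residual variance
evaluated at the conditional prediction, giving a Gaussian marginal with
covariance `J·Ω·Jᵀ + R` whose −2·log density is summed over subjects. A
Laplace objective (joint density at the mode plus Gauss–Newton curvature
correction) is available via `ModelSpec(approximation="laplace")`; on these
examples the two give nearly identical ΔOFV pools. FOCE-I is the default
because it is the estimator the mapped-power literature and the worked
examples are built on.

Parallel (single-occasion) designs are re-estimated *without* IOV — the data
cannot identify it — so simulated IOV is absorbed into the corresponding IIV
(hypothetical drug) or into the residual and remaining IIV terms
(dihydroartemisinin, whose MTT carries IOV but no IIV). Estimation starts at
the generating values inflated by 20%; starting at the truth would understate
real-world difficulty.

Numerical scheme: variances and fixed effects are optimized on the log scale;
the inner mode search is a damped, active-set Gauss–Newton iteration
vectorized across subjects, with a saddle-free true-Hessian polish and a
per-subject Nelder–Mead fallback for subjects where Gauss–Newton's curvature
model is poor (large residuals), and a multi-start sweep — re-run whenever
the outer parameters move materially and always for the final reported
iOFVs — to avoid spurious basins of the nonconvex per-subject objective.
The outer optimization is restarted L-BFGS-B with central-difference
gradients, followed by cyclic coordinate descent (bounded Brent line
minimizations) that recovers the convergence tail which finite-difference
gradients cannot resolve against the inner-solver noise floor; with this
scheme, fits started from three different points agree to within about one
OFV unit. When ΔOFV pools are built, the full and reduced evaluations
additionally exchange conditional modes (each model re-evaluated from the
counterpart's modes, keeping the per-subject better likelihood), which
removes spurious basin mismatches from the pool tails. Observations at the
dose time (structural prediction exactly zero) carry no likelihood
information under either residual model and are excluded from fitting
while remaining in datasets and sample counts.

## Mapped power

Per-subject ΔOFV_i = iOFV(reduced) − iOFV(full), both at their own MLEs,
form one pool per arm (dense A, sparse B). A candidate design with
`n_dense`/`n_sparse` patients is scored by drawing that many ΔOFV_i values
with replacement (10,000 draws per design), summing, and comparing against
the χ²₁ threshold 3.84 (p < 0.05, one covariate parameter); power is the
exceedance percentage and 80% is the design criterion. Parallel draws are
stratified 50/50 by covariate status, mirroring the balanced
pseudo-population (odd patient counts are skipped rather than rounded);
cross-over pools bundle a subject's two occasions as one resampling unit.
Without-replacement draws and unstratified draws are available as options;
on the worked examples they move the minimum N by at most one grid step.
Minimum-N searches march along a path (dense-only, sparse-only, or a fixed
dense:sparse ratio) with an independent seeded stream per design cell.

## Validation of shortlisted designs

* **Precision** — `RSE(%) = 100 × SD(replicate estimates) / mean(replicate
  estimates)` over simulated and re-fitted replicates of the candidate
  design (the replicate SD, not an asymptotic SE; non-converged replicates
  are dropped and the converged fraction reported, with a hard failure
  above 50% loss). The bundled configurations default to 100 replicates;
  the test suite exercises the dense-vs-sparse precision ordering at 40
  replicates, a problem size chosen so the full suite stays desk-sized
  while the ordering contrast (sharpest for the absorption-phase
  parameters) remains well resolved.
* **Cost** — `budget = hospitalisation × patient-days + assay × samples`,
  one hospital day per occasion (every printed schedule fits in 24 h), so
  cross-over patients accrue two patient-days; unit costs are 1,000 /
  750 / 50 per dense day / sparse day / sample. The cost model reproduces
  the published tables exactly except one cell that is printed rounded
  (124,000 vs the arithmetic 123,900).

## What passing tests do and do not show

The generator emulates exactly the idealized conditions above: perfect
adherence, no dropout, no below-quantification censoring, covariates known
without error, and a correctly specified structural model. Power estimates
are therefore upper bounds relative to messier field data. Two statistical
caveats deserve emphasis. First, the minimum-N estimate inherits the
sampling noise of the pseudo-population itself: at the prescribed 1,000
(parallel) or 500 (cross-over) subjects, repeat runs with different
pseudo-population seeds move the minimum N by roughly ±4–6 patients
(±10 for the dihydroartemisinin example, whose unmodelled transit-time
variability widens the pool). Second, resampling per-subject contributions
from a single pseudo-population maps the *noncentrality* of an effect, not
the null sampling distribution of the likelihood-ratio statistic: with no
covariate effect simulated, full and reduced fits nearly coincide and the
mapped exceedance probability collapses toward zero rather than the nominal
5% (the suite records this behaviour). Calibrating the type-I error proper
requires refitting replicate null datasets, which is exactly the expensive
route the mapped-power shortcut avoids; the threshold's known inflation for
very sparse designs likewise lies outside what single-pool resampling can
show.

## Known limitations

* The sparse-design reading is one sample per printed window. Because each
  sparse subject then always carries one elimination-phase sample, the
  per-occasion clearance estimate is precise, and sparse arms lose less
  covariate information than the published minimum-N values imply; the
  package's sparse-only minimum N is correspondingly smaller (most visibly
  for the cross-over example). Drawing all samples from the pooled candidate
  set would weaken sparse arms, but that reading contradicts the printed
  window structure and is not implemented as a default.
* The dihydroartemisinin pseudo-population omits the unpublished
  parasitemia-on-F covariate; the real model's extra between-subject
  variability would reduce per-subject covariate information and raise the
  required N (the package finds roughly 66–78 dense-only patients across
  pseudo-population seeds where the published analysis reports 88).
* Inner/outer optimizer tolerances bound the reproducibility of individual
  OFVs at ~1e−5 and of fixed-effect recovery at ~0.5%; ΔOFV pools are
  evaluated with a fresh multi-start mode search to keep per-subject
  contributions path-independent.
* Only diagonal Ω, single oral doses, and one binary covariate per test are
  supported; SAEM-type estimators and Fisher-information design scoring are
  out of scope.
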
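# Methods

This note records the models implemented by `levnet`, the assumptions and
defaults behind them, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Pharmacokinetic model

Structure: one-compartment disposition with first-order oral absorption,

    C(t) = D·ka / (V·(ka − ke)) · (e^(−ke·t) − e^(−ka·t)),   ke = CL/V.

When ka and ke coincide to relative 1e−9 the analytic equal-rate limit
C(t) = (D·ka·t/V)·e^(−ka·t) is used, so the curve is continuous through
the degenerate case.  Apparent clearance CL/F (L/h) and volume V/F (L) are
allometrically scaled to body weight with fixed exponents 0.75 and 1.0
around a reference weight of 25 g.  The dose covariate defaults to a
power form on dose normalized to 30 mg/kg (the midpoint of the PK doses);
a proportional form is configurable.  Concentrations are in ng/mL, doses
in mg, exposure (AUC₀–∞ = D / CL/F) in mg·h/L ≡ µg·h/mL.  Chronic
twice-daily exposure is reported as the steady-state daily AUC
(2·D)/CL under linearity, separately from single-dose AUC.

Default generating parameters (ka = 2 /h, CL/F = 0.0035 L/h,
V/F = 0.015 L at 25 g) are configuration values chosen for plausible
mouse levetiracetam kinetics — terminal half-life about 3 h, Cmax in the
tens of µg/mL at 30 mg/kg.  They are stated in config, never treated as
empirical truth.

### Estimation

Population estimation is deliberately a desk-scale stand-in for a full
nonlinear mixed-effects engine, with two methods:

* **two_stage (default)** — each animal's profile is fit by nonlinear
  least squares on log concentrations (3 parameters from ≥4 positive
  observations), then the allometry-corrected individual log parameters
  are regressed on the dose covariate.  Because individual estimates are
  independent across animals, the covariate likelihood-ratio test
  (retention at a drop ≥ 3.84 in n·log(RSS/n), χ²(1) at p < 0.05) holds
  its nominal level in the presence of between-animal variability, and
  the stage-two residual SDs double as estimates of the lognormal BSV.
* **pooled** — a single weighted least squares over all log
  concentrations.  Exact on variability-free data, but residuals of one
  animal share its random effect, which makes pooled covariate tests
  anticonservative; it is kept for the noise-free identifiability case
  and as a cross-check.

Noncompartmental analysis uses the linear-up/log-down trapezoid for
AUC(0–last); the terminal slope λz is a log-linear regression over the
last k observations, k ∈ 3..6, excluding the Cmax point and non-positive
values, keeping the candidate with the best adjusted R² (a common NCA
convention; the choice is isolated in `run_nca`).  AUC(0–∞) adds
C_last/λz; an increasing or too-short terminal phase is flagged
non-estimable rather than extrapolated.

## SUVr processing

Pipeline order is fixed: unilateral → bilateral averaging (arithmetic mean
of left/right) first, then per-animal division by the cerebellum value.
The two operations commute only when the left and right cerebellum values
are equal, which is asserted as a documented non-property with a
counterexample test.  The packaged pairing table maps 56 unilateral labels
to 28 bilateral regions (27 analysis regions + cerebellum) and can be
overridden by a user file.

Consensus region selection is the committed interpretation of an
under-specified rule ("regions explaining 80% of the variance"): per
cohort, PCA on the column-standardized animal × region SUVr matrix
(standardized so high-mean regions do not dominate; covariance-matrix PCA
is the natural alternative and can be swapped inside one function);
regions are ranked by Σⱼ λⱼ·Vᵢⱼ² over the leading components reaching 80%
cumulative explained variance, and the minimal top-ranked set holding 80%
of the total contribution is selected.  "Consistently across cohorts" is
a strict intersection by default, with a frequency-threshold union in
config.  Zero-variance regions are excluded from the ranking with a
warning; cohorts under 3 animals are skipped.

## Covariance networks

Edges are Pearson correlations of regional SUVr across the animals of one
group (≥4 animals; correlation is invariant to z-scoring of the inputs,
which is asserted rather than performed).  Two-sided p-values use the
t transform with n−2 df.  Thresholding keeps the signed correlation where
p < α (default 0.05, the least restrictive level that leaves analyzable
graphs); for a fixed group size this is identical to keeping |r| above the
inverse-t critical value, an equivalence the tests check.  No
edge-level multiplicity correction is applied — the threshold is on raw p
by design.  Zero-variance regions degrade to isolated nodes (r = 0,
p = 1) instead of aborting the group.

Nodal metrics on the thresholded graph: degree (count of surviving
edges), positive strength (sum of positive weights), negative strength
(summed magnitude of negative weights — reported as a positive quantity),
and the clustering coefficient.  The default clustering is the binary,
sign-blind Watts–Strogatz coefficient (triangles / (k·(k−1)/2)) on the
surviving-edge graph; Onnela weighted and Zhang–Horvath-style signed
variants are available behind a flag since the metric name alone does not
pin down a variant.

Distribution comparisons use the two-sample Kolmogorov–Smirnov test.  The
p-value is computed by full enumeration over label assignments when
C(n+m, n) ≤ 20,000 (exact under ties), by scipy's exact method when both
samples have ≤30 points (the standard use case is 27 regions per
distribution), and asymptotically otherwise.

## Multi-resolution consensus clustering

Community detection runs on the positive-weight subgraph only; negative
edges are retained for nodal metrics but excluded from modularity.  The
ensemble is Louvain modularity at 200 resolutions γ evenly spanning
[0.5, 3.0] by default — an even grid rather than random draws, since it
gives deterministic uniform coverage of the resolution interval and the
ensemble is averaged anyway.  The co-classification matrix (fraction of
ensemble partitions placing two regions together) is thresholded at the
95th percentile of a permutation null with 10,000 replicates, then
re-clustered (γ = 1, 32 restarts) until all restarts agree, iterating the
threshold–recluster step to unanimity.

The permutation null is computed analytically-equivalently: under a
random relabeling of a partition with community sizes {n_k}, every node
pair is co-assigned with the same probability Σ n_k(n_k−1)/(N(N−1)), so a
null replicate of the ensemble co-classification is a mean of independent
Bernoulli draws at the per-partition probabilities.  This is the same
null distribution as materializing label permutations at a fraction of
the cost.  The "10,000 permutations" figure parameterizes this consensus
null (not the ensemble size); the reading is isolated in config.

All randomness flows from a required seed through named SeedSequence
spawns; tie-breaking inside Louvain follows the seeded visit order, and
the consensus is empirically stable across seeds for structured networks
(tested).  A network with no positive edges collapses to a single
community with a warning; non-convergence raises with diagnostics rather
than silently falling back.

Partition imposition computes, per animal and community of a reference
partition (WT male by default — the healthier baseline against which
deviations are tracked), the arithmetic mean SUVr over member regions;
group comparisons are one-way ANOVA per community (two groups ⇒
F = t² of the pooled t test, an identity the tests verify) with
Bonferroni correction by the community count.

## Expression models

The exposure–response model is per-gene least squares of log2 intensity
on AUC (continuous) + sex, fit as one vectorized solve since all genes
share the design.  Sex is an indicator with male = 0 (reference); the
coding is configurable because the sign of the sex coefficient flips with
it.  The design-factor screen regresses each gene on categorical
genotype + sex + treatment with partial (type-II-style) F-tests per
factor, flagging genes with any factor p < 0.05 on raw p-values — no
multiplicity correction, by design — while an optional Benjamini–Hochberg
column is emitted for users.  Delta-from-vehicle tables subtract the same
sex's vehicle mean (or the WT vehicle baseline, selectable).  The same
AUC + sex regression applied to network summary metrics reports its fit
either way: a null result is a reported result, not an asserted one.
Gene-level models are fit on treated-cohort animals (the exposure
covariate is undefined for untreated animals beyond AUC = 0).

A generic utility correlates per-group deltas against a user-supplied
per-gene module signature vector; module definition and enrichment are
out of scope.

## Synthetic data: what it emulates, and what it does not

The cohort generator draws animal × region SUVr from a multivariate
normal whose correlation matrix is block-constant: `within_block_r`
inside each planted community, `between_block_r` elsewhere — validated
positive semi-definite before sampling, with the offending eigenvalue
named on rejection.  This parameterization is deliberately restrictive:
planted values are interpretable and PSD is checkable, at the cost of
ruling out arbitrary correlation structure.  Total covariance is
`scale_sd²·C + noise_sd²·I`: `scale_sd` (default 0.1 SUVr) sizes the
correlated variation, `noise_sd` (default 0) adds independent measurement
noise that dilutes the observed correlations.  Sex and treatment enter
the means only (default shifts: +0.002 SUVr per mg/kg of dose and +0.03
for females, config values on the scale of reported group differences);
per-group correlation overrides can emulate dose-dependent connectivity
but are off by default.  Group variances are config values — no
per-group variances are available to anchor them empirically.

The PK generator follows the study design (3 animals per dose per sex at
10/30/100 mg/kg, sampling 0.25–24 h), with lognormal between-animal
variability on CL and V (default SD 0.2), proportional residual error
(default 0.15, no additive floor — the simplest model consistent with the
assayed concentration range), and weights drawn N(25 g, 2 g).  Negative
simulated concentrations are truncated at zero and counted.  The
expression generator is the linear model the downstream fit assumes, with
default effect sizes at the scale of the published exposure-response
table (β_AUC ≈ 7.5e−4 per µg·h/mL, β_sex ≈ −0.069 log2 units).

Because the generators share their functional form with the models that
analyze them, passing recovery tests demonstrates correctness of the
estimation machinery, not robustness to model misspecification: real PET
data have registration error, partial-volume effects and non-Gaussian
tails; real PK data have absorption delays and assay floors; count-level
nanoString noise is not Gaussian in log2.  None of these are simulated.

## Numerical and reproducibility choices

* All generators and the pipeline are pure functions of (spec, seed);
  per-stage seeds are derived from the config seed by name, so stage
  outputs do not depend on execution order, and a fixed config is
  byte-identical across runs (tested at the byte level).
* Tables are comma-delimited text with headers, floats at full
  round-trip precision; resumed stages re-read them with round-trip float
  parsing so a regenerated intermediate is bit-identical.
* Problem sizes in the test-suite simulations (e.g. 50 PK replicates,
  20 MRCC seeds at 200 animals, 500-gene null panels) were chosen as the
  smallest sizes at which the Monte-Carlo checks are stable.

## Known limitations

* The population fit estimates no full random-effects covariance and no
  sex covariate by default (dose only, mirroring the implemented
  selection logic); commercial NLME numerics are explicitly not
  reproduced.
* The consensus-region rule is one committed interpretation of an
  under-specified selection criterion; alternatives (covariance-PCA,
  rotated loadings, union-with-frequency) sit behind the same function
  boundary.
* KS comparisons of nodal metrics treat the 27 regional values of a group
  as a sample; regional values are correlated, so the nominal p-values
  are descriptive rather than strictly valid — a property inherited from
  the analysis design itself.
* MRCC's resolution range [0.5, 3.0] and ensemble size 200 are defaults,
  not derived quantities; very unstable networks can legitimately fail to
  reach consensus and raise.
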
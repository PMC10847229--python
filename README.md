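# levnet

Dose- and sex-resolved analysis of metabolic covariance networks and
levetiracetam pharmacokinetics in the 5XFAD mouse model of Alzheimer's
disease.

Chronic levetiracetam (LEV) modulates aberrant neuronal activity in
amyloid models, and its effect on brain-wide glucose metabolism is dose-
and sex-dependent. `levnet` implements the full analysis chain such a
study needs, as a tested, reusable library plus CLI:

* **Population pharmacokinetics** — one-compartment first-order-absorption
  model, C(t) = D·ka / (V·(ka−ke)) · (e^(−ke·t) − e^(−ka·t)) with
  ke = CL/V, CL/F and V/F allometrically scaled to body weight with fixed
  exponents 0.75 and 1.0 and an optional dose covariate.  Estimation is
  two-stage (per-animal nonlinear least squares, then covariate regression
  on individual parameters) with covariate retention at a 3.84 drop in the
  objective function (χ², p < 0.05); noncompartmental analysis (Cmax,
  Tmax, λz, linear-up/log-down AUC) is included.  Per-animal exposure is
  AUC₀–∞ = dose / CL/F.
* **SUVr processing** — 56 unilateral atlas regions averaged to 28
  bilateral regions, normalized per animal to cerebellum (SUVr), and a
  PCA-based selection of the consensus regions explaining 80% of the
  variance across cohorts.
* **Metabolic covariance networks** — per-group Pearson correlation of
  regional SUVr across animals, edges thresholded at p < 0.05 (t transform,
  n−2 df), signed nodal metrics (degree, positive/negative strength,
  clustering coefficient), and two-sample Kolmogorov–Smirnov comparison of
  nodal-metric distributions between groups (exact p for small samples).
* **Community structure** — multi-resolution consensus clustering (MRCC):
  Louvain modularity partitions of the positive subgraph across a grid of
  resolutions γ, co-classification matrix thresholded against a
  10,000-replicate permutation null, re-clustered to unanimity.  A
  reference partition (WT male by default) can be imposed on comparison
  groups, with community-mean SUVr compared by ANOVA with Bonferroni
  correction.
* **Exposure–response models** — per-gene lm(log2 intensity ~ AUC + sex)
  (the PK/PD model), design-factor OLS with partial F-tests,
  delta-from-vehicle summaries, and the same multi-linear regression
  applied to network summary metrics.
* **Synthetic cohorts** — generators with planted block-covariance
  structure, lognormal between-animal PK variability and per-gene linear
  effects, so the whole pipeline runs and is testable without any data
  download.

## Worked example

```python
import numpy as np
from levnet import synthetic as syn, pk, suvr, network as net, community as comm

# --- population PK on a simulated study (3 animals/dose/sex, 10/30/100 mg/kg)
sim = syn.generate_pk_profiles(syn.PKSimSpec(seed=7))
results = pk.PopulationPKModel(sim.observations).fit()
print(results.summary())
```

```
Population PK fit (method: two_stage)
n_obs = 126, OFV = -118.309 (base -118.309), residual SD(log) = 0.2823
typical ka = 2.016 1/h, CL/F = 0.003269 L/h, V/F = 0.01526 L (at 25 g)
covariate decisions: {'dose_on_cl': False, 'dose_on_v': False}
              estimate       se
log_ka         0.70125   0.0391
log_cl_f_typ   -5.7233 0.049711
log_v_f_typ    -4.1825 0.044244
```

The typical clearance (0.0033 L/h at 25 g) and volume (0.015 L) recover
the generating values within ~7%, and the dose covariate is correctly not
retained (none was simulated).  Exposure follows directly:

```python
est = pk.predict_individual_auc(results.params, "M01", dose_mg=0.025 * 56,
                                weight_kg=0.025, dose_mg_per_kg=56.0)
print(f"predicted daily exposure at 56 mg/kg BID: {est.auc_daily_bid:.0f} ug*h/mL")
# predicted daily exposure at 56 mg/kg BID: 857 ug*h/mL

# --- covariance network + communities on a synthetic cohort
spec = syn.CohortSpec(n_per_group=12, sexes=("male",),
                      treatments=("vehicle",), seed=3)
table = suvr.compute_suvr(syn.generate_suvr_cohort(spec))
tnet = net.threshold_network(net.covariance_matrix(table), alpha=0.05)
print(f"network density: {tnet.density:.3f}")          # 0.259
res = comm.mrcc(tnet, seed=4)
print(f"consensus communities: K={res.partition.k}")   # K=3
```

The cohort was generated with three planted covariance blocks; MRCC
recovers exactly those three communities from 12 animals.  Per-region
metrics come from `net.nodal_metrics(tnet)`:

```
        degree  s_pos  s_neg  clustering
region
AI       5.000  4.006  0.000       0.900
AuDMV    4.000  2.879  0.000       0.667
CC       6.000  4.670  0.000       0.667
Cg       6.000  4.707  0.000       0.733
```

The full chain (cohort → PK exposure → SUVr → networks → communities →
expression models) runs end to end with:

```sh
levnet run --seed 7 --out results/
```

which writes every intermediate table as CSV plus a `manifest.json`
recording parameters and per-stage seeds; a fixed config and seed is
byte-identical across runs.

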
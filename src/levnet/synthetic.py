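"""Synthetic cohorts with planted structure for every pipeline stage.

Three generators, all pure functions of (spec, seed):

* :func:`generate_suvr_cohort` — animal x region SUVr tables whose
  region-region correlation has a planted block (community) structure,
  with per-(sex, treatment) mean shifts.  This emulates regional FDG-PET
  uptake tables for cohorts of ~8-12 animals per arm over 27 bilateral
  regions plus the cerebellum reference.
* :func:`generate_pk_profiles` — plasma concentration-time profiles from
  the one-compartment first-order-absorption model with lognormal
  between-animal variability on CL/F and V/F, allometric weight scaling,
  a dose covariate, and proportional residual error (doses 10/30/100
  mg/kg, sampling 0.25-24 h).
* :func:`generate_expression` — gene x animal log2 intensities with
  per-gene linear exposure (AUC) and sex effects plus Gaussian noise.

The cohort generator's correlation model is block-constant: correlation
``within_block_r`` inside each planted community, ``between_block_r``
elsewhere.  The total residual covariance is
``scale_sd^2 * C + noise_sd^2 * I`` where C is that correlation matrix:
``scale_sd`` sets the size of the correlated (structured) variation and
``noise_sd`` adds independent measurement noise on top (default 0, so the
sample correlations converge to the planted values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pk import (PKParameterSet, apply_allometry, one_compartment_concentration,
                 _MG_L_TO_NG_ML)
from .regions import DEFAULT_REGIONS, REFERENCE_REGION

__all__ = [
    "CohortSpec",
    "PKSimSpec",
    "ExpressionSimSpec",
    "default_planted_partition",
    "generate_suvr_cohort",
    "generate_pk_profiles",
    "PKSimResult",
    "generate_expression",
    "DEFAULT_PK_PARAMS",
]

#: Generating PK parameters used as config defaults: plausible mouse
#: levetiracetam kinetics (terminal half-life ~3 h at 25 g).
DEFAULT_PK_PARAMS = PKParameterSet(
    ka=2.0, cl_f_typ=0.0035, v_f_typ=0.015, ref_weight_kg=0.025,
    dose_effect_cl=0.0, dose_effect_v=0.0)

SEXES = ("male", "female")
TREATMENTS = ("vehicle", "low", "medium", "high")
#: chronic dose arms, mg/kg (vehicle = 0)
TREATMENT_DOSES = {"vehicle": 0.0, "low": 10.0, "medium": 30.0, "high": 56.0}


def default_planted_partition(regions: Sequence[str] = DEFAULT_REGIONS,
                              n_blocks: int = 3) -> dict[str, int]:
    """Split ``regions`` (in order) into ``n_blocks`` contiguous blocks."""
    n = len(regions)
    sizes = [n // n_blocks + (1 if i < n % n_blocks else 0)
             for i in range(n_blocks)]
    part, start = {}, 0
    for b, size in enumerate(sizes, start=1):
        for r in regions[start:start + size]:
            part[r] = b
        start += size
    return part


@dataclass
class CohortSpec:
    """Design of a synthetic SUVr cohort.

    One arm = one (sex, treatment) cell with ``n_per_group`` animals.
    ``group_mean_shifts`` maps (sex, treatment) to either a scalar offset
    applied to all regions or a per-region offset vector.
    """

    n_per_group: int = 10
    regions: tuple[str, ...] = DEFAULT_REGIONS
    planted_partition: Mapping[str, int] = field(default_factory=dict)
    within_block_r: float = 0.8
    between_block_r: float = 0.0
    group_mean_shifts: Mapping[tuple[str, str], object] = field(default_factory=dict)
    baseline_mean: float = 1.2
    scale_sd: float = 0.1
    noise_sd: float = 0.0
    reference_mean: float = 1.0
    reference_sd: float = 0.0
    sexes: tuple[str, ...] = SEXES
    treatments: tuple[str, ...] = TREATMENTS
    genotype: str = "5XFAD"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.planted_partition:
            self.planted_partition = default_planted_partition(self.regions)
        if not (abs(self.within_block_r) <= 1 and abs(self.between_block_r) <= 1):
            raise ValueError("block correlations must lie in [-1, 1]")
        if self.scale_sd < 0 or self.noise_sd < 0:
            raise ValueError("scale_sd and noise_sd must be >= 0")
        missing = set(self.regions) - set(self.planted_partition)
        extra = set(self.planted_partition) - set(self.regions)
        if missing or extra:
            raise ValueError(
                f"planted partition must cover every region exactly once "
                f"(missing={sorted(missing)}, extra={sorted(extra)})")

    def correlation_matrix(self) -> np.ndarray:
        """The implied region x region correlation matrix; validated PSD."""
        labels = np.array([self.planted_partition[r] for r in self.regions])
        same = labels[:, None] == labels[None, :]
        corr = np.where(same, self.within_block_r, self.between_block_r)
        np.fill_diagonal(corr, 1.0)
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals[0] < -1e-10:
            raise ValueError(
                f"implied correlation matrix is not positive semi-definite: "
                f"smallest eigenvalue {eigvals[0]:.6g} "
                f"(within_block_r={self.within_block_r}, "
                f"between_block_r={self.between_block_r})")
        return corr


def generate_suvr_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per animal: metadata + SUVr per region + the reference column.

    Values are multivariate normal with covariance
    ``scale_sd^2 * C + noise_sd^2 * I`` around ``baseline_mean`` plus the
    (sex, treatment) mean shift.  The reference (cerebellum) column is
    drawn independently around ``reference_mean``.
    """
    corr = spec.correlation_matrix()
    p = len(spec.regions)
    cov = spec.scale_sd ** 2 * corr + spec.noise_sd ** 2 * np.eye(p)
    rng = np.random.default_rng(spec.seed)
    rows = []
    idx = 0
    for sex in spec.sexes:
        for trt in spec.treatments:
            shift = spec.group_mean_shifts.get((sex, trt), 0.0)
            mean = spec.baseline_mean + np.broadcast_to(
                np.asarray(shift, dtype=float), (p,))
            vals = rng.multivariate_normal(mean, cov, size=spec.n_per_group,
                                           method="eigh")
            ref = spec.reference_mean + spec.reference_sd * rng.standard_normal(
                spec.n_per_group)
            for i in range(spec.n_per_group):
                idx += 1
                row = {"animal_id": f"A{idx:04d}", "sex": sex,
                       "genotype": spec.genotype, "treatment": trt}
                row.update(dict(zip(spec.regions, vals[i])))
                row[REFERENCE_REGION] = ref[i]
                rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PKSimSpec:
    """Design of a synthetic single-dose PK study.

    Mirrors the sampling design of the source study: n animals per dose
    per sex, doses 10/30/100 mg/kg, serial sampling 0.25-24 h.  Body
    weights are drawn N(weight_mean_kg, weight_sd_kg) unless supplied.
    """

    structural: PKParameterSet = field(default_factory=lambda: DEFAULT_PK_PARAMS)
    doses_mg_per_kg: tuple[float, ...] = (10.0, 30.0, 100.0)
    weights_kg: Sequence[float] | None = None
    weight_mean_kg: float = 0.025
    weight_sd_kg: float = 0.002
    bsv_sd: float = 0.2
    prop_error_sd: float = 0.15
    sample_times_h: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 24.0)
    n_per_dose_per_sex: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.sample_times_h, dtype=float)
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("sample times must be >= 0 and strictly increasing")
        if any(d <= 0 for d in self.doses_mg_per_kg):
            raise ValueError("doses must be positive")
        if self.bsv_sd < 0 or self.prop_error_sd < 0:
            raise ValueError("SDs must be >= 0")


@dataclass
class PKSimResult:
    """Simulated study: long observation table + per-animal truth."""

    observations: pd.DataFrame
    animals: pd.DataFrame
    n_truncated: int = 0


def generate_pk_profiles(spec: PKSimSpec) -> PKSimResult:
    """Simulate the PK study.

    Individual CL/F and V/F are the allometrically scaled, dose-adjusted
    typical values times exp(eta), eta ~ N(0, bsv_sd^2) independent for
    CL and V.  Observations are the model prediction times
    (1 + proportional error); negative values are truncated at zero and
    counted.
    """
    rng = np.random.default_rng(spec.seed)
    times = np.asarray(spec.sample_times_h, dtype=float)
    n_animals = len(spec.doses_mg_per_kg) * 2 * spec.n_per_dose_per_sex
    if spec.weights_kg is not None:
        weights = np.asarray(spec.weights_kg, dtype=float)
        if len(weights) != n_animals:
            raise ValueError(
                f"weights_kg must have length {n_animals}, got {len(weights)}")
    else:
        weights = np.maximum(
            spec.weight_mean_kg + spec.weight_sd_kg * rng.standard_normal(n_animals),
            0.5 * spec.weight_mean_kg)

    obs_rows, animal_rows = [], []
    n_trunc = 0
    i = 0
    for dose_mg_per_kg in spec.doses_mg_per_kg:
        for sex in SEXES:
            for _ in range(spec.n_per_dose_per_sex):
                w = weights[i]
                dose_mg = dose_mg_per_kg * w
                eta_cl = spec.bsv_sd * rng.standard_normal()
                eta_v = spec.bsv_sd * rng.standard_normal()
                cl, v = apply_allometry(spec.structural, w, dose_mg_per_kg)
                cl *= np.exp(eta_cl)
                v *= np.exp(eta_v)
                pred = one_compartment_concentration(
                    times, dose_mg, spec.structural.ka, cl, v) * _MG_L_TO_NG_ML
                eps = spec.prop_error_sd * rng.standard_normal(len(times))
                obs = pred * (1.0 + eps)
                n_trunc += int(np.sum(obs < 0))
                obs = np.maximum(obs, 0.0)
                aid = f"PK{i + 1:03d}"
                animal_rows.append(dict(
                    animal_id=aid, sex=sex, dose_mg_per_kg=dose_mg_per_kg,
                    dose_mg=dose_mg, weight_kg=w, eta_cl=eta_cl, eta_v=eta_v,
                    cl_f_true=cl, v_f_true=v))
                for t, c in zip(times, obs):
                    obs_rows.append(dict(
                        animal_id=aid, sex=sex, dose_mg_per_kg=dose_mg_per_kg,
                        dose_mg=dose_mg, weight_kg=w, time_h=t,
                        conc_ng_per_ml=c))
                i += 1
    if n_trunc:
        warnings.warn(f"{n_trunc} simulated concentrations truncated at 0",
                      stacklevel=2)
    return PKSimResult(observations=pd.DataFrame(obs_rows),
                       animals=pd.DataFrame(animal_rows),
                       n_truncated=n_trunc)


@dataclass
class ExpressionSimSpec:
    """Per-gene linear model generating log2 intensities.

    log2 intensity = intercept + beta_auc * AUC + beta_sex * 1[female]
    + N(0, noise_sd^2).  Every per-gene parameter vector must have length
    equal to the number of genes; scalars are broadcast.
    """

    genes: tuple[str, ...]
    beta_auc: Sequence[float] = 0.0
    beta_sex: Sequence[float] = 0.0
    intercept: Sequence[float] = 8.0
    noise_sd: Sequence[float] = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        g = len(self.genes)
        for name in ("beta_auc", "beta_sex", "intercept", "noise_sd"):
            v = np.broadcast_to(np.asarray(getattr(self, name), dtype=float), (g,))
            object.__setattr__(self, name, np.array(v))
        if np.any(self.noise_sd < 0):
            raise ValueError("noise_sd must be >= 0")


def generate_expression(spec: ExpressionSimSpec, exposures: Sequence[float],
                        sexes: Sequence[str],
                        animal_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Gene x animal log2-intensity table.

    ``exposures`` and ``sexes`` must be aligned per animal.  Returns a
    DataFrame with genes as the index and animal ids as columns.
    """
    auc = np.asarray(exposures, dtype=float)
    sexes = list(sexes)
    if len(auc) != len(sexes):
        raise ValueError("exposures and sexes must be aligned per animal")
    if animal_ids is None:
        animal_ids = [f"A{i + 1:04d}" for i in range(len(auc))]
    elif len(animal_ids) != len(auc):
        raise ValueError("animal_ids must be aligned with exposures")
    female = np.array([1.0 if s == "female" else 0.0 for s in sexes])
    rng = np.random.default_rng(spec.seed)
    mean = (spec.intercept[:, None]
            + spec.beta_auc[:, None] * auc[None, :]
            + spec.beta_sex[:, None] * female[None, :])
    vals = mean + spec.noise_sd[:, None] * rng.standard_normal(mean.shape)
    return pd.DataFrame(vals, index=list(spec.genes), columns=list(animal_ids))
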
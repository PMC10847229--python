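"""Gene-level linear models: design factors, vehicle deltas, exposure PK/PD.

Three analyses over gene x animal log2-intensity tables:

* :func:`de_linear_model` — per-gene OLS on genotype + sex + treatment
  (categorical), flagging genes with any factor partial-F p < 0.05
  (raw p; an optional Benjamini-Hochberg column is attached for users).
* :func:`delta_from_vehicle` — per (sex, treatment) mean log2 intensity
  minus the same sex's vehicle mean (or the WT vehicle baseline).
* :class:`GeneExposureModel` — per-gene lm(log2 ~ AUC + sex), the PK/PD
  model of the exposure-response analysis; and
  :func:`network_metric_exposure_model`, the same regression applied to
  network summary metrics (which the source analysis found to carry no
  exposure relationship — the fit is reported, never asserted).

Sex is coded as an indicator with male = 0 (reference) by default; the
coding is configurable since the sign of the sex coefficient flips with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionTable",
    "de_linear_model",
    "delta_from_vehicle",
    "GeneExposureModel",
    "GeneExposureResults",
    "network_metric_exposure_model",
    "module_signature_correlation",
]


@dataclass
class ExpressionTable:
    """Gene x animal log2 intensities with aligned animal metadata.

    ``values``: DataFrame, genes as index, animal ids as columns.
    ``metadata``: DataFrame indexed by animal id with columns sex,
    genotype, treatment and (optionally) auc.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.metadata.index):
            if set(self.values.columns) != set(self.metadata.index):
                raise ValueError("metadata does not cover the table's animals")
            self.metadata = self.metadata.loc[self.values.columns]
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def animals(self) -> list[str]:
        return list(self.values.columns)


def _ols_many(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X. Returns (beta, rss, rank)."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = (resid ** 2).sum(axis=0)
    return beta, rss, rank


def _factor_columns(series: pd.Series, prefix: str) -> pd.DataFrame:
    """Treatment-contrast dummies (first level = reference), level-sorted."""
    levels = sorted(series.unique())
    return pd.DataFrame(
        {f"{prefix}[{lev}]": (series == lev).astype(float).to_numpy()
         for lev in levels[1:]},
        index=series.index)


def de_linear_model(expr: ExpressionTable, alpha: float = 0.05,
                    factors: Sequence[str] = ("genotype", "sex", "treatment"),
                    ) -> pd.DataFrame:
    """Per-gene OLS on categorical design factors with partial F-tests.

    For each factor the partial (type II-style) F-test compares the full
    model against the model with that factor's columns removed.  A gene is
    ``significant`` when any factor's raw p < alpha.  Genes whose design
    is rank-deficient are flagged non-estimable.
    """
    meta = expr.metadata
    for f in factors:
        if meta[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels present")
    blocks = {f: _factor_columns(meta[f], f) for f in factors}
    n = len(meta)
    col_names = ["Intercept"] + [c for f in factors for c in blocks[f].columns]
    X_full = np.column_stack([np.ones(n)]
                             + [blocks[f].to_numpy() for f in factors])
    p_full = X_full.shape[1]
    Y = expr.values.to_numpy(dtype=float).T  # animals x genes
    beta, rss_full, rank = _ols_many(X_full, Y)
    df_resid = n - p_full
    out = pd.DataFrame(index=expr.values.index)
    for j, name in enumerate(col_names):
        out[f"beta_{name}"] = beta[j]
    estimable = rank == p_full and df_resid > 0
    for f in factors:
        cols = [blocks[g].to_numpy() for g in factors if g != f]
        X_red = np.column_stack([np.ones(n)] + cols)
        _, rss_red, _ = _ols_many(X_red, Y)
        df1 = X_full.shape[1] - X_red.shape[1]
        with np.errstate(invalid="ignore", divide="ignore"):
            F = ((rss_red - rss_full) / df1) / (rss_full / df_resid)
        pvals = stats.f.sf(F, df1, df_resid)
        # numerically perfect fits: the factor is either decisive (removing
        # it leaves real residual) or irrelevant (both models fit exactly)
        tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        tiny = 1e-12 * np.maximum(tss, 1e-300)
        degenerate = rss_full <= tiny
        pvals = np.where(degenerate,
                         np.where(rss_red > tiny, 0.0, 1.0), pvals)
        out[f"F_{f}"] = F
        out[f"p_{f}"] = pvals
    pcols = [f"p_{f}" for f in factors]
    if estimable:
        out["significant"] = (out[pcols] < alpha).any(axis=1)
        out["estimable"] = True
    else:
        out["significant"] = False
        out["estimable"] = False
        out["reason"] = ("rank-deficient design" if rank < p_full
                         else "no residual degrees of freedom")
    # convenience FDR column over the per-gene minimum p (not used for the
    # significance flag, which matches the raw p < alpha rule)
    pmin = out[pcols].min(axis=1).fillna(1.0)
    out["q_bh_min_p"] = multipletests(pmin.to_numpy(), method="fdr_bh")[1]
    return out


def delta_from_vehicle(expr: ExpressionTable,
                       baseline: str = "matched_vehicle") -> pd.DataFrame:
    """Gene x (sex, treatment) mean-difference table against vehicle.

    delta = mean log2 intensity in (sex, treatment) minus the mean in that
    sex's vehicle group.  ``baseline="wt_vehicle"`` subtracts the same
    sex's wild-type vehicle group instead.  Missing vehicle cells yield
    NaN columns (reported, not raised).
    """
    if baseline not in ("matched_vehicle", "wt_vehicle"):
        raise ValueError("baseline must be matched_vehicle|wt_vehicle")
    meta = expr.metadata
    vals = expr.values
    sexes = sorted(meta["sex"].unique())
    treatments = [t for t in meta["treatment"].unique()]
    cols: dict[tuple[str, str], pd.Series] = {}
    for sex in sexes:
        if baseline == "matched_vehicle":
            base_mask = (meta["sex"] == sex) & (meta["treatment"] == "vehicle")
        else:
            base_mask = ((meta["sex"] == sex) & (meta["treatment"] == "vehicle")
                         & (meta["genotype"] == "WT"))
        base_animals = meta.index[base_mask]
        base = (vals[base_animals].mean(axis=1) if len(base_animals)
                else pd.Series(np.nan, index=vals.index))
        for trt in treatments:
            grp = meta.index[(meta["sex"] == sex) & (meta["treatment"] == trt)]
            if len(grp) == 0:
                continue
            cols[(sex, trt)] = vals[grp].mean(axis=1) - base
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["sex", "treatment"])
    return out


@dataclass
class GeneModelFit:
    gene: str
    beta_auc: float
    se_auc: float
    p_auc: float
    beta_sex: float
    se_sex: float
    p_sex: float
    r_squared: float
    estimable: bool = True
    message: str = ""


class GeneExposureModel:
    """Per-gene lm(log2 intensity ~ AUC + sex).

    AUC is the per-animal predicted exposure (continuous); sex is a binary
    indicator (``female_level`` = 1, reference = 0).  All genes share one
    design matrix, so the fit is a single vectorized least-squares solve.
    """

    def __init__(self, expr: ExpressionTable, female_level: str = "female"):
        if "auc" not in expr.metadata.columns:
            raise ValueError("metadata must carry a per-animal 'auc' column")
        if expr.metadata["sex"].nunique() < 2:
            raise ValueError("both sexes must be present")
        self.expr = expr
        self.female_level = female_level

    def fit(self) -> "GeneExposureResults":
        meta = self.expr.metadata
        auc = meta["auc"].to_numpy(dtype=float)
        sex = (meta["sex"] == self.female_level).astype(float).to_numpy()
        n = len(meta)
        if np.ptp(auc) == 0:
            raise ValueError("AUC is constant across animals; "
                             "exposure term non-estimable")
        X = np.column_stack([np.ones(n), auc, sex])
        Y = self.expr.values.to_numpy(dtype=float).T
        beta, rss, rank = _ols_many(X, Y)
        df_resid = n - X.shape[1]
        if rank < X.shape[1] or df_resid <= 0:
            raise ValueError("design matrix rank-deficient or saturated")
        sigma2 = rss / df_resid
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))  # (3, genes)
        with np.errstate(invalid="ignore", divide="ignore"):
            tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), df=df_resid)
        tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(tss > 0, 1 - rss / tss, 0.0)
        table = pd.DataFrame({
            "beta_auc": beta[1], "se_auc": se[1], "p_auc": pvals[1],
            "beta_sex": beta[2], "se_sex": se[2], "p_sex": pvals[2],
            "r_squared": r2,
        }, index=self.expr.values.index)
        return GeneExposureResults(model=self, table=table, n=n,
                                   df_resid=df_resid)


@dataclass
class GeneExposureResults:
    """Table of per-gene exposure/sex coefficients (Table-1 schema)."""

    model: GeneExposureModel
    table: pd.DataFrame
    n: int
    df_resid: int

    def summary(self, genes: Sequence[str] | None = None) -> str:
        t = self.table if genes is None else self.table.loc[list(genes)]
        lines = [
            f"Gene exposure model: log2 ~ AUC + sex "
            f"(n={self.n} animals, {len(self.table)} genes, "
            f"female={self.model.female_level!r} coded 1)",
            t.to_string(float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


def network_metric_exposure_model(metrics: pd.DataFrame,
                                  female_level: str = "female") -> pd.DataFrame:
    """Multi-linear regression of network summaries on AUC + sex.

    ``metrics`` must have columns ``auc`` and ``sex`` plus one column per
    network summary (mean degree, density, mean strengths, mean
    clustering).  Returns one row per summary with betas, SEs, p-values
    and R^2.  The source analysis reports this as a null result; the
    function reports the fit either way.
    """
    needed = {"auc", "sex"}
    if not needed <= set(metrics.columns):
        raise ValueError("metrics table needs 'auc' and 'sex' columns")
    value_cols = [c for c in metrics.columns if c not in needed]
    if len(metrics) < 3:
        raise ValueError("need >= 3 observations per metric")
    auc = metrics["auc"].to_numpy(dtype=float)
    sex = (metrics["sex"] == female_level).astype(float).to_numpy()
    if np.ptp(auc) == 0:
        raise ValueError("AUC is constant; exposure term non-estimable")
    n = len(metrics)
    X = np.column_stack([np.ones(n), auc, sex])
    Y = metrics[value_cols].to_numpy(dtype=float)
    beta, rss, rank = _ols_many(X, Y)
    df_resid = n - X.shape[1]
    if rank < X.shape[1] or df_resid <= 0:
        raise ValueError("design matrix rank-deficient or saturated")
    sigma2 = rss / df_resid
    se = np.sqrt(np.outer(np.diag(np.linalg.inv(X.T @ X)), sigma2))
    with np.errstate(invalid="ignore", divide="ignore"):
        tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=df_resid)
    tss = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(tss > 0, 1 - rss / tss, 0.0)
    return pd.DataFrame({
        "beta_auc": beta[1], "se_auc": se[1], "p_auc": pvals[1],
        "beta_sex": beta[2], "se_sex": se[2], "p_sex": pvals[2],
        "r_squared": r2,
    }, index=pd.Index(value_cols, name="metric"))


def module_signature_correlation(deltas: pd.DataFrame,
                                 signature: pd.Series) -> pd.DataFrame:
    """Correlate per-group expression deltas against a module signature.

    Generic utility for comparing mouse delta-from-vehicle profiles with a
    user-supplied per-gene signature vector (e.g. a human co-expression
    module): Pearson r and two-sided p per delta column, over the genes
    shared between the two inputs.
    """
    shared = deltas.index.intersection(signature.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    sig = signature.loc[shared].to_numpy(dtype=float)
    rows = []
    for col in deltas.columns:
        x = deltas.loc[shared, col].to_numpy(dtype=float)
        mask = np.isfinite(x)
        if mask.sum() < 3 or np.ptp(x[mask]) == 0 or np.ptp(sig[mask]) == 0:
            rows.append((col, np.nan, np.nan, int(mask.sum())))
            continue
        r, p = stats.pearsonr(x[mask], sig[mask])
        rows.append((col, r, p, int(mask.sum())))
    return pd.DataFrame(rows, columns=["group", "r", "p", "n_genes"]
                        ).set_index("group")
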
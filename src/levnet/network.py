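"""Metabolic covariance networks and signed nodal graph metrics.

A group's network is the region x region matrix of Pearson correlations of
SUVr across the animals of that group (equivalently of the z-scored
columns; Pearson r is invariant to affine rescaling).  Edges are
thresholded on the two-sided p-value of each correlation (t transform with
n-2 degrees of freedom), keeping the signed correlation as the edge weight
where p < alpha (default 0.05).  For each region the nodal degree, the
positive strength (sum of positive weights), the negative strength
(summed magnitude of negative weights) and the clustering coefficient are
computed; group-level comparisons use the two-sample Kolmogorov-Smirnov
test on the 27-point distributions of each metric.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import comb

from .regions import REFERENCE_REGION
from .suvr import region_columns

__all__ = [
    "CovarianceNetwork",
    "ThresholdedNetwork",
    "covariance_matrix",
    "threshold_network",
    "nodal_metrics",
    "global_metrics",
    "critical_r",
    "KSComparison",
    "compare_metric_distributions",
]

METRIC_NAMES = ("degree", "s_pos", "s_neg", "clustering")


@dataclass
class CovarianceNetwork:
    """Pearson r and p matrices for one group of animals."""

    regions: list[str]
    r: np.ndarray
    p: np.ndarray
    n: int
    group: str = ""

    def r_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.regions, columns=self.regions)

    def p_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.p, index=self.regions, columns=self.regions)


@dataclass
class ThresholdedNetwork:
    """Signed weighted adjacency after the p < alpha edge threshold."""

    regions: list[str]
    adjacency: np.ndarray
    alpha: float
    n: int
    group: str = ""

    @property
    def density(self) -> float:
        n = len(self.regions)
        possible = n * (n - 1) / 2
        surviving = np.count_nonzero(np.triu(self.adjacency, 1))
        return surviving / possible

    def adjacency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.adjacency, index=self.regions,
                            columns=self.regions)


def covariance_matrix(group: pd.DataFrame,
                      reference: str = REFERENCE_REGION,
                      group_label: str = "") -> CovarianceNetwork:
    """Pairwise Pearson correlation network for one group of animals.

    Requires >= 4 animals.  The reference region is excluded.  Two-sided
    p-values come from t = r * sqrt((n-2)/(1-r^2)) with n-2 df.
    Zero-variance regions get r = 0, p = 1 on all their edges (isolated
    nodes) with a warning.
    """
    regions = [c for c in region_columns(group) if c != reference]
    X = group[regions].to_numpy(dtype=float)
    n = len(X)
    if n < 4:
        raise ValueError(f"need >= 4 animals, got {n}")
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn("zero-variance regions degraded to isolated nodes: "
                      f"{[r for r, z in zip(regions, zero) if z]}",
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.nan_to_num(r, nan=0.0)
    r[zero, :] = 0.0
    r[:, zero] = 0.0
    np.fill_diagonal(r, 0.0)
    rc = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = rc * np.sqrt((n - 2) / (1 - rc ** 2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[zero, :] = 1.0
    p[:, zero] = 1.0
    np.fill_diagonal(p, 1.0)
    # exact collinearity: p underflows to 0
    p[np.abs(r) >= 1 - 1e-15] = 0.0
    np.fill_diagonal(p, 1.0)
    return CovarianceNetwork(regions=regions, r=r, p=p, n=n, group=group_label)


def critical_r(alpha: float, n: int) -> float:
    """|r| above which the two-sided p-value falls below alpha."""
    tcrit = stats.t.isf(alpha / 2, df=n - 2)
    return tcrit / math.sqrt(n - 2 + tcrit ** 2)


def threshold_network(net: CovarianceNetwork,
                      alpha: float = 0.05) -> ThresholdedNetwork:
    """Keep signed weights where p < alpha; everything else is 0."""
    adj = np.where(net.p < alpha, net.r, 0.0)
    np.fill_diagonal(adj, 0.0)
    return ThresholdedNetwork(regions=list(net.regions), adjacency=adj,
                              alpha=alpha, n=net.n, group=net.group)


def _clustering_binary(A: np.ndarray, k: np.ndarray) -> np.ndarray:
    tri = np.diag(A @ A @ A) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 2.0 * tri / (k * (k - 1))
    c[k < 2] = 0.0
    return c


def _clustering_onnela(W: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering on |w| rescaled by the max weight."""
    wmax = np.abs(W).max()
    if wmax == 0:
        return np.zeros(len(W))
    w13 = np.cbrt(np.abs(W) / wmax)
    tri = np.diag(w13 @ w13 @ w13) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = 2.0 * tri / (k * (k - 1))
    c[k < 2] = 0.0
    return c


def _clustering_signed(W: np.ndarray) -> np.ndarray:
    """Zhang-Horvath-style signed clustering: sum of signed triangle
    products over the sum of |w_ij w_ik| over neighbor pairs."""
    num = np.diag(W @ W @ W)
    absW = np.abs(W)
    s = absW.sum(axis=1)
    den = s ** 2 - (absW ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = num / den
    c[den == 0] = 0.0
    return c


def nodal_metrics(tnet: ThresholdedNetwork,
                  clustering: str = "binary") -> pd.DataFrame:
    """Per-region degree, positive/negative strength, clustering.

    Degree counts surviving edges; s_pos sums positive weights; s_neg sums
    magnitudes of negative weights.  Clustering variants: "binary"
    (default; sign-blind Watts-Strogatz on the surviving-edge graph),
    "onnela" (weighted), "signed" (Zhang-Horvath-style).
    """
    W = tnet.adjacency
    A = (W != 0).astype(float)
    k = A.sum(axis=1)
    s_pos = np.where(W > 0, W, 0.0).sum(axis=1)
    s_neg = np.abs(np.where(W < 0, W, 0.0)).sum(axis=1)
    if clustering == "binary":
        c = _clustering_binary(A, k)
    elif clustering == "onnela":
        c = _clustering_onnela(W, k)
    elif clustering == "signed":
        c = _clustering_signed(W)
    else:
        raise ValueError("clustering must be binary|onnela|signed")
    return pd.DataFrame(
        {"degree": k, "s_pos": s_pos, "s_neg": s_neg, "clustering": c},
        index=pd.Index(tnet.regions, name="region"))


def global_metrics(tnet: ThresholdedNetwork,
                   clustering: str = "binary") -> dict[str, float]:
    """Network-level summaries used in exposure-response modeling."""
    m = nodal_metrics(tnet, clustering=clustering)
    return {
        "density": tnet.density,
        "mean_degree": float(m["degree"].mean()),
        "mean_s_pos": float(m["s_pos"].mean()),
        "mean_s_neg": float(m["s_neg"].mean()),
        "mean_clustering": float(m["clustering"].mean()),
    }


@dataclass
class KSComparison:
    statistic: float
    p_value: float
    metric: str = ""
    group_a: str = ""
    group_b: str = ""
    method: str = ""


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.sort(np.concatenate([x, y]))
    cdf_x = np.searchsorted(np.sort(x), pooled, side="right") / len(x)
    cdf_y = np.searchsorted(np.sort(y), pooled, side="right") / len(y)
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _ks_p_enumeration(x: np.ndarray, y: np.ndarray) -> float:
    """Exact conditional p by enumerating all label assignments of the
    pooled sample; correct in the presence of ties."""
    d_obs = _ks_statistic(x, y)
    pooled = np.concatenate([x, y])
    n_total, n_x = len(pooled), len(x)
    idx = range(n_total)
    count = total = 0
    for subset in combinations(idx, n_x):
        mask = np.zeros(n_total, dtype=bool)
        mask[list(subset)] = True
        d = _ks_statistic(pooled[mask], pooled[~mask])
        count += d >= d_obs - 1e-12
        total += 1
    return count / total


def compare_metric_distributions(a: Sequence[float], b: Sequence[float],
                                 metric: str = "", group_a: str = "",
                                 group_b: str = "",
                                 max_enumeration: int = 20000) -> KSComparison:
    """Two-sample Kolmogorov-Smirnov comparison of two metric distributions.

    The p-value is exact by full enumeration over label assignments when
    C(n+m, n) <= max_enumeration (ties handled correctly), otherwise
    scipy's exact method when both samples have <= 30 points (the paper's
    use case: 27 regions per distribution), otherwise asymptotic.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    n_comb = comb(len(x) + len(y), len(x), exact=True)
    if n_comb <= max_enumeration:
        d = _ks_statistic(x, y)
        p = _ks_p_enumeration(x, y)
        method = "enumeration"
    else:
        mode = "exact" if (len(x) <= 30 and len(y) <= 30) else "asymp"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = stats.ks_2samp(x, y, method=mode)
        d, p = float(res.statistic), float(res.pvalue)
        method = mode
    return KSComparison(statistic=d, p_value=min(p, 1.0), metric=metric,
                        group_a=group_a, group_b=group_b, method=method)
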
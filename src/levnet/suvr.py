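"""Regional uptake processing: bilateral averaging, SUVr, region selection.

Pipeline order is fixed: unilateral regions are first averaged left/right
into 28 bilateral regions, then every region is divided by the animal's
cerebellum value to give the standardized uptake value ratio (SUVr).  Note
the two steps commute only when the left and right reference values are
equal, which is why the order matters.

Consensus region selection runs a principal component analysis per cohort
on the standardized animal x region SUVr matrix, ranks regions by their
variance-weighted squared loadings over the leading components reaching
the target explained-variance fraction (default 80%), takes the minimal
top-ranked set reaching that fraction of the total contribution, and
intersects the per-cohort sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .regions import REFERENCE_REGION, RegionPairing

__all__ = [
    "METADATA_COLUMNS",
    "region_columns",
    "average_bilateral",
    "compute_suvr",
    "select_consensus_regions",
    "ConsensusRegionReport",
]

#: Columns treated as animal metadata rather than regions.
METADATA_COLUMNS = ("animal_id", "sex", "genotype", "treatment", "cohort")


def region_columns(table: pd.DataFrame) -> list[str]:
    """All non-metadata columns of a cohort table, in table order."""
    return [c for c in table.columns if c not in METADATA_COLUMNS]


def _check_complete(table: pd.DataFrame, cols: Sequence[str]) -> None:
    bad = [c for c in cols if table[c].isna().any()]
    if bad:
        raise ValueError(f"missing region values in columns: {bad}")


def average_bilateral(table: pd.DataFrame, pairing: RegionPairing) -> pd.DataFrame:
    """Average left/right unilateral columns into bilateral regions.

    Every unilateral region column must appear in ``pairing``; each
    bilateral output value is the arithmetic mean of its two members.
    """
    uni = region_columns(table)
    _check_complete(table, uni)
    unknown = [c for c in uni if c not in pairing.mapping]
    if unknown:
        raise ValueError(f"unilateral labels missing from pairing: {unknown}")
    out = table[[c for c in table.columns if c in METADATA_COLUMNS]].copy()
    for bilateral in pairing.bilateral_labels:
        members = [m for m in pairing.members(bilateral) if m in uni]
        if not members:
            continue
        if len(members) != 2:
            raise ValueError(
                f"bilateral region {bilateral!r} has {len(members)} of its "
                f"members present; need both")
        out[bilateral] = table[members].mean(axis=1)
    return out


def compute_suvr(table: pd.DataFrame,
                 reference: str = REFERENCE_REGION) -> pd.DataFrame:
    """Divide every region by the animal's reference-region value.

    The reference column is retained and becomes identically 1.
    Idempotent: applying twice equals applying once.
    """
    if reference not in table.columns:
        raise ValueError(f"reference region {reference!r} not in table")
    regions = region_columns(table)
    _check_complete(table, regions)
    ref = table[reference].to_numpy(dtype=float)
    bad = np.where(ref <= 0)[0]
    if len(bad):
        ids = (table["animal_id"].iloc[bad].tolist()
               if "animal_id" in table.columns else bad.tolist())
        raise ValueError(
            f"non-positive reference value for animals {ids}; SUVr undefined")
    out = table.copy()
    out[regions] = table[regions].to_numpy(dtype=float) / ref[:, None]
    return out


@dataclass
class ConsensusRegionReport:
    """Consensus region subset and the per-cohort evidence behind it."""

    consensus: list[str]
    per_cohort: dict[str, list[str]]
    contributions: dict[str, pd.Series] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)


def _rank_regions_pca(X: np.ndarray, regions: list[str],
                      variance_fraction: float) -> tuple[list[str], pd.Series]:
    """Rank regions by variance-weighted squared PCA loadings.

    Columns are z-standardized (zero-variance columns get zero score and a
    warning); eigendecomposition of the correlation matrix; the leading m
    components reaching >= variance_fraction cumulative explained variance
    define region contributions score_i = sum_j lambda_j * V_ij^2; the
    minimal top-ranked set whose cumulative share of the total contribution
    reaches variance_fraction is selected.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"zero-variance regions excluded from PCA ranking: "
            f"{[r for r, z in zip(regions, zero) if z]}", stacklevel=3)
    live = ~zero
    Xl = X[:, live]
    Z = (Xl - Xl.mean(axis=0)) / sd[live]
    corr = Z.T @ Z / (len(Z) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.maximum(eigval[order], 0.0), eigvec[:, order]
    total = eigval.sum()
    cum = np.cumsum(eigval) / total
    m = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    scores_live = (eigvec[:, :m] ** 2 * eigval[:m]).sum(axis=1)
    scores = np.zeros(len(regions))
    scores[live] = scores_live
    contrib = pd.Series(scores, index=regions).sort_values(
        ascending=False, kind="stable")
    share = contrib.cumsum() / contrib.sum()
    k = int(np.searchsorted(share.to_numpy(), variance_fraction - 1e-12) + 1)
    return list(contrib.index[:k]), contrib


def select_consensus_regions(tables: dict[str, pd.DataFrame] | Sequence[pd.DataFrame],
                             variance_fraction: float = 0.80,
                             reference: str = REFERENCE_REGION,
                             mode: str = "intersection",
                             min_frequency: float = 0.5) -> ConsensusRegionReport:
    """Regions that consistently explain ``variance_fraction`` of variance.

    Per cohort: PCA ranking as in :func:`_rank_regions_pca` on the SUVr
    columns (reference region excluded).  Cohorts with fewer than 3 animals
    are skipped with a warning.  ``mode="intersection"`` (default) takes
    the strict intersection across cohorts; ``mode="frequency"`` keeps
    regions selected in at least ``min_frequency`` of cohorts.  An empty
    result is returned (with the per-cohort report), not raised.
    """
    if not isinstance(tables, dict):
        tables = {f"cohort{i + 1}": t for i, t in enumerate(tables)}
    if mode not in ("intersection", "frequency"):
        raise ValueError("mode must be 'intersection' or 'frequency'")
    per_cohort: dict[str, list[str]] = {}
    contributions: dict[str, pd.Series] = {}
    skipped: list[str] = []
    for name, table in tables.items():
        regions = [c for c in region_columns(table) if c != reference]
        if len(table) < 3:
            warnings.warn(f"cohort {name!r} has <3 animals; skipped",
                          stacklevel=2)
            skipped.append(name)
            continue
        selected, contrib = _rank_regions_pca(
            table[regions].to_numpy(dtype=float), regions, variance_fraction)
        per_cohort[name] = selected
        contributions[name] = contrib
    if not per_cohort:
        return ConsensusRegionReport(consensus=[], per_cohort={},
                                     contributions={}, skipped=skipped)
    all_regions = list(next(iter(contributions.values())).index)
    if mode == "intersection":
        sets = [set(s) for s in per_cohort.values()]
        consensus_set = set.intersection(*sets)
    else:
        counts = {r: sum(r in s for s in per_cohort.values())
                  for r in all_regions}
        consensus_set = {r for r, c in counts.items()
                         if c / len(per_cohort) >= min_frequency}
    # stable order: by mean contribution rank across cohorts
    mean_contrib = pd.concat(contributions.values(), axis=1).mean(axis=1)
    consensus = [r for r in mean_contrib.sort_values(
        ascending=False, kind="stable").index if r in consensus_set]
    return ConsensusRegionReport(consensus=consensus, per_cohort=per_cohort,
                                 contributions=contributions, skipped=skipped)
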
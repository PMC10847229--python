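"""Multi-resolution consensus community structure of covariance networks.

Community detection runs on the positive-weight subgraph of a thresholded
covariance network (negative edges are kept for nodal metrics but excluded
from modularity).  An ensemble of Louvain modularity partitions is computed
across a grid of resolution parameters gamma; the co-classification matrix
(fraction of ensemble partitions placing two regions together) is
thresholded against a permutation null (random relabelings of each ensemble
partition, 95th percentile) and re-clustered until the ensemble is
unanimous — the multi-resolution consensus clustering (MRCC) procedure.

A reference partition (in the source design, the wild-type male network's
communities) can then be imposed on any comparison group: per animal and
community, the mean SUVr over member regions, compared between groups by
one-way ANOVA with Bonferroni correction over communities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .network import ThresholdedNetwork
from .suvr import METADATA_COLUMNS, region_columns

__all__ = [
    "Partition",
    "MRCCResult",
    "mrcc",
    "impose_partition",
    "community_anova",
    "CommunityComparison",
    "count_communities",
]


@dataclass
class Partition:
    """Region -> community labels, canonicalized to contiguous 1..K."""

    labels: dict[str, int]

    def __post_init__(self) -> None:
        relabel: dict[int, int] = {}
        out: dict[str, int] = {}
        for region, lab in self.labels.items():
            if lab not in relabel:
                relabel[lab] = len(relabel) + 1
            out[region] = relabel[lab]
        self.labels = out

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    @property
    def regions(self) -> list[str]:
        return list(self.labels)

    def members(self, community: int) -> list[str]:
        return [r for r, c in self.labels.items() if c == community]

    def as_array(self, regions: Sequence[str]) -> np.ndarray:
        return np.array([self.labels[r] for r in regions])

    def equivalent(self, other: "Partition") -> bool:
        """Equality up to community relabeling."""
        if set(self.labels) != set(other.labels):
            return False
        pairs = {(self.labels[r], other.labels[r]) for r in self.labels}
        return (len({a for a, _ in pairs}) == len(pairs)
                and len({b for _, b in pairs}) == len(pairs))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region": list(self.labels),
                             "community": list(self.labels.values())})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Partition":
        return cls(dict(zip(df["region"], df["community"].astype(int))))


def count_communities(p: Partition) -> int:
    """Number of distinct community labels."""
    return p.k


def _louvain_labels(G: nx.Graph, n_nodes: int, gamma: float,
                    seed: int) -> np.ndarray:
    comms = nx.community.louvain_communities(
        G, weight="weight", resolution=gamma, seed=int(seed))
    labels = np.empty(n_nodes, dtype=int)
    for ci, members in enumerate(comms):
        for node in members:
            labels[node] = ci
    return labels


def _coclassification(label_matrix: np.ndarray) -> np.ndarray:
    eq = (label_matrix[:, :, None] == label_matrix[:, None, :])
    return eq.mean(axis=0)


def _null_threshold(label_matrix: np.ndarray, n_null: int,
                    quantile: float, rng: np.random.Generator) -> float:
    """Permutation-null threshold for co-classification values.

    Under a random relabeling of a partition with community sizes {n_k}
    every node pair is co-assigned with probability
    sum_k n_k (n_k - 1) / (N (N - 1)); a null replicate of the ensemble
    co-classification of a pair is the mean of independent Bernoulli draws
    at the per-partition probabilities.  Returns the ``quantile`` of
    ``n_null`` such replicates.
    """
    n_samples, n_nodes = label_matrix.shape
    probs = np.empty(n_samples)
    for s in range(n_samples):
        _, counts = np.unique(label_matrix[s], return_counts=True)
        probs[s] = (counts * (counts - 1)).sum() / (n_nodes * (n_nodes - 1))
    draws = rng.random((n_null, n_samples)) < probs[None, :]
    null_vals = draws.mean(axis=1)
    return float(np.quantile(null_vals, quantile))


@dataclass
class MRCCResult:
    """Consensus partition plus the ensemble evidence behind it."""

    partition: Partition
    coclassification: pd.DataFrame
    null_threshold: float
    gammas: np.ndarray
    n_samples: int
    n_null: int
    n_iterations: int
    regions: list[str] = field(default_factory=list)


def mrcc(tnet: ThresholdedNetwork, gamma_range: tuple[float, float] = (0.5, 3.0),
         n_samples: int = 200, n_null: int = 10000, seed: int | None = None,
         null_quantile: float = 0.95, max_iter: int = 50) -> MRCCResult:
    """Multi-resolution consensus clustering of the positive subgraph.

    Louvain modularity partitions are computed at ``n_samples`` resolutions
    evenly spanning ``gamma_range``; the co-classification matrix is
    thresholded at the ``null_quantile`` of the permutation null
    (``n_null`` replicates) and re-clustered (at gamma = 1) until all
    partitions of the re-clustering ensemble agree.  Deterministic given
    ``seed`` (required).
    """
    if seed is None:
        raise ValueError("mrcc requires an explicit seed")
    regions = list(tnet.regions)
    n = len(regions)
    W = np.where(tnet.adjacency > 0, tnet.adjacency, 0.0)
    if not np.any(W > 0):
        warnings.warn("no positive edges; returning a single community",
                      stacklevel=2)
        part = Partition({r: 1 for r in regions})
        return MRCCResult(partition=part,
                          coclassification=pd.DataFrame(
                              np.ones((n, n)), index=regions, columns=regions),
                          null_threshold=1.0,
                          gammas=np.array([]), n_samples=0, n_null=n_null,
                          n_iterations=0, regions=regions)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    gammas = np.linspace(gamma_range[0], gamma_range[1], n_samples)
    G = nx.from_numpy_array(W)
    louvain_seeds = rng.integers(0, 2 ** 31 - 1, size=n_samples)
    L = np.stack([_louvain_labels(G, n, g, s)
                  for g, s in zip(gammas, louvain_seeds)])
    A = _coclassification(L)
    thr = _null_threshold(L, n_null, null_quantile, rng)

    A_current = A
    n_rep = 32
    for iteration in range(1, max_iter + 1):
        A_thr = np.where(A_current > thr, A_current, 0.0)
        np.fill_diagonal(A_thr, 1.0)
        Gc = nx.from_numpy_array(A_thr)
        seeds = rng.integers(0, 2 ** 31 - 1, size=n_rep)
        Lc = np.stack([_louvain_labels(Gc, n, 1.0, s) for s in seeds])
        if all(np.array_equal(
                _canonical(Lc[0]), _canonical(Lc[i])) for i in range(1, n_rep)):
            labels = _canonical(Lc[0])
            part = Partition({r: int(l) for r, l in zip(regions, labels)})
            return MRCCResult(
                partition=part,
                coclassification=pd.DataFrame(A, index=regions, columns=regions),
                null_threshold=thr, gammas=gammas, n_samples=n_samples,
                n_null=n_null, n_iterations=iteration, regions=regions)
        A_current = _coclassification(Lc)
    raise RuntimeError(
        f"MRCC consensus did not converge in {max_iter} iterations "
        f"(n={n} regions, threshold={thr:.3f}); inspect the "
        f"co-classification matrix for unstable region assignments")


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel communities by first occurrence (1..K)."""
    relabel: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        out[i] = relabel[lab]
    return out


def impose_partition(reference: Partition, suvr_group: pd.DataFrame,
                     reference_region: str = "Cerebellum") -> pd.DataFrame:
    """Per-animal community-mean SUVr under a reference partition.

    Returns a table with the group's metadata columns plus one
    ``community_<k>`` column per community: the arithmetic mean SUVr over
    the community's member regions.
    """
    regions = [c for c in region_columns(suvr_group) if c != reference_region]
    missing = [r for r in regions if r not in reference.labels]
    if missing:
        raise ValueError(f"regions missing from reference partition: {missing}")
    out = suvr_group[[c for c in suvr_group.columns
                      if c in METADATA_COLUMNS]].copy()
    for k in range(1, reference.k + 1):
        members = [r for r in reference.members(k) if r in regions]
        if members:
            out[f"community_{k}"] = suvr_group[members].mean(axis=1)
    return out


@dataclass
class CommunityComparison:
    community: int
    members: list[str]
    f_statistic: float
    p_raw: float
    p_bonferroni: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    estimable: bool = True
    message: str = ""


def community_anova(a: pd.DataFrame, b: pd.DataFrame,
                    reference: Partition) -> list[CommunityComparison]:
    """One-way ANOVA per community between two community-mean tables.

    With two groups F has (1, n_a + n_b - 2) df and equals the square of
    the pooled two-sample t statistic.  Bonferroni correction multiplies
    each raw p by the community count K (capped at 1).
    """
    k_total = reference.k
    results: list[CommunityComparison] = []
    for k in range(1, k_total + 1):
        col = f"community_{k}"
        if col not in a.columns or col not in b.columns:
            raise ValueError(f"column {col} missing from a community-mean table")
        xa = a[col].to_numpy(dtype=float)
        xb = b[col].to_numpy(dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError("each group needs >= 2 animals")
        if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa[0] == xb[0]:
            results.append(CommunityComparison(
                community=k, members=reference.members(k),
                f_statistic=float("nan"), p_raw=float("nan"),
                p_bonferroni=float("nan"), n_a=len(xa), n_b=len(xb),
                mean_a=float(xa.mean()), mean_b=float(xb.mean()),
                estimable=False,
                message="zero within-group variance and equal means; "
                        "F undefined"))
            continue
        f, p = stats.f_oneway(xa, xb)
        results.append(CommunityComparison(
            community=k, members=reference.members(k),
            f_statistic=float(f), p_raw=float(p),
            p_bonferroni=min(1.0, float(p) * k_total),
            n_a=len(xa), n_b=len(xb),
            mean_a=float(xa.mean()), mean_b=float(xb.mean())))
    return results
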
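"""Consensus clustering of gene-set enrichment profiles.

Curated gene-set catalogues are redundant: many sets describe the same
underlying process and therefore show near-identical enrichment profiles
across components.  Resampling-based consensus clustering (Monti-style)
collapses this redundancy: each resampling subsamples sets (rows) and
components (columns), hierarchically clusters the sampled rows on
1 - Pearson distance with average linkage, and the consensus matrix
records how often two sets co-cluster when co-sampled.  The number of
clusters k is chosen by the relative change in the area under the CDF of
consensus values: the smallest k after which relative gains fall below a
threshold (default 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .enrichment import EnrichmentMatrix

logger = logging.getLogger(__name__)

__all__ = ["ConsensusClusteringResult", "consensus_cluster", "choose_k"]


@dataclass
class ConsensusClusteringResult:
    assignment: pd.Series
    consensus: dict[int, np.ndarray]
    cdf_area: dict[int, float]
    chosen_k: int
    assignments_per_k: dict[int, pd.Series] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)


def _pearson_distance(rows: np.ndarray) -> np.ndarray:
    """Condensed 1 - Pearson distance; rows constant -> correlation 0."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(rows)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, None)
    return squareform(dist, checks=False)


def _cdf_area(values: np.ndarray, grid_size: int = 100) -> float:
    """Mean of the empirical CDF on a fixed grid of points in [0, 1]."""
    grid = np.linspace(0.0, 1.0, grid_size)
    return float(np.mean(values[None, :] <= grid[:, None]))


def choose_k(cdf_area: Mapping[int, float], delta_threshold: float = 0.01) -> int:
    """Pick k by the relative change in CDF area.

    With areas A(k) for k = 2..maxK, the relative change is
    Delta(k) = (A(k) - A(k-1)) / A(k-1) for k >= 3 and Delta(2) = A(2).
    Returns the smallest k whose successor's relative change falls below
    the threshold, i.e. the last k before gains become negligible; the
    threshold comparison is inclusive up to floating-point rounding.  If no
    k qualifies, returns maxK with a warning.
    """
    ks = sorted(cdf_area)
    if len(ks) < 3:
        raise ValueError("need CDF areas for at least 3 values of k")
    if ks != list(range(ks[0], ks[-1] + 1)) or ks[0] != 2:
        raise ValueError("cdf_area must be indexed by consecutive k starting at 2")
    delta = {2: cdf_area[2]}
    for k in ks[1:]:
        prev = cdf_area[k - 1]
        gain = cdf_area[k] - prev
        delta[k] = gain / prev if prev > 0 else (0.0 if gain == 0 else np.inf)
    cutoff = delta_threshold * (1.0 + 1e-9)
    for k in ks[:-1]:
        if delta[k + 1] < cutoff:
            return k
    logger.warning(
        "relative CDF-area change never fell below %.3g; returning maxK=%d",
        delta_threshold, ks[-1],
    )
    return ks[-1]


def consensus_cluster(
    E: EnrichmentMatrix,
    max_k: int = 15,
    reps: int = 100,
    p_item: float = 0.8,
    p_feature: float = 0.8,
    seed: int = 0,
    delta_threshold: float = 0.01,
    linkage_method: str = "average",
    max_redraws: int = 100,
) -> ConsensusClusteringResult:
    """Monti-style consensus clustering of the sets x components Z matrix.

    Parameters mirror the reference procedure: ``p_item`` is the fraction
    of sets (rows) and ``p_feature`` the fraction of components (columns)
    drawn per resampling.  The published profile uses maxK = 150 and
    reps = 2000; the defaults here are desk-scale.
    """
    Z = E.z.to_numpy(dtype=float)
    n_sets, n_comp = Z.shape
    if n_sets < 3:
        raise ValueError("need at least 3 gene sets")
    if not 2 <= max_k < n_sets:
        raise ValueError("max_k must be in [2, n_sets)")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), n_sets, n_comp]))
    n_rows = int(np.ceil(p_item * n_sets))
    n_cols = int(np.ceil(p_feature * n_comp))

    ks = list(range(2, max_k + 1))
    co_sample = np.zeros((n_sets, n_sets))
    co_cluster = {k: np.zeros((n_sets, n_sets)) for k in ks}
    for _ in range(reps):
        for _attempt in range(max_redraws):
            idx = np.sort(rng.choice(n_sets, size=n_rows, replace=False))
            cols = np.sort(rng.choice(n_comp, size=n_cols, replace=False))
            sub = Z[np.ix_(idx, cols)]
            if np.unique(sub, axis=0).shape[0] >= 2:
                break
        else:
            raise RuntimeError("could not draw a resampling with 2 distinct rows")
        link = linkage(_pearson_distance(sub), method=linkage_method)
        co_sample[np.ix_(idx, idx)] += 1.0
        for k in ks:
            labels = fcluster(link, t=min(k, n_rows), criterion="maxclust")
            eq = labels[:, None] == labels[None, :]
            co_cluster[k][np.ix_(idx, idx)] += eq

    consensus: dict[int, np.ndarray] = {}
    cdf_area: dict[int, float] = {}
    assignments: dict[int, pd.Series] = {}
    iu = np.triu_indices(n_sets, k=1)
    never = co_sample == 0
    if never[iu].any():
        logger.warning(
            "%d set pairs were never co-sampled; their consensus is 0",
            int(never[iu].sum()),
        )
    for k in ks:
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(co_sample > 0, co_cluster[k] / np.maximum(co_sample, 1), 0.0)
        np.fill_diagonal(M, 1.0)
        M = (M + M.T) / 2.0
        consensus[k] = M
        cdf_area[k] = _cdf_area(M[iu])
        final = fcluster(
            linkage(squareform(np.clip(1.0 - M, 0.0, None), checks=False),
                    method=linkage_method),
            t=k, criterion="maxclust",
        )
        assignments[k] = pd.Series(final, index=E.set_ids, name="cluster")

    k_star = choose_k(cdf_area, delta_threshold)
    return ConsensusClusteringResult(
        assignment=assignments[k_star],
        consensus=consensus,
        cdf_area=cdf_area,
        chosen_k=k_star,
        assignments_per_k=assignments,
        parameters={
            "max_k": max_k, "reps": reps, "p_item": p_item, "p_feature": p_feature,
            "linkage": linkage_method, "distance": "1 - Pearson", "seed": seed,
            "delta_threshold": delta_threshold,
        },
    )
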
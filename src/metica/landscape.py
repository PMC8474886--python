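"""The metabolic transcriptional landscape: subtypes, variance attribution
and association screens.

* :func:`subtype_samples` clusters samples on 1 - Pearson correlation of
  their component activity profiles with Ward (ward.D2) linkage and sweeps
  the dendrogram cut height upward until the smallest cluster reaches a
  minimum size; the clusters at that height are the metabolic subtypes.
* :func:`explained_variance` attributes, per sample, the share of squared
  activity carried by each component; averaged within studies or tissue
  types it flags components whose activity is dominated by a single group
  (putative batch or tissue effects, default flag at 10%).
* :func:`associate` screens component activities against per-sample
  feature tables (drug IC50 panels, immune-cell fractions) with Spearman
  correlation on pairwise-complete observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .concordance import spearman_t
from .ica import MixingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SubtypeAssignment",
    "ExplainedVarianceSummary",
    "AssociationResult",
    "subtype_samples",
    "explained_variance",
    "associate",
    "subtype_medians",
]


@dataclass
class SubtypeAssignment:
    labels: pd.Series
    cut_height: float
    min_cluster_size: int
    linkage_matrix: np.ndarray

    @property
    def n_subtypes(self) -> int:
        return int(self.labels.nunique())


def _activities(M) -> pd.DataFrame:
    return M.activities if isinstance(M, MixingMatrix) else M


def subtype_samples(
    M,
    min_cluster_size: int = 50,
    sweep: tuple[float, float, float] = (0.0, 8.0, 0.2),
) -> SubtypeAssignment:
    """Cluster samples into metabolic subtypes.

    ``M`` is a mixing matrix (or plain activity DataFrame), typically
    restricted to the selected mTCs.  The dendrogram (Ward on 1 - Pearson)
    is cut at ascending heights ``sweep = (start, stop, step)``; the chosen
    height is the first at which the smallest cluster holds at least
    ``min_cluster_size`` samples.
    """
    A = _activities(M)
    n = len(A)
    if n < 2 * min_cluster_size:
        raise ValueError(f"need at least {2 * min_cluster_size} samples, got {n}")
    rows = A.to_numpy(dtype=float)
    if np.any(rows.std(axis=1) == 0):
        bad = A.index[rows.std(axis=1) == 0].tolist()
        raise ValueError(f"constant activity rows (correlation undefined): {bad[:10]}")
    corr = np.corrcoef(rows)
    dist = squareform(np.clip(1.0 - corr, 0.0, None), checks=False)
    link = linkage(dist, method="ward")  # Ward2 criterion on precomputed distances

    start, stop, step = sweep
    heights = np.arange(start, stop + step / 2, step)
    for h in heights:
        labels = fcluster(link, t=h, criterion="distance")
        smallest = int(np.bincount(labels)[1:].min())
        if smallest >= min_cluster_size:
            return SubtypeAssignment(
                labels=pd.Series(labels, index=A.index, name="subtype"),
                cut_height=float(h),
                min_cluster_size=min_cluster_size,
                linkage_matrix=link,
            )
    raise ValueError(
        f"no cut height in [{start}, {stop}] produced a smallest cluster of "
        f">= {min_cluster_size} samples; widen the sweep or lower the minimum"
    )


@dataclass
class ExplainedVarianceSummary:
    """Per-sample and per-group explained-variance fractions.

    ``per_sample`` rows sum to 1; ``per_group`` holds group means;
    ``max_group_ev`` is each component's highest group mean, flagged when
    it exceeds ``flag_threshold``.
    """

    per_sample: pd.DataFrame
    per_group: pd.DataFrame
    max_group_ev: pd.Series
    flagged: pd.Series
    flag_threshold: float
    excluded_samples: list[str] = field(default_factory=list)


def explained_variance(
    M, groups: pd.Series, flag_threshold: float = 0.10
) -> ExplainedVarianceSummary:
    """Share of each sample's squared activity carried by each component.

    EV(sample, component) = a^2 / sum_j a_j^2.  Samples with an all-zero
    activity row are excluded with a warning.  ``groups`` maps sample to
    study/tissue label; per-group means flag putative batch or tissue
    effects when a component's top group mean exceeds the threshold.
    """
    A = _activities(M)
    sq = A.to_numpy(dtype=float) ** 2
    total = sq.sum(axis=1)
    zero = total == 0
    excluded = A.index[zero].tolist()
    if excluded:
        logger.warning("%d all-zero activity rows excluded from EV", len(excluded))
    ev = pd.DataFrame(
        sq[~zero] / total[~zero, None], index=A.index[~zero], columns=A.columns
    )
    aligned = groups.reindex(ev.index)
    if aligned.isna().any():
        raise ValueError("groups must cover every sample with nonzero activity")
    per_group = ev.groupby(aligned).mean()
    max_ev = per_group.max(axis=0).rename("max_group_ev")
    return ExplainedVarianceSummary(
        per_sample=ev,
        per_group=per_group,
        max_group_ev=max_ev,
        flagged=(max_ev > flag_threshold).rename("flagged"),
        flag_threshold=flag_threshold,
        excluded_samples=excluded,
    )


@dataclass
class AssociationResult:
    """Long-format component x feature Spearman screen."""

    table: pd.DataFrame  # columns: component, feature, rho, p, n, flagged, reason
    threshold: float

    def flagged_pairs(self) -> pd.DataFrame:
        return self.table[self.table["flagged"]]


def associate(
    M, features: pd.DataFrame, threshold: float = 0.2, min_pairs: int = 4
) -> AssociationResult:
    """Spearman screen of every (component, feature) pair.

    Features may contain missing values; each cell uses the pairwise
    complete samples.  Cells with fewer than ``min_pairs`` complete pairs
    or a constant vector are recorded as undefined (NaN rho) and never
    flagged.  Pairs with |rho| strictly above ``threshold`` are flagged
    (drug screens conventionally use 0.2).
    """
    A = _activities(M)
    shared = A.index.intersection(features.index)
    if len(shared) == 0:
        raise ValueError("no shared samples between activities and features")
    A = A.loc[shared]
    F = features.loc[shared]
    records = []
    for comp in A.columns:
        a = A[comp].to_numpy(dtype=float)
        for feat in F.columns:
            f = F[feat].to_numpy(dtype=float)
            ok = np.isfinite(a) & np.isfinite(f)
            n = int(ok.sum())
            if n < min_pairs:
                records.append((comp, feat, np.nan, np.nan, n, False,
                                f"{n} complete pairs < {min_pairs}"))
                continue
            if np.ptp(a[ok]) == 0 or np.ptp(f[ok]) == 0:
                records.append((comp, feat, np.nan, np.nan, n, False,
                                "constant on complete pairs"))
                continue
            rho, p, _ = spearman_t(a[ok], f[ok])
            records.append((comp, feat, rho, p, n, abs(rho) > threshold, ""))
    table = pd.DataFrame(
        records, columns=["component", "feature", "rho", "p", "n", "flagged", "reason"]
    )
    return AssociationResult(table=table, threshold=threshold)


def subtype_medians(M, assignment: SubtypeAssignment) -> pd.DataFrame:
    """Median activity per (component, subtype): the subtype characterization."""
    A = _activities(M)
    return A.groupby(assignment.labels.reindex(A.index)).median()
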
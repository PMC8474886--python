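"""Consensus independent component analysis of expression matrices.

Bulk expression profiles are additive mixtures of transcriptional
footprints: gene-weight vectors of underlying regulatory factors, each
active to a different degree in each sample.  A single ICA run recovers
such footprints only up to run-to-run variability from its random
initialization, so we run the estimator many times, pool all estimated
components, cluster them across runs by absolute Pearson correlation of
their gene weights, and keep the clusters that recur in a sufficient
fraction of runs.  The sign-aligned cluster centroids are the consensus
transcriptional components (TCs); per-sample activity scores (the mixing
matrix) are obtained by least-squares projection of the centered data onto
the consensus weights.

Estimator: fixed-point negentropy maximization (log-cosh contrast) after
PCA whitening — scikit-learn's FastICA — applied to the genes x samples
matrix so that independence is sought across genes, giving heavy-tailed
gene-weight vectors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .formats import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentSet",
    "MixingMatrix",
    "decompose",
    "project_activities",
    "suggest_n_components",
]


def _standardize_columns(W: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd (population sd) columns."""
    mu = W.mean(axis=0, keepdims=True)
    sd = W.std(axis=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant component")
    return (W - mu) / sd


@dataclass
class ComponentSet:
    """Genes x components standardized weight matrix with stability scores.

    Each column has mean 0 and sd 1; the entry of largest magnitude in each
    column is positive (ICA signs are arbitrary, so a deterministic
    convention makes cross-dataset comparisons reproducible).  ``stability``
    is the fraction of consensus runs contributing to each component and is
    non-increasing in the reported component order.
    """

    weights: pd.DataFrame
    dataset_label: str
    stability: pd.Series

    def __post_init__(self) -> None:
        W = self.weights.to_numpy()
        if not np.allclose(W.mean(axis=0), 0.0, atol=1e-9):
            raise ValueError("component columns must have mean 0")
        if not np.allclose(W.std(axis=0), 1.0, atol=1e-9):
            raise ValueError("component columns must have sd 1")
        peaks = W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])]
        if np.any(peaks < 0):
            raise ValueError("sign convention violated: largest-|weight| entry negative")
        s = self.stability.to_numpy()
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("stability must be non-increasing in component order")
        if not self.stability.index.equals(self.weights.columns):
            raise ValueError("stability index must match component ids")

    @property
    def component_ids(self) -> pd.Index:
        return self.weights.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.weights.index


@dataclass
class MixingMatrix:
    """Samples x components activity scores paired with a ComponentSet."""

    activities: pd.DataFrame
    dataset_label: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.activities.to_numpy()).all():
            raise ValueError("activities must be finite")

    @property
    def sample_ids(self) -> pd.Index:
        return self.activities.index

    @property
    def component_ids(self) -> pd.Index:
        return self.activities.columns


def _apply_sign_convention(W: np.ndarray) -> np.ndarray:
    peaks = W[np.abs(W).argmax(axis=0), np.arange(W.shape[1])]
    return W * np.where(peaks < 0, -1.0, 1.0)


def decompose(
    X: ExpressionMatrix,
    n_components: int,
    n_runs: int = 25,
    stability_threshold: float = 0.5,
    seed: int = 0,
    cluster_corr: float = 0.9,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> tuple[ComponentSet, MixingMatrix]:
    """Consensus decomposition into at most ``n_components`` components.

    Runs FastICA ``n_runs`` times from seeded random initializations,
    greedily clusters the pooled standardized components at absolute
    Pearson correlation >= ``cluster_corr`` (sign-aligning members), and
    keeps clusters present in at least ``stability_threshold`` of the
    surviving runs, capped at ``n_components`` by stability.  Returns the
    consensus components and the least-squares mixing matrix.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    V = X.values.to_numpy(dtype=float)
    n_genes, n_samples = V.shape
    if not 2 <= n_components <= min(n_genes, n_samples):
        raise ValueError("n_components must be in [2, min(genes, samples)]")
    Xc = V - V.mean(axis=1, keepdims=True)
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds matrix rank {rank}")

    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs)
    estimates = []  # (run index, standardized weight vector)
    n_ok = 0
    for r, rs in enumerate(run_seeds):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                ica = FastICA(
                    n_components=n_components,
                    algorithm="parallel",
                    whiten="unit-variance",
                    fun="logcosh",
                    max_iter=max_iter,
                    tol=tol,
                    random_state=int(rs % (2**32 - 1)),
                )
                S = ica.fit_transform(Xc)  # genes x K
        except Exception as exc:  # noqa: BLE001 - a failed run is discarded
            logger.warning("ICA run %d failed and was discarded: %s", r, exc)
            continue
        n_ok += 1
        S = _standardize_columns(S)
        for k in range(S.shape[1]):
            estimates.append((r, S[:, k]))
    if n_ok < 2:
        raise RuntimeError(f"only {n_ok} ICA runs survived; need at least 2")

    # greedy centroid clustering of pooled run components
    cluster_sum: list[np.ndarray] = []   # running sums of sign-aligned members
    cluster_n: list[int] = []
    cluster_runs: list[set[int]] = []
    centroids: np.ndarray | None = None  # genes x n_clusters, standardized
    for r, s in estimates:
        joined = False
        if centroids is not None:
            corr = (centroids.T @ s) / n_genes
            best = int(np.argmax(np.abs(corr)))
            if abs(corr[best]) >= cluster_corr:
                aligned = s if corr[best] >= 0 else -s
                cluster_sum[best] += aligned
                cluster_n[best] += 1
                cluster_runs[best].add(r)
                centroids[:, best] = _standardize_columns(
                    (cluster_sum[best] / cluster_n[best])[:, None]
                )[:, 0]
                joined = True
        if not joined:
            cluster_sum.append(s.copy())
            cluster_n.append(1)
            cluster_runs.append({r})
            col = s[:, None]
            centroids = col.copy() if centroids is None else np.hstack([centroids, col])

    stability = np.array([len(rs) / n_ok for rs in cluster_runs])
    keep = np.flatnonzero(stability >= stability_threshold)
    # order: stability desc, then cluster size desc, then first-seen index
    order = sorted(keep, key=lambda i: (-stability[i], -cluster_n[i], i))
    order = order[:n_components]
    if not order:
        raise RuntimeError("no component cluster reached the stability threshold")

    W = np.column_stack(
        [_standardize_columns((cluster_sum[i] / cluster_n[i])[:, None])[:, 0] for i in order]
    )
    W = _apply_sign_convention(W)
    comp_ids = [f"{X.dataset_label}_TC{j + 1:03d}" for j in range(W.shape[1])]
    components = ComponentSet(
        weights=pd.DataFrame(W, index=X.gene_ids, columns=comp_ids),
        dataset_label=X.dataset_label,
        stability=pd.Series(stability[order], index=comp_ids, name="stability"),
    )

    coef, *_ = np.linalg.lstsq(W, Xc, rcond=None)
    mixing = MixingMatrix(
        activities=pd.DataFrame(coef.T, index=X.sample_ids, columns=comp_ids),
        dataset_label=X.dataset_label,
    )
    logger.info(
        "%s: %d/%d component clusters kept (threshold %.2f) from %d runs",
        X.dataset_label, len(order), len(stability), stability_threshold, n_ok,
    )
    return components, mixing


def project_activities(
    C: ComponentSet, X: ExpressionMatrix, min_overlap: float = 0.5
) -> MixingMatrix:
    """Least-squares activities of ``C``'s components in new samples.

    Profiles are restricted to the genes shared with the component set
    (at least ``min_overlap`` of the component genes must be present) and
    centered per sample before projection.  Because standardized weight
    columns have zero mean, the per-sample centering does not bias the
    coefficients.
    """
    shared = C.gene_ids.intersection(X.gene_ids)
    frac = len(shared) / len(C.gene_ids)
    logger.info("projection gene overlap: %.1f%% (%d genes)", 100 * frac, len(shared))
    if frac < min_overlap:
        raise ValueError(
            f"only {frac:.1%} of component genes present in data "
            f"(floor {min_overlap:.0%})"
        )
    W = C.weights.loc[shared].to_numpy()
    V = X.values.loc[shared].to_numpy(dtype=float)
    Vc = V - V.mean(axis=0, keepdims=True)  # center each sample profile
    coef, *_ = np.linalg.lstsq(W, Vc, rcond=None)
    return MixingMatrix(
        activities=pd.DataFrame(
            coef.T, index=X.sample_ids, columns=C.component_ids
        ),
        dataset_label=X.dataset_label,
    )


def suggest_n_components(X: ExpressionMatrix, variance_target: float = 0.8) -> int:
    """Smallest number of principal components reaching the variance target."""
    if not 0 < variance_target <= 1:
        raise ValueError("variance_target must be in (0, 1]")
    V = X.values.to_numpy(dtype=float)
    Xc = V - V.mean(axis=1, keepdims=True)
    sv = np.linalg.svd(Xc, compute_uv=False)
    frac = np.cumsum(sv**2) / np.sum(sv**2)
    return int(np.searchsorted(frac, variance_target) + 1)
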
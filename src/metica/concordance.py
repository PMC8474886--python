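"""Cross-dataset concordance of metabolic transcriptional components.

Two components from different datasets describe the same transcriptional
footprint when (a) their top genes (standardized |weight| > 3) overlap more
than chance predicts, and (b) the weights of the overlapping genes are
strongly rank-correlated.  The overlap null is a Monte-Carlo permutation:
draw two random gene sets of the observed sizes from the shared gene
universe and count how often their overlap reaches the observed one (the
hypergeometric upper tail is available as a fast exact alternative and is
proven equivalent by test).  A pair is concordant when |rho| > 0.5 with
Spearman p < 0.05 and overlap p < 0.05.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ica import ComponentSet
from .selection import MTCSelection

logger = logging.getLogger(__name__)

__all__ = [
    "ConcordancePair",
    "SpearmanResult",
    "top_genes",
    "overlap_pvalue",
    "hypergeom_overlap_pvalue",
    "spearman_t",
    "call_concordance",
    "summarize_concordance",
]


def top_genes(C, component: str, threshold: float = 3.0) -> set[str]:
    """Genes whose standardized absolute weight strictly exceeds threshold.

    ``C`` is a :class:`~metica.ica.ComponentSet` or a plain genes x
    components weight DataFrame.
    """
    W = C.weights if isinstance(C, ComponentSet) else C
    if component not in W.columns:
        raise KeyError(f"unknown component {component!r}")
    w = W[component]
    return set(w.index[w.abs() > threshold])


def overlap_pvalue(
    n_top_a: int,
    n_top_b: int,
    n_overlap: int,
    universe_size: int,
    n_perm: int = 10_000,
    seed: int = 0,
    chunk: int = 2000,
) -> float:
    """Monte-Carlo p-value for the observed top-gene overlap.

    Per permutation, two gene sets of sizes ``n_top_a`` and ``n_top_b`` are
    drawn independently and without replacement from a universe of
    ``universe_size`` identifiers; p = (#{overlap >= observed} + 1) /
    (n_perm + 1), which cannot be zero.
    """
    if not (0 <= n_top_a <= universe_size and 0 <= n_top_b <= universe_size):
        raise ValueError("set sizes must be within the universe")
    if not 0 <= n_overlap <= min(n_top_a, n_top_b):
        raise ValueError("impossible overlap for the given set sizes")
    if n_overlap == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # rank of n smallest random keys per row = a uniform subset
        keys_a = rng.random((m, universe_size))
        keys_b = rng.random((m, universe_size))
        in_a = np.argpartition(keys_a, n_top_a - 1, axis=1)[:, :n_top_a] if n_top_a else None
        in_b = np.argpartition(keys_b, n_top_b - 1, axis=1)[:, :n_top_b] if n_top_b else None
        mask_a = np.zeros((m, universe_size), dtype=bool)
        mask_b = np.zeros((m, universe_size), dtype=bool)
        np.put_along_axis(mask_a, in_a, True, axis=1)
        np.put_along_axis(mask_b, in_b, True, axis=1)
        hits += int(((mask_a & mask_b).sum(axis=1) >= n_overlap).sum())
        done += m
    return (hits + 1) / (n_perm + 1)


def hypergeom_overlap_pvalue(
    n_top_a: int, n_top_b: int, n_overlap: int, universe_size: int
) -> float:
    """Exact upper-tail overlap probability (hypergeometric)."""
    if not (0 <= n_top_a <= universe_size and 0 <= n_top_b <= universe_size):
        raise ValueError("set sizes must be within the universe")
    if not 0 <= n_overlap <= min(n_top_a, n_top_b):
        raise ValueError("impossible overlap for the given set sizes")
    return float(stats.hypergeom.sf(n_overlap - 1, universe_size, n_top_a, n_top_b))


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    exact_limit: bool  # |rho| = 1: p below the t-approximation's reach


def spearman_t(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman correlation with the t-distribution p-value approximation.

    rho is the Pearson correlation of average ranks; the two-sided p comes
    from t = rho * sqrt((n-2)/(1-rho^2)) with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0 - 1e-13:
        return SpearmanResult(float(np.sign(rho)), 0.0, True)
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0), False)


@dataclass
class ConcordancePair:
    """Full record of one cross-dataset component comparison."""

    mtc_a: str
    mtc_b: str
    dataset_a: str
    dataset_b: str
    n_top_a: int
    n_top_b: int
    n_overlap: int
    overlap_p: float
    rho: float
    rho_p: float
    concordant: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.n_overlap > min(self.n_top_a, self.n_top_b):
            raise ValueError("overlap exceeds the smaller top-gene set")


def _pair_seed(seed: int, id_a: str, id_b: str) -> int:
    """Order-independent per-pair seed so (A,B) and (B,A) agree exactly."""
    key = "|".join(sorted([id_a, id_b]))
    return (int(seed) * 2654435761 + zlib.crc32(key.encode())) % (2**31 - 1)


def call_concordance(
    C_a: ComponentSet,
    C_b: ComponentSet,
    mtcs_a: MTCSelection,
    mtcs_b: MTCSelection,
    seed: int = 0,
    weight_threshold: float = 3.0,
    rho_threshold: float = 0.5,
    p_threshold: float = 0.05,
    n_perm: int = 10_000,
    overlap_method: str = "permutation",
    min_overlap_genes: int = 4,
) -> list[ConcordancePair]:
    """Evaluate every cross pair of selected components.

    Weights are restricted to the intersection of the two datasets' gene
    universes (overlap is only observable on shared identifiers); top genes
    are those with standardized |weight| > ``weight_threshold`` among the
    shared genes.  rho is computed on the overlapping top genes' weights.
    Pairs with fewer than ``min_overlap_genes`` overlapping genes are
    recorded as non-concordant with a reason.
    """
    if overlap_method not in ("permutation", "exact"):
        raise ValueError("overlap_method must be 'permutation' or 'exact'")
    shared = C_a.gene_ids.intersection(C_b.gene_ids)
    if len(shared) == 0:
        raise ValueError("the two component sets share no genes")
    Wa = C_a.weights.loc[shared]
    Wb = C_b.weights.loc[shared]
    universe = len(shared)

    pairs: list[ConcordancePair] = []
    for a in mtcs_a.mtc_ids:
        wa = Wa[a]
        ta = set(wa.index[wa.abs() > weight_threshold])
        for b in mtcs_b.mtc_ids:
            wb = Wb[b]
            tb = set(wb.index[wb.abs() > weight_threshold])
            ov = sorted(ta & tb)
            n_ov = len(ov)
            if overlap_method == "exact":
                p_ov = hypergeom_overlap_pvalue(len(ta), len(tb), n_ov, universe)
            else:
                p_ov = overlap_pvalue(
                    len(ta), len(tb), n_ov, universe,
                    n_perm=n_perm, seed=_pair_seed(seed, a, b),
                )
            if n_ov < min_overlap_genes:
                pairs.append(ConcordancePair(
                    mtc_a=a, mtc_b=b,
                    dataset_a=C_a.dataset_label, dataset_b=C_b.dataset_label,
                    n_top_a=len(ta), n_top_b=len(tb), n_overlap=n_ov,
                    overlap_p=p_ov, rho=float("nan"), rho_p=1.0,
                    concordant=False,
                    reason=f"overlap {n_ov} < {min_overlap_genes}: rho undefined",
                ))
                continue
            rho, rho_p, _ = spearman_t(wa.loc[ov].to_numpy(), wb.loc[ov].to_numpy())
            verdict = (
                abs(rho) > rho_threshold
                and rho_p < p_threshold
                and p_ov < p_threshold
            )
            pairs.append(ConcordancePair(
                mtc_a=a, mtc_b=b,
                dataset_a=C_a.dataset_label, dataset_b=C_b.dataset_label,
                n_top_a=len(ta), n_top_b=len(tb), n_overlap=n_ov,
                overlap_p=p_ov, rho=rho, rho_p=rho_p, concordant=verdict,
            ))
    return pairs


def summarize_concordance(pairs: Sequence[ConcordancePair]) -> dict:
    """Per-dataset robustness summary over a list of evaluated pairs.

    Returns, per dataset, the fraction of its components concordant with at
    least one component of another dataset, and the count of components
    concordant with at least one component in *every* other dataset.
    """
    datasets: dict[str, set[str]] = {}
    partners: dict[tuple[str, str], set[str]] = {}
    for p in pairs:
        datasets.setdefault(p.dataset_a, set()).add(p.mtc_a)
        datasets.setdefault(p.dataset_b, set()).add(p.mtc_b)
        if p.concordant:
            partners.setdefault((p.dataset_a, p.mtc_a), set()).add(p.dataset_b)
            partners.setdefault((p.dataset_b, p.mtc_b), set()).add(p.dataset_a)
    fraction_any: dict[str, float] = {}
    count_all: dict[str, int] = {}
    for ds, comps in datasets.items():
        others = set(datasets) - {ds}
        hit_any = sum(1 for c in comps if partners.get((ds, c)))
        hit_all = sum(1 for c in comps if others and partners.get((ds, c), set()) >= others)
        fraction_any[ds] = hit_any / len(comps) if comps else float("nan")
        count_all[ds] = hit_all
    return {"fraction_concordant_any": fraction_any, "count_concordant_all": count_all}


def pairs_to_frame(pairs: Sequence[ConcordancePair]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in pairs])
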
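"""Gene-set enrichment of component weights via the Welch t -> Z statistic.

A component is enriched for a gene set when the weights of the member genes
differ systematically from the weights of all other genes.  The two groups
are compared with a two-sample Welch t-test (unequal variances); the t
statistic is transformed to a signed Z-score through its two-sided p-value,

    z = sign(t) * Phi^{-1}(1 - p/2),

so that scores are comparable across gene sets of different sizes.  |z| is
clamped at 40 to keep p-values below double precision representable while
preserving ordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .formats import GeneSetCollection
from .ica import ComponentSet

logger = logging.getLogger(__name__)

__all__ = ["WelchResult", "EnrichmentMatrix", "welch_z", "enrich_all"]

Z_CLAMP = 40.0


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float
    z: float


@dataclass
class EnrichmentMatrix:
    """Gene sets x components Z-scores with per-set membership counts."""

    z: pd.DataFrame
    n_in: pd.Series
    n_out: pd.Series
    skipped: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.z.to_numpy()).all():
            raise ValueError("enrichment z-scores must be finite")

    @property
    def set_ids(self) -> pd.Index:
        return self.z.index

    @property
    def component_ids(self) -> pd.Index:
        return self.z.columns


def _welch_arrays(
    w_in: np.ndarray, w_out: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t, df, two-sided p and z over trailing axes."""
    n1, n2 = w_in.shape[0], w_out.shape[0]
    m1, m2 = w_in.mean(axis=0), w_out.mean(axis=0)
    v1, v2 = w_in.var(axis=0, ddof=1), w_out.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    diff = m1 - m2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se2 > 0, diff / np.sqrt(se2), np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
        df = np.where(
            se2 > 0,
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)),
            n1 + n2 - 2,
        )
    finite = np.isfinite(t)
    p = np.ones_like(np.atleast_1d(t), dtype=float)
    tt = np.atleast_1d(t)
    dd = np.atleast_1d(df)
    p[np.atleast_1d(finite)] = 2.0 * stats.t.sf(
        np.abs(tt[np.atleast_1d(finite)]), dd[np.atleast_1d(finite)]
    )
    p[~np.atleast_1d(finite)] = 0.0
    with np.errstate(divide="ignore"):
        z = np.sign(tt) * stats.norm.isf(p / 2.0)
    z = np.clip(np.nan_to_num(z, nan=0.0, posinf=Z_CLAMP, neginf=-Z_CLAMP), -Z_CLAMP, Z_CLAMP)
    return t, df, p.reshape(np.shape(t)), z.reshape(np.shape(t))


def welch_z(weights: pd.Series, members: Iterable[str]) -> WelchResult:
    """Welch test of member-gene weights against all other genes.

    ``weights`` is a per-gene real vector indexed by gene ID; ``members``
    the gene-set member IDs.  Members absent from the weight index are
    ignored.  Requires at least 2 genes on each side.
    """
    members = set(members)
    mask = weights.index.isin(members)
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 2 or n_out < 2:
        raise ValueError(
            f"need >= 2 genes on each side (got {n_in} in-set, {n_out} out-set)"
        )
    w = weights.to_numpy(dtype=float)
    t, df, p, z = _welch_arrays(w[mask][:, None], w[~mask][:, None])
    return WelchResult(float(t[0]), float(df[0]), float(p[0]), float(z[0]))


def enrich_all(C: ComponentSet, G: GeneSetCollection) -> EnrichmentMatrix:
    """Score every gene set against every component of ``C``.

    The gene universe is the component set's gene index; sets with fewer
    than 2 member or 2 non-member genes in the universe are skipped with a
    logged reason.  Raises if no set intersects the universe usefully.
    """
    W = C.weights.to_numpy(dtype=float)
    universe = C.gene_ids
    rows, n_ins, n_outs, kept = [], [], [], []
    skipped: dict[str, str] = {}
    for name, genes in G:
        mask = universe.isin(genes)
        n_in = int(mask.sum())
        n_out = len(universe) - n_in
        absent = len(genes) - n_in
        if absent:
            logger.debug("set %s: %d member genes absent from universe", name, absent)
        if n_in < 2 or n_out < 2:
            skipped[name] = f"{n_in} member genes in universe, {n_out} outside"
            continue
        _, _, _, z = _welch_arrays(W[mask], W[~mask])
        rows.append(z)
        n_ins.append(n_in)
        n_outs.append(n_out)
        kept.append(name)
    if not kept:
        raise ValueError("no gene set has a usable intersection with the gene universe")
    if skipped:
        logger.info("enrichment skipped %d/%d sets", len(skipped), len(G))
    return EnrichmentMatrix(
        z=pd.DataFrame(np.vstack(rows), index=kept, columns=C.component_ids),
        n_in=pd.Series(n_ins, index=kept, name="n_in"),
        n_out=pd.Series(n_outs, index=kept, name="n_out"),
        skipped=skipped,
    )
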
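"""Selection of metabolic transcriptional components (mTCs).

Given the enrichment matrix and a clustering of gene sets, two top-3 rules
nominate components per cluster:

* rule A (``max_single_set``): the three components with the highest
  absolute enrichment score for any single gene set in the cluster;
* rule B (``max_cluster_mean``): the three components with the highest
  absolute mean enrichment score over all the cluster's gene sets.

The union over clusters and rules, deduplicated, is the mTC selection.
Rule B uses the absolute value of the signed mean by default, so a
component enriched in opposite directions for different sets of a cluster
can be picked by rule A yet excluded by rule B; the mean-of-absolutes
reading is available via ``rule_b="mean_of_abs"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .enrichment import EnrichmentMatrix

__all__ = ["MTCSelection", "select_mtcs", "count_enriched_sets"]


@dataclass
class MTCSelection:
    """Selected component ids with per-selection provenance.

    ``provenance[mtc]`` lists (cluster, rule, score) tuples; every mTC has
    at least one entry and the selection size is bounded by 6 clusters'
    worth of picks.
    """

    mtc_ids: list[str]
    provenance: dict[str, list[tuple[int, str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mtc in self.mtc_ids:
            if not self.provenance.get(mtc):
                raise ValueError(f"mTC {mtc!r} has no provenance entry")


def select_mtcs(
    E: EnrichmentMatrix,
    assignment: pd.Series,
    rule_b: str = "abs_of_mean",
    top_n: int = 3,
) -> MTCSelection:
    """Apply the two per-cluster top-3 rules and union the picks."""
    if rule_b not in ("abs_of_mean", "mean_of_abs"):
        raise ValueError("rule_b must be 'abs_of_mean' or 'mean_of_abs'")
    missing = E.set_ids.difference(assignment.index)
    if len(missing):
        raise ValueError(f"sets without cluster assignment: {list(missing)[:10]}")
    provenance: dict[str, list[tuple[int, str, float]]] = {}
    for cluster in sorted(assignment.unique()):
        sets = assignment.index[assignment == cluster].intersection(E.set_ids)
        if len(sets) == 0:
            raise ValueError(f"cluster {cluster!r} has no sets in the enrichment matrix")
        zc = E.z.loc[sets]
        score_a = zc.abs().max(axis=0)
        if rule_b == "abs_of_mean":
            score_b = zc.mean(axis=0).abs()
        else:
            score_b = zc.abs().mean(axis=0)
        for rule, scores in (("max_single_set", score_a), ("max_cluster_mean", score_b)):
            picks = sorted(scores.index, key=lambda c: (-scores[c], str(c)))[:top_n]
            for comp in picks:
                provenance.setdefault(str(comp), []).append(
                    (cluster, rule, float(scores[comp]))
                )
    mtc_ids = sorted(provenance)
    return MTCSelection(mtc_ids=mtc_ids, provenance=provenance)


def count_enriched_sets(E: EnrichmentMatrix, threshold: float = 3.0) -> pd.Series:
    """Per component, the number of gene sets with |z| strictly above threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return (E.z.abs() > threshold).sum(axis=0).rename("n_enriched_sets")
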
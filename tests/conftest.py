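"""Shared fixtures: the default synthetic compendium and its decomposition.

The heavy objects (consensus-ICA decompositions, enrichment matrices) are
session-scoped so the whole suite pays for them once.
"""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from metica import (
    decompose,
    default_config,
    enrich_all,
    generate_all,
    select_mtcs,
)
from metica.enrichment import EnrichmentMatrix
from metica.setcluster import consensus_cluster

DECOMPOSE_SEED = 11  # fixed decomposition seed used throughout the suite


def match_components(truth, dataset_index, components):
    """Map each planted source to its best-matching component.

    Returns {source index: (component id, |Pearson| of gene weights)}.
    """
    S = truth.true_sources[dataset_index]
    Sz = (S - S.mean(axis=0)) / S.std(axis=0)
    W = components.weights.to_numpy()
    corr = np.abs(Sz.T @ W) / S.shape[0]
    return {
        k: (str(components.component_ids[int(corr[k].argmax())]), float(corr[k].max()))
        for k in range(S.shape[1])
    }


@pytest.fixture(scope="session")
def matcher():
    return match_components


@pytest.fixture(scope="session")
def default_fixture():
    """Default compendium: 2000 genes, 300+250 samples, 8 sources, 4 shared."""
    cfg = default_config()
    datasets, gene_sets, drugs, immune, truth = generate_all(cfg)
    return SimpleNamespace(
        config=cfg, datasets=datasets, gene_sets=gene_sets,
        drugs=drugs, immune=immune, truth=truth,
    )


@pytest.fixture(scope="session")
def decomposition(default_fixture):
    """Consensus decomposition of both default datasets (K=12, R=25)."""
    components, mixings = [], []
    for X in default_fixture.datasets:
        C, M = decompose(X, n_components=12, n_runs=25, seed=DECOMPOSE_SEED)
        components.append(C)
        mixings.append(M)
    return SimpleNamespace(components=components, mixings=mixings)


@pytest.fixture(scope="session")
def enrichments(default_fixture, decomposition):
    per_dataset = [
        enrich_all(C, default_fixture.gene_sets) for C in decomposition.components
    ]
    joint = EnrichmentMatrix(
        z=pd.concat([E.z for E in per_dataset], axis=1),
        n_in=per_dataset[0].n_in,
        n_out=per_dataset[0].n_out,
    )
    return SimpleNamespace(per_dataset=per_dataset, joint=joint)


@pytest.fixture(scope="session")
def geneset_clusters(enrichments):
    return consensus_cluster(enrichments.joint, max_k=15, reps=100, seed=3)


@pytest.fixture(scope="session")
def selections(enrichments, geneset_clusters):
    return [
        select_mtcs(E, geneset_clusters.assignment) for E in enrichments.per_dataset
    ]
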
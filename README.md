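# metica

Consensus independent component analysis of bulk expression compendia:
metabolic transcriptional components, cross-dataset concordance, and
metabolic subtyping.

## The problem

Bulk expression profiles of tumor biopsies average over every cell in the
sample — cancer cells, immune and stromal cells of the microenvironment —
plus experimental artifacts. The transcriptional footprint of a metabolic
process (glycolysis under hypoxia, glutathione-mediated drug
detoxification, oxidative phosphorylation, ...) is therefore often buried
under stronger signals. `metica` implements the decomposition-first
strategy for recovering such footprints from large compendia and turning
them into a queryable "metabolic landscape":

1. **Consensus ICA (c-ICA).** Each dataset's genes × samples matrix `X` is
   modeled as an additive mixture `X ≈ W Aᵀ`, where the columns of `W`
   (genes × K) are statistically independent transcriptional components
   (TCs) — standardized gene-weight vectors — and `A` (samples × K) is the
   mixing matrix of per-sample activity scores. FastICA (log-cosh
   negentropy after PCA whitening) is run R times from random
   initializations; pooled estimates are clustered across runs at
   |Pearson| ≥ 0.9, and clusters recurring in at least half the runs
   become consensus components. Activities are least-squares projections,
   so components can also be projected onto new samples.
2. **Metabolic enrichment.** Every component is scored against every
   metabolic gene set with a two-sample Welch t-test (member vs.
   non-member gene weights), transformed to a signed Z-score,
   `z = sign(t)·Φ⁻¹(1 − p/2)`, comparable across sets of different sizes.
3. **Gene-set redundancy collapse.** Monti-style consensus clustering
   (resampled hierarchical clustering, 1 − Pearson distance, average
   linkage) groups redundant gene sets by their enrichment profiles; the
   cluster count k is chosen where the relative gain in area under the
   consensus CDF falls below a threshold (default 0.01).
4. **mTC selection.** Per gene-set cluster, the three TCs with the highest
   absolute enrichment for any single set, and the three with the highest
   absolute mean enrichment over the cluster, are nominated as metabolic
   TCs (mTCs).
5. **Cross-dataset concordance.** Two mTCs from different datasets are
   concordant when their top genes (|weight| > 3) overlap more than a
   10,000-draw permutation null predicts (p < 0.05) and the overlapping
   weights are rank-correlated with |ρ| > 0.5 at p < 0.05 (Spearman,
   t-approximation).
6. **The landscape.** Samples are clustered into metabolic subtypes (Ward
   ward.D2 on 1 − correlation of mTC activities, dendrogram cut at the
   first height where the smallest cluster reaches a minimum size);
   per-sample explained variance `a²ₖ/Σⱼa²ⱼ` is averaged per study/tissue
   to flag batch- or tissue-dominated components; and activities are
   screened against drug IC50 panels and immune-cell fractions with
   Spearman correlation (drug flag at |ρ| > 0.2).

Every stage is exercisable on a synthetic multi-dataset compendium with
planted sources, gene-set blocks, sample groups, and drug/immune targets,
so each result can be checked against exact ground truth.

## Worked example

```python
from metica import (default_config, generate_all, decompose, enrich_all,
                    select_mtcs, call_concordance, summarize_concordance,
                    subtype_samples, consensus_cluster)
from metica.enrichment import EnrichmentMatrix
import pandas as pd

cfg = default_config()                      # 2000 genes, 300+250 samples, 8 sources
datasets, gene_sets, drugs, immune, truth = generate_all(cfg)

components, mixings = [], []
for X in datasets:
    C, M = decompose(X, n_components=12, n_runs=25, seed=11)
    components.append(C); mixings.append(M)
    print(f"{X.dataset_label}: {C.weights.shape[1]} consensus components, "
          f"median stability {C.stability.median():.2f}")

enr = [enrich_all(C, gene_sets) for C in components]
joint = EnrichmentMatrix(z=pd.concat([E.z for E in enr], axis=1),
                         n_in=enr[0].n_in, n_out=enr[0].n_out)
clusters = consensus_cluster(joint, max_k=15, reps=100, seed=3)
print(f"gene-set clusters: k = {clusters.chosen_k}")

sels = [select_mtcs(E, clusters.assignment) for E in enr]
print(f"mTCs selected: {len(sels[0].mtc_ids)} (DS0), {len(sels[1].mtc_ids)} (DS1)")

pairs = call_concordance(components[0], components[1], sels[0], sels[1],
                         seed=17, n_perm=10_000)
print(summarize_concordance(pairs))

st = subtype_samples(mixings[0].activities, min_cluster_size=20)
print(f"DS0: {st.n_subtypes} metabolic subtypes at cut height {st.cut_height:.1f}")
```

prints

```
DS0: 12 consensus components, median stability 1.00
DS1: 12 consensus components, median stability 1.00
gene-set clusters: k = 9
mTCs selected: 12 (DS0), 11 (DS1)
{'fraction_concordant_any': {'DS0': 0.3333333333333333, 'DS1': 0.36363636363636365}, 'count_concordant_all': {'DS0': 4, 'DS1': 4}}
DS0: 5 metabolic subtypes at cut height 0.8
```

Reading the numbers: the two synthetic datasets share exactly 4 of their
8 planted sources, and the concordance caller finds exactly those 4 mTCs
per dataset robust across both datasets (`count_concordant_all = 4`) while
every dataset-unique pair stays below the concordance thresholds. The 8
planted sources are all among the selected mTCs; the selection also
carries the deterministic extra components that K = 12 > 8 sources forces
(see the methods note). The 5 subtypes at the first qualifying cut height
split one of the 4 planted sample groups; adjusted Rand index against the
planted groups is 0.92.

## Command line

The same stages are available as `metica
simulate|decompose|enrich|cluster-genesets|select-mtc|concordance|subtype|explained-variance|associate|run-all`;
`run-all` executes the whole pipeline from one YAML config and writes a
JSON run manifest with per-stage seeds and SHA-256 checksums of every
input and output, so a re-run under the same seed is verifiably
bit-identical (`metica.pipeline.verify_outputs`).

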
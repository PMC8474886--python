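"""Multi-dataset synthetic expression compendia with planted ground truth.

The generator emulates the structure of a multi-compendium study: several
"datasets" (different cohorts/platforms) share a subset of latent
transcriptional sources, each source has a heavy-tailed block of top genes,
a gene-set catalogue carries blocks of redundant sets drawn from those top
genes, samples fall into groups with shifted source activity, and optional
drug-response (IC50) and immune-fraction tables are monotone functions of a
target source's activity.  Every downstream stage of the pipeline can
therefore be scored against an exact planted truth.

Model
-----
For dataset ``d`` with ``n_d`` samples, ``G`` genes and ``K`` sources:

    X_d = S_d @ M_d.T + E_d

where ``S_d`` (G x K) holds spike-and-slab gene weights (slab: normal
sd 4 on a top-gene block of ``top_gene_fraction * G`` genes; spike: normal
sd 0.5 elsewhere), ``M_d`` (n_d x K) holds standard-normal activities with
a ``group_activity_shift`` added on each sample group's own source, and
``E_d`` is i.i.d. Gaussian noise with sd ``noise_sd``.  The first
``n_shared_sources`` columns of ``S_d`` are identical in every dataset;
the rest are drawn independently per dataset.

Each dataset draws from its own pseudo-random stream derived from the
master seed, so adding a dataset never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from scipy.linalg import hadamard

from .formats import ExpressionMatrix, GeneSetCollection

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "generate_compendium",
    "generate_gene_sets",
    "generate_response_tables",
    "generate_all",
]

# stream tags for per-purpose random streams derived from the master seed
_STREAM_SHARED = 0
_STREAM_DATASET = 100  # + dataset index
_STREAM_GENE_SETS = 200
_STREAM_DRUGS = 300
_STREAM_IMMUNE = 400


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic compendium; defaults are the study conditions."""

    n_genes: int = 2000
    n_samples_per_dataset: tuple[int, ...] = (300, 250)
    n_sources: int = 8
    n_shared_sources: int = 4
    n_metabolic_sources: int = 8
    top_gene_fraction: float = 0.02
    noise_sd: float = 0.5
    n_gene_sets: int = 64
    sets_per_block: int = 8
    genes_per_set: int = 20
    set_signal_fraction: float = 0.8
    n_sample_groups: int = 4
    group_activity_shift: float = 3.0
    n_drugs: int = 12
    n_null_drugs: int = 4
    drug_noise_sd: float = 0.5
    n_immune_types: int = 6
    immune_base: float = 0.12
    immune_effect: float = 0.04
    immune_noise_sd: float = 0.02
    seed: int = 7

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if len(self.n_samples_per_dataset) == 0 or any(
            n <= 0 for n in self.n_samples_per_dataset
        ):
            raise ValueError("n_samples_per_dataset must be non-empty positive integers")
        if self.n_sources <= 0:
            raise ValueError("n_sources must be positive")
        if self.n_shared_sources > self.n_sources or self.n_shared_sources < 0:
            raise ValueError("n_shared_sources must be in [0, n_sources]")
        if not (0 <= self.n_metabolic_sources <= self.n_sources):
            raise ValueError("n_metabolic_sources must be in [0, n_sources]")
        if not 0 < self.top_gene_fraction < 1:
            raise ValueError("top_gene_fraction must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.genes_per_set > self.n_genes:
            raise ValueError("genes_per_set exceeds n_genes")
        if self.n_gene_sets < self.n_metabolic_sources * self.sets_per_block:
            raise ValueError(
                "n_gene_sets too small for n_metabolic_sources blocks of sets_per_block"
            )
        if not 0 < self.set_signal_fraction <= 1:
            raise ValueError("set_signal_fraction must be in (0, 1]")
        if self.n_sample_groups <= 0:
            raise ValueError("n_sample_groups must be positive")
        if self.n_sample_groups > self.n_sources:
            raise ValueError("n_sample_groups must not exceed n_sources")
        if self.n_drugs < 0 or self.n_immune_types < 0 or self.n_null_drugs < 0:
            raise ValueError("table sizes must be non-negative")
        if self.n_null_drugs > self.n_drugs:
            raise ValueError("n_null_drugs must not exceed n_drugs")

    @property
    def n_top_genes(self) -> int:
        return max(1, round(self.top_gene_fraction * self.n_genes))


def default_config(**overrides) -> SyntheticConfig:
    """The default synthetic compendium (seed 7, 2000 genes, 300+250 samples)."""
    return SyntheticConfig(**overrides) if overrides else SyntheticConfig()


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated compendium.

    ``true_sources[d]`` and ``true_mixing[d]`` reconstruct dataset ``d``
    exactly (minus noise); ``top_gene_indices[d][k]`` holds the slab block
    of source ``k`` in dataset ``d``.  Gene-set blocks are planted from
    dataset 0's top-gene blocks of the metabolic sources.
    """

    gene_ids: list[str]
    source_ids: list[str]
    true_sources: list[np.ndarray]
    true_mixing: list[np.ndarray]
    top_gene_indices: list[np.ndarray]
    shared_source_ids: list[int]
    metabolic_source_ids: list[int]
    group_labels: list[np.ndarray]
    sample_ids: list[list[str]]
    dataset_labels: list[str]
    drug_target_map: dict[str, tuple[int | None, int]] = field(default_factory=dict)
    immune_target_map: dict[str, tuple[int, int]] = field(default_factory=dict)
    gene_set_blocks: dict[str, int] = field(default_factory=dict)

    def top_gene_ids(self, source: int, dataset: int = 0) -> list[str]:
        return [self.gene_ids[i] for i in self.top_gene_indices[dataset][source]]


def _rng(config: SyntheticConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), int(tag)]))


def _group_sign_patterns(n_groups: int, n_sources: int) -> np.ndarray:
    """Orthogonal +-1 activity signatures, one per sample group.

    Rows 1..n_groups of a Hadamard matrix (row 0, all ones, is skipped so
    signatures are balanced across sources).  Groups of samples are shifted
    by ``group_activity_shift`` times their signature, giving each group a
    distinct activity profile whose pairwise correlations vanish.
    """
    m = 1
    while m < max(n_sources, n_groups + 1):
        m *= 2
    H = hadamard(m)
    return H[1 : n_groups + 1, :n_sources].astype(float)


def _draw_source(rng: np.random.Generator, n_genes: int, n_top: int):
    """Spike-and-slab weight vector; returns (weights, top indices)."""
    w = rng.normal(0.0, 0.5, size=n_genes)
    top = rng.choice(n_genes, size=n_top, replace=False)
    w[top] = rng.normal(0.0, 4.0, size=n_top)
    return w, np.sort(top)


def generate_compendium(
    config: SyntheticConfig,
) -> tuple[list[ExpressionMatrix], SyntheticTruth]:
    """Generate one expression matrix per dataset plus the planted truth."""
    G, K = config.n_genes, config.n_sources
    n_top = config.n_top_genes
    gene_ids = [f"G{i:05d}" for i in range(G)]
    source_ids = [f"SRC{k}" for k in range(K)]

    rng_shared = _rng(config, _STREAM_SHARED)
    shared_cols, shared_tops = [], []
    for _ in range(config.n_shared_sources):
        w, top = _draw_source(rng_shared, G, n_top)
        shared_cols.append(w)
        shared_tops.append(top)

    datasets: list[ExpressionMatrix] = []
    true_sources, true_mixing, top_indices = [], [], []
    group_labels, sample_ids_all, dataset_labels = [], [], []
    for d, n_samples in enumerate(config.n_samples_per_dataset):
        rng_d = _rng(config, _STREAM_DATASET + d)
        cols = [w.copy() for w in shared_cols]
        tops = [t.copy() for t in shared_tops]
        for _ in range(config.n_shared_sources, K):
            w, top = _draw_source(rng_d, G, n_top)
            cols.append(w)
            tops.append(top)
        S = np.column_stack(cols)  # genes x sources

        M = rng_d.normal(0.0, 1.0, size=(n_samples, K))
        labels = (np.arange(n_samples) * config.n_sample_groups) // n_samples
        patterns = _group_sign_patterns(config.n_sample_groups, K)
        for g in range(config.n_sample_groups):
            M[labels == g] += config.group_activity_shift * patterns[g]

        X = S @ M.T
        if config.noise_sd > 0:
            X = X + rng_d.normal(0.0, config.noise_sd, size=X.shape)

        label = f"DS{d}"
        samples = [f"{label}_s{i:04d}" for i in range(n_samples)]
        datasets.append(
            ExpressionMatrix(
                values=pd.DataFrame(X, index=gene_ids, columns=samples),
                dataset_label=label,
            )
        )
        true_sources.append(S)
        true_mixing.append(M)
        top_indices.append(np.array(tops))
        group_labels.append(labels)
        sample_ids_all.append(samples)
        dataset_labels.append(label)

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        source_ids=source_ids,
        true_sources=true_sources,
        true_mixing=true_mixing,
        top_gene_indices=top_indices,
        shared_source_ids=list(range(config.n_shared_sources)),
        metabolic_source_ids=list(range(config.n_metabolic_sources)),
        group_labels=group_labels,
        sample_ids=sample_ids_all,
        dataset_labels=dataset_labels,
    )
    return datasets, truth


def generate_gene_sets(config: SyntheticConfig, truth: SyntheticTruth) -> GeneSetCollection:
    """Plant blocks of redundant gene sets on the metabolic sources.

    Per metabolic source, ``sets_per_block`` sets each draw a fraction
    ``set_signal_fraction`` of their members from the positive-weight tail
    of that source's top-gene block (dataset 0) and the rest uniformly from
    the remaining genes; the leftover sets are fully uniform.  Drawing from
    one tail mirrors co-regulated pathway genes, whose weights share a sign
    within a component, and gives each block a coherent enrichment
    direction.  Block membership is recorded in ``truth.gene_set_blocks``
    (-1 for the uniform sets).
    """
    rng = _rng(config, _STREAM_GENE_SETS)
    G = config.n_genes
    n_signal = round(config.set_signal_fraction * config.genes_per_set)
    sets: dict[str, list[str]] = {}
    blocks: dict[str, int] = {}
    labels: dict[str, str] = {}
    idx = 0
    for b, src in enumerate(truth.metabolic_source_ids):
        block_genes = truth.top_gene_indices[0][src]
        w = truth.true_sources[0][block_genes, src]
        # positive-weight tail, topped up by descending weight if needed
        by_weight = block_genes[np.argsort(-w)]
        n_pool = max(int((w > 0).sum()), min(n_signal, len(block_genes)))
        top = by_weight[:n_pool]
        others = np.setdiff1d(np.arange(G), block_genes)
        n_sig = min(n_signal, len(top))
        for _ in range(config.sets_per_block):
            members = rng.choice(top, size=n_sig, replace=False)
            filler = rng.choice(others, size=config.genes_per_set - n_sig, replace=False)
            genes = [truth.gene_ids[i] for i in np.concatenate([members, filler])]
            name = f"GS{idx:03d}"
            sets[name] = list(dict.fromkeys(genes))
            blocks[name] = b
            labels[name] = "synthetic_metabolic"
            idx += 1
    while idx < config.n_gene_sets:
        genes = [
            truth.gene_ids[i]
            for i in rng.choice(G, size=config.genes_per_set, replace=False)
        ]
        name = f"GS{idx:03d}"
        sets[name] = genes
        blocks[name] = -1
        labels[name] = "synthetic_random"
        idx += 1
    truth.gene_set_blocks = blocks
    return GeneSetCollection(sets=sets, collection_labels=labels)


def generate_response_tables(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    dataset_index: int = -1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drug IC50 and immune-fraction tables tied to one dataset's activities.

    Each targeted drug's IC50 column is ``sign * activity + noise`` on its
    target source; the last ``n_null_drugs`` drugs are pure noise (target
    ``None``).  Immune fractions are an affine monotone transform of the
    target source's activity plus noise, clipped at zero.  Target maps are
    recorded on ``truth``.
    """
    d = dataset_index % len(truth.true_mixing)
    M = truth.true_mixing[d]
    samples = truth.sample_ids[d]
    n = M.shape[0]

    rng = _rng(config, _STREAM_DRUGS)
    drug_cols, drug_map = {}, {}
    for j in range(config.n_drugs):
        name = f"drug{j:02d}"
        if j >= config.n_drugs - config.n_null_drugs:
            drug_cols[name] = rng.normal(0.0, 1.0, size=n)
            drug_map[name] = (None, 0)
        else:
            src = j % config.n_sources
            sign = 1 if j % 2 == 0 else -1
            drug_cols[name] = sign * M[:, src] + rng.normal(
                0.0, config.drug_noise_sd, size=n
            )
            drug_map[name] = (src, sign)
    drugs = pd.DataFrame(drug_cols, index=samples)

    rng_i = _rng(config, _STREAM_IMMUNE)
    imm_cols, imm_map = {}, {}
    for t in range(config.n_immune_types):
        name = f"immune{t:02d}"
        src = t % config.n_sources
        sign = 1 if t % 2 == 0 else -1
        raw = (
            config.immune_base
            + config.immune_effect * sign * M[:, src]
            + rng_i.normal(0.0, config.immune_noise_sd, size=n)
        )
        imm_cols[name] = np.clip(raw, 0.0, None)
        imm_map[name] = (src, sign)
    immune = pd.DataFrame(imm_cols, index=samples)

    truth.drug_target_map = drug_map
    truth.immune_target_map = imm_map
    return drugs, immune


def generate_all(config: SyntheticConfig):
    """Convenience wrapper: compendium, gene sets and response tables."""
    datasets, truth = generate_compendium(config)
    gene_sets = generate_gene_sets(config, truth)
    drugs, immune = generate_response_tables(config, truth)
    return datasets, gene_sets, drugs, immune, truth
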
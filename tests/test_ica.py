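"""Consensus-ICA contracts: recovery, symmetry, projection, stability."""

import numpy as np
import pandas as pd
import pytest

from metica import (
    ComponentSet,
    SyntheticConfig,
    decompose,
    generate_compendium,
    project_activities,
    suggest_n_components,
)
from metica.formats import ExpressionMatrix
from conftest import DECOMPOSE_SEED, match_components


def _mini(noise_sd=0.5, n_sources=6, seed=5, n_genes=500, n_samples=120):
    cfg = SyntheticConfig(
        n_genes=n_genes, n_samples_per_dataset=(n_samples,), n_sources=n_sources,
        n_shared_sources=0, n_metabolic_sources=0, n_gene_sets=0, sets_per_block=8,
        n_sample_groups=1, group_activity_shift=0.0, noise_sd=noise_sd,
        n_drugs=0, n_null_drugs=0, n_immune_types=0, seed=seed,
    )
    return generate_compendium(cfg)


def _best_matches(truth, C, d=0):
    return match_components(truth, d, C)


class TestDecompose:
    def test_noiseless_two_source_mixture_recovered(self):
        datasets, truth = _mini(noise_sd=0.0, n_sources=2)
        C, M = decompose(datasets[0], n_components=2, n_runs=10, seed=1)
        for _, (comp, corr) in _best_matches(truth, C).items():
            assert corr >= 0.99

    def test_sample_permutation_leaves_weights_unchanged(self):
        datasets, _ = _mini()
        X = datasets[0]
        rng = np.random.default_rng(3)
        perm = rng.permutation(X.values.shape[1])
        Xp = ExpressionMatrix(values=X.values.iloc[:, perm], dataset_label="perm")
        C1, M1 = decompose(X, n_components=6, n_runs=8, seed=2)
        C2, M2 = decompose(Xp, n_components=6, n_runs=8, seed=2)
        W1, W2 = C1.weights.to_numpy(), C2.weights.to_numpy()
        corr = np.abs(W1.T @ W2) / W1.shape[0]
        # every component re-found with identical weights (sign convention fixed)
        assert corr.max(axis=1).min() > 1 - 1e-6
        # activities are the permuted ones, for matched columns
        for i in range(W1.shape[1]):
            j = int(corr[i].argmax())
            a1 = M1.activities.to_numpy()[perm, i]
            a2 = M2.activities.to_numpy()[:, j]
            sign = np.sign(np.dot(W1[:, i], W2[:, j]))
            # whitening on the permuted matrix shifts floats by ~1e-4
            np.testing.assert_allclose(a1, sign * a2, atol=1e-2)

    def test_negated_data_negates_activities_only(self):
        datasets, _ = _mini()
        X = datasets[0]
        Xn = ExpressionMatrix(values=-X.values, dataset_label="neg")
        C1, M1 = decompose(X, n_components=6, n_runs=8, seed=2)
        C2, M2 = decompose(Xn, n_components=6, n_runs=8, seed=2)
        W1, W2 = C1.weights.to_numpy(), C2.weights.to_numpy()
        corr = (W1.T @ W2) / W1.shape[0]
        for i in range(W1.shape[1]):
            j = int(np.abs(corr[i]).argmax())
            assert abs(corr[i, j]) > 1 - 1e-6
            # standardized |weights| identical under the sign convention
            np.testing.assert_allclose(
                np.abs(W1[:, i]), np.abs(W2[:, j]), atol=1e-6
            )
            np.testing.assert_allclose(
                M1.activities.to_numpy()[:, i] * np.sign(corr[i, j]),
                -M2.activities.to_numpy()[:, j],
                atol=1e-6,
            )

    def test_same_seed_is_bit_identical(self):
        datasets, _ = _mini()
        C1, M1 = decompose(datasets[0], n_components=6, n_runs=6, seed=4)
        C2, M2 = decompose(datasets[0], n_components=6, n_runs=6, seed=4)
        assert C1.weights.equals(C2.weights)
        assert M1.activities.equals(M2.activities)

    def test_different_seeds_agree_on_stable_components(self):
        datasets, _ = _mini()
        C1, _ = decompose(datasets[0], n_components=6, n_runs=10, seed=4)
        C2, _ = decompose(datasets[0], n_components=6, n_runs=10, seed=5)
        W1, W2 = C1.weights.to_numpy(), C2.weights.to_numpy()
        corr = np.abs(W1.T @ W2) / W1.shape[0]
        stable = C1.stability.to_numpy() >= 0.9
        assert corr.max(axis=1)[stable].min() >= 0.95

    def test_residual_variance_decreases_with_k(self):
        datasets, _ = _mini()
        V = datasets[0].values.to_numpy()
        Xc = V - V.mean(axis=1, keepdims=True)
        resid = []
        for k in (2, 4, 6, 8):
            C, M = decompose(datasets[0], n_components=k, n_runs=6, seed=9)
            R = Xc - C.weights.to_numpy() @ M.activities.to_numpy().T
            resid.append(np.var(R))
        assert all(a >= b - 1e-9 for a, b in zip(resid, resid[1:]))

    def test_k_above_rank_rejected(self):
        datasets, _ = _mini(noise_sd=0.0, n_sources=2)
        with pytest.raises(ValueError, match="rank"):
            decompose(datasets[0], n_components=4, n_runs=4, seed=0)

    def test_too_few_runs_rejected(self):
        datasets, _ = _mini()
        with pytest.raises(ValueError, match="n_runs"):
            decompose(datasets[0], n_components=4, n_runs=1, seed=0)

    def test_stability_reported_non_increasing(self, decomposition):
        for C in decomposition.components:
            s = C.stability.to_numpy()
            assert (np.diff(s) <= 1e-12).all()
            assert ((0 <= s) & (s <= 1)).all()


class TestProjectActivities:
    def _component_set(self, n_genes=200, k=4, seed=0):
        rng = np.random.default_rng(seed)
        W, _ = np.linalg.qr(rng.normal(size=(n_genes, k)))
        W = (W - W.mean(0)) / W.std(0)
        peaks = W[np.abs(W).argmax(axis=0), np.arange(k)]
        W = W * np.where(peaks < 0, -1, 1)
        genes = [f"g{i}" for i in range(n_genes)]
        comps = [f"TC{j}" for j in range(k)]
        return ComponentSet(
            weights=pd.DataFrame(W, index=genes, columns=comps),
            dataset_label="D",
            stability=pd.Series(1.0, index=comps),
        )

    def test_exact_recovery_of_constructing_activities(self):
        C = self._component_set()
        rng = np.random.default_rng(1)
        A = rng.normal(size=(30, 4))
        X = ExpressionMatrix(
            values=pd.DataFrame(
                C.weights.to_numpy() @ A.T,
                index=C.gene_ids, columns=[f"s{i}" for i in range(30)],
            ),
            dataset_label="D",
        )
        M = project_activities(C, X)
        np.testing.assert_allclose(M.activities.to_numpy(), A, atol=1e-8)

    def test_single_component_profile_yields_unit_activity(self):
        C = self._component_set()
        X = ExpressionMatrix(
            values=C.weights[["TC1"]].rename(columns={"TC1": "sample0"}),
            dataset_label="D",
        )
        M = project_activities(C, X)
        expected = np.zeros(4)
        expected[1] = 1.0
        np.testing.assert_allclose(M.activities.to_numpy()[0], expected, atol=1e-8)

    def test_projected_activities_match_truth(self, default_fixture, decomposition, matcher):
        truth = default_fixture.truth
        for d in range(2):
            C = decomposition.components[d]
            M = project_activities(C, default_fixture.datasets[d])
            matches = matcher(truth, d, C)
            for s in truth.shared_source_ids:
                comp, corr = matches[s]
                if corr < 0.9:
                    continue
                r = np.corrcoef(
                    truth.true_mixing[d][:, s], M.activities[comp].to_numpy()
                )[0, 1]
                assert abs(r) >= 0.9

    def test_low_gene_overlap_rejected(self):
        C = self._component_set()
        rng = np.random.default_rng(2)
        few = list(C.gene_ids[:50])
        X = ExpressionMatrix(
            values=pd.DataFrame(
                rng.normal(size=(50, 3)), index=few, columns=list("abc")
            ),
            dataset_label="D",
        )
        with pytest.raises(ValueError, match="floor"):
            project_activities(C, X)


def test_suggest_n_components_matches_exact_rank():
    datasets, _ = _mini(noise_sd=0.0, n_sources=3)
    assert suggest_n_components(datasets[0], variance_target=0.999) == 3
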
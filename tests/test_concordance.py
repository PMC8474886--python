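"""Cross-dataset concordance: top genes, overlap null, Spearman, verdicts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metica import (
    call_concordance,
    hypergeom_overlap_pvalue,
    overlap_pvalue,
    spearman_t,
    summarize_concordance,
    top_genes,
)
from metica.ica import ComponentSet
from metica.selection import MTCSelection


class TestTopGenes:
    def test_strict_threshold(self):
        W = pd.DataFrame({"C0": [3.0, 3.01, -3.5]}, index=["g1", "g2", "g3"])
        assert top_genes(W, "C0") == {"g2", "g3"}

    def test_zero_threshold_returns_all(self):
        W = pd.DataFrame({"C0": [0.1, -0.2, 1.0]}, index=["g1", "g2", "g3"])
        assert top_genes(W, "C0", threshold=0.0) == {"g1", "g2", "g3"}

    def test_normal_tail_count(self):
        """Standardized normal weights: ~2*(1 - Phi(3))*n genes above 3."""
        rng = np.random.default_rng(5)
        w = rng.normal(size=10_000)
        w = (w - w.mean()) / w.std()
        W = pd.DataFrame({"C0": w}, index=[f"g{i}" for i in range(10_000)])
        count = len(top_genes(W, "C0"))
        p = 2 * stats.norm.sf(3)
        expected = p * 10_000
        se = np.sqrt(10_000 * p * (1 - p))
        assert abs(count - expected) <= 3 * se

    def test_unknown_component_rejected(self):
        W = pd.DataFrame({"C0": [1.0, 2.0]}, index=["g1", "g2"])
        with pytest.raises(KeyError):
            top_genes(W, "C9")


class TestOverlapPvalue:
    def test_zero_overlap_is_certain(self):
        assert overlap_pvalue(5, 5, 0, 100, seed=0) == 1.0

    def test_full_set_forces_overlap(self):
        assert overlap_pvalue(20, 5, 5, 20, n_perm=500, seed=0) == 1.0

    def test_example_matches_hypergeometric_tail(self):
        """Universe 20, sets of 5, overlap 3: exact tail ~ 0.0726."""
        exact = hypergeom_overlap_pvalue(5, 5, 3, 20)
        assert exact == pytest.approx(0.07262641898864809, abs=1e-12)
        mc = overlap_pvalue(5, 5, 3, 20, n_perm=10_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(mc - exact) <= 3 * se + 1e-4

    def test_monte_carlo_converges_to_exact_tail(self):
        """20 random parameter triples: >= 19 within 3 MC standard errors."""
        rng = np.random.default_rng(77)
        good = 0
        for _ in range(20):
            universe = int(rng.integers(50, 1500))
            na = int(rng.integers(5, universe // 3))
            nb = int(rng.integers(5, universe // 3))
            ov = int(min(na, nb, rng.poisson(na * nb / universe) + rng.integers(0, 3)))
            exact = hypergeom_overlap_pvalue(na, nb, ov, universe)
            mc = overlap_pvalue(na, nb, ov, universe, n_perm=10_000,
                                seed=int(rng.integers(1 << 30)))
            se = max(np.sqrt(exact * (1 - exact) / 10_000), 1e-4)
            good += abs(mc - exact) <= 3 * se
        assert good >= 19

    def test_impossible_inputs_rejected(self):
        with pytest.raises(ValueError):
            overlap_pvalue(5, 5, 6, 100)
        with pytest.raises(ValueError):
            overlap_pvalue(200, 5, 2, 100)
        with pytest.raises(ValueError):
            hypergeom_overlap_pvalue(5, 5, 6, 100)


class TestSpearman:
    def test_worked_example(self):
        """(1,2,3,4,5) vs (1,3,2,5,4): rho = 1 - 6*4/120 = 0.8, p ~ 0.104."""
        res = spearman_t([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert res.rho == pytest.approx(0.8, abs=1e-12)
        assert res.p == pytest.approx(0.10408803866182788, abs=1e-10)
        assert not res.exact_limit

    def test_antitone_is_exact(self):
        res = spearman_t([1, 2, 3, 4], [4, 3, 2, 1])
        assert res.rho == -1.0
        assert res.p == 0.0
        assert res.exact_limit

    def test_uncorrelated_permutation_gives_p_one(self):
        # sum d^2 = 10 = n(n^2-1)/6, so rho = 0 exactly
        res = spearman_t([1, 2, 3, 4], [2, 4, 1, 3])
        assert res.rho == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n = int(rng.integers(5, 60))
            x = rng.integers(0, 8, size=n).astype(float)
            y = rng.normal(size=n)
            if np.ptp(x) == 0:
                continue
            res = spearman_t(x, y)
            ref = stats.spearmanr(x, y)
            assert res.rho == pytest.approx(ref.statistic, abs=1e-10)
            if not res.exact_limit:
                assert res.p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            spearman_t([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            spearman_t([1, 1, 1, 1], [1, 2, 3, 4])


def _toy_components(seed, label, n_genes=500, k=3, planted=None):
    """Standardized heavy-tailed components; ``planted`` maps column -> weights."""
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(n_genes, k)) * 0.5
    for j in range(k):
        top = rng.choice(n_genes, size=15, replace=False)
        W[top, j] = rng.normal(scale=6, size=15)
    if planted:
        for j, w in planted.items():
            W[:, j] = w
    W = (W - W.mean(0)) / W.std(0)
    peaks = W[np.abs(W).argmax(0), np.arange(k)]
    W *= np.where(peaks < 0, -1, 1)
    comps = [f"{label}_TC{j}" for j in range(k)]
    return ComponentSet(
        weights=pd.DataFrame(W, index=[f"g{i}" for i in range(n_genes)], columns=comps),
        dataset_label=label,
        stability=pd.Series(1.0, index=comps),
    )


def _selection(C):
    return MTCSelection(
        mtc_ids=list(C.component_ids),
        provenance={m: [(0, "max_single_set", 1.0)] for m in C.component_ids},
    )


class TestCallConcordance:
    def test_component_paired_with_itself_is_concordant(self):
        C = _toy_components(1, "A")
        pairs = call_concordance(C, C, _selection(C), _selection(C), seed=0,
                                 n_perm=2000)
        same = [p for p in pairs if p.mtc_a == p.mtc_b]
        assert same
        for p in same:
            assert p.concordant
            assert p.rho == 1.0
            assert p.n_overlap == p.n_top_a == p.n_top_b

    def test_shared_planted_component_found_across_datasets(self):
        rng = np.random.default_rng(2)
        shared = rng.normal(size=500) * 0.5
        top = rng.choice(500, size=15, replace=False)
        shared[top] = rng.normal(scale=6, size=15)
        Ca = _toy_components(3, "A", planted={0: shared})
        Cb = _toy_components(4, "B", planted={0: shared})
        pairs = call_concordance(Ca, Cb, _selection(Ca), _selection(Cb), seed=1,
                                 n_perm=2000)
        verdicts = {(p.mtc_a, p.mtc_b): p.concordant for p in pairs}
        assert verdicts[("A_TC0", "B_TC0")]
        assert not any(
            v for (a, b), v in verdicts.items() if (a, b) != ("A_TC0", "B_TC0")
        )

    def test_symmetry_of_verdicts_and_rho(self):
        Ca = _toy_components(5, "A")
        Cb = _toy_components(6, "B")
        ab = call_concordance(Ca, Cb, _selection(Ca), _selection(Cb), seed=7,
                              n_perm=2000)
        ba = call_concordance(Cb, Ca, _selection(Cb), _selection(Ca), seed=7,
                              n_perm=2000)
        fwd = {(p.mtc_a, p.mtc_b): p for p in ab}
        rev = {(p.mtc_b, p.mtc_a): p for p in ba}
        assert fwd.keys() == rev.keys()
        for key, p in fwd.items():
            q = rev[key]
            assert p.concordant == q.concordant
            assert p.overlap_p == q.overlap_p
            if not np.isnan(p.rho):
                assert abs(p.rho) == pytest.approx(abs(q.rho), abs=1e-12)

    def test_small_overlap_recorded_not_concordant(self):
        Ca = _toy_components(8, "A")
        Cb = _toy_components(9, "B")
        pairs = call_concordance(Ca, Cb, _selection(Ca), _selection(Cb), seed=2,
                                 n_perm=500)
        undef = [p for p in pairs if p.n_overlap < 4]
        assert undef  # independent heavy tails rarely share top genes
        for p in undef:
            assert not p.concordant
            assert "rho undefined" in p.reason

    def test_summary_counts_partners(self):
        rng = np.random.default_rng(10)
        shared = rng.normal(size=500) * 0.5
        top = rng.choice(500, size=15, replace=False)
        shared[top] = rng.normal(scale=6, size=15)
        Ca = _toy_components(11, "A", planted={0: shared})
        Cb = _toy_components(12, "B", planted={0: shared})
        pairs = call_concordance(Ca, Cb, _selection(Ca), _selection(Cb), seed=3,
                                 n_perm=1000)
        summ = summarize_concordance(pairs)
        assert summ["fraction_concordant_any"]["A"] == pytest.approx(1 / 3)
        assert summ["count_concordant_all"]["B"] == 1

    def test_exact_overlap_method_agrees_on_verdicts(self):
        Ca = _toy_components(13, "A")
        Cb = _toy_components(14, "B")
        perm = call_concordance(Ca, Cb, _selection(Ca), _selection(Cb), seed=4,
                                n_perm=10_000)
        exact = call_concordance(Ca, Cb, _selection(Ca), _selection(Cb), seed=4,
                                 overlap_method="exact")
        for p, q in zip(perm, exact):
            assert p.concordant == q.concordant
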
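"""Pearson/BH screens, function dissimilarities and Mantel tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

from propstab.association import (
    function_dissimilarity,
    mantel_test,
    pearson_bh_matrix,
    taxa_function_correlations,
    trait_correlation_network,
)
from propstab.stability import MOST_STABLE


def _bh_stepup(pvals):
    """Independent step-up oracle."""
    m = len(pvals)
    order = np.argsort(pvals)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = m - rank_from_top
        prev = min(prev, pvals[idx] * m / k)
        adj[idx] = prev
    return adj


class TestPearsonBH:
    def test_bh_hand_example(self):
        # raw p's (0.01, 0.02, 0.04), m=3 -> adjusted (0.03, 0.03, 0.04)
        oracle = _bh_stepup(np.array([0.01, 0.02, 0.04]))
        assert np.allclose(oracle, [0.03, 0.03, 0.04])
        from statsmodels.stats.multitest import multipletests
        adj = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert np.allclose(adj, oracle)

    def test_bh_matches_oracle_on_random_pvectors(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(9)
        for _ in range(20):
            p = rng.random(rng.integers(2, 30))
            assert np.allclose(
                multipletests(p, method="fdr_bh")[1], _bh_stepup(p), atol=1e-12
            )

    def test_perfect_and_anti_correlation(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "x2": 2 * x + 1, "negx": -x})
        res = pearson_bh_matrix(df).set_index(["feature_a", "feature_b"])
        assert res.loc[("x", "x2"), "r"] == pytest.approx(1.0)
        assert res.loc[("x", "negx"), "r"] == pytest.approx(-1.0)

    def test_zero_variance_feature_na_excluded_from_family(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame({
            "a": rng.normal(size=20),
            "b": rng.normal(size=20),
            "const": np.ones(20),
        })
        res = pearson_bh_matrix(df)
        na_rows = res[res["feature_b"] == "const"]
        assert na_rows["r"].isna().all()
        ok = res.dropna(subset=["p"])
        # single remaining test => p_adj equals p
        assert len(ok) == 1
        assert ok["p_adj"].iloc[0] == pytest.approx(ok["p"].iloc[0])

    def test_padj_at_least_p(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(30, 6)),
                          columns=list("abcdef"))
        res = pearson_bh_matrix(df).dropna(subset=["p"])
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestFunctionDissimilarity:
    def _meta(self, doc, co2):
        from propstab.tables import MetadataTable, SampleRecord
        recs = [
            SampleRecord(f"s{i}", "O", 0, f"L{i}", None, "R",
                         doc[i], co2[i], 0.5)
            for i in range(len(doc))
        ]
        return MetadataTable(recs)

    def test_single_variable_absolute_difference(self):
        d = function_dissimilarity(self._meta([1.0, 3.0], [0.0, 0.0]), ("DOC",))
        assert d["s0", "s1"] == pytest.approx(2.0)

    def test_identical_samples_zero(self):
        d = function_dissimilarity(self._meta([2.0, 2.0, 5.0], [1, 1, 1]),
                                   ("DOC",))
        assert d["s0", "s1"] == 0.0

    def test_combined_with_constant_co2_reduces_to_doc(self):
        doc = [1.0, 2.0, 4.0, 7.0]
        co2 = [5.0, 5.0, 5.0, 5.0]
        meta = self._meta(doc, co2)
        combined = function_dissimilarity(meta, ("DOC", "CO2"))
        z = (np.array(doc) - np.mean(doc)) / np.std(doc, ddof=1)
        expect = np.abs(z[:, None] - z[None, :])
        assert np.allclose(combined.data, expect, atol=1e-12)

    def test_product_mode(self):
        meta = self._meta([1.0, 2.0], [3.0, 4.0])
        d = function_dissimilarity(meta, ("DOC", "CO2"), combined_mode="product")
        assert d["s0", "s1"] == pytest.approx(abs(1 * 3 - 2 * 4))


class TestMantel:
    def _pair(self, n, seed):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        X = rng.normal(size=(n, 3))
        Y = rng.normal(size=(n, 3))
        return (DistanceMatrix(squareform(pdist(X)), ids=ids),
                DistanceMatrix(squareform(pdist(Y)), ids=ids))

    def test_self_correlation(self):
        d1, _ = self._pair(10, 12)
        m = mantel_test(d1, d1, n_perm=999, seed=0)
        assert m.r == pytest.approx(1.0)
        assert m.p == pytest.approx(1 / 1000)

    def test_exact_enumeration_matches_bruteforce(self):
        d1, d2 = self._pair(4, 13)
        m = mantel_test(d1, d2, exact=True)
        il = np.tril_indices(4, k=-1)
        x = d1.data[il]
        r_obs = np.corrcoef(x, d2.data[il])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            p = np.array(perm)
            r = np.corrcoef(x, d2.data[np.ix_(p, p)][il])[0, 1]
            count += r >= r_obs - 1e-12
        assert m.p == pytest.approx(count / 24)
        assert m.r == pytest.approx(r_obs)

    def test_r_matches_skbio(self):
        d1, d2 = self._pair(12, 14)
        from skbio.stats.distance import mantel as sk_mantel
        r_sk = sk_mantel(d1, d2, permutations=0)[0]
        assert mantel_test(d1, d2, n_perm=9).r == pytest.approx(r_sk, abs=1e-9)

    def test_order_invariance(self):
        d1, d2 = self._pair(8, 15)
        shuffled = list(d1.ids)[::-1]
        m1 = mantel_test(d1, d2, n_perm=99, seed=3)
        m2 = mantel_test(d1.filter(shuffled), d2, n_perm=99, seed=3)
        assert m1.r == pytest.approx(m2.r, abs=1e-12)

    def test_mismatched_ids_error(self):
        d1, _ = self._pair(5, 16)
        _, d2 = self._pair(5, 17)
        d2 = DistanceMatrix(d2.data, ids=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError):
            mantel_test(d1, d2)

    def test_null_calibration(self):
        rejections = 0
        n_sim = 100
        for s in range(n_sim):
            d1, d2 = self._pair(15, 1000 + s)
            m = mantel_test(d1, d2, n_perm=199, seed=s)
            rejections += m.p <= 0.05
        assert 0.0 <= rejections / n_sim <= 0.12


class TestTaxaFunctionScreen:
    def test_planted_doc_taxon_recovered(self, default_experiment):
        cfg, (bact, _, meta, truth) = default_experiment
        # strongest planted positive-effect taxon among prevalent taxa
        prev = (bact.counts > 0).mean(axis=1)
        cands = {t: w for t, w in truth.doc_effect_taxa.items()
                 if w > 0 and prev[bact.taxon_ids.index(t)] > 0.8}
        taxon = max(cands, key=cands.get)
        assign = {s: "all" for s in bact.sample_ids}
        res = taxa_function_correlations(
            bact, meta, ("DOC",), assign, min_prevalence=0.8
        )["all"]
        row = res[(res["taxon"] == taxon) & (res["variable"] == "DOC")]
        assert len(row) == 1
        assert row["r"].iloc[0] > 0
        assert row["p_adj"].iloc[0] < 0.05

    def test_empty_group_errors(self, default_experiment):
        _, (bact, _, meta, _) = default_experiment
        with pytest.raises(ValueError):
            taxa_function_correlations(bact, meta, ("DOC",),
                                       {"not_a_sample": MOST_STABLE})

    def test_shuffled_abundances_few_significant(self, default_experiment):
        _, (bact, _, meta, _) = default_experiment
        rng = np.random.default_rng(18)
        shuffled = bact.counts.copy()
        for i in range(shuffled.shape[0]):
            shuffled[i] = shuffled[i, rng.permutation(shuffled.shape[1])]
        from propstab.tables import AbundanceTable
        tab = AbundanceTable(list(bact.taxon_ids), list(bact.sample_ids),
                             shuffled, dict(bact.taxonomy))
        assign = {s: "all" for s in tab.sample_ids}
        res = taxa_function_correlations(tab, meta, ("DOC",), assign)["all"]
        frac_sig = res["significant"].mean() if len(res) else 0.0
        assert frac_sig <= 0.2  # 2 x FDR level


class TestTraitNetwork:
    def test_empty_when_nothing_significant(self):
        res = pd.DataFrame({"feature_a": ["a"], "feature_b": ["b"],
                            "r": [0.1], "p": [0.9], "p_adj": [0.95]})
        assert len(trait_correlation_network(res)) == 0

    def test_edge_count_matches_bruteforce(self):
        rng = np.random.default_rng(19)
        res = pd.DataFrame({
            "feature_a": [f"a{i}" for i in range(30)],
            "feature_b": [f"b{i}" for i in range(30)],
            "r": rng.uniform(-1, 1, 30),
            "p": rng.random(30),
            "p_adj": rng.random(30),
        })
        edges = trait_correlation_network(res, alpha=0.3)
        assert len(edges) == int((res["p_adj"] < 0.3).sum())
        assert (edges.loc[edges["r"] >= 0, "sign"] == "positive").all()

    def test_doc_co2_tradeoff_recovered(self):
        from propstab.synth import SyntheticConfig, generate_experiment
        cfg = SyntheticConfig(
            n_origins=5, n_taxa_bacteria=40, n_taxa_fungi=20,
            seq_depth_bacteria=1000, seq_depth_fungi=1000,
            co2_tradeoff=-2.0, co2_noise_sd=0.5, seed=20,
        )
        _, _, meta, _ = generate_experiment(cfg)
        df = meta.to_dataframe()[["DOC", "CO2", "TN"]]
        res = pearson_bh_matrix(df)
        edges = trait_correlation_network(res)
        pair = edges[
            (edges["feature_a"] == "DOC") & (edges["feature_b"] == "CO2")
        ]
        assert len(pair) == 1 and pair["sign"].iloc[0] == "negative"
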
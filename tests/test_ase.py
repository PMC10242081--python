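import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from endoase.ase import (aggregate_allelic_counts, assess_ase,
                         binomial_pvalue, classify_bias_strength,
                         cluster_enrichment_scores,
                         per_cluster_maternal_fraction)
from endoase.containers import ValidationError
from endoase.qc import normalize_log_cpm

from conftest import make_acm


def oracle_two_sided_p(m, n, f0):
    """Independent enumeration oracle: sum pmf over outcomes no more likely
    than the observed one."""
    pmf = stats.binom.pmf(np.arange(n + 1), n, f0)
    return float(pmf[pmf <= pmf[m] * (1 + 1e-12)].sum())


class TestBinomialPvalue:
    def test_all_maternal_upper_tail(self):
        # (m, p) = (20, 0): the upper tail alone is (2/3)^20 ~ 3.01e-4
        assert (2 / 3) ** 20 == pytest.approx(3.007e-4, rel=1e-3)
        p = binomial_pvalue(20, 20, 2 / 3)
        assert p == pytest.approx(oracle_two_sided_p(20, 20, 2 / 3), rel=1e-12)

    def test_all_paternal_lower_tail(self):
        # (m, p) = (0, 10): lower tail (1/3)^10 ~ 1.69e-5
        assert (1 / 3) ** 10 == pytest.approx(1.6935e-5, rel=1e-3)
        p = binomial_pvalue(0, 10, 2 / 3)
        assert p == pytest.approx(oracle_two_sided_p(0, 10, 2 / 3), rel=1e-12)

    def test_observation_at_expectation_has_p_one(self):
        assert binomial_pvalue(2, 3, 2 / 3) == pytest.approx(1.0)

    @given(n=st.integers(1, 80), m_frac=st.floats(0, 1),
           f0=st.floats(0.1, 0.9))
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle(self, n, m_frac, f0):
        m = int(round(m_frac * n))
        assert binomial_pvalue(m, n, f0) == pytest.approx(
            oracle_two_sided_p(m, n, f0), rel=1e-9, abs=1e-300
        )

    @given(n=st.integers(1, 60), m_frac=st.floats(0, 1))
    @settings(max_examples=60, deadline=None)
    def test_allele_swap_symmetry_is_exact(self, n, m_frac):
        m = int(round(m_frac * n))
        assert binomial_pvalue(m, n, 2 / 3) == pytest.approx(
            binomial_pvalue(n - m, n, 1 / 3), rel=1e-12
        )


class TestAggregation:
    def test_summation_example(self):
        acm = make_acm([[5, 1], [3, 2]], maternal=[[3, 0], [1, 1]],
                       paternal=[[1, 0], [1, 1]])
        agg = aggregate_allelic_counts(acm)
        assert list(agg["m_reads"]) == [4, 1]
        assert list(agg["p_reads"]) == [2, 1]
        assert list(agg["n_informative_nuclei"]) == [2, 1]

    def test_empty_subset_is_all_zero(self):
        acm = make_acm([[5]], maternal=[[3]], paternal=[[1]])
        agg = aggregate_allelic_counts(acm, nuclei_subset=np.array([], dtype=int))
        assert agg[["m_reads", "p_reads", "n_informative_nuclei"]].sum().sum() == 0

    def test_cluster_additivity(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(2, 9, size=(10, 4))
        m = rng.binomial(counts, 0.5)
        p = counts - m
        acm = make_acm(counts, maternal=m, paternal=p)
        whole = aggregate_allelic_counts(acm)
        first = aggregate_allelic_counts(acm, np.arange(5))
        second = aggregate_allelic_counts(acm, np.arange(5, 10))
        assert (first["m_reads"] + second["m_reads"]).equals(whole["m_reads"])

    def test_missing_layers_raise(self):
        with pytest.raises(ValidationError):
            aggregate_allelic_counts(make_acm([[1]]))


class TestAssess:
    def test_filter_and_calls(self):
        agg = pd.DataFrame({
            "gene": ["shallow", "meg", "peg", "balanced"],
            "m_reads": [10, 95, 5, 40],
            "p_reads": [5, 5, 95, 20],
            "n_informative_nuclei": [8, 30, 30, 30],
        })
        res = assess_ase(agg).set_index("gene")
        assert res.loc["shallow", "call"] == "not_assessed"
        assert np.isnan(res.loc["shallow", "p_value"])
        assert res.loc["meg", "call"] == "MEG"
        assert res.loc["peg", "call"] == "PEG"
        assert res.loc["balanced", "call"] == "biparental"

    def test_min_nuclei_filter(self):
        agg = pd.DataFrame({"gene": ["g"], "m_reads": [30], "p_reads": [10],
                            "n_informative_nuclei": [3]})
        assert assess_ase(agg)["call"].iloc[0] == "not_assessed"

    def test_expected_fraction_domain(self):
        agg = pd.DataFrame({"gene": ["g"], "m_reads": [30], "p_reads": [10],
                            "n_informative_nuclei": [10]})
        with pytest.raises(ValueError):
            assess_ase(agg, expected_fraction=1.0)

    def test_table_level_allele_swap(self):
        rng = np.random.default_rng(8)
        m = rng.binomial(80, 2 / 3, size=200)
        agg = pd.DataFrame({"gene": [f"g{i}" for i in range(200)],
                            "m_reads": m, "p_reads": 80 - m,
                            "n_informative_nuclei": 40})
        swapped = agg.rename(columns={"m_reads": "p_reads", "p_reads": "m_reads"})
        a = assess_ase(agg, expected_fraction=2 / 3)
        b = assess_ase(swapped, expected_fraction=1 / 3)
        assert np.allclose(a["p_value"], b["p_value"], rtol=1e-12)
        flip = {"MEG": "PEG", "PEG": "MEG"}
        assert [flip.get(c, c) for c in a["call"]] == list(b["call"])


class TestStrength:
    def test_rule_application(self):
        res = pd.DataFrame({
            "gene": list("abc"),
            "maternal_fraction": [0.97, 0.10, 0.70],
            "call": ["MEG", "PEG", "MEG"],
        })
        out = classify_bias_strength(res)
        assert list(out["strength"]) == ["strong", "intermediate", "weak"]

    def test_non_calls_get_none(self):
        res = pd.DataFrame({"gene": ["x"], "maternal_fraction": [np.nan],
                            "call": ["not_assessed"]})
        assert classify_bias_strength(res)["strength"].iloc[0] == "none"

    def test_bad_cut_order_raises(self):
        res = pd.DataFrame({"gene": [], "maternal_fraction": [], "call": []})
        with pytest.raises(ValueError):
            classify_bias_strength(res, meg_cuts=(0.85, 0.95))


class TestEnrichmentScores:
    def build(self):
        # 3 clusters x 2 nuclei; one gene with cluster means 1, 2, 3
        counts = np.full((6, 2), 50)
        counts[:, 0] = [10, 10, 20, 20, 30, 30]
        m = np.minimum(counts, [[4, 4]] * 6)
        p = np.minimum(counts - m, 4)
        acm = normalize_log_cpm(make_acm(counts, maternal=m, paternal=p))
        labels = np.array([0, 0, 1, 1, 2, 2])
        return acm, labels

    def test_zscore_of_linear_means(self):
        acm, labels = self.build()
        # overwrite norm with the raw pattern so cluster means are 1, 2, 3
        import scipy.sparse as sp
        norm = np.column_stack([[1, 1, 2, 2, 3, 3], [5, 5, 5, 5, 5, 5]]).astype(float)
        acm.norm = sp.csr_matrix(norm)
        res = cluster_enrichment_scores(acm, labels, ["g0", "g1"])
        g0 = res[res["gene"] == "g0"].sort_values("cluster")["es_total"]
        assert list(g0.round(4)) == [-1.2247, 0.0, 1.2247]
        # constant gene: all-zero profile
        g1 = res[res["gene"] == "g1"]["es_total"]
        assert (g1 == 0).all()

    def test_layer_swap_negates_es_diff(self):
        acm, labels = self.build()
        res = cluster_enrichment_scores(acm, labels, ["g0"])
        acm_sw = make_acm(acm.counts.toarray(), maternal=acm.paternal.toarray(),
                          paternal=acm.maternal.toarray())
        acm_sw.norm = acm.norm
        res_sw = cluster_enrichment_scores(acm_sw, labels, ["g0"])
        assert np.allclose(res["es_diff"], -res_sw["es_diff"], atol=1e-12)

    def test_absent_gene_warns_and_skips(self):
        acm, labels = self.build()
        with pytest.warns(UserWarning, match="absent"):
            res = cluster_enrichment_scores(acm, labels, ["g0", "nope"])
        assert set(res["gene"]) == {"g0"}


class TestPerClusterFraction:
    def test_informative_single_cluster_and_weighted_identity(self):
        rng = np.random.default_rng(9)
        counts = np.full((8, 2), 60)
        m = rng.binomial(30, 0.7, size=(8, 2))
        m[4:, 1] = 0
        p = 30 - m
        p[4:, 1] = 0
        acm = make_acm(counts, maternal=m, paternal=p)
        labels = np.array([0] * 4 + [1] * 4)
        table = per_cluster_maternal_fraction(acm, labels, ["g0", "g1"],
                                              min_reads=10)
        assert np.isnan(table.loc[1, "g1"])  # cluster 1 uninformative for g1
        # read-weighted average of cluster fractions == whole-tissue fraction
        whole = m[:, 0].sum() / (m[:, 0].sum() + p[:, 0].sum())
        weights = np.array([(m[:4, 0] + p[:4, 0]).sum(),
                            (m[4:, 0] + p[4:, 0]).sum()], dtype=float)
        combined = (table["g0"] * weights / weights.sum()).sum()
        assert combined == pytest.approx(whole)


def test_null_calibration_quick():
    """On null allelic data the exact test rejects at slightly below the
    nominal level (binomial discreteness makes it conservative)."""
    from endoase.simulate import simulate_null_allelic

    tab = simulate_null_allelic(3000, 60, 2 / 3, seed=2)
    res = assess_ase(tab)
    rate = (res["p_value"] < 0.05).mean()
    assert 0.035 <= rate <= 0.065


class TestBetaBinomial:
    def test_reduces_toward_binomial_at_tiny_overdispersion(self):
        from endoase.ase import betabinomial_pvalue

        p_bin = binomial_pvalue(40, 60, 2 / 3)
        p_bb = betabinomial_pvalue(40, 60, 2 / 3, overdispersion=1e-6)
        assert p_bb == pytest.approx(p_bin, rel=1e-3)

    def test_overdispersion_makes_test_more_conservative(self):
        from endoase.ase import betabinomial_pvalue

        extreme = binomial_pvalue(55, 60, 2 / 3)
        relaxed = betabinomial_pvalue(55, 60, 2 / 3, overdispersion=0.1)
        assert relaxed > extreme

    def test_assess_ase_flag(self):
        agg = pd.DataFrame({"gene": ["g"], "m_reads": [58], "p_reads": [2],
                            "n_informative_nuclei": [20]})
        plain = assess_ase(agg)
        bb = assess_ase(agg, overdispersion=0.05)
        assert bb["p_value"].iloc[0] > plain["p_value"].iloc[0]

    def test_domain(self):
        from endoase.ase import betabinomial_pvalue

        with pytest.raises(ValueError):
            betabinomial_pvalue(1, 2, 0.5, overdispersion=0.0)
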
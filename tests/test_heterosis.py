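import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endoase.heterosis import (classify_expression_pattern,
                               classify_heterosis_mode, median_ratio_factors,
                               pairwise_deg, summarize_pattern_fractions)

from conftest import make_acm


def oracle_pattern(lp, hp, f1, k=3.0):
    """Direct region-membership oracle (independent re-statement of the
    partition inequalities)."""
    hits = []
    if 0 < f1 < lp / k:
        hits.append("BLP")
    if lp / k <= f1 < lp:
        hits.append("BMP")
    if lp <= f1 <= hp:
        hits.append("MPV")
    if hp < f1 < k * hp:
        hits.append("OMP")
    if f1 >= k * hp:
        hits.append("OHP")
    return hits


class TestPatternPartition:
    @pytest.mark.parametrize("p1,p2,f1,expected", [
        (10, 20, 70, "OHP"),   # 70 >= 3*20
        (10, 20, 2, "BLP"),    # 2 < 10/3
        (10, 20, 15, "MPV"),
        (10, 20, 45, "OMP"),
        (10, 20, 5, "BMP"),
    ])
    def test_worked_triples(self, p1, p2, f1, expected):
        assert classify_expression_pattern(p1, p2, f1) == expected

    def test_dense_grid_is_total_and_disjoint(self):
        rng = np.random.default_rng(20)
        for _ in range(60):
            lp = rng.uniform(0.1, 50)
            hp = lp * rng.uniform(1.0, 10)
            for f1 in np.linspace(1e-6, 5 * 3 * hp, 400):
                hits = oracle_pattern(lp, hp, f1)
                assert len(hits) == 1, (lp, hp, f1, hits)
                assert classify_expression_pattern(lp, hp, f1) == hits[0]

    @given(p1=st.floats(0.01, 1e3), ratio=st.floats(1.0, 20.0),
           f1=st.floats(1e-6, 1e5), c=st.floats(0.01, 100.0))
    @settings(max_examples=200, deadline=None)
    def test_scale_and_swap_invariance(self, p1, ratio, f1, c):
        p2 = p1 * ratio
        cls = classify_expression_pattern(p1, p2, f1)
        assert classify_expression_pattern(p2, p1, f1) == cls
        assert classify_expression_pattern(c * p1, c * p2, c * f1) == cls

    def test_degenerate_and_bad_k(self):
        with pytest.raises(ValueError):
            classify_expression_pattern(0.0, 5.0, 1.0)
        with pytest.raises(ValueError):
            classify_expression_pattern(1.0, 2.0, 1.5, k=1.0)


class TestPairwiseDEG:
    def test_identical_matrices_yield_no_significant_genes(self):
        rng = np.random.default_rng(21)
        counts = rng.integers(0, 30, size=(30, 50))
        a = make_acm(counts)
        b = make_acm(counts)
        res = pairwise_deg(a, b)
        assert not res["significant"].any()
        assert np.allclose(res["log2fc"], 0.0)

    def test_depth_invariance(self):
        rng = np.random.default_rng(22)
        counts_a = rng.integers(0, 30, size=(25, 40))
        counts_b = rng.integers(0, 30, size=(25, 40))
        base = pairwise_deg(make_acm(counts_a), make_acm(counts_b))
        doubled = pairwise_deg(make_acm(counts_a * 2), make_acm(counts_b))
        assert np.allclose(base["log2fc"], doubled["log2fc"], atol=1e-9)

    def test_mismatched_universes_raise(self):
        from endoase.containers import ValidationError
        a = make_acm([[1, 2]], genes=["x", "y"])
        b = make_acm([[1, 2]], genes=["x", "z"])
        with pytest.raises(ValidationError):
            pairwise_deg(a, b)

    def test_undersized_cluster_skipped_with_warning(self):
        rng = np.random.default_rng(23)
        a = make_acm(rng.integers(0, 9, size=(10, 5)))
        b = make_acm(rng.integers(0, 9, size=(10, 5)))
        labels_a = np.array([0] * 9 + [1])
        labels_b = np.array([0] * 9 + [1])
        with pytest.warns(UserWarning, match="skipped"):
            res = pairwise_deg(a, b, labels_a, labels_b)
        assert set(res["cluster"]) == {"all", "0"}


class TestModes:
    def draw(self, rng, mean, n=200):
        return rng.normal(mean, mean * 0.3 + 1, size=n)

    def test_definitional_cases(self):
        rng = np.random.default_rng(24)
        p1 = self.draw(rng, 10)
        p2 = self.draw(rng, 40)
        assert classify_heterosis_mode(self.draw(rng, 25), p1, p2) == "additive"
        assert classify_heterosis_mode(self.draw(rng, 40), p1, p2) == "dominant"
        assert classify_heterosis_mode(self.draw(rng, 120), p1, p2) == "overdominant"
        assert classify_heterosis_mode(self.draw(rng, 1), p1, p2) == "overdominant"

    def test_undersized_group_unclassified(self):
        with pytest.warns(UserWarning):
            assert classify_heterosis_mode([1, 2], [1, 2, 3], [4, 5, 6]) == "unclassified"


class TestSummary:
    def test_all_mpv_gives_fraction_one(self):
        rec = pd.DataFrame({"cluster": ["all"] * 4, "pattern": ["MPV"] * 4,
                            "mode": ["additive"] * 4})
        out = summarize_pattern_fractions(rec)
        assert out["frac_MPV"].iloc[0] == 1.0
        assert out["frac_additive"].iloc[0] == 1.0

    def test_fractions_sum_to_one_per_cluster(self):
        rng = np.random.default_rng(25)
        rec = pd.DataFrame({
            "cluster": rng.choice(["a", "b"], 100),
            "pattern": rng.choice(["BLP", "BMP", "MPV", "OMP", "OHP"], 100),
            "mode": rng.choice(["additive", "dominant", "overdominant"], 100),
        })
        out = summarize_pattern_fractions(rec)
        pats = out[[c for c in out.columns if c.startswith("frac_") and
                    c.split("_")[1].isupper()]]
        assert np.allclose(pats.sum(axis=1), 1.0, atol=1e-12)


def test_median_ratio_factors_cancel_global_scaling():
    rng = np.random.default_rng(26)
    base = rng.uniform(5, 100, size=500)
    factors = median_ratio_factors({"a": base, "b": base * 3.0})
    # scaled means must coincide: mean_a * f_a == mean_b * f_b
    assert factors["a"] / factors["b"] == pytest.approx(3.0, rel=1e-6)


class TestDistanceBasedModes:
    def test_point_estimate_heuristic(self):
        from endoase.heterosis import heterosis_modes_table

        rng = np.random.default_rng(27)
        p1 = rng.normal(10, 0.5, size=(100, 3))
        p2 = rng.normal(40, 0.5, size=(100, 3))
        f1 = np.column_stack([
            rng.normal(25, 0.5, 100),   # mid-parent -> additive
            rng.normal(40, 0.5, 100),   # high parent -> dominant
            rng.normal(90, 0.5, 100),   # transgressive -> overdominant
        ])
        res = heterosis_modes_table(f1, p1, p2, ["a", "d", "o"],
                                    method="distance")
        assert list(res["mode"]) == ["additive", "dominant", "overdominant"]

    def test_unknown_method_rejected(self):
        from endoase.heterosis import heterosis_modes_table

        with pytest.raises(ValueError):
            heterosis_modes_table(np.ones((5, 1)), np.ones((5, 1)),
                                  np.ones((5, 1)), ["g"], method="nope")
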
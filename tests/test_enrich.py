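from fractions import Fraction
from math import comb

import numpy as np
import pytest

from endoase.enrich import (GeneSetCollection, bh_fdr, enrich,
                            hypergeom_pvalue, read_gene_sets)


def oracle_upper_tail(N, n, M, m):
    """Exact rational enumeration of P(X >= m)."""
    num = sum(comb(M, i) * comb(N - M, n - i)
              for i in range(m, min(n, M) + 1))
    return Fraction(num, comb(N, n))


class TestHypergeom:
    def test_worked_example(self):
        p = hypergeom_pvalue(20, 5, 5, 3)
        exact = oracle_upper_tail(20, 5, 5, 3)
        assert exact == Fraction(1126, 15504)
        assert p == pytest.approx(float(exact), rel=1e-12)

    def test_empty_sum_gives_one(self):
        assert hypergeom_pvalue(100, 10, 5, 0) == 1.0

    def test_forced_full_overlap_gives_one(self):
        # n = N forces m = M: observing the maximum is certain
        assert hypergeom_pvalue(10, 10, 4, 4) == pytest.approx(1.0)

    def test_non_increasing_in_m(self):
        ps = [hypergeom_pvalue(50, 12, 8, m) for m in range(0, 9)]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_small_sweep_matches_rational_oracle(self):
        for N in range(1, 26):
            for M in range(0, N + 1, 3):
                for n in range(0, N + 1, 3):
                    for m in range(max(0, n + M - N), min(n, M) + 1):
                        exact = float(oracle_upper_tail(N, n, M, m))
                        if exact == 0:
                            continue
                        assert hypergeom_pvalue(N, n, M, m) == pytest.approx(
                            exact, rel=1e-12
                        )

    def test_precondition_violations(self):
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, 4, 5)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 11, 4, 2)
        with pytest.raises(ValueError):
            hypergeom_pvalue(10, 5, -1, 0)


def oracle_bh(p):
    """Hand step-up: q_(i) = min_{j>=i} p_(j) * n / j."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        running = min(running, p[order[rank - 1]] * n / rank)
        q[order[rank - 1]] = running
    return q


class TestBH:
    def test_hand_worked_case(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_random_vectors_match_oracle_and_stepup_equivalence(self):
        """q-values match the hand step-up oracle, dominate the raw
        p-values, and thresholding them at alpha reproduces the classical
        step-up rejection set (so no second adjustment is ever needed)."""
        rng = np.random.default_rng(30)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 50))
            q = bh_fdr(p)
            assert np.allclose(q, oracle_bh(p), rtol=1e-12)
            assert np.all(q >= p - 1e-15) and np.all(q <= 1.0)
            for alpha in (0.01, 0.05, 0.2):
                assert np.array_equal(q <= alpha, stepup_rejections(p, alpha))


def stepup_rejections(p, alpha):
    """Classical BH step-up decision rule, independent of the adjustment."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = np.flatnonzero(sorted_p <= alpha * np.arange(1, n + 1) / n)
    reject = np.zeros(n, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return reject

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestGMT:
    def write(self, path, lines):
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_union_universe(self, tmp_path):
        gmt = self.write(tmp_path / "s.gmt", [
            "T1\tfirst\ta\tb\tc",
            "T2\tsecond\tc\td\te\tf",
        ])
        col = read_gene_sets(gmt)
        assert len(col.universe) == 6
        assert col.sets["T1"][1] == frozenset("abc")

    def test_duplicate_member_warns(self, tmp_path):
        gmt = self.write(tmp_path / "d.gmt", ["T1\tx\ta\ta\tb"])
        with pytest.warns(UserWarning, match="duplicate"):
            col = read_gene_sets(gmt)
        assert col.sets["T1"][1] == frozenset("ab")

    def test_malformed_line_reports_number(self, tmp_path):
        gmt = self.write(tmp_path / "m.gmt", ["T1\tonly-description"])
        with pytest.raises(ValueError, match=":1:"):
            read_gene_sets(gmt)

    def test_empty_file_rejected(self, tmp_path):
        (tmp_path / "e.gmt").write_text("")
        with pytest.raises(ValueError, match="no gene sets"):
            read_gene_sets(tmp_path / "e.gmt")


class TestEnrich:
    @pytest.fixture
    def collection(self):
        universe = frozenset(f"g{i}" for i in range(100))
        return GeneSetCollection(
            sets={
                "FULL": ("fully recovered term", frozenset(f"g{i}" for i in range(8))),
                "HALF": ("partial term", frozenset(f"g{i}" for i in range(4, 24))),
                "NONE": ("disjoint term", frozenset(f"g{i}" for i in range(50, 70))),
            },
            universe=universe,
        )

    def test_full_membership_query_is_top_hit(self, collection):
        res = enrich([f"g{i}" for i in range(8)], collection)
        top = res.iloc[0]
        assert top["term_id"] == "FULL"
        assert top["m"] == top["M"] == 8
        assert top["p_value"] == res["p_value"].min()

    def test_min_overlap_filter_empties_result(self, collection):
        res = enrich([f"g{i}" for i in range(8)], collection, min_overlap=99)
        assert len(res) == 0

    def test_out_of_universe_query_dropped(self, collection):
        res = enrich(["g0", "g1", "not_a_gene"], collection)
        assert (res["n"] == 2).all()

    def test_empty_in_universe_query_raises(self, collection):
        with pytest.raises(ValueError):
            enrich(["nope"], collection)

    def test_member_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside the universe"):
            GeneSetCollection(sets={"T": ("x", frozenset("ab"))},
                              universe=frozenset("a"))

    def test_random_query_rejection_rate_matches_oracle(self, collection):
        """Uniform random queries reject each term at roughly the exact
        oracle rate (discrete test, so at most the nominal level)."""
        rng = np.random.default_rng(31)
        universe = sorted(collection.universe)
        hits = 0
        trials = 300
        for _ in range(trials):
            q = rng.choice(universe, size=10, replace=False)
            res = enrich(list(q), collection, min_overlap=0)
            hits += int((res[res["term_id"] == "HALF"]["p_value"] < 0.05).any())
        # exact oracle rejection rate for the HALF term (M=20, n=10, N=100)
        from scipy import stats
        pm = stats.hypergeom.pmf(np.arange(0, 11), 100, 20, 10)
        crit = np.array([hypergeom_pvalue(100, 10, 20, m) for m in range(11)])
        oracle_rate = pm[crit < 0.05].sum()
        se = np.sqrt(oracle_rate * (1 - oracle_rate) / trials)
        assert abs(hits / trials - oracle_rate) < max(3 * se, 0.02)
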
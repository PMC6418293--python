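"""Ensemble enrichment: algorithm closed forms, enumeration oracles,
combination rules, BH and the ensemble driver."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from evfusion.enrichment import (
    ContrastStats,
    EnsembleConfig,
    bh_adjust,
    combine_pvalues,
    ensemble_enrichment,
    gene_level_stats,
    ks_enrichment,
    ora_test,
    ranksum_test,
)
from evfusion.graph import GeneSet, ValidationError


def stats_of(values, name="c"):
    genes = [f"g{i:03d}" for i in range(len(values))]
    return ContrastStats(name, genes, np.asarray(values, float))


class TestGeneLevelStats:
    def test_identical_groups_give_zero(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0, 1.0]], index=["g0"], columns=list("abcd")
        )
        cs = gene_level_stats(expr, ["x", "x", "y", "y"])
        assert cs.stats[0] == 0.0

    def test_sign_convention_group2_minus_group1(self):
        rng = np.random.default_rng(0)
        vals = np.array([[0.0, 0.0, 1.0, 1.0]]) + rng.normal(0, 1e-6, (1, 4))
        expr = pd.DataFrame(vals, index=["g0"], columns=list("abcd"))
        cs = gene_level_stats(expr, ["x", "x", "y", "y"])
        assert cs.stats[0] > 100

    def test_matches_welch_formula_on_fixture(self, rng):
        """10 genes, 3+3 samples: agree with the Welch formula evaluated
        directly (pooled-free variance, Welch denominator)."""
        x = rng.normal(size=(10, 3))
        y = rng.normal(loc=0.5, size=(10, 3))
        expr = pd.DataFrame(
            np.hstack([x, y]),
            index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(6)],
        )
        cs = gene_level_stats(expr, ["a"] * 3 + ["b"] * 3)
        for i in range(10):
            num = y[i].mean() - x[i].mean()
            den = np.sqrt(x[i].var(ddof=1) / 3 + y[i].var(ddof=1) / 3)
            assert cs.stats[i] == pytest.approx(num / den, rel=1e-9)

    def test_single_sample_group_rejected(self):
        expr = pd.DataFrame(np.zeros((3, 3)), columns=list("abc"))
        with pytest.raises(ValidationError):
            gene_level_stats(expr, ["x", "x", "y"])


class TestOra:
    def test_complete_overlap_closed_form(self):
        """All 5 set members inside a 5-gene selection from a 20-gene
        universe: p = 1/C(20,5)."""
        values = list(range(20, 0, -1))
        cs = stats_of(values)
        gs = GeneSet.of("s", [f"g{i:03d}" for i in range(5)])
        cfg = EnsembleConfig(ora_selection=0.25)
        assert ora_test(gs, cs, cfg) == pytest.approx(1 / comb(20, 5), rel=1e-9)
        assert ora_test(gs, cs, cfg) == pytest.approx(6.449e-5, rel=1e-3)

    def test_zero_overlap_is_vacuous_tail(self):
        values = list(range(20, 0, -1))
        cs = stats_of(values)
        gs = GeneSet.of("s", [f"g{i:03d}" for i in range(15, 20)])
        assert ora_test(gs, cs, EnsembleConfig(ora_selection=0.25)) == 1.0

    def test_tail_matches_exhaustive_selection_enumeration(self):
        """p(k) from the closed form equals the empirical tail over all
        C(10,5) equally likely selections."""
        cs = stats_of(range(10))
        set_idx = {0, 2, 4, 6, 8}
        n_total = comb(10, 5)
        for k_obs in range(6):
            count = sum(
                1
                for sel in combinations(range(10), 5)
                if len(set_idx & set(sel)) >= k_obs
            )
            closed = st.hypergeom.sf(k_obs - 1, 10, 5, 5)
            assert closed == pytest.approx(count / n_total, rel=1e-9)

    def test_disjoint_universe_warns_and_returns_one(self, caplog):
        cs = stats_of(range(10))
        gs = GeneSet.of("s", ["absent1", "absent2"])
        with caplog.at_level("WARNING"):
            assert ora_test(gs, cs) == 1.0
        assert "shares no genes" in caplog.text


class TestRanksum:
    def test_most_extreme_table_exact_p(self):
        """Members occupying the top m |stat| ranks: two-sided exact
        p = 2/C(N,m)."""
        n, m = 10, 3
        cs = stats_of(range(n, 0, -1))
        gs = GeneSet.of("s", [f"g{i:03d}" for i in range(m)])
        assert ranksum_test(gs, cs) == pytest.approx(2 / comb(n, m), rel=1e-9)

    def test_near_total_set_is_powerless(self):
        # leaving out a single median-ranked gene gives no separation
        cs = stats_of(range(12))
        gs = GeneSet.of("s", [f"g{i:03d}" for i in range(12) if i != 5])
        assert ranksum_test(gs, cs) > 0.3

    def test_null_pvalues_uniform(self, rng):
        """Random sets on a 200-gene universe: asymptotic rank-sum p is
        uniform (KS not rejected at alpha=0.01, 1000 replicates)."""
        pvals = []
        for _ in range(1000):
            cs = stats_of(rng.normal(size=200))
            members = rng.choice(200, size=20, replace=False)
            gs = GeneSet.of("s", [f"g{i:03d}" for i in members])
            pvals.append(ranksum_test(gs, cs))
        assert st.kstest(pvals, "uniform").pvalue > 0.01


def _running_sum_es(member_mask, abs_stats_sorted):
    """Independent oracle: literal running-sum walk over the ranking."""
    n = len(member_mask)
    k = int(member_mask.sum())
    w = abs_stats_sorted * member_mask
    if w.sum() == 0:
        w = member_mask.astype(float)
    inc = w / w.sum()
    dec = (~member_mask).astype(float) / (n - k)
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    lo, hi = running.min(), running.max()
    return hi if hi >= -lo else lo


class TestKsEnrichment:
    def test_members_at_top_reach_maximal_score(self):
        cs = stats_of(np.linspace(5, 0.1, 12))
        gs = GeneSet.of("s", [f"g{i:03d}" for i in range(3)])
        es, _ = ks_enrichment(gs, cs)
        assert es == pytest.approx(1.0)

    def test_interleaved_members_score_low(self, rng):
        n = 400
        cs = stats_of(np.linspace(3, -3, n))
        members = [f"g{i:03d}" for i in range(0, n, 40)]
        es, p = ks_enrichment(GeneSet.of("s", members), cs)
        assert abs(es) < 0.5
        assert p > 0.05

    def test_exhaustive_permutation_matches_enumeration_oracle(self):
        """12-gene universe, 3-member set: the exhaustive permutation p must
        equal a direct enumeration of all C(12,3) placements with an
        independently coded running sum."""
        rng = np.random.default_rng(4)
        values = rng.normal(size=12)
        cs = stats_of(values)
        members = ["g001", "g005", "g009"]
        gs = GeneSet.of("s", members)
        es, p = ks_enrichment(gs, cs)  # C(12,3)=220 <= 999 -> exhaustive

        order = sorted(range(12), key=lambda i: (-values[i], f"g{i:03d}"))
        abs_sorted = np.abs(values)[order]
        member_pos = {order.index(int(m[1:])) for m in members}
        mask = np.array([i in member_pos for i in range(12)])
        es_oracle = _running_sum_es(mask, abs_sorted)
        assert es == pytest.approx(es_oracle, rel=1e-9)

        null = []
        for combo in combinations(range(12), 3):
            m = np.zeros(12, dtype=bool)
            m[list(combo)] = True
            null.append(_running_sum_es(m, abs_sorted))
        p_oracle = np.mean(np.abs(null) >= abs(es_oracle) - 1e-12)
        assert p == pytest.approx(p_oracle, rel=1e-9)

    def test_sampled_null_pvalues_uniform(self, rng):
        """Continuous statistics, random member placement: sampled KS
        permutation p is uniform on its grid."""
        cfg = EnsembleConfig(ks_n_perm=199)
        pvals = []
        for r in range(500):
            cs = stats_of(rng.normal(size=60))
            members = rng.choice(60, size=8, replace=False)
            gs = GeneSet.of("s", [f"g{i:03d}" for i in members])
            _, p = ks_enrichment(gs, cs, cfg,
                                 rng=np.random.default_rng(10_000 + r))
            pvals.append(p)
        assert st.kstest(pvals, "uniform").pvalue > 0.01


class TestOraNullBehaviour:
    def test_null_pvalues_super_uniform(self, rng):
        """A discrete test's null p satisfies P(p <= t) <= t; check with
        slack for sampling noise."""
        pvals = []
        for _ in range(1000):
            cs = stats_of(rng.normal(size=200))
            members = rng.choice(200, size=20, replace=False)
            gs = GeneSet.of("s", [f"g{i:03d}" for i in members])
            pvals.append(ora_test(gs, cs))
        pvals = np.sort(pvals)
        for t in (0.05, 0.1, 0.25, 0.5):
            assert np.mean(pvals <= t) <= t + 0.05


class TestCombination:
    def test_fisher_no_evidence(self):
        assert combine_pvalues([1.0, 1.0], "fisher") == pytest.approx(1.0)

    def test_fisher_half_half(self):
        # chi2 = -2(ln .5 + ln .5) = 2.7726 on 4 df
        assert combine_pvalues([0.5, 0.5], "fisher") == pytest.approx(
            st.chi2.sf(2.772589, 4), rel=1e-5
        )
        assert combine_pvalues([0.5, 0.5], "fisher") == pytest.approx(0.5966, abs=1e-3)

    def test_stouffer_symmetry(self):
        assert combine_pvalues([0.5, 0.5], "stouffer") == pytest.approx(0.5)

    def test_wilkinson_median_is_beta_tail(self):
        ps = [0.1, 0.4, 0.9]
        assert combine_pvalues(ps, "wilkinson_median") == pytest.approx(
            st.beta.cdf(0.4, 2, 2)
        )

    def test_out_of_range_pvalues_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5], [0.5]):
            with pytest.raises(ValidationError):
                combine_pvalues(bad)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=6
        ),
        hst.data(),
    )
    def test_fisher_monotone_property(self, ps, data):
        """Decreasing any single input p never increases the Fisher
        combination."""
        i = data.draw(hst.integers(min_value=0, max_value=len(ps) - 1))
        smaller = list(ps)
        smaller[i] = ps[i] / 2
        assert combine_pvalues(smaller, "fisher") <= combine_pvalues(
            ps, "fisher"
        ) + 1e-12


class TestBH:
    def test_step_up_by_hand(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_tied_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert bh_adjust([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_adjusted_never_below_raw(self, rng):
        ps = rng.uniform(1e-4, 1, size=20)
        adj = bh_adjust(list(ps))
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))
        assert all(0 < a <= 1 for a in adj)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        hst.lists(
            hst.floats(min_value=1e-6, max_value=1.0), min_size=2, max_size=10
        ),
        hst.randoms(use_true_random=False),
    )
    def test_permutation_equivariance_property(self, ps, rnd):
        """BH commutes with any permutation of its input."""
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        base = bh_adjust(ps)
        shuffled = bh_adjust([ps[i] for i in idx])
        for j, i in enumerate(idx):
            assert shuffled[j] == pytest.approx(base[i], rel=1e-12)


class TestEnsemble:
    def _contrast(self, rng, name="c"):
        return stats_of(rng.normal(size=100), name)

    def test_bookkeeping_rows_and_within_contrast_bh(self, rng):
        sets = [
            GeneSet.of(f"s{i}", [f"g{j:03d}" for j in rng.choice(100, 10, False)])
            for i in range(5)
        ]
        contrasts = [self._contrast(rng, f"c{i}") for i in range(4)]
        cfg = EnsembleConfig(ks_n_perm=99)
        et = ensemble_enrichment(sets, contrasts, cfg)
        assert len(et.table) == 20
        for _, grp in et.table.groupby("contrast"):
            assert list(grp["adjusted_p"]) == pytest.approx(
                bh_adjust(list(grp["combined_p"]))
            )
            assert (grp["adjusted_p"] >= grp["combined_p"] - 1e-12).all()

    def test_duplicate_contrast_rows_identical(self, rng):
        sets = [
            GeneSet.of("s0", [f"g{j:03d}" for j in range(10)]),
            GeneSet.of("s1", [f"g{j:03d}" for j in range(50, 65)]),
        ]
        c = self._contrast(rng)
        cfg = EnsembleConfig(ks_n_perm=99)
        et = ensemble_enrichment(sets, [c, ContrastStats("c2", c.universe, c.stats)], cfg)
        a = et.table[et.table.contrast == "c"].drop(columns="contrast")
        b = et.table[et.table.contrast == "c2"].drop(columns="contrast")
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_config_invariants(self):
        with pytest.raises(Exception):
            EnsembleConfig(algorithms=("ora",))
        with pytest.raises(Exception):
            EnsembleConfig(ks_n_perm=10)
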
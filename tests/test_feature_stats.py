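"""Fisher, BH, Mann-Whitney, KS, isoelectric point, GO, fragment tiling."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

import serptools as st
from serptools.feature_stats import (
    PkaTable, enrichment_table, net_charge, set_overlap,
)
from serptools.onsets import onset_window_peptide
from serptools.synthetic import simulate_genome


def fisher_oracle(a, b, c, d):
    """Two-sided p by explicit factorial enumeration in exact rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)

    def prob(x):
        return Fraction(
            math.factorial(r1) * math.factorial(r2)
            * math.factorial(c1) * math.factorial(n - c1),
            math.factorial(n) * math.factorial(x) * math.factorial(r1 - x)
            * math.factorial(c1 - x) * math.factorial(r2 - c1 + x),
        )

    observed = prob(a)
    return float(sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= observed))


class TestFisher:
    def test_enumeration_example(self):
        _, p = st.fisher_exact_two_sided(2, 8, 8, 2)
        assert p == pytest.approx(fisher_oracle(2, 8, 8, 2), rel=1e-12)

    def test_balanced_table_is_null(self):
        odds, p = st.fisher_exact_two_sided(5, 5, 5, 5)
        assert odds == 1.0 and p == 1.0

    def test_zero_margin_is_degenerate(self):
        _, p = st.fisher_exact_two_sided(0, 0, 3, 7)
        assert p == 1.0

    def test_zero_cell_odds_ratio_conventions(self):
        odds, _ = st.fisher_exact_two_sided(3, 0, 2, 5)
        assert np.isinf(odds)
        odds, _ = st.fisher_exact_two_sided(0, 3, 0, 5)
        assert np.isnan(odds)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            st.fisher_exact_two_sided(-1, 2, 3, 4)

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 30, 4))
            _, p1 = st.fisher_exact_two_sided(a, b, c, d)
            _, p2 = stats.fisher_exact([[a, b], [c, d]])
            assert p1 == pytest.approx(p2, abs=1e-10)

    def test_large_table_path_agrees_with_scipy(self):
        a, b, c, d = 150, 900, 1100, 21400
        _, p1 = st.fisher_exact_two_sided(a, b, c, d)
        _, p2 = stats.fisher_exact([[a, b], [c, d]])
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestBhAdjust:
    def test_closed_form_sequence(self):
        np.testing.assert_allclose(
            st.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert st.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_textbook_step_up_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        order = np.argsort(p)
        m = p.size
        adj_sorted = p[order] * m / np.arange(1, m + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(st.bh_adjust(p), oracle, atol=1e-12)

    def test_permutation_equivariant_dominating_and_capped(self):
        rng = np.random.default_rng(2)
        p = rng.random(30)
        adj = st.bh_adjust(p)
        perm = rng.permutation(30)
        np.testing.assert_allclose(st.bh_adjust(p[perm]), adj[perm], atol=1e-12)
        assert np.all(adj >= p) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            st.bh_adjust([0.5, 1.5])


def mwu_enumeration_oracle(x, y):
    """Exact two-sided p by enumerating every labeling of the pooled sample."""
    x, y = list(x), list(y)
    pooled = x + y
    nx = len(x)

    def u_stat(xs, ys):
        return sum(1.0 if xi > yi else 0.5 if xi == yi else 0.0
                   for xi in xs for yi in ys)

    observed = u_stat(x, y)
    mean_u = nx * len(y) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_are_not_significant(self):
        u, p = st.mann_whitney_u([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert u == pytest.approx(8.0)  # U at its mean
        assert p > 0.9

    def test_complete_separation_has_minimal_exact_p(self):
        x = [10.0, 11.0, 12.0, 13.0, 14.0]
        y = [1.0, 2.0, 3.0, 4.0, 5.0]
        u, p = st.mann_whitney_u(x, y)
        assert u == 25.0
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_matches_enumeration_over_all_labelings(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 5)
            _, p = st.mann_whitney_u(x, y)
            assert p == pytest.approx(mwu_enumeration_oracle(x, y), rel=1e-9)

    def test_large_samples_use_corrected_normal_approximation(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.8, 1, 40)
        _, p = st.mann_whitney_u(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert p == pytest.approx(res.pvalue, rel=1e-12)
        assert p < 0.01


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        d, p = st.ks_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == pytest.approx(1.0)

    def test_disjoint_supports(self):
        d, _ = st.ks_two_sided([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert d == 1.0

    def test_null_rejection_rate_is_calibrated(self):
        rng = np.random.default_rng(5)
        rejected = sum(
            st.ks_two_sided(rng.normal(size=100), rng.normal(size=100))[1] < 0.05
            for _ in range(1000)
        )
        assert 30 <= rejected <= 70


class TestIsoelectricPoint:
    def _grid_oracle(self, seq, pka=None):
        grid = np.arange(0.0, 14.0001, 1e-4)
        charges = np.array([net_charge(seq, ph, pka) for ph in grid[::100]])
        coarse = grid[::100][np.argmin(np.abs(charges))]
        fine = np.arange(max(0, coarse - 0.02), min(14, coarse + 0.02), 1e-4)
        charges = np.array([net_charge(seq, ph, pka) for ph in fine])
        return fine[np.argmin(np.abs(charges))]

    def test_bisection_matches_dense_grid_scan(self):
        rng = np.random.default_rng(6)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(20):
            seq = "".join(rng.choice(aas, size=rng.integers(5, 60)))
            pi = st.isoelectric_point(seq)
            assert abs(net_charge(seq, pi)) < 1e-4
            assert pi == pytest.approx(self._grid_oracle(seq), abs=1e-3)

    def test_appending_lysine_never_decreases_pi(self):
        for seq in ("GAVL", "DDEE", "KKRR", "MNQST"):
            assert st.isoelectric_point(seq + "K") >= st.isoelectric_point(seq) - 1e-6

    def test_appending_aspartate_never_increases_pi(self):
        for seq in ("GAVL", "DDEE", "KKRR", "MNQST"):
            assert st.isoelectric_point(seq + "D") <= st.isoelectric_point(seq) + 1e-6

    def test_composition_only_dependence(self):
        seq = "MKRDDEAVLKY"
        scrambled = "".join(sorted(seq))
        assert st.isoelectric_point(seq) == pytest.approx(
            st.isoelectric_point(scrambled), abs=1e-9)

    def test_nonstandard_residue_rejected(self):
        with pytest.raises(ValueError):
            st.isoelectric_point("MKX")

    def test_custom_pka_table_validated(self):
        with pytest.raises(ValueError):
            PkaTable(pka={"K": 15.0, "R": 12.5, "H": 6.5, "D": 3.9,
                          "E": 4.1, "C": 8.5, "Y": 10.1})


class TestAaEnrichment:
    def test_identical_composition_is_null(self):
        proteins = ["ACDEFGHIKLMNPQRSTVWY" * 5] * 10
        windows = ["ACDEFGHIKLMNPQRSTVWY"] * 10
        results = st.aa_enrichment(windows, proteins)
        assert all(r.odds_ratio == pytest.approx(1.0) for r in results)
        assert all(r.p_adj > 0.05 for r in results)

    def test_pure_lysine_windows_against_lysine_free_background(self):
        results = st.aa_enrichment(["KKKKKKKKKK"] * 5, ["AAAAAGGGGG"] * 20)
        by_item = {r.item: r for r in results}
        assert np.isinf(by_item["K"].odds_ratio)
        assert by_item["K"].flag == "odds_infinite"
        assert by_item["K"].p_adj < 1e-10

    def test_planted_kr_enrichment_is_recovered(self):
        cfg = st.SimulationConfig(seed=3, n_target_genes=50, n_background_genes=0)
        _, proteins, truth = simulate_genome(cfg)
        windows = [onset_window_peptide(proteins[g], r.onset_codon)
                   for g, r in truth.items() if r.is_target]
        results = st.aa_enrichment([w for w in windows if w],
                                   list(proteins.values()))
        top2 = {r.item for r in sorted(results, key=lambda r: r.p_adj)[:2]}
        assert top2 == {"K", "R"}

    def test_enrichment_table_shape(self):
        results = st.aa_enrichment(["KR"] * 3, ["ACDEFGHIKLMNPQRSTVWY"] * 3)
        df = enrichment_table(results)
        assert len(df) == 20 and set(df.item) == set("ACDEFGHIKLMNPQRSTVWY")


class TestGoEnrichment:
    @staticmethod
    def _go_map(term_members):
        import pandas as pd
        rows = [{"gene_id": g, "term_id": t, "term_name": t.lower()}
                for t, members in term_members.items() for g in members]
        return pd.DataFrame(rows)

    def test_term_covering_all_hits_has_minimal_p(self):
        background = [f"g{i}" for i in range(400)]
        hits = background[:30]
        go = self._go_map({
            "T_HITS": hits + background[300:380],
            "T_RAND": background[100:205],
        })
        df = st.go_enrichment(hits, background, go)
        assert df.iloc[0].term_id == "T_HITS" and df.iloc[0].reported

    def test_independent_term_has_odds_near_one(self):
        rng = np.random.default_rng(7)
        background = [f"g{i}" for i in range(500)]
        hits = list(rng.choice(background, 50, replace=False))
        members = list(rng.choice(background, 150, replace=False))
        df = st.go_enrichment(hits, background, self._go_map({"T": members}))
        assert 0.3 < df.iloc[0].odds_ratio < 3.0

    def test_min_term_size_is_strictly_more_than(self):
        background = [f"g{i}" for i in range(300)]
        hits = background[:20]
        go = self._go_map({
            "T_100": background[:100],     # exactly 100: excluded
            "T_101": background[:101],     # strictly more: tested
        })
        df = st.go_enrichment(hits, background, go)
        assert set(df.term_id) == {"T_101"}

    def test_planted_enriched_term_detected(self):
        cfg = st.SimulationConfig(seed=17)
        ds = st.simulate_dataset(cfg)
        targets = ds.target_ids()
        background = [g.gene_id for g in ds.annotation.coding_genes()]
        df = st.go_enrichment(targets, background, ds.go_map)
        planted = df[df.term_id == "GO:9000001"]
        assert len(planted) == 1 and planted.iloc[0].p_value < 0.1

    def test_empty_hit_set_rejected(self):
        with pytest.raises(ValueError):
            st.go_enrichment([], ["g1"], self._go_map({"T": ["g1"]}))


class TestFragmentTiling:
    def test_550_residue_protein_gives_ten_full_fragments(self):
        protein = "A" * 550
        frags = st.nls_fragment_tiling(protein)
        assert len(frags) == 10
        assert [f[0] for f in frags] == list(range(1, 452, 50))
        assert all(f[1] - f[0] + 1 == 100 for f in frags)

    def test_short_proteins(self):
        assert [(s, e) for s, e, _ in st.nls_fragment_tiling("A" * 120)] == \
            [(1, 100), (51, 120)]
        assert [(s, e) for s, e, _ in st.nls_fragment_tiling("A" * 40)] == [(1, 40)]

    def test_coverage_at_most_twice_with_half_overlap(self):
        for L in (40, 99, 100, 101, 240, 549, 550, 551, 700):
            frags = st.nls_fragment_tiling("A" * L)
            coverage = np.zeros(L + 1)
            for s, e, seq in frags:
                assert len(seq) == e - s + 1
                coverage[s:e + 1] += 1
            covered_until = max(e for _, e, _ in frags)
            assert np.all(coverage[1:covered_until + 1] >= 1)
            assert np.all(coverage <= 2)

    def test_overlap_must_be_smaller_than_fragment(self):
        with pytest.raises(ValueError):
            st.nls_fragment_tiling("A" * 100, frag_len=50, overlap=50)


def test_set_overlap_counts():
    df = set_overlap({"a": {"x", "y"}, "b": {"y", "z"}})
    row = df[(df.set_a == "a") & (df.set_b == "b")].iloc[0]
    assert row.intersection == 1 and row.union == 3
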
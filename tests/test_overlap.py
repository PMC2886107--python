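"""Representation factor, exact hypergeometric tests and term enrichment."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import beepop as bp
from beepop.lme import SignificanceTable


def enum_overlap_pvalue(o, n_x, n_y, N):
    """Oracle: P(X >= o) by explicit hypergeometric PMF summation."""
    total = comb(N, n_y)
    return sum(
        comb(n_x, k) * comb(N - n_x, n_y - k) for k in range(o, min(n_x, n_y) + 1)
    ) / total


class TestRepresentationFactor:
    def test_printed_formula(self):
        assert bp.representation_factor(10, 20, 30, 100) == pytest.approx(10 * 100 / 600)

    def test_expected_overlap_gives_one(self):
        assert bp.representation_factor(6, 20, 30, 100) == pytest.approx(1.0)

    def test_zero_overlap_gives_zero(self):
        assert bp.representation_factor(0, 20, 30, 100) == 0.0

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            bp.representation_factor(25, 20, 30, 100)

    def test_rf_above_one_iff_overlap_above_expectation(self):
        N = 60
        for n_x in (5, 12, 20):
            for n_y in (5, 15):
                for o in range(0, min(n_x, n_y) + 1):
                    rf = bp.representation_factor(o, n_x, n_y, N)
                    assert (rf > 1) == (o > n_x * n_y / N)


class TestHypergeomOverlap:
    def test_full_overlap_enumeration(self):
        # N=10, both sets of size 5, all 5 shared: 1/C(10,5)
        assert bp.hypergeom_overlap_test(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_zero_overlap_is_certain(self):
        assert bp.hypergeom_overlap_test(0, 5, 5, 10) == 1.0

    def test_symmetry_in_set_sizes(self):
        assert bp.hypergeom_overlap_test(3, 7, 12, 40) == pytest.approx(
            bp.hypergeom_overlap_test(3, 12, 7, 40)
        )

    @settings(derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_pmf_enumeration_to_1e12(self, data):
        N = data.draw(st.integers(5, 60))
        n_x = data.draw(st.integers(1, N))
        n_y = data.draw(st.integers(1, N))
        o = data.draw(st.integers(0, min(n_x, n_y)))
        p = bp.hypergeom_overlap_test(o, n_x, n_y, N)
        assert p == pytest.approx(enum_overlap_pvalue(o, n_x, n_y, N), abs=1e-12)


class TestSimilarityMatrix:
    def table(self, up, down, alpha=0.05):
        pops = sorted(set(up) | set(down))
        return SignificanceTable(
            alpha=alpha,
            up={p: set(up.get(p, ())) for p in pops},
            down={p: set(down.get(p, ())) for p in pops},
        )

    def test_identical_sets_have_max_rf_and_min_p(self):
        bg = [f"P{i}" for i in range(40)]
        shared = set(bg[:8])
        tab = self.table({"X": shared, "Y": shared, "Z": set(bg[20:24])}, {})
        sim = bp.similarity_matrix(tab, bg)
        row = sim.set_index(["pop_x", "pop_y"]).loc[("X", "Y")]
        assert row["representation_factor"] == pytest.approx(40 / 8)
        assert row["p_value"] == sim["p_value"].min()

    def test_disjoint_sets_rf_zero_p_one(self):
        bg = [f"P{i}" for i in range(40)]
        tab = self.table({"X": set(bg[:10]), "Y": set(bg[10:20])}, {})
        sim = bp.similarity_matrix(tab, bg).iloc[0]
        assert sim["representation_factor"] == 0.0
        assert sim["p_value"] == pytest.approx(1.0)

    def test_signed_overlap_requires_same_direction(self):
        bg = [f"P{i}" for i in range(30)]
        tab = self.table({"X": {"P1", "P2"}}, {"Y": {"P1", "P2"}})
        signed = bp.similarity_matrix(tab, bg, direction="signed").iloc[0]
        blind = bp.similarity_matrix(tab, bg, direction="blind").iloc[0]
        assert signed["n_overlap"] == 0
        assert blind["n_overlap"] == 2

    def test_empty_signature_flagged_not_crashed(self):
        bg = [f"P{i}" for i in range(10)]
        tab = self.table({"X": set(), "Y": {"P1"}}, {})
        sim = bp.similarity_matrix(tab, bg).iloc[0]
        assert np.isnan(sim["representation_factor"])
        assert not sim["significant"]

    def test_random_sets_calibration_under_permutation(self):
        """P(p < 0.05) for random same-size sets should be ~5% (conservative
        discreteness allowed: the exact test never exceeds the nominal rate)."""
        rng = np.random.default_rng(12)
        bg = [f"P{i}" for i in range(60)]
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            x = set(rng.choice(bg, 15, replace=False))
            y = set(rng.choice(bg, 15, replace=False))
            p = bp.hypergeom_overlap_test(len(x & y), 15, 15, 60)
            hits += p < 0.05
        rate = hits / n_perm
        assert rate <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_perm)


class TestTermEnrichment:
    def test_universal_term_is_not_enriched(self):
        bg = [f"P{i}" for i in range(12)]
        ann = {p: {"T"} for p in bg}
        res = bp.term_enrichment(bg[:4], bg, ann)
        assert res.loc[0, "p_value"] == pytest.approx(1.0)

    def test_exclusive_term_matches_enumeration(self):
        # foreground = exactly the term's carriers: p = 1 / C(n_bg, n_fg)
        bg = [f"P{i}" for i in range(12)]
        fg = bg[:5]
        ann = {p: {"T"} for p in fg}
        res = bp.term_enrichment(fg, bg, ann)
        assert res.loc[0, "p_value"] == pytest.approx(1 / comb(12, 5), abs=1e-12)

    def test_bh_adjustment_arithmetic_and_monotonicity(self):
        bg = [f"P{i}" for i in range(100)]
        fg = bg[:10]
        # craft three terms with increasing raw p
        ann = {}
        for p in bg[:10]:
            ann.setdefault(p, set()).add("T1")
        for p in bg[:30]:
            ann.setdefault(p, set()).add("T2")
        for p in bg:
            ann.setdefault(p, set()).add("T3")
        res = bp.term_enrichment(fg, bg, ann).set_index("term_id")
        raw = res["p_value"]
        adj = res["fdr_adjusted_p"]
        assert (adj >= raw - 1e-15).all()
        ordered = res.sort_values("p_value")
        assert ordered["fdr_adjusted_p"].is_monotonic_increasing

    def test_bh_on_known_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.03], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_foreground_outside_background_rejected(self):
        with pytest.raises(ValueError):
            bp.term_enrichment(["X"], ["A", "B"], {})

    def test_unannotated_ids_count_in_background(self):
        bg = ["A", "B", "C", "D"]
        ann = {"A": {"T"}, "B": {"T"}}
        res = bp.term_enrichment(["A", "B"], bg, ann)
        row = res.iloc[0]
        assert row["n_bg"] == 4 and row["n_bg_with_term"] == 2
        assert row["p_value"] == pytest.approx(enum_overlap_pvalue(2, 2, 2, 4), abs=1e-12)
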
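"""Fisher/binomial enrichment machinery against enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cnvreg.enrich import (
    bh_adjust,
    binomial_overrep,
    fisher_exact_two_sided,
    qtl_enrichment,
)
from conftest import fisher_two_sided_enumeration  # noqa: F401


class TestFisher:
    def test_hand_enumerated_examples(self):
        assert fisher_exact_two_sided(3, 1, 1, 3) == pytest.approx(34 / 70)
        assert fisher_exact_two_sided(5, 0, 0, 5) == pytest.approx(2 / 252)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_two_sided(-1, 2, 3, 4)

    def test_matches_enumeration_small_sweep(self):
        # full oracle equivalence on every table with total <= 8
        for n in range(1, 9):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                assert fisher_exact_two_sided(a, b, c, d) == pytest.approx(
                    fisher_two_sided_enumeration(a, b, c, d), abs=1e-10
                ), (a, b, c, d)

    def test_symmetry_under_transpose(self):
        assert fisher_exact_two_sided(7, 2, 3, 9) == pytest.approx(
            fisher_exact_two_sided(7, 3, 2, 9)
        )


class TestBH:
    def test_hand_computed_stepup(self):
        got = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert got == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert bh_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30), st.randoms())
    def test_permutation_invariant_and_bounded(self, pvals, rnd):
        base = bh_adjust(pvals)
        assert np.all(base >= np.asarray(pvals) - 1e-12)  # never decreases p
        assert np.all(base <= 1.0 + 1e-12)
        order = list(range(len(pvals)))
        rnd.shuffle(order)
        permuted = bh_adjust([pvals[i] for i in order])
        restored = np.empty_like(permuted)
        restored[order] = np.arange(len(order))
        assert [permuted[order.index(i)] for i in range(len(pvals))] == pytest.approx(
            list(base)
        )


class TestQtlEnrichment:
    @staticmethod
    def _track(trait_sizes):
        rows = []
        qid = 0
        for trait, n in trait_sizes.items():
            for _ in range(n):
                rows.append({"feature_id": f"Q{qid}", "label": trait})
                qid += 1
        return pd.DataFrame(rows)

    def test_fully_overlapped_trait_vs_untouched_trait(self):
        qtl = self._track({"X": 4, "Y": 4})
        overlapped = set(qtl.loc[qtl["label"] == "X", "feature_id"])
        res = qtl_enrichment(overlapped, qtl)
        assert list(res["label"]) == ["X"]  # Y has no overlap: outside the family
        row = res.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (4, 0, 0, 4)
        # two-sided at margins (4,4,4,4): the opposite extreme table
        # (0,4,4,0) is equally improbable, so p = 2/70 (one-sided: 1/70)
        assert row["p"] == pytest.approx(2 / 70)
        assert row["p"] == pytest.approx(
            fisher_two_sided_enumeration(4, 0, 0, 4)
        )

    def test_no_signal_gives_p_one(self):
        # identical per-trait tables of the form (k, k, k, k)
        qtl = self._track({"X": 4, "Y": 4})
        overlapped = {"Q0", "Q1", "Q4", "Q5"}  # 2 of 4 in each trait
        res = qtl_enrichment(overlapped, qtl)
        assert res["p"].tolist() == pytest.approx([1.0, 1.0])

    def test_empty_track_rejected(self):
        with pytest.raises(ValueError):
            qtl_enrichment(set(), pd.DataFrame(columns=["feature_id", "label"]))

    def test_ranked_by_overlap_count_then_padj(self):
        rng = np.random.default_rng(0)
        qtl = self._track({f"t{i}": 10 for i in range(8)})
        overlapped = set(rng.choice(qtl["feature_id"], size=30, replace=False))
        res = qtl_enrichment(overlapped, qtl)
        assert list(res["a"]) == sorted(res["a"], reverse=True)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_margins_consistent(self):
        rng = np.random.default_rng(1)
        qtl = self._track({f"t{i}": int(rng.integers(3, 12)) for i in range(6)})
        overlapped = set(rng.choice(qtl["feature_id"], size=20, replace=False))
        res = qtl_enrichment(overlapped, qtl)
        for row in res.itertuples(index=False):
            assert row.a + row.b + row.c + row.d == len(qtl)
            assert row.a + row.b == row.n_qtl


class TestBinomialOverrep:
    def test_upper_tail_matches_direct_summation(self):
        universe = {f"g{i}" for i in range(1000)}
        term = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(90, 140)}  # n=50, k=10
        res = binomial_overrep(study, {"T": term}, universe)
        k, n, p0 = 10, 50, 0.1
        expected = sum(
            sps.binom.pmf(j, n, p0) for j in range(k, n + 1)
        )
        assert res.iloc[0]["p"] == pytest.approx(expected, rel=1e-9)
        assert (res.iloc[0]["k"], res.iloc[0]["n"]) == (k, n)

    def test_zero_hits_excluded_from_family(self):
        universe = {f"g{i}" for i in range(100)}
        res = binomial_overrep(
            {"g0"}, {"T": {f"g{i}" for i in range(50, 60)}}, universe
        )
        assert res.empty

    def test_term_equal_universe_forced_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        study = {f"g{i}" for i in range(5)}
        res = binomial_overrep(study, {"ALL": set(universe)}, universe)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            binomial_overrep({"g1"}, {}, set())
        with pytest.raises(ValueError):
            binomial_overrep({"zz"}, {}, {"g1"})
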
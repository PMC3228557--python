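"""Hypergeometric/chi-square/BH statistics and the gene-list procedures."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from promotif import (
    ValidationError,
    annotation_enrichment,
    benjamini_hochberg,
    chi_square_2x2,
    consensus_to_pwm,
    hypergeom_tail,
    motif_set_enrichment,
    parse_consensus,
    read_annotation,
    read_differential_table,
    select_common_set,
    select_differential,
)
from promotif.simulate import generate_promoters, plant_motif, stratified_rates


def enumerate_tail(k: int, K: int, n: int, N: int) -> float:
    """Independent oracle: exhaustive enumeration of all C(N, n) draws."""
    urn = [1] * K + [0] * (N - K)
    hits = sum(1 for draw in itertools.combinations(urn, n) if sum(draw) >= k)
    return hits / math.comb(N, n)


class TestHypergeomTail:
    @pytest.mark.parametrize(
        "k,K,n,N,expected",
        [
            (4, 5, 4, 10, 5 / 210),
            (2, 2, 2, 4, 1 / 6),
            (0, 3, 2, 8, 1.0),
            (5, 10, 5, 20, 252 / 15504),
        ],
    )
    def test_enumerated_values(self, k, K, n, N, expected):
        assert hypergeom_tail(k, K, n, N) == pytest.approx(expected, abs=1e-12)
        assert enumerate_tail(k, K, n, N) == pytest.approx(expected, abs=1e-12)

    def test_k_zero_is_one_for_any_valid_counts(self):
        assert hypergeom_tail(0, 7, 3, 12) == 1.0

    @pytest.mark.parametrize(
        "k,K,n,N", [(5, 4, 5, 10), (3, 3, 2, 10), (2, 5, 3, 4), (-1, 2, 2, 4)]
    )
    def test_inconsistent_counts_are_error(self, k, K, n, N):
        with pytest.raises(ValidationError):
            hypergeom_tail(k, K, n, N)

    def test_agrees_with_enumeration_on_small_grid(self):
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        assert hypergeom_tail(k, K, n, N) == pytest.approx(
                            enumerate_tail(k, K, n, N), abs=1e-12
                        )


class TestChiSquare:
    def test_hand_computed_statistic(self):
        stat, p = chi_square_2x2(20, 80, 10, 90)
        assert stat == pytest.approx(3.9216, abs=1e-4)
        assert p == pytest.approx(0.0477, abs=1e-4)

    def test_identical_proportions_give_zero(self):
        stat, p = chi_square_2x2(10, 90, 10, 90)
        assert stat == 0.0
        assert p == 1.0

    @pytest.mark.parametrize("table", [(0, 0, 10, 90), (5, 0, 5, 0), (0, 5, 0, 5)])
    def test_zero_margin_is_error(self, table):
        with pytest.raises(ValidationError, match="degenerate"):
            chi_square_2x2(*table)

    @given(
        a=st.integers(1, 60),
        b=st.integers(1, 60),
        c=st.integers(1, 60),
        d=st.integers(1, 60),
    )
    @settings(max_examples=50)
    def test_matches_scipy_contingency(self, a, b, c, d):
        stat, p = chi_square_2x2(a, b, c, d)
        ref = chi2_contingency([[a, b], [c, d]], correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.04], [0.03, 0.03, 0.04]),
            ([0.5], [0.5]),
            ([0.05, 0.05, 0.05, 0.05], [0.05, 0.05, 0.05, 0.05]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(benjamini_hochberg(p), expected)

    @pytest.mark.parametrize("p", [[0.1, 1.2], [-0.01], [0.5, float("nan")]])
    def test_out_of_range_is_error(self, p):
        with pytest.raises(ValidationError):
            benjamini_hochberg(p)

    @given(
        p=st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    @settings(max_examples=100)
    def test_adjustment_properties(self, p):
        q = benjamini_hochberg(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        # rank order preserved
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-15)

    @given(
        p=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=2, max_size=20
        ),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=50)
    def test_permutation_equivariance(self, p, seed):
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(p))
        q = benjamini_hochberg(p)
        q_perm = benjamini_hochberg(np.asarray(p)[perm])
        np.testing.assert_allclose(q_perm, q[perm])

    def test_null_fdr_control(self):
        """Expected BH selections under the uniform null stay near alpha*m."""
        rng = np.random.default_rng(77)
        selected = [
            int(np.sum(benjamini_hochberg(rng.uniform(size=100)) < 0.05))
            for _ in range(200)
        ]
        assert np.mean(selected) <= 5 + 3 * np.std(selected) / np.sqrt(len(selected)) + 1e-9


class TestMotifSetEnrichment:
    def test_planted_design_counts_and_significance(self):
        motif = parse_consensus("AAAGACATGTCCGTA", motif_id="planted")
        sset = generate_promoters(500, 400, seed=51)
        target = sset.gene_ids[:50]
        rates = stratified_rates(sset.gene_ids, set(target), 0.6, 0.06)
        planted, truth = plant_motif(sset, motif, rates, seed=52)
        table = motif_set_enrichment(
            target, planted, [consensus_to_pwm(motif)], cutoff=1.0
        )
        row = table.iloc[0]
        assert row["K"] == len(set(truth["gene_id"]))
        assert row["k"] == len(set(truth["gene_id"]) & set(target))
        assert row["significant"]
        assert row["p_adj"] >= row["p_hypergeom"]

    def test_target_equal_to_background_is_whole_urn(self, hbs, hbs_pwm):
        sset = generate_promoters(30, 300, seed=53)
        planted, _ = plant_motif(sset, hbs, 0.5, seed=54)
        table = motif_set_enrichment(
            planted.gene_ids, planted, [hbs_pwm], cutoff=1.0
        )
        row = table.iloc[0]
        assert row["k"] == row["K"]
        assert row["n"] == row["N"]
        assert row["p_hypergeom"] == 1.0

    def test_empty_target_is_error(self, hbs_pwm):
        sset = generate_promoters(5, 100, seed=2)
        with pytest.raises(ValidationError):
            motif_set_enrichment([], sset, [hbs_pwm], cutoff=1.0)

    def test_extent_truncation_applies(self):
        motif = parse_consensus("AAAGACATGTCCGTA", motif_id="m")
        sset = generate_promoters(40, 2000, seed=55)
        planted, truth = plant_motif(
            sset, motif, 1.0, position_model="fixed", fixed_start=-1500, seed=56
        )
        far = motif_set_enrichment(
            planted.gene_ids[:10], planted, [consensus_to_pwm(motif)],
            cutoff=1.0, extent=1000,
        )
        assert far.iloc[0]["K"] == 0  # all sites lie beyond 1 kb
        near = motif_set_enrichment(
            planted.gene_ids[:10], planted, [consensus_to_pwm(motif)],
            cutoff=1.0, extent=2000,
        )
        assert near.iloc[0]["K"] == len(planted)


class TestAnnotationEnrichment:
    def test_enumerated_example(self):
        background = [f"g{i}" for i in range(20)]
        annotation = {"T1": set(background[:10])}
        table = annotation_enrichment(background[:5], annotation, background)
        row = table.iloc[0]
        assert row["p_hypergeom"] == pytest.approx(252 / 15504, abs=1e-12)
        assert row["dataset_frequency"] == 100.0
        assert row["background_frequency"] == 50.0
        assert row["p_adj"] == row["p_hypergeom"]  # single term: m = 1

    def test_disjoint_term_not_selected(self):
        background = [f"g{i}" for i in range(20)]
        annotation = {"T1": set(background[10:]), "T2": set(background[:10])}
        table = annotation_enrichment(background[:5], annotation, background)
        row = table.set_index("item_id").loc["T1"]
        assert row["k"] == 0
        assert row["p_hypergeom"] == 1.0
        assert not row["selected"]

    def test_empty_annotation_is_error(self):
        with pytest.raises(ValidationError):
            annotation_enrichment(["g1"], {}, ["g1", "g2"])

    def test_annotation_outside_background_is_error(self):
        with pytest.raises(ValidationError, match="absent"):
            annotation_enrichment(["g1"], {"T": {"zz"}}, ["g1", "g2"])

    def test_read_annotation_dialects(self, tmp_path):
        three = tmp_path / "three.tsv"
        three.write_text("T1\tTerm one\tg1\nT1\tTerm one\tg2\nT2\tTerm two\tg3\n")
        two = tmp_path / "two.tsv"
        two.write_text("T1\tg1,g2\nT2\tg3\n")
        assert read_annotation(three) == read_annotation(two) == {
            "T1": {"g1", "g2"},
            "T2": {"g3"},
        }


class TestSelectDifferential:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "fold_change", "p_value"])

    def test_bh_worked_example_selects_true_five(self):
        rows = [(f"t{i}", 2.0, 0.001) for i in range(5)]
        rows += [(f"n{i}", 1.0, 0.5) for i in range(95)]
        up, down = select_differential(self._table(rows), correct=True)
        assert up == {f"t{i}" for i in range(5)}
        assert down == set()

    def test_nothing_significant(self):
        table = self._table([(f"g{i}", 1.5, 0.9) for i in range(10)])
        assert select_differential(table) == (set(), set())

    def test_single_down_gene_uncorrected_equals_corrected(self):
        table = self._table([("g1", 0.5, 0.04)])
        assert select_differential(table, correct=True) == (set(), {"g1"})
        assert select_differential(table, correct=False) == (set(), {"g1"})

    def test_signed_fold_convention(self):
        table = self._table([("g1", -2.0, 0.001), ("g2", 2.0, 0.001)])
        up, down = select_differential(table)
        assert (up, down) == ({"g2"}, {"g1"})

    def test_duplicate_gene_is_error(self):
        table = self._table([("g1", 2.0, 0.01), ("g1", 0.5, 0.01)])
        with pytest.raises(ValidationError, match="duplicate"):
            select_differential(table)

    def test_read_differential_table(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("gene_id\tfold_change\tp_value\ng1\t2.0\t0.01\n")
        table = read_differential_table(path)
        assert list(table["gene_id"]) == ["g1"]
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene_id\tfold\tp\ng1\t2.0\t0.01\n")
        with pytest.raises(ValidationError, match="columns"):
            read_differential_table(bad)


class TestSelectCommonSet:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["gene_id", "fold_change", "p_value"])

    def test_ten_percent_rule_on_up_genes(self):
        a = self._table([("g1", 2.0, 0.001), ("g2", 2.0, 0.001)])
        b = self._table([("g1", 1.7, 0.5), ("g2", 1.95, 0.5)])
        up, down = select_common_set(a, b)
        assert up == {"g1"}  # 1.7/2.0 = 0.85 <= 0.90
        assert down == set()  # g2: 0.975 > 0.90

    def test_down_genes_compared_on_magnitude(self):
        a = self._table([("g1", 0.5, 0.001), ("g2", 0.5, 0.001)])
        # g1 recovers toward 1 (diminished 2x alteration); g2 unchanged
        b = self._table([("g1", 0.7, 0.5), ("g2", 0.51, 0.5)])
        up, down = select_common_set(a, b)
        assert down == {"g1"}  # 0.5/0.7 = 0.714 <= 0.90
        assert up == set()

    def test_gene_missing_from_second_table_excluded(self):
        a = self._table([("g1", 2.0, 0.001)])
        b = self._table([("other", 1.0, 0.5)])
        assert select_common_set(a, b) == (set(), set())

    def test_invalid_cutoff_fraction(self):
        a = self._table([("g1", 2.0, 0.001)])
        with pytest.raises(ValidationError):
            select_common_set(a, a, cutoff_fraction=1.5)
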
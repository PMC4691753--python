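"""Gene classification, hypergeometric/permutation enrichment (with exact
enumeration and brute-force oracles), multiple-testing adjustment, and word
enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirmzt.enrichment import (
    adjust,
    classify_genes,
    enrich_hyper,
    enrich_perm,
    enrichment_table,
    intersect_classes,
    rank_mirnas,
    word_enrich,
)
from mirmzt.targets import UtrRecord

from helpers import random_seq


class TestClassifyGenes:
    @pytest.mark.parametrize(
        "log2fc,padj,expected",
        [
            (-1.5, 0.01, "down"),
            (1.5, 0.01, "up"),
            (-3.0, 0.20, "none"),  # large change but not significant
            (-0.5, 0.001, "none"),  # significant but under twofold
            (-1.0, 0.049, "down"),  # exactly twofold counts
        ],
    )
    def test_threshold_arithmetic(self, log2fc, padj, expected):
        table = pd.DataFrame({"gene": ["g"], "log2fc": [log2fc], "padj": [padj]})
        out = classify_genes(table)
        assert out.loc[0, "class"] == expected

    def test_missing_padj_excluded_and_counted(self):
        table = pd.DataFrame(
            {"gene": ["a", "b"], "log2fc": [-2.0, -2.0], "padj": [0.01, np.nan]}
        )
        out = classify_genes(table)
        assert list(out["gene"]) == ["a"]
        assert out.attrs["n_excluded"] == 1

    def test_classes_partition_universe(self, dataset):
        table = classify_genes(dataset.de_tables["e08_16"])
        assert set(table["class"]) <= {"down", "up", "none"}
        assert len(table) == len(dataset.config.gene_ids())

    def test_intersection_equals_planted_always_down(self, dataset):
        classified = {
            c: classify_genes(t) for c, t in dataset.de_tables.items()
        }
        inters = intersect_classes(classified)
        assert inters["down"] == set(dataset.truth.always_down)
        assert inters["up"] == set(dataset.truth.always_up)


def oracle_hypergeom_upper(N, K, n, k):
    """Exact upper tail by enumerating the hypergeometric pmf."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestEnrichHyper:
    def test_exact_enumeration_example(self):
        universe = {f"g{i}" for i in range(10)}
        targets = {f"g{i}" for i in range(5)}
        gene_set = {f"g{i}" for i in range(4)}  # all four are targets
        res = enrich_hyper(targets, gene_set, universe)
        assert res.overlap == 4
        assert res.p_hyper == pytest.approx(5 / 210)
        assert res.p_hyper == pytest.approx(oracle_hypergeom_upper(10, 5, 4, 4))

    def test_zero_overlap_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        res = enrich_hyper({"g0"}, {"g5", "g6"}, universe)
        if res.overlap == 0:
            assert res.p_hyper == pytest.approx(1.0)

    def test_saturated_sample(self):
        universe = {f"g{i}" for i in range(8)}
        targets = {f"g{i}" for i in range(3)}
        res = enrich_hyper(targets, universe, universe)
        assert res.overlap == 3
        assert res.p_hyper == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich_hyper(set(), set(), set())

    @given(
        N=st.integers(5, 40), K=st.integers(0, 40), n=st.integers(0, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(deadline=None, max_examples=50)
    def test_matches_exact_enumeration(self, N, K, n, seed):
        K, n = min(K, N), min(n, N)
        rng = np.random.default_rng(seed)
        universe = {f"g{i}" for i in range(N)}
        targets = set(rng.choice(sorted(universe), size=K, replace=False))
        gene_set = set(rng.choice(sorted(universe), size=n, replace=False))
        res = enrich_hyper(targets, gene_set, universe)
        expected = oracle_hypergeom_upper(N, K, n, res.overlap)
        assert res.p_hyper == pytest.approx(expected, rel=1e-9)


class TestEnrichPerm:
    def test_degenerate_full_universe_draw(self):
        universe = {f"g{i}" for i in range(12)}
        targets = {f"g{i}" for i in range(4)}
        p = enrich_perm(targets, 12, universe, observed_overlap=4, n_perm=50, rng=0)
        assert p == pytest.approx(1.0)

    def test_zero_observed_overlap_gives_one(self):
        universe = {f"g{i}" for i in range(12)}
        p = enrich_perm({"g0"}, 3, universe, observed_overlap=0, n_perm=50, rng=0)
        assert p == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        universe = {f"g{i}" for i in range(30)}
        targets = {f"g{i}" for i in range(10)}
        p1 = enrich_perm(targets, 8, universe, 5, n_perm=200, rng=7)
        p2 = enrich_perm(targets, 8, universe, 5, n_perm=200, rng=7)
        assert p1 == p2

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            enrich_perm(set(), 5, {"a", "b"}, 0)

    def test_concordance_with_hypergeometric(self, rng):
        """The permutation null IS the hypergeometric law: on random
        instances the two p-values agree within Monte-Carlo error."""
        n_perm = 1000
        for _ in range(10):
            N = int(rng.integers(30, 120))
            K = int(rng.integers(3, N // 2))
            n = int(rng.integers(3, N // 2))
            universe = {f"g{i}" for i in range(N)}
            targets = set(rng.choice(sorted(universe), size=K, replace=False))
            gene_set = set(rng.choice(sorted(universe), size=n, replace=False))
            res = enrich_hyper(targets, gene_set, universe)
            p_perm = enrich_perm(
                targets, n, universe, res.overlap, n_perm=n_perm, rng=rng
            )
            se = math.sqrt(res.p_hyper * (1 - res.p_hyper) / n_perm)
            assert abs(p_perm - res.p_hyper) <= 3 * se + 2 / (n_perm + 1)


def oracle_bh(pvals):
    """Brute-force Benjamini-Hochberg: sort, scale, right cummin, cap."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / (np.arange(m) + 1)
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = np.empty(m)
    out[order] = np.minimum(scaled, 1.0)
    return out


class TestAdjust:
    def test_bonferroni_multiplies_and_caps(self):
        assert adjust([1e-4] * 1 + [0.5], "bonferroni")[0] == pytest.approx(2e-4)
        assert adjust([0.0001] + [1.0] * 99, "bonferroni")[0] == pytest.approx(0.01)
        assert adjust([0.9, 0.8], "bonferroni").max() == 1.0

    def test_single_test_identity(self):
        for method in ("bonferroni", "benjamini_hochberg"):
            assert adjust([0.037], method)[0] == pytest.approx(0.037)

    def test_bh_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 60)))
            np.testing.assert_allclose(
                adjust(p, "benjamini_hochberg"), oracle_bh(p), rtol=1e-12
            )

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust([0.0, 0.5], "bonferroni")
        with pytest.raises(ValueError):
            adjust([0.5, 1.5], "bonferroni")


class TestWordEnrich:
    def test_planted_word_ranks_first(self, rng):
        word = "GATCGA"
        utrs, universe, gene_set = [], set(), set()
        for i in range(40):
            gene = f"g{i}"
            seq = random_seq(rng, 300).replace(word, "TTTTTT")
            if i < 8:
                seq = seq[:100] + word + seq[106:]
                gene_set.add(gene)
            utrs.append(UtrRecord(gene, seq))
            universe.add(gene)
        table = word_enrich(utrs, gene_set, universe, k=6)
        assert table.loc[0, "word"] == word

    def test_gene_set_equal_universe_all_p_one(self, rng):
        utrs = [UtrRecord(f"g{i}", random_seq(rng, 200)) for i in range(10)]
        universe = {u.gene for u in utrs}
        table = word_enrich(utrs, universe, universe, k=5)
        assert (table["p_hyper"] == 1.0).all()

    def test_word_length_bounds(self, rng):
        utrs = [UtrRecord("g0", random_seq(rng, 50))]
        with pytest.raises(ValueError):
            word_enrich(utrs, {"g0"}, {"g0"}, k=3)
        with pytest.raises(ValueError):
            word_enrich(utrs, {"g0"}, {"g0"}, k=9)


class TestRankMirnas:
    def _table(self, rows):
        t = pd.DataFrame(rows)
        return t

    def test_zero_target_mirna_never_flagged(self):
        table = self._table(
            [
                {"mirna": "m0", "gene_set": "down", "N": 100, "K": 0, "n": 10, "k": 0,
                 "p_hyper": 1.0, "p_perm": 1.0, "p_adjusted": 1e-9},
                {"mirna": "m0", "gene_set": "up", "N": 100, "K": 0, "n": 10, "k": 0,
                 "p_hyper": 1.0, "p_perm": 1.0, "p_adjusted": 1.0},
            ]
        )
        out = rank_mirnas(table, pd.Series({"m0": 100.0}))
        assert not out["flagged"].any()

    def test_down_significant_up_quiet_is_flagged(self):
        table = self._table(
            [
                {"mirna": "m1", "gene_set": "down", "N": 100, "K": 20, "n": 10, "k": 9,
                 "p_hyper": 1e-8, "p_perm": 1e-3, "p_adjusted": 1e-6},
                {"mirna": "m1", "gene_set": "up", "N": 100, "K": 20, "n": 10, "k": 1,
                 "p_hyper": 0.9, "p_perm": 0.9, "p_adjusted": 1.0},
            ]
        )
        out = rank_mirnas(table, pd.Series({"m1": 500.0}))
        assert out.loc[0, "flagged"]
        assert out.loc[0, "neg_log10_p_down"] == pytest.approx(6.0)

    def test_raising_threshold_only_grows_flagged_set(self, rng):
        rows = []
        for i in range(30):
            p_down = float(10 ** rng.uniform(-8, 0))
            rows.append({"mirna": f"m{i}", "gene_set": "down", "N": 100, "K": 10,
                         "n": 10, "k": 3, "p_hyper": p_down, "p_perm": p_down,
                         "p_adjusted": p_down})
            rows.append({"mirna": f"m{i}", "gene_set": "up", "N": 100, "K": 10,
                         "n": 10, "k": 0, "p_hyper": 1.0, "p_perm": 1.0,
                         "p_adjusted": 1.0})
        table = self._table(rows)
        expr = pd.Series({f"m{i}": 1.0 for i in range(30)})
        flagged_small = set(
            rank_mirnas(table, expr, p_threshold=1e-4).query("flagged")["mirna"]
        )
        flagged_large = set(
            rank_mirnas(table, expr, p_threshold=1e-2).query("flagged")["mirna"]
        )
        assert flagged_small <= flagged_large


def test_enrichment_table_records_family_size(dataset):
    targets = {"m1": {"g0001", "g0002"}, "m2": {"g0003"}}
    universe = set(dataset.config.gene_ids())
    gene_sets = {"down": {"g0001", "g0002", "g0010"}, "up": {"g0050"}}
    table = enrichment_table(targets, gene_sets, universe, n_perm=100, rng_seed=0)
    assert table.attrs["correction_family_size"] == 4  # 2 mirnas x 2 sets
    assert (table["p_adjusted"] >= table["p_hyper"] - 1e-15).all()
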
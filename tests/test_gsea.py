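"""Enrichment engine: ranking, running-sum walks, permutation inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunocyt import (
    APOBEC3_PANEL,
    CHECKPOINT_PANEL,
    GeneSet,
    RankedList,
    build_score_frame,
    enrichment_score,
    gsea_collection,
    normalize_and_test,
    rank_genes,
)
from immunocyt.errors import ConfigError, DegenerateInputError, NoOverlapError
from tests.conftest import make_expression


def uniform_ranked(n: int, value: float = 1.0) -> RankedList:
    genes = np.array([f"G{i:03d}" for i in range(1, n + 1)])
    return RankedList(genes=genes, metric=np.full(n, value))


class TestRankGenes:
    def test_constant_gene_has_zero_metric(self):
        expr = make_expression(
            {"FLAT": [5.0] * 6, "UP": [1, 1, 1, 9, 9, 9]},
            [f"S{i}" for i in range(6)],
        )
        groups = pd.Series(
            ["low"] * 3 + ["high"] * 3, index=[f"S{i}" for i in range(6)]
        )
        ranked = rank_genes(expr, groups)
        metric = dict(zip(ranked.genes, ranked.metric))
        assert metric["FLAT"] == 0.0
        assert metric["UP"] > 0

    def test_ties_break_lexicographically_and_deterministically(self):
        expr = make_expression(
            {"B": [1.0] * 4, "A": [1.0] * 4, "C": [1.0] * 4},
            [f"S{i}" for i in range(4)],
        )
        groups = pd.Series(["low", "low", "high", "high"], index=[f"S{i}" for i in range(4)])
        first = rank_genes(expr, groups)
        second = rank_genes(expr, groups)
        assert list(first.genes) == ["A", "B", "C"]
        assert list(first.genes) == list(second.genes)

    def test_small_group_rejected(self):
        expr = make_expression({"A": [1.0, 2.0, 3.0]}, ["S0", "S1", "S2"])
        groups = pd.Series(["high", "low", "low"], index=["S0", "S1", "S2"])
        with pytest.raises(DegenerateInputError):
            rank_genes(expr, groups)

    def test_planted_heat_genes_rank_top_decile(self, hot_cohort):
        frame = build_score_frame(hot_cohort.expression)
        ranked = rank_genes(hot_cohort.expression, frame.groups("cyt"))
        planted = set(APOBEC3_PANEL.members) | set(CHECKPOINT_PANEL.members)
        cutoff = len(ranked) // 10
        top = set(ranked.genes[:cutoff])
        assert len(planted & top) / len(planted) > 0.8


class TestEnrichmentScore:
    def test_single_top_gene_scores_one(self):
        ranked = uniform_ranked(4)
        es, _, lead = enrichment_score(ranked, GeneSet("S", "", frozenset({"G001"})), 0.0)
        assert es == pytest.approx(1.0)
        assert lead == ("G001",)

    def test_all_genes_in_set_scores_one(self):
        ranked = uniform_ranked(5)
        es, running, _ = enrichment_score(
            ranked, GeneSet("ALL", "", frozenset(ranked.genes)), 0.0
        )
        assert es == pytest.approx(1.0)
        assert running[-1] == pytest.approx(1.0)

    def test_hand_enumerated_walk(self):
        """N=10, hits at ranks 2 and 5, weight 0: +1/2 at hits, -1/8 at misses."""
        genes = np.array([f"G{i}" for i in range(1, 11)])
        ranked = RankedList(genes=genes, metric=np.linspace(1.0, 0.1, 10))
        es, running, lead = enrichment_score(
            ranked, GeneSet("S", "", frozenset({"G2", "G5"})), 0.0
        )
        expected = np.cumsum([-1/8, 1/2, -1/8, -1/8, 1/2, -1/8, -1/8, -1/8, -1/8, -1/8])
        assert np.allclose(running, expected, atol=1e-15)
        assert es == pytest.approx(0.625, abs=1e-12)
        assert lead == ("G2", "G5")

    def test_no_overlap_raises(self):
        with pytest.raises(NoOverlapError):
            enrichment_score(uniform_ranked(5), GeneSet("S", "", frozenset({"NOPE"})), 0.0)

    def test_negative_es_leading_edge_from_bottom(self):
        ranked = uniform_ranked(10)
        es, _, lead = enrichment_score(
            ranked, GeneSet("S", "", frozenset({"G009", "G010"})), 0.0
        )
        assert es < 0
        assert set(lead) == {"G009", "G010"}

    @settings(deadline=None, max_examples=60)
    @given(
        n=st.integers(5, 120),
        k=st.integers(1, 20),
        seed=st.integers(0, 10_000),
        weight=st.sampled_from([0.0, 1.0, 1.5]),
    )
    def test_walk_invariants_on_random_inputs(self, n, k, seed, weight):
        """ES in [-1,1]; the full walk always returns to 0 (weight-0 balance
        is exact; weighted walks balance by construction of the increments)."""
        k = min(k, n - 1)
        rng = np.random.default_rng(seed)
        genes = np.array([f"G{i:04d}" for i in range(n)])
        metric = np.sort(rng.normal(size=n))[::-1]
        ranked = RankedList(genes=genes, metric=metric)
        members = frozenset(rng.choice(genes, size=k, replace=False))
        es, running, _ = enrichment_score(ranked, GeneSet("S", "", members), weight)
        assert -1.0 <= es <= 1.0
        assert running[-1] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 10_000), n=st.integers(6, 60), k=st.integers(1, 5))
    def test_reversal_negates_weight0_es(self, seed, n, k):
        """Flipping the ranking reverses and negates the weight-0 walk, so the
        signed extremum negates (up to ties between the max and min deviation)."""
        rng = np.random.default_rng(seed)
        genes = np.array([f"G{i:04d}" for i in range(n)])
        metric = np.arange(n, 0, -1.0)  # irrelevant at weight 0
        members = frozenset(rng.choice(genes, size=min(k, n - 1), replace=False))
        gs = GeneSet("S", "", members)
        fwd, run_f, _ = enrichment_score(RankedList(genes, metric), gs, 0.0)
        rev, run_r, _ = enrichment_score(RankedList(genes[::-1].copy(), metric), gs, 0.0)
        if abs(run_f.max() + run_f.min()) > 1e-9:  # no extremum tie
            assert rev == pytest.approx(-fwd, abs=1e-12)


class TestPermutationInference:
    def test_determinism_given_seed(self, hot_cohort):
        frame = build_score_frame(hot_cohort.expression)
        groups = frame.groups("cyt")
        planted = GeneSet("P", "", frozenset(CHECKPOINT_PANEL.members))
        runs = [
            gsea_collection(
                hot_cohort.expression, groups, [planted],
                n_perm=150, perm_mode="gene_set", seed=42,
            )[0]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_too_few_permutations_rejected(self):
        ranked = uniform_ranked(20)
        gs = GeneSet("S", "", frozenset({"G001"}))
        with pytest.raises(ConfigError):
            normalize_and_test(0.5, ranked, gs, n_perm=50, perm_mode="gene_set")

    def test_planted_set_detected(self, hot_cohort):
        frame = build_score_frame(hot_cohort.expression)
        planted = GeneSet(
            "PLANTED", "",
            frozenset(list(CHECKPOINT_PANEL.members) + list(APOBEC3_PANEL.members)),
        )
        decoys = GeneSet(
            "DECOYS", "", frozenset(f"DECOY{i:04d}" for i in range(1, 31))
        )
        results = gsea_collection(
            hot_cohort.expression, frame.groups("cyt"), [planted, decoys],
            n_perm=300, perm_mode="gene_set", seed=7,
        )
        by_name = {r.set_name: r for r in results}
        assert by_name["PLANTED"].es > 0
        assert by_name["PLANTED"].nominal_p < 0.05
        assert by_name["DECOYS"].nominal_p > 0.05
        # NES sign mirrors ES sign
        for r in results:
            if r.es != 0:
                assert np.sign(r.nes) == np.sign(r.es)

    def test_phenotype_mode_chosen_automatically(self, hot_cohort):
        frame = build_score_frame(hot_cohort.expression)
        groups = frame.groups("cyt")
        planted = GeneSet("P", "", frozenset(CHECKPOINT_PANEL.members))
        res = gsea_collection(
            hot_cohort.expression, groups, [planted],
            n_perm=100, perm_mode="auto", seed=1,
        )[0]
        assert res.perm_mode == "phenotype"
        assert res.nominal_p < 0.05

    def test_p_monotone_in_abs_nes_within_run(self, hot_cohort):
        """Across sets of one run, larger |NES| never gets a larger nominal p."""
        frame = build_score_frame(hot_cohort.expression)
        rng = np.random.default_rng(0)
        decoys = sorted(g for g in hot_cohort.expression.genes if g.startswith("DECOY"))
        sets = [
            GeneSet("P", "", frozenset(CHECKPOINT_PANEL.members)),
            GeneSet("D1", "", frozenset(rng.choice(decoys, 15, replace=False))),
            GeneSet("D2", "", frozenset(rng.choice(decoys, 15, replace=False))),
        ]
        results = gsea_collection(
            hot_cohort.expression, frame.groups("cyt"), sets,
            n_perm=200, perm_mode="gene_set", seed=3,
        )
        pos = sorted((r for r in results if r.es > 0), key=lambda r: -abs(r.nes))
        for earlier, later in zip(pos, pos[1:]):
            assert earlier.nominal_p <= later.nominal_p + 1e-12
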
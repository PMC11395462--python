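"""The five knowledge-based evidence scores on hand-checkable inputs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from mclprio.kb_model import (
    DisorderAnnotation,
    Effect,
    GeneSet,
    GeneSetKind,
    Interaction,
    KnowledgeBase,
    Mechanism,
    Protein,
    TargetStatus,
    build_graph,
)
from mclprio.knowledge_scoring import (
    biomarker_score,
    interaction_inference,
    knowledge_score_table,
    linear_pathway_score,
    metaminer_count,
    pathway_enrichment_score,
)


def kb_with(n: int, edges, biomarkers, pathways=(), metaminer=(), chains=()):
    proteins = {i: Protein(i, f"G{i}") for i in range(1, n + 1)}
    interactions = [
        Interaction(a, b, Effect.activation, Mechanism.binding) for a, b in edges
    ]
    ann = DisorderAnnotation(
        "d",
        GeneSet("d__biomarkers", frozenset(biomarkers), GeneSetKind.biomarker_set),
        GeneSet("d__targets", frozenset(), GeneSetKind.target_set),
        {},
    )
    return KnowledgeBase(
        proteins=proteins,
        interactions=interactions,
        pathway_maps=list(pathways),
        metaminer_pathways=list(metaminer),
        linear_pathways=list(chains),
        disorder_annotations={"d": ann},
    )


class TestBiomarkerScore:
    def test_indicator_and_vector_sum(self, tiny_kb):
        s = biomarker_score(tiny_kb, "d")
        assert s[2] == 1.0 and s[5] == 1.0
        assert s[1] == 0.0
        assert s.sum() == len(tiny_kb.disorder_annotations["d"].biomarkers.members)

    def test_unknown_disorder_raises(self, tiny_kb):
        with pytest.raises(KeyError, match="unknown disorder"):
            biomarker_score(tiny_kb, "nope")


class TestInteractionInference:
    def test_hand_computed_hypergeometric_example(self):
        """Protein 1 with 4 neighbors, 2 of the 10 biomarkers among them, in
        a universe of 100: p = 191235/3921225 = 0.048769 -> -ln p = 3.0207
        (exact integer-binomial summation)."""
        edges = [(1, j) for j in (2, 3, 4, 5)]
        kb = kb_with(100, edges, biomarkers={2, 3, 50, 51, 52, 53, 54, 55, 56, 57})
        s = interaction_inference(kb, "d")
        p_exact = (
            math.comb(10, 2) * math.comb(90, 2)
            + math.comb(10, 3) * math.comb(90, 1)
            + math.comb(10, 4)
        ) / math.comb(100, 4)
        assert p_exact == pytest.approx(0.0487692, rel=1e-5)
        assert s[1] == pytest.approx(-math.log(p_exact), rel=1e-9)
        assert s[1] == pytest.approx(3.020656, rel=1e-5)

    def test_degree_zero_scores_zero_and_no_negative_scores(self):
        kb = kb_with(50, [(1, 2)], biomarkers={40, 41})
        s = interaction_inference(kb, "d")
        assert s[10] == 0.0  # isolated
        assert (s >= 0).all()  # p near 1 clamps to 0, never negative

    def test_monotone_in_biomarker_neighbors_at_equal_degree(self):
        """With rare biomarkers, more biomarker neighbors at the same degree
        always means a larger score (checked by direct enumeration)."""
        # proteins 1 and 2 both have degree 3; 1 has 3 biomarker neighbors, 2 has 1
        edges = [(1, 11), (1, 12), (1, 13), (2, 11), (2, 21), (2, 22)]
        kb = kb_with(60, edges, biomarkers={11, 12, 13})
        s = interaction_inference(kb, "d")
        assert s[1] > s[2] > 0

    def test_brute_force_agreement_on_small_graphs(self):
        rng = np.random.default_rng(17)
        for trial in range(5):
            n = int(rng.integers(10, 50))
            m = int(rng.integers(n, 3 * n))
            pairs = set()
            while len(pairs) < m:
                a, b = rng.integers(1, n + 1, size=2)
                if a != b:
                    pairs.add((min(a, b), max(a, b)))
            biom = set(int(x) for x in rng.choice(np.arange(1, n + 1), size=max(2, n // 5), replace=False))
            kb = kb_with(n, sorted(pairs), biom)
            s = interaction_inference(kb, "d")
            g = build_graph(kb)
            for pid in kb.universe:
                d = g.degree[pid]
                if d == 0:
                    assert s[pid] == 0.0
                    continue
                hits = sum(1 for nb in g[pid] if nb in biom)
                total = sum(
                    math.comb(len(biom), x) * math.comb(n - len(biom), d - x)
                    for x in range(hits, min(d, len(biom)) + 1)
                ) / math.comb(n, d)
                expected = max(0.0, -math.log(max(total, 1e-300)))
                assert s[pid] == pytest.approx(expected, abs=1e-9)


class TestPathwayEnrichment:
    def test_single_pathway_hand_value_shared_by_members(self):
        """5-member pathway holding 3 of 10 biomarkers in a 100 universe:
        s = -ln P(X >= 3) is identical for all 5 members, 0 for others."""
        members = {1, 2, 3, 4, 5}
        biom = {1, 2, 3, 50, 51, 52, 53, 54, 55, 56}
        pw = GeneSet("pw", frozenset(members), GeneSetKind.pathway_map)
        kb = kb_with(100, [], biomarkers=biom, pathways=[pw])
        s = pathway_enrichment_score(kb, "d")
        p = sum(
            math.comb(10, x) * math.comb(90, 5 - x) for x in range(3, 6)
        ) / math.comb(100, 5)
        expected = -math.log(p)
        for pid in members:
            assert s[pid] == pytest.approx(expected, rel=1e-9)
        assert s[60] == 0.0

    def test_scores_add_across_containing_pathways(self):
        biom = {1, 2}
        pw1 = GeneSet("a", frozenset({1, 2, 3}), GeneSetKind.pathway_map)
        pw2 = GeneSet("b", frozenset({2, 3, 4}), GeneSetKind.pathway_map)
        kb = kb_with(50, [], biomarkers=biom, pathways=[pw1, pw2])
        s = pathway_enrichment_score(kb, "d")
        kb1 = kb_with(50, [], biomarkers=biom, pathways=[pw1])
        kb2 = kb_with(50, [], biomarkers=biom, pathways=[pw2])
        s1 = pathway_enrichment_score(kb1, "d")
        s2 = pathway_enrichment_score(kb2, "d")
        assert s[3] == pytest.approx(s1[3] + s2[3], rel=1e-12)


class TestMetaminerCount:
    def test_counts_and_double_counting_identity(self, tiny_kb):
        s = metaminer_count(tiny_kb)
        assert s[3] == 2.0  # on both consortium pathways
        assert s[8] == 0.0
        assert s.sum() == sum(len(gs) for gs in tiny_kb.metaminer_pathways)


class TestLinearPathwayScore:
    def test_ratio_of_biomarker_carrying_chains(self):
        from mclprio.kb_model import LinearPathway

        chains = [
            LinearPathway("c1", (1, 2, 9)),  # has biomarker 9
            LinearPathway("c2", (1, 3)),
            LinearPathway("c3", (1, 4)),
            LinearPathway("c4", (1, 5)),
        ]
        kb = kb_with(20, [], biomarkers={9}, chains=chains)
        s = linear_pathway_score(kb, "d")
        assert s[1] == pytest.approx(0.25)  # 1 of 4 chains carries a biomarker
        assert s[3] == 0.0
        assert s[9] == 1.0  # every chain containing it has a biomarker (itself)

    def test_protein_on_no_chain_scores_zero(self, tiny_kb):
        s = linear_pathway_score(tiny_kb, "d")
        assert s[8] == 0.0
        assert ((s >= 0) & (s <= 1)).all()


class TestScoreTable:
    def test_column_layout_and_index(self, small_kb):
        table = knowledge_score_table(small_kb)
        d = len(small_kb.disorders)
        assert table.shape == (len(small_kb.universe), 4 * d + 1)
        assert "metaminer.count" in table.columns
        for disorder in small_kb.disorders:
            for method in ("biomarker", "interaction", "pathway", "linear"):
                assert f"{disorder}.{method}" in table.columns
        assert (table >= 0).all().all()  # every channel is nonnegative
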
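"""Chemical-space audit: Tanimoto, scaffolds, similarity graph."""

from itertools import combinations

import numpy as np
import pytest

from solqspr.chemspace import (
    build_similarity_graph,
    murcko_scaffold,
    murcko_summary,
    set_to_set_distribution,
    tanimoto,
)
from solqspr.curation import standardize
from solqspr.features import Fingerprint, morgan_fp


def fp(bits, nbits=2048):
    return Fingerprint(bits=tuple(sorted(bits)), nbits=nbits)


class TestTanimoto:
    def test_identical_is_one(self):
        f = fp({1, 5, 9})
        assert tanimoto(f, f) == 1.0

    def test_hand_example(self):
        assert tanimoto(fp({1, 2, 3}), fp({2, 3, 4})) == 0.5

    def test_disjoint_is_zero(self):
        assert tanimoto(fp({1, 2}), fp({3, 4})) == 0.0

    def test_both_empty_defined_zero(self):
        assert tanimoto(fp(set()), fp(set())) == 0.0

    def test_symmetry(self, rng):
        for _ in range(20):
            a = fp(set(rng.integers(0, 2048, 30).tolist()))
            b = fp(set(rng.integers(0, 2048, 30).tolist()))
            assert tanimoto(a, b) == tanimoto(b, a)

    def test_length_mismatch_fails(self):
        with pytest.raises(ValueError, match="length"):
            tanimoto(fp({1}), fp({1}, nbits=1024))


class TestDistribution:
    def test_pair_count(self, records):
        d = set_to_set_distribution(records[:3], records[3:7])
        assert d.scores.size == 12

    def test_single_molecule_against_itself(self, records):
        d = set_to_set_distribution(records[:1], records[:1])
        assert d.scores.size == 1 and d.scores[0] == 1.0

    def test_matches_brute_force_double_loop(self, records):
        A, B = records[:5], records[5:9]
        d = set_to_set_distribution(A, B)
        brute = sorted(
            tanimoto(morgan_fp(a), morgan_fp(b)) for a in A for b in B
        )
        assert sorted(d.scores.tolist()) == pytest.approx(brute)
        assert d.max == pytest.approx(max(brute))
        assert int(d.histogram.sum()) == len(brute)

    def test_within_set_count(self, records):
        d = set_to_set_distribution(records[:6])
        assert d.within_set and d.scores.size == 15

    def test_empty_set_rejected(self, records):
        with pytest.raises(ValueError):
            set_to_set_distribution([], records[:2])


class TestScaffolds:
    def test_side_chains_stripped(self):
        tol = standardize("Cc1ccccc1", id="toluene")
        eb = standardize("CCc1ccccc1", id="ethylbenzene")
        assert murcko_scaffold(tol) == murcko_scaffold(eb) != ""

    def test_benzene_single_scaffold(self):
        s = murcko_summary({"a": [standardize("c1ccccc1", id="bz")]})
        assert s.counts["a"] == 1

    def test_acyclic_goes_to_empty_bucket(self):
        hexane = standardize("CCCCCC", id="hexane")
        s = murcko_summary({"a": [hexane]})
        assert murcko_scaffold(hexane) == ""
        assert s.acyclic_flagged["a"] == 1
        assert s.counts["a"] == 1  # the empty bucket counts once

    def test_overlap_matches_set_intersection_oracle(self, records):
        A, B = records[:20], records[15:40]
        s = murcko_summary({"A": A, "B": B})
        oracle = {murcko_scaffold(r) for r in A} & {murcko_scaffold(r) for r in B}
        assert s.overlaps[("A", "B")] == len(oracle)
        assert s.overlaps[("A", "B")] <= min(s.counts["A"], s.counts["B"])


class TestSimilarityGraph:
    def test_edges_respect_threshold(self, records):
        sets = {"all": records[:25]}
        g = build_similarity_graph(sets, threshold=0.5, layout_seed=1)
        fps = {r.id: morgan_fp(r) for r in records[:25]}
        expected = {
            frozenset((a, b))
            for a, b in combinations(fps, 2)
            if tanimoto(fps[a], fps[b]) >= 0.5
        }
        got = {frozenset(e) for e in g.graph.edges}
        assert got == expected
        for a, b, d in g.graph.edges(data=True):
            assert 0.5 <= d["weight"] <= 1.0

    def test_threshold_inclusive_and_exclusive_cases(self):
        a = standardize("CCCCCCC", id="a")
        b = standardize("CCCCCCO", id="b")
        s = tanimoto(morgan_fp(a), morgan_fp(b))
        assert 0.0 < s < 1.0
        g = build_similarity_graph({"x": [a, b]}, threshold=s, layout_seed=0)
        assert g.graph.number_of_edges() == 1  # equality included
        g2 = build_similarity_graph({"x": [a, b]}, threshold=s + 1e-6, layout_seed=0)
        assert g2.graph.number_of_edges() == 0

    def test_single_molecule_graph(self, records):
        g = build_similarity_graph({"x": records[:1]}, layout_seed=0)
        assert g.graph.number_of_nodes() == 1 and g.graph.number_of_edges() == 0
        (xy,) = g.layout.values()
        assert np.isfinite(xy).all()

    def test_input_order_invariance(self, records):
        a = build_similarity_graph({"x": records[:15]}, layout_seed=0)
        b = build_similarity_graph({"x": list(reversed(records[:15]))}, layout_seed=0)
        assert {frozenset(e) for e in a.graph.edges} == {frozenset(e) for e in b.graph.edges}

    def test_degree_consistent_and_exports(self, tmp_path, records):
        g = build_similarity_graph({"x": records[:10]}, layout_seed=0)
        for n in g.graph.nodes:
            assert g.graph.nodes[n]["degree"] == g.degree(n)
        g.write_edge_csv(tmp_path / "edges.csv")
        g.write_graphml(tmp_path / "graph.graphml")
        assert (tmp_path / "edges.csv").read_text().startswith("id_a,id_b,weight")
        assert (tmp_path / "graph.graphml").stat().st_size > 0

    def test_bad_threshold(self, records):
        with pytest.raises(ValueError):
            build_similarity_graph({"x": records[:2]}, threshold=0.0)
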
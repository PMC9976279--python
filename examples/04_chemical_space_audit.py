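"""Audit train/test chemical-space overlap.

Three views: the distribution of pairwise Tanimoto similarities (Morgan
radius-2, 2048-bit fingerprints) between the sets; unique Bemis-Murcko
scaffold counts and their overlap; and a similarity graph connecting
molecules at Tanimoto >= 0.5, with a seeded force-directed layout.
"""

from solqspr.chemspace import build_similarity_graph, murcko_summary, set_to_set_distribution
from solqspr.synthetic import SyntheticSpec, generate_library, split_fixture

lib = generate_library(SyntheticSpec(n_molecules=150, seed=4, noise_sigma=0.17))
# scaffold groups are indivisible; 0.4 is realizable for this library
# (an infeasible fraction raises an error listing the achievable ones)
train, test = split_fixture(lib, "scaffold_disjoint", test_frac=0.4, seed=4)
print(f"scaffold-disjoint split: {len(train)} train / {len(test)} test")

d = set_to_set_distribution(train, test)
print(f"train-vs-test Tanimoto: {d.scores.size} pairs, "
      f"mean {d.mean:.3f}, median {d.median:.3f}, max {d.max:.3f}")
# low scores indicate the test set probes chemistry the training set lacks

s = murcko_summary({"train": train, "test": test})
print(f"unique scaffolds: train {s.counts['train']}, test {s.counts['test']}, "
      f"shared {s.overlaps[('test', 'train')]} (0 = scaffold-disjoint holds)")

g = build_similarity_graph({"train": train, "test": test}, threshold=0.5, layout_seed=4)
print(f"similarity graph: {g.graph.number_of_nodes()} nodes, "
      f"{g.graph.number_of_edges()} edges at Tanimoto >= 0.5")
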
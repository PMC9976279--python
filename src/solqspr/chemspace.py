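"""Chemical-space audit: Tanimoto similarity distributions, Bemis-Murcko
scaffold summaries and a thresholded molecular-similarity graph.

Training/testing set overlap in chemical space is assessed three ways:
the full distribution of pairwise Tanimoto similarities (Morgan radius-2,
2048-bit fingerprints) between two sets; counts and overlaps of unique
Bemis-Murcko scaffolds (ring systems plus linkers, side chains removed);
and a graph connecting molecules whose similarity reaches a threshold
(default 0.5, inclusive), laid out with the Fruchterman-Reingold
force-directed algorithm using the similarity as spring weight.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold

from .curation import MoleculeRecord
from .features import Fingerprint, morgan_fp

__all__ = [
    "SimilarityDistribution",
    "ScaffoldSummary",
    "SimilarityGraph",
    "tanimoto",
    "set_to_set_distribution",
    "murcko_summary",
    "build_similarity_graph",
]

HISTOGRAM_BIN_WIDTH = 0.05


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|a AND b| / |a OR b| over set bits; 0 when both fingerprints are empty."""
    if a.nbits != b.nbits:
        raise ValueError(f"fingerprint length mismatch: {a.nbits} vs {b.nbits}")
    sa, sb = set(a.bits), set(b.bits)
    union = len(sa | sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union


@dataclass(frozen=True)
class SimilarityDistribution:
    """All pairwise Tanimoto scores between two sets, with summaries."""

    scores: np.ndarray
    mean: float
    median: float
    max: float
    histogram: np.ndarray          # counts in 0.05-wide bins on [0, 1]
    bin_edges: np.ndarray
    within_set: bool = False


def set_to_set_distribution(
    A: Sequence[MoleculeRecord], B: Sequence[MoleculeRecord] | None = None
) -> SimilarityDistribution:
    """Distribution of pairwise similarities between sets A and B.

    With ``B`` omitted (or identical to ``A``) the within-set distribution
    over the |A|(|A|-1)/2 unordered pairs is computed instead.
    """
    if not A or (B is not None and len(B) == 0):
        raise ValueError("both molecule sets must be non-empty")
    fa = [morgan_fp(r) for r in A]
    within = B is None
    if within:
        scores = np.array([tanimoto(x, y) for x, y in combinations(fa, 2)]) if len(fa) > 1 else np.empty(0)
    else:
        fb = [morgan_fp(r) for r in B]
        scores = np.array([tanimoto(x, y) for x in fa for y in fb])
    edges = np.arange(0.0, 1.0 + HISTOGRAM_BIN_WIDTH, HISTOGRAM_BIN_WIDTH)
    hist, _ = np.histogram(scores, bins=edges)
    if scores.size == 0:
        mean = median = mx = float("nan")
    else:
        mean, median, mx = float(scores.mean()), float(np.median(scores)), float(scores.max())
    return SimilarityDistribution(
        scores=scores, mean=mean, median=median, max=mx,
        histogram=hist, bin_edges=edges, within_set=within,
    )


#: Scaffold SMILES used for acyclic molecules (no ring system).
EMPTY_SCAFFOLD = ""


def murcko_scaffold(record: MoleculeRecord) -> str:
    """Bemis-Murcko scaffold SMILES; empty string for acyclic molecules."""
    return MurckoScaffold.MurckoScaffoldSmiles(smiles=record.smiles, includeChirality=False)


@dataclass(frozen=True)
class ScaffoldSummary:
    """Unique scaffolds per named set and pairwise overlap counts."""

    scaffolds: Mapping[str, frozenset]
    counts: Mapping[str, int]
    overlaps: Mapping[tuple[str, str], int]
    acyclic_flagged: Mapping[str, int]   # molecules per set in the empty-scaffold bucket

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": dict(self.counts),
                "overlaps": {f"{a}|{b}": v for (a, b), v in self.overlaps.items()},
                "acyclic_molecules": dict(self.acyclic_flagged),
                "scaffolds": {k: sorted(v) for k, v in self.scaffolds.items()},
            },
            indent=2,
        )


def murcko_summary(sets: Mapping[str, Sequence[MoleculeRecord]]) -> ScaffoldSummary:
    """Scaffold counts and overlaps across named molecule sets.

    Acyclic molecules share one "empty" scaffold bucket which counts as a
    single distinct scaffold and is flagged separately.
    """
    scaffolds: dict[str, frozenset] = {}
    acyclic: dict[str, int] = {}
    for name, recs in sets.items():
        smis = [murcko_scaffold(r) for r in recs]
        acyclic[name] = sum(1 for s in smis if s == EMPTY_SCAFFOLD)
        scaffolds[name] = frozenset(smis)
    counts = {k: len(v) for k, v in scaffolds.items()}
    names = sorted(sets)
    overlaps = {
        (a, b): len(scaffolds[a] & scaffolds[b]) for a, b in combinations(names, 2)
    }
    return ScaffoldSummary(scaffolds=scaffolds, counts=counts, overlaps=overlaps, acyclic_flagged=acyclic)


@dataclass(frozen=True)
class SimilarityGraph:
    """Molecules as nodes; edges where Tanimoto >= threshold."""

    graph: nx.Graph
    threshold: float
    layout: Mapping[str, tuple[float, float]]

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def write_edge_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id_a", "id_b", "weight"])
            for a, b, d in self.graph.edges(data=True):
                w.writerow([a, b, f"{d['weight']:.6f}"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for node, (x, y) in self.layout.items():
            g.nodes[node]["x"], g.nodes[node]["y"] = float(x), float(y)
        nx.write_graphml(g, path)


def build_similarity_graph(
    sets: Mapping[str, Sequence[MoleculeRecord]],
    threshold: float = 0.5,
    layout_seed: int = 0,
) -> SimilarityGraph:
    """Build the thresholded similarity graph over all molecules.

    Edges connect molecule pairs with Tanimoto >= threshold (inclusive)
    weighted by the similarity; isolated nodes are kept.  Coordinates come
    from the Fruchterman-Reingold force-directed layout with similarity as
    spring weight; they are advisory output, seeded for reproducibility.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    g = nx.Graph()
    items: list[tuple[str, Fingerprint]] = []
    for set_name in sorted(sets):
        for r in sets[set_name]:
            g.add_node(r.id, set_label=set_name)
            items.append((r.id, morgan_fp(r)))
    items.sort(key=lambda t: t[0])  # input-order invariance
    for (ia, fa), (ib, fb) in combinations(items, 2):
        s = tanimoto(fa, fb)
        if s >= threshold:
            g.add_edge(ia, ib, weight=s)
    for node in g.nodes:
        g.nodes[node]["degree"] = g.degree[node]
    pos = nx.spring_layout(g, weight="weight", seed=layout_seed)
    layout = {n: (float(p[0]), float(p[1])) for n, p in pos.items()}
    return SimilarityGraph(graph=g, threshold=threshold, layout=layout)
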
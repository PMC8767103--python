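"""Per-sample BCR similarity networks, clone calling and Gini statistics.

Each vertex is a unique clonotype keyed by (V gene, J gene, CDR3 nucleotide
sequence) and sized by its summed read count. Edges join vertices that share
the same V and J genes, the same CDR3 length, and at least 90% CDR3
nucleotide identity; connected components of this graph are the clones
(single-linkage clustering, so the network clusters and the clone partition
are the same objects).

Two inequality statistics summarise a sample's repertoire: the vertex Gini
index (inequality of per-clonotype read counts; clonal expansion) and the
cluster Gini index (inequality of vertices per cluster; clonal
diversification from somatic hypermutation).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import networkx as nx
import numpy as np

from .errors import RepnetError
from .io import ClonotypeRecord

VertexKey = tuple[str, str, str]  # (v_gene, j_gene, cdr3_nt)

#: numerator/denominator of the identity threshold: identity >= 9/10
IDENTITY_NUM, IDENTITY_DEN = 9, 10


def cdr3_identity(a: str, b: str) -> Fraction:
    """Exact fraction of matching positions between two equal-length CDR3s.

    Returned as a rational so that the 90% edge-eligibility threshold can be
    evaluated without floating-point rounding. Unequal lengths are a caller
    error (sequences must be pre-binned by length).
    """
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("cdr3_identity requires equal, positive lengths")
    matches = sum(x == y for x, y in zip(a, b))
    return Fraction(matches, len(a))


def _eligible_pairs(seqs: list[str]) -> list[tuple[int, int]]:
    """Index pairs among equal-length sequences with identity >= 90%.

    Integer threshold: matches * 10 >= 9 * L, evaluated exactly.
    """
    m = len(seqs)
    if m < 2:
        return []
    L = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    arr = arr.reshape(m, L)
    pairs: list[tuple[int, int]] = []
    # chunk rows so the broadcast stays small for big bins
    chunk = max(1, int(5e6 // (m * L)) or 1)
    for start in range(0, m, chunk):
        block = arr[start : start + chunk]
        matches = (block[:, None, :] == arr[None, :, :]).sum(axis=2)
        ok = matches * IDENTITY_DEN >= IDENTITY_NUM * L
        for i_local, j in zip(*np.nonzero(ok)):
            i = start + int(i_local)
            if i < j:
                pairs.append((i, int(j)))
    return pairs


@dataclass
class RepertoireNetwork:
    """Similarity network of one sample x chain."""

    vertices: dict[VertexKey, int]
    edges: set[tuple[VertexKey, VertexKey]]
    clusters: list[frozenset[VertexKey]]

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def vertex_sizes(self) -> list[int]:
        return list(self.vertices.values())

    def cluster_sizes(self) -> list[int]:
        """Number of vertices in each cluster."""
        return [len(c) for c in self.clusters]


@dataclass
class Clone:
    v_gene: str
    j_gene: str
    members: tuple[VertexKey, ...]
    read_count: int


@dataclass
class CloneSet:
    clones: list[Clone]
    total_reads: int

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    def counts(self) -> list[int]:
        return [c.read_count for c in self.clones]

    def proportions(self) -> list[float]:
        return [c.read_count / self.total_reads for c in self.clones]


def build_network(records: Sequence[ClonotypeRecord]) -> RepertoireNetwork:
    """Build the similarity network for one sample's records in one chain.

    Output is deterministic and independent of record order: vertices are
    aggregated by key, clusters are sorted by their smallest member key.
    """
    chains = {r.chain for r in records}
    if len(chains) > 1:
        raise RepnetError(f"records mix chains: {sorted(chains)}")

    sizes: dict[VertexKey, int] = {}
    for rec in records:
        key = (rec.v_gene, rec.j_gene, rec.cdr3_nt)
        sizes[key] = sizes.get(key, 0) + rec.read_count

    graph = nx.Graph()
    graph.add_nodes_from(sizes)
    bins: dict[tuple[str, str, int], list[VertexKey]] = {}
    for key in sorted(sizes):
        bins.setdefault((key[0], key[1], len(key[2])), []).append(key)
    edges: set[tuple[VertexKey, VertexKey]] = set()
    for members in bins.values():
        seqs = [k[2] for k in members]
        for i, j in _eligible_pairs(seqs):
            a, b = members[i], members[j]
            edge = (a, b) if a <= b else (b, a)
            edges.add(edge)
            graph.add_edge(a, b)

    clusters = [frozenset(c) for c in nx.connected_components(graph)]
    clusters.sort(key=lambda c: min(c))
    return RepertoireNetwork(vertices=sizes, edges=edges, clusters=clusters)


def gini(values: Sequence[float]) -> float:
    """Population Gini index of a list of positive values, in [0, 1).

    G = sum_ij |x_i - x_j| / (2 n^2 xbar), computed via the sorted identity
    G = (2 sum_i i*x_(i)) / (n sum_i x_i) - (n+1)/n. A single value gives 0
    (complete equality by convention).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("gini is undefined for an empty list")
    if np.any(x <= 0):
        raise ValueError("gini requires strictly positive values")
    x = np.sort(x)
    n = x.size
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * x)) / (n * np.sum(x)) - (n + 1) / n)


def vertex_gini(net: RepertoireNetwork) -> float:
    """Gini index of the vertex-size distribution (clonal expansion).

    An empty network yields NaN (missing), not an error.
    """
    if net.n_vertices == 0:
        return float("nan")
    return gini(net.vertex_sizes())


def cluster_gini(net: RepertoireNetwork) -> float:
    """Gini index of vertices-per-cluster (clonal diversification)."""
    if net.n_clusters == 0:
        return float("nan")
    return gini(net.cluster_sizes())


def call_clones(net: RepertoireNetwork) -> CloneSet:
    """One clone per connected component; counts are summed member sizes."""
    clones = []
    for cluster in net.clusters:
        members = tuple(sorted(cluster))
        count = sum(net.vertices[k] for k in members)
        clones.append(
            Clone(
                v_gene=members[0][0],
                j_gene=members[0][1],
                members=members,
                read_count=count,
            )
        )
    return CloneSet(clones=clones, total_reads=sum(c.read_count for c in clones))
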
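"""Sequence similarity networks and neighbor-joining phylogeny.

The similarity network treats sequences as nodes and keeps an edge for
every pair whose chosen pairwise metric clears a threshold; connected
components then serve as putative isofunctional families, and candidate
selection keeps the members that share a component with a known reference
enzyme.  The companion tree builder runs canonical neighbor joining on
p-distances with column-resampling bootstrap support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .sequence_core import ProteinRecord, SubstitutionMatrix, align_pair

METRICS = ("score_per_column", "identity", "similarity")

__all__ = [
    "SimilarityNetwork",
    "ClusterAssignment",
    "PhyloTree",
    "all_vs_all",
    "build_network",
    "components",
    "select_cocluster",
    "nj_tree",
    "p_distance_matrix",
    "bootstrap_support",
]


@dataclass
class SimilarityNetwork:
    """Undirected weighted graph of sequences above a similarity cutoff."""

    graph: nx.Graph
    threshold: float
    metric: str

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return sorted(
            (min(a, b), max(a, b), d["weight"]) for a, b, d in self.graph.edges(data=True)
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["id_a", "id_b", "weight"])


@dataclass
class ClusterAssignment:
    """Connected-component labels, canonicalised by smallest member id."""

    labels: dict[str, str]

    @property
    def cluster_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for lab in self.labels.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        return sizes

    def members(self, label: str) -> list[str]:
        return sorted(i for i, lab in self.labels.items() if lab == label)

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class PhyloTree:
    """An unrooted NJ tree with optional bootstrap supports per bipartition.

    ``supports`` maps each non-trivial bipartition — the frozenset of leaf
    names on the side not containing the alphabetically first leaf — to a
    percentage in [0, 100].
    """

    tree: TreeNode
    leaves: tuple[str, ...]
    negative_branches_clamped: bool = False
    supports: dict[frozenset, float] | None = None
    star: bool = False

    def newick(self) -> str:
        if self.supports:
            annotated = self.tree.copy()
            ref = min(self.leaves)
            for node in annotated.non_tips():
                bip = _bipartition(node, set(self.leaves), ref)
                if bip is not None and bip in self.supports:
                    node.name = f"{self.supports[bip]:.0f}"
            return str(annotated).strip()
        return str(self.tree).strip()

    def bipartitions(self) -> set[frozenset]:
        return _tree_bipartitions(self.tree, self.leaves)


def all_vs_all(
    seqs: Sequence[ProteinRecord],
    metric: str = "score_per_column",
    matrix: SubstitutionMatrix | None = None,
) -> pd.DataFrame:
    """Symmetric pairwise metric matrix over all sequences.

    ``score_per_column`` is the global alignment score divided by the
    number of alignment columns; ``identity``/``similarity`` are the
    fractions from :func:`align_pair`.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    n = len(seqs)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            aln = align_pair(seqs[i], seqs[j], matrix, mode="global")
            if metric == "score_per_column":
                w = aln.score / len(aln)
            elif metric == "identity":
                w = aln.identity
            else:
                w = aln.similarity
            mat[i, j] = mat[j, i] = w
    return pd.DataFrame(mat, index=ids, columns=ids)


def build_network(weights: pd.DataFrame, threshold: float, metric: str = "score_per_column") -> SimilarityNetwork:
    """Keep edges whose pairwise weight is >= threshold (no self-edges)."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    g = nx.Graph()
    ids = list(weights.index)
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            w = float(weights.loc[a, b])
            if w >= threshold:
                g.add_edge(a, b, weight=w)
    return SimilarityNetwork(graph=g, threshold=threshold, metric=metric)


def components(network: SimilarityNetwork) -> ClusterAssignment:
    """Connected components labeled by their lexicographically smallest id."""
    labels: dict[str, str] = {}
    for comp in nx.connected_components(network.graph):
        label = min(comp)
        for node in comp:
            labels[node] = label
    return ClusterAssignment(labels=labels)


def select_cocluster(assignment: ClusterAssignment, reference_ids: Sequence[str]) -> list[str]:
    """Candidates sharing a cluster with at least one reference, sorted by id."""
    unknown = [r for r in reference_ids if r not in assignment.labels]
    if unknown:
        raise ValueError(f"reference ids not in network: {unknown}")
    ref_set = set(reference_ids)
    ref_clusters = {assignment.labels[r] for r in ref_set}
    return sorted(
        i
        for i, lab in assignment.labels.items()
        if lab in ref_clusters and i not in ref_set
    )


# ---------------------------------------------------------------------------
# Neighbor joining + bootstrap


def nj_tree(distances: pd.DataFrame) -> PhyloTree:
    """Canonical neighbor joining on a symmetric zero-diagonal matrix.

    Negative branch-length estimates (possible on non-additive input) are
    clamped to zero and flagged.  Exact on additive matrices.
    """
    ids = list(distances.index)
    mat = np.asarray(distances, dtype=float)
    if mat.shape[0] != mat.shape[1] or list(distances.columns) != ids:
        raise ValueError("distance matrix must be square with matching labels")
    if (mat < 0).any():
        raise ValueError("negative distances")
    if not np.allclose(mat, mat.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0):
        raise ValueError("distance matrix diagonal must be zero")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if n == 2:
        d = mat[0, 1]
        tree = TreeNode.read([f"({ids[0]}:{d / 2},{ids[1]}:{d / 2});"])
        return PhyloTree(tree=tree, leaves=tuple(sorted(ids)))
    dm = DistanceMatrix(mat, ids)
    raw = nj(dm, neg_as_zero=False)
    clamped = False
    for node in raw.traverse():
        if node.length is not None and node.length < 0:
            clamped = True
    tree = nj(dm, neg_as_zero=True) if clamped else raw
    return PhyloTree(tree=tree, leaves=tuple(sorted(ids)), negative_branches_clamped=clamped)


def p_distance_matrix(
    aligned: Mapping[str, str], poisson: bool = False
) -> pd.DataFrame:
    """Pairwise p-distances over equal-length gapped sequences.

    The p-distance is the fraction of differing positions among columns
    where neither sequence is gapped; ``poisson=True`` applies the
    -ln(1 - p) correction.  Pairs with no comparable columns get distance 0.
    """
    ids = sorted(aligned)
    length = len(aligned[ids[0]])
    if any(len(aligned[i]) != length for i in ids):
        raise ValueError("aligned sequences differ in length")
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = aligned[ids[i]], aligned[ids[j]]
            comparable = diff = 0
            for x, y in zip(a, b):
                if x != "-" and y != "-":
                    comparable += 1
                    if x != y:
                        diff += 1
            p = diff / comparable if comparable else 0.0
            if poisson:
                if p >= 1.0:
                    raise ValueError("p-distance 1.0 cannot be Poisson-corrected")
                p = -np.log(1.0 - p)
            mat[i, j] = mat[j, i] = p
    return pd.DataFrame(mat, index=ids, columns=ids)


def _bipartition(node: TreeNode, all_leaves: set, ref: str) -> frozenset | None:
    """Normalized non-trivial bipartition below an internal node, else None."""
    side = {t.name for t in node.tips()}
    if ref in side:
        side = all_leaves - side
    if len(side) < 2 or len(all_leaves - side) < 2:
        return None
    return frozenset(side)


def _tree_bipartitions(tree: TreeNode, leaves: Sequence[str]) -> set[frozenset]:
    all_leaves = set(leaves)
    ref = min(all_leaves)
    out: set[frozenset] = set()
    for node in tree.non_tips():
        bip = _bipartition(node, all_leaves, ref)
        if bip is not None:
            out.add(bip)
    return out


def bootstrap_support(
    aligned: Mapping[str, str],
    n_replicates: int = 100,
    seed: int = 0,
    poisson: bool = False,
) -> PhyloTree:
    """NJ tree with bootstrap supports from alignment-column resampling.

    Columns are resampled with replacement ``n_replicates`` times by a
    single :class:`numpy.random.Generator` seeded with ``seed`` (sequences
    processed in sorted-id order, the package's reproducibility contract);
    an NJ tree is built per replicate from p-distances; support for each
    internal bipartition of the full-alignment tree is the percentage of
    replicate trees containing it.

    A distance matrix that is identically zero (all sequences equal) is
    flagged as a star tree and trivial supports are reported as 100.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ids = sorted(aligned)
    if len(ids) < 3:
        raise ValueError("bootstrap needs >= 3 sequences")
    full = p_distance_matrix(aligned, poisson=poisson)
    if np.allclose(np.asarray(full), 0):
        star = TreeNode.read(["(" + ",".join(f"{i}:0.0" for i in ids) + ");"])
        supports = {}  # no non-trivial bipartitions on a star tree
        warnings.warn("all sequences identical: star tree, supports trivial (100)")
        return PhyloTree(
            tree=star, leaves=tuple(ids), supports=supports, star=True
        )
    main = nj_tree(full)
    target = _tree_bipartitions(main.tree, ids)
    counts = {bip: 0 for bip in target}
    rng = np.random.default_rng(seed)
    length = len(aligned[ids[0]])
    seqs = [aligned[i] for i in ids]
    for _ in range(n_replicates):
        cols = rng.integers(0, length, size=length)
        resampled = {
            i: "".join(s[c] for c in cols) for i, s in zip(ids, seqs)
        }
        dmat = p_distance_matrix(resampled, poisson=poisson)
        if np.allclose(np.asarray(dmat), 0):
            continue
        rep = nj_tree(dmat)
        rep_bips = _tree_bipartitions(rep.tree, ids)
        for bip in target:
            if bip in rep_bips:
                counts[bip] += 1
    supports = {bip: 100.0 * c / n_replicates for bip, c in counts.items()}
    return PhyloTree(
        tree=main.tree,
        leaves=tuple(ids),
        negative_branches_clamped=main.negative_branches_clamped,
        supports=supports,
    )
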
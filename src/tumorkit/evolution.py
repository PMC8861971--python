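"""Cross-biopsy somatic-variant classification and minimum-evolution phylogeny.

Somatic variants called across a primary tumor and serial metastatic
biopsies are classified as ubiquitous (called in every sample), shared
(called in at least two), or private (called in exactly one); a weaker
"supported" evidence state marks variants not independently called but
backed by at least two sequencing reads. The called/absent pattern forms a
binary sample-by-variant matrix whose pairwise mismatch counts give a
genetic distance, and the phylogeny is the unrooted tree minimizing total
branch length under ordinary-least-squares (OLS) branch-length fits — the
minimum-evolution criterion. For the handful of biopsies in a single
patient, all unrooted binary topologies are enumerated, so the optimum is
exact rather than heuristic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VARIANT_COLUMNS",
    "PhyloTree",
    "filter_variants",
    "classify_across_samples",
    "binary_matrix",
    "append_outgroup",
    "pairwise_gene_distance",
    "minimum_evolution_tree",
    "to_newick",
    "tree_splits",
    "leaf_distances",
]

#: required columns of a per-sample variant observation table
VARIANT_COLUMNS = ("sample_id", "variant_id", "vaf", "depth", "called", "supporting_reads")

CALLED, SUPPORTED, ABSENT = "called", "supported", "absent"
MAX_EXHAUSTIVE_TAXA = 8


def filter_variants(
    records: pd.DataFrame, min_vaf: float = 0.05, min_depth: int = 30
) -> pd.DataFrame:
    """Drop variant observations below the VAF or depth floor.

    Observations with VAF lower than ``min_vaf`` or depth lower than
    ``min_depth`` are removed; values exactly at the boundary are kept.
    """
    missing = [c for c in ("vaf", "depth") if c not in records.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    return records.loc[(records["vaf"] >= min_vaf) & (records["depth"] >= min_depth)]


def classify_across_samples(
    records: pd.DataFrame,
    samples: Sequence[str] | None = None,
    *,
    include_supported: bool = False,
    min_supporting_reads: int = 2,
) -> pd.DataFrame:
    """Assign per-sample evidence states and a cross-sample category.

    Evidence per (variant, sample): ``called`` if the caller flag is set,
    ``supported`` if not called but backed by at least
    ``min_supporting_reads`` reads, else ``absent`` (missing pairs are
    absent). The category counts samples where the variant is "present":
    by default only called evidence counts (the supported state is an
    annotation); with ``include_supported=True`` supported evidence counts
    as presence too. Ubiquitous = present in all samples, shared = in at
    least two (but not all), private = exactly one.

    Variants called in no sample are excluded with a warning.

    Returns a DataFrame indexed by variant_id with one evidence column per
    sample plus a ``category`` column.
    """
    missing = [c for c in VARIANT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    if samples is None:
        samples = sorted(records["sample_id"].unique())
    samples = list(samples)

    evidence = pd.DataFrame(
        ABSENT, index=sorted(records["variant_id"].unique()), columns=samples
    )
    for row in records.itertuples(index=False):
        if row.sample_id not in evidence.columns:
            continue
        if bool(row.called):
            evidence.loc[row.variant_id, row.sample_id] = CALLED
        elif int(row.supporting_reads) >= min_supporting_reads:
            if evidence.loc[row.variant_id, row.sample_id] != CALLED:
                evidence.loc[row.variant_id, row.sample_id] = SUPPORTED

    called_counts = (evidence == CALLED).sum(axis=1)
    never_called = called_counts == 0
    if never_called.any():
        warnings.warn(
            f"{int(never_called.sum())} variant(s) called in no sample were excluded",
            stacklevel=2,
        )
        evidence = evidence.loc[~never_called]
        called_counts = called_counts.loc[~never_called]

    if include_supported:
        present_counts = (evidence != ABSENT).sum(axis=1)
    else:
        present_counts = called_counts

    n = len(samples)
    category = pd.Series("private", index=evidence.index, name="category")
    category[present_counts >= 2] = "shared"
    category[present_counts == n] = "ubiquitous"

    out = evidence.copy()
    out["category"] = category
    out.index.name = "variant_id"
    return out


def binary_matrix(classified: pd.DataFrame, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Sample-by-variant 0/1 presence matrix (1 iff evidence is called).

    Columns are ordered by variant_id.
    """
    if samples is None:
        samples = [c for c in classified.columns if c != "category"]
    mat = (classified[list(samples)] == CALLED).T.astype(int)
    mat = mat[sorted(mat.columns)]
    mat.index.name = "sample_id"
    return mat


def append_outgroup(matrix: pd.DataFrame, label: str = "normal") -> pd.DataFrame:
    """Append an all-zero germline row to root the tree at the normal state."""
    if label in matrix.index:
        raise ValueError(f"outgroup label {label!r} already present")
    out = matrix.copy()
    out.loc[label] = 0
    return out


def pairwise_gene_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise mismatch-count distance between sample rows of a 0/1 matrix."""
    x = matrix.to_numpy()
    d = (x[:, None, :] != x[None, :, :]).sum(axis=2).astype(float)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


# ---------------------------------------------------------------------------
# minimum-evolution tree
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree over the sample leaves with OLS branch lengths.

    Leaves are nodes ``0..n-1`` mapping to ``labels``; internal nodes are
    ``n..2n-3``. ``edges`` carry the branch lengths used for the tree-length
    criterion (negative OLS estimates clamped to zero); the raw OLS values
    are retained in ``raw_lengths``.
    """

    labels: tuple[str, ...]
    edges: tuple[tuple[int, int], ...]
    lengths: tuple[float, ...]
    raw_lengths: tuple[float, ...]
    total_length: float

    def __post_init__(self):
        if len(self.edges) != len(self.lengths):
            raise ValueError("edge/length mismatch")

    def to_newick(self, lengths: bool = True) -> str:
        return to_newick(self, lengths=lengths)


def _enumerate_topologies(n: int):
    """Yield edge lists of all unrooted binary topologies on n labeled leaves.

    Built by stepwise leaf addition: each new leaf subdivides an existing
    edge, which enumerates each topology exactly once.
    """
    base = [(0, n), (1, n), (2, n)]
    if n == 3:
        yield base
        return

    def rec(edges, next_leaf, next_internal):
        if next_leaf == n:
            yield edges
            return
        for i in range(len(edges)):
            u, v = edges[i]
            w = next_internal
            new_edges = edges[:i] + edges[i + 1:] + [(u, w), (w, v), (next_leaf, w)]
            yield from rec(new_edges, next_leaf + 1, next_internal + 1)

    yield from rec(base, 3, n + 1)


def _adjacency(edges):
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def _path_matrix(edges, n):
    """Indicator matrix: leaf pairs (i<j) x edges, 1 iff edge on the path."""
    adj = _adjacency(edges)
    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    parent_of = {}
    for leaf in range(n):
        parent = {leaf: None}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v in adj[u]:
                if v not in parent:
                    parent[v] = u
                    stack.append(v)
        parent_of[leaf] = parent
    for r, (i, j) in enumerate(pairs):
        parent = parent_of[i]
        u = j
        while parent[u] is not None:
            A[r, edge_index[frozenset((u, parent[u]))]] = 1.0
            u = parent[u]
    return pairs, A


def _topology_key(edges, n, labels):
    """Canonical label-based string of a topology (no lengths), for tie-breaks."""
    adj = _adjacency(edges)

    def subtree(node, parent):
        if node < n:
            return labels[node]
        parts = sorted(subtree(c, node) for c in adj[node] if c != parent)
        return "(" + ",".join(parts) + ")"

    root = n  # first internal node
    parts = sorted(subtree(c, root) for c in adj[root])
    return "(" + ",".join(parts) + ")"


def minimum_evolution_tree(d: pd.DataFrame) -> PhyloTree:
    """Exact OLS minimum-evolution tree by exhaustive topology search.

    Every unrooted binary topology over the taxa is enumerated; branch
    lengths are the ordinary-least-squares fit of tree path lengths to the
    observed distances; the selected topology minimizes total branch length
    with negative estimates clamped to zero. Ties are broken by the
    canonical (label-sorted) topology string, so the result is
    deterministic. Restricted to 3..8 taxa, where exhaustive search is
    exact; larger problems need an external heuristic search.
    """
    labels = tuple(str(x) for x in d.index)
    if list(d.index) != list(d.columns):
        raise ValueError("distance matrix rows and columns must match")
    n = len(labels)
    if not 3 <= n <= MAX_EXHAUSTIVE_TAXA:
        raise ValueError(
            f"exhaustive minimum-evolution search supports 3..{MAX_EXHAUSTIVE_TAXA} "
            f"taxa (got {n}); use a heuristic ME implementation beyond that"
        )
    dmat = d.to_numpy(dtype=float)
    if not np.allclose(dmat, dmat.T):
        raise ValueError("distance matrix must be symmetric")

    pairs = list(itertools.combinations(range(n), 2))
    dvec = np.array([dmat[i, j] for i, j in pairs])

    best = None
    for edges in _enumerate_topologies(n):
        _, A = _path_matrix(edges, n)
        w, *_ = np.linalg.lstsq(A, dvec, rcond=None)
        clamped = np.maximum(w, 0.0)
        total = float(clamped.sum())
        key = _topology_key(edges, n, labels)
        if (
            best is None
            or total < best[0] - 1e-12
            or (abs(total - best[0]) <= 1e-12 and key < best[1])
        ):
            best = (total, key, list(edges), w.copy(), clamped.copy())

    total, _, edges, raw, clamped = best
    return PhyloTree(
        labels=labels,
        edges=tuple((int(u), int(v)) for u, v in edges),
        lengths=tuple(float(x) for x in clamped),
        raw_lengths=tuple(float(x) for x in raw),
        total_length=total,
    )


def to_newick(tree: PhyloTree, lengths: bool = True) -> str:
    """Serialize a tree to Newick, children in canonical (sorted) order."""
    n = len(tree.labels)
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), ln in zip(tree.edges, tree.lengths):
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))

    def fmt(x: float) -> str:
        return format(x, ".12g")

    def subtree(node, parent, blen):
        if node < n:
            s = tree.labels[node]
        else:
            parts = sorted(
                subtree(c, node, ln) for c, ln in adj[node] if c != parent
            )
            s = "(" + ",".join(parts) + ")"
        if lengths and blen is not None:
            s += ":" + fmt(blen)
        return s

    root = n if n in adj else 0
    parts = sorted(subtree(c, root, ln) for c, ln in adj[root])
    return "(" + ",".join(parts) + ");"


def tree_splits(tree: PhyloTree) -> set[frozenset[str]]:
    """Nontrivial leaf bipartitions (as the lexicographically smaller side)."""
    n = len(tree.labels)
    adj: dict[int, list[int]] = {}
    for u, v in tree.edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    splits = set()
    for u, v in tree.edges:
        # leaves on the u side of edge (u, v)
        seen = {v, u}
        stack = [u]
        side = set()
        while stack:
            x = stack.pop()
            if x < n:
                side.add(tree.labels[x])
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if 2 <= len(side) <= n - 2:
            other = frozenset(tree.labels) - side
            splits.add(frozenset(min(sorted(side), sorted(other))))
    return splits


def leaf_distances(tree: PhyloTree) -> pd.DataFrame:
    """Path-length (patristic) distance matrix between the leaves."""
    n = len(tree.labels)
    adj: dict[int, list[tuple[int, float]]] = {}
    for (u, v), ln in zip(tree.edges, tree.lengths):
        adj.setdefault(u, []).append((v, ln))
        adj.setdefault(v, []).append((u, ln))
    out = np.zeros((n, n))
    for leaf in range(n):
        dist = {leaf: 0.0}
        stack = [leaf]
        while stack:
            u = stack.pop()
            for v, ln in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + ln
                    stack.append(v)
        for other in range(n):
            out[leaf, other] = dist[other]
    return pd.DataFrame(out, index=tree.labels, columns=tree.labels)
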
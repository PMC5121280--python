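"""Distance-based phylogeny and subfamily assignment.

Protein distances are p-distances under pairwise deletion (sites with a gap
in either sequence of a pair are skipped for that pair) with Poisson
correction d = -ln(1 - p). Trees are built with Saitou–Nei neighbor joining
using the Studier–Keppler criterion; support comes from column-resampling
bootstrap. Subfamilies are obtained by cutting the k-1 longest
well-supported internal branches, labelling groups I, II, ... by
decreasing size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "poisson_correct",
    "pairwise_distance",
    "build_nj",
    "bootstrap",
    "assign_subfamilies",
    "roman",
]


def poisson_correct(p: float) -> float:
    """Multiple-hit correction d = -ln(1 - p); infinite at p >= 1."""
    if p < 0:
        raise ValueError("p-distance cannot be negative")
    if p >= 1:
        return math.inf
    return -math.log(1.0 - p)


@dataclass
class DistanceMatrix:
    taxa: list[str]
    p: np.ndarray  # proportion of differing sites, pairwise deletion
    d: np.ndarray  # Poisson-corrected; inf flags an undefined entry

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.p.shape != (n, n) or self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")

    @property
    def n(self) -> int:
        return len(self.taxa)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(~np.isfinite(self.d))
        return [(self.taxa[a], self.taxa[b]) for a, b in zip(i, j) if a < b]


def _encode_alignment(aln: dict[str, str]) -> tuple[list[str], np.ndarray]:
    taxa = list(aln)
    L = len(aln[taxa[0]])
    if any(len(aln[t]) != L for t in taxa):
        raise ValueError("aligned sequences must have equal length")
    M = np.zeros((len(taxa), L), dtype=np.int16)
    for i, t in enumerate(taxa):
        M[i] = np.frombuffer(aln[t].encode("ascii"), dtype=np.uint8)
    M[(M == ord("-")) | (M == ord("."))] = -1
    return taxa, M


def _distances_from_matrix(M: np.ndarray, strict: bool) -> tuple[np.ndarray, np.ndarray]:
    valid = M >= 0
    both = valid[:, None, :] & valid[None, :, :]
    diff = (M[:, None, :] != M[None, :, :]) & both
    n_comp = both.sum(axis=2)
    n_diff = diff.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_comp > 0, n_diff / np.maximum(n_comp, 1), np.nan)
    if strict and np.isnan(p[np.triu_indices_from(p, 1)]).any():
        i, j = np.argwhere(np.isnan(p))[0]
        raise ValueError(f"no comparable sites for a sequence pair (indices {i},{j})")
    with np.errstate(divide="ignore"):
        d = np.where(np.isnan(p) | (p >= 1), np.inf, -np.log(np.clip(1.0 - p, 1e-300, None)))
    np.fill_diagonal(p, 0.0)
    np.fill_diagonal(d, 0.0)
    return p, d + 0.0  # normalise -0.0


def pairwise_distance(aln: dict[str, str], strict: bool = False) -> DistanceMatrix:
    """Poisson-corrected pairwise-deletion distances from a protein MSA.

    A pair with zero comparable sites gets p = NaN / d = inf (an error in
    strict mode). Permuting the input order permutes the matrix identically.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    taxa, M = _encode_alignment(aln)
    p, d = _distances_from_matrix(M, strict)
    return DistanceMatrix(taxa=taxa, p=p, d=d)


# ---------------------------------------------------------------------------
# neighbor joining


def build_nj(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei NJ with the Studier–Keppler Q criterion.

    Negative branch lengths are clamped to zero. Ties in Q are broken by
    the lexicographically smallest (taxon, taxon) label pair, making the
    topology deterministic. Missing (non-finite) distances are an error.
    """
    n = dm.n
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    bad = dm.undefined_pairs()
    if bad:
        raise ValueError(f"missing distances for pairs: {bad[:5]}")
    taxa = list(dm.taxa)
    D = dm.d.astype(float).copy()
    namespace = dendropy.TaxonNamespace(taxa)
    nodes = []
    for t in taxa:
        node = dendropy.Node()
        node.taxon = namespace.get_taxon(t)
        nodes.append(node)
    labels = list(taxa)  # cluster label = smallest member label, for tie-breaks

    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((labels[active[i]], labels[active[j]]))), (i, j))
            for i, j in cand if i < j
        )[1]
        i, j = best
        ai, aj = active[i], active[j]
        dij = sub[i, j]
        vi = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = dij - vi
        vi, vj = max(vi, 0.0), max(vj, 0.0)
        parent = dendropy.Node()
        for child, edge_len in ((nodes[ai], vi), (nodes[aj], vj)):
            parent.add_child(child)
            child.edge.length = edge_len
        new_D = 0.5 * (D[ai, :] + D[aj, :] - dij)
        D = np.vstack([D, new_D])
        D = np.hstack([D, np.append(new_D, 0.0)[:, None]])
        nodes.append(parent)
        labels.append(min(labels[ai], labels[aj]))
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b = active
    root = dendropy.Node()
    if nodes[a].is_leaf() or nodes[b].is_leaf():
        # attach the leaf under the other cluster's root
        leaf, other = (a, b) if nodes[a].is_leaf() else (b, a)
        root = nodes[other]
        root.add_child(nodes[leaf])
        nodes[leaf].edge.length = max(D[a, b], 0.0)
    else:
        root.add_child(nodes[a])
        root.add_child(nodes[b])
        half = max(D[a, b], 0.0) / 2.0
        nodes[a].edge.length = half
        nodes[b].edge.length = half
    tree = dendropy.Tree(taxon_namespace=namespace)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=True, collapse_unrooted_basal_bifurcation=False)
    return tree


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Edge]:
    """Internal edges keyed by the smaller-side leaf set (unrooted sense)."""
    all_leaves = frozenset(t.label for t in tree.taxon_namespace)
    out = {}
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            key = min(side, other, key=lambda s: (len(s), sorted(s)))
            out[key] = edge
    return out


def bootstrap(
    aln: dict[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    tree: dendropy.Tree | None = None,
) -> dendropy.Tree:
    """Column-resampling bootstrap supports on the NJ tree of ``aln``.

    Support for each internal edge of the original tree is the number of
    replicates (out of ``n_reps``) whose NJ tree contains the same leaf
    bipartition; stored as integer ``edge.head_node.label`` and
    ``support`` attribute. Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa, M = _encode_alignment(aln)
    if tree is None:
        tree = build_nj(pairwise_distance(aln))
    original = _bipartitions(tree)
    counts = {key: 0 for key in original}
    rng = np.random.default_rng(seed)
    L = M.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        p, d = _distances_from_matrix(M[:, cols], strict=False)
        if not np.isfinite(d).all():
            finite_max = d[np.isfinite(d)].max(initial=1.0)
            d = np.where(np.isfinite(d), d, 2.0 * finite_max)
        rep_tree = build_nj(DistanceMatrix(taxa=taxa, p=p, d=d))
        for key in _bipartitions(rep_tree):
            if key in counts:
                counts[key] += 1
    for key, edge in original.items():
        edge.head_node.label = str(counts[key])
        edge.support = counts[key]
    return tree


def roman(i: int) -> str:
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X",
                "XI", "XII", "XIII", "XIV", "XV"]
    return numerals[i - 1] if 1 <= i <= len(numerals) else f"G{i}"


def assign_subfamilies(
    tree: dendropy.Tree, k: int = 5, min_support: int = 500
) -> dict[str, str]:
    """Partition leaves into k subfamilies by cutting internal branches.

    The k-1 longest internal branches with bootstrap support >=
    ``min_support`` are removed; the resulting connected leaf groups are
    labelled I (largest) .. in decreasing size (ties by smallest member).
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return {t: "I" for t in leaves}
    edges = []
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node or node.is_leaf():
            continue
        support = getattr(edge, "support", None)
        if support is None and node.label is not None:
            try:
                support = int(node.label)
            except ValueError:
                support = None
        if support is not None and support >= min_support:
            edges.append((edge.length or 0.0, id(edge), edge))
    if len(edges) < k - 1:
        raise ValueError(
            f"only {len(edges)} internal branches with support >= {min_support}; "
            "lower min_support or k"
        )
    cut = {id(e) for _, _, e in sorted(edges, reverse=True)[: k - 1]}

    groups: list[list[str]] = []

    def collect(node, bucket: list[str]) -> None:
        if node.is_leaf():
            bucket.append(node.taxon.label)
        for child in node.child_nodes():
            if id(child.edge) in cut:
                newb: list[str] = []
                groups.append(newb)
                collect(child, newb)
            else:
                collect(child, bucket)

    first: list[str] = []
    groups.append(first)
    collect(tree.seed_node, first)
    groups = [g for g in groups if g]
    groups.sort(key=lambda g: (-len(g), sorted(g)[0]))
    out = {}
    for gi, group in enumerate(groups, start=1):
        for t in group:
            out[t] = roman(gi)
    return out
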
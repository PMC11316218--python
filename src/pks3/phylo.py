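"""JTT distances, neighbor-joining trees, bootstrap support and rooting.

Pairwise evolutionary distances are maximum-likelihood estimates under the
JTT amino-acid substitution model with equal rates across sites, computed
per pair on the columns free of gaps in both rows (pairwise deletion).
Trees are built with Saitou-Nei neighbor joining (BioNJ variance-weighted
pooling available as a flag), support is nonparametric bootstrap over
alignment columns, and trees are rooted on a designated outgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar

from . import jtt
from .errors import DistanceError, TreeError

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # avoid import cycle with pks3.msa (which uses nj_tree)
    from .msa import MultipleAlignment

logger = logging.getLogger(__name__)

#: Distances at or above this value are reported as saturated.
SATURATION_CAP = 10.0


@dataclass
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances (substitutions/site)."""

    ids: list[str]
    matrix: np.ndarray
    saturated: np.ndarray = field(default=None)  # boolean mask, same shape

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        if not np.allclose(self.matrix, self.matrix.T, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.ids.index(pair[0]), self.ids.index(pair[1])
        return float(self.matrix[i, j])

    def write_phylip(self, path) -> None:
        """Square PHYLIP-style tab-separated matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, name in enumerate(self.ids):
                row = "\t".join(f"{x:.6f}" for x in self.matrix[i])
                fh.write(f"{name}\t{row}\n")


@dataclass(frozen=True)
class JttDistanceResult:
    distance: float
    saturated: bool
    n_sites: int     # shared gap-free columns used
    n_diff: int      # differing columns among them


def _pair_count_matrix(row_a: str, row_b: str) -> np.ndarray:
    """20x20 counts of aligned residue pairs over shared gap-free columns.

    Columns containing a gap or an ambiguous residue (X) in either row are
    excluded.
    """
    counts = np.zeros((20, 20))
    idx = jtt.AA_INDEX
    for ca, cb in zip(row_a, row_b):
        ia = idx.get(ca)
        ib = idx.get(cb)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    return counts


def jtt_distance(
    row_a: str, row_b: str, cap: float = SATURATION_CAP
) -> JttDistanceResult:
    """ML distance between two aligned rows under the JTT model.

    Maximises sum_columns log(pi_i P_ij(t)) over t >= 0 by bounded scalar
    optimisation. Distances hitting ``cap`` are flagged saturated.
    Raises :class:`DistanceError` when the rows share no gap-free column.
    """
    if len(row_a) != len(row_b):
        raise DistanceError("aligned rows differ in length")
    counts = _pair_count_matrix(row_a, row_b)
    n_sites = int(counts.sum())
    if n_sites == 0:
        raise DistanceError("no shared gap-free columns between rows")
    n_diff = n_sites - int(np.trace(counts))
    if n_diff == 0:
        return JttDistanceResult(0.0, False, n_sites, 0)

    log_pi = np.log(jtt.JTT_FREQS)

    def neg_log_lik(t: float) -> float:
        p = jtt.transition_matrix(t)
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(p))
        return -np.sum(ll[counts > 0])

    res = minimize_scalar(
        neg_log_lik, bounds=(1e-8, cap), method="bounded",
        options={"xatol": 1e-8},
    )
    t_hat = float(res.x)
    saturated = t_hat >= cap - 1e-3
    return JttDistanceResult(cap if saturated else t_hat, saturated, n_sites, n_diff)


def build_distance_matrix(
    msa: MultipleAlignment, cap: float = SATURATION_CAP
) -> DistanceMatrix:
    """All-pairs JTT distances for an alignment of >= 3 taxa."""
    ids = msa.ids()
    n = len(ids)
    if n < 3:
        raise DistanceError("distance matrix needs at least 3 taxa")
    rows = [row for _, row in msa.rows]
    mat = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                res = jtt_distance(rows[i], rows[j], cap=cap)
            except DistanceError as exc:
                raise DistanceError(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            mat[i, j] = mat[j, i] = res.distance
            sat[i, j] = sat[j, i] = res.saturated
    return DistanceMatrix(ids=ids, matrix=mat, saturated=sat)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix, bionj: bool = False) -> dendropy.Tree:
    """Saitou-Nei neighbor joining (or BioNJ variance-weighted pooling).

    Deterministic: ties in the Q-criterion are broken by the lowest
    (row, column) index pair in the current working order. Negative branch
    lengths are clamped to zero and the deficit logged. Returns an unrooted
    tree whose seed node is the final trifurcation (for >= 4 taxa) or the
    central node (3 taxa).
    """
    n = len(dm.ids)
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 taxa")
    mat = np.asarray(dm.matrix, dtype=float)
    if np.isnan(mat).any():
        raise TreeError("distance matrix contains NaN")
    if not np.allclose(mat, mat.T):
        raise TreeError("distance matrix is not symmetric")

    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in dm.ids:
        node = dendropy.Node()
        node.taxon = tns.new_taxon(label=name)
        nodes.append(node)

    d = {(i, j): mat[i, j] for i in range(n) for j in range(n)}
    v = dict(d)  # BioNJ variance estimates; initialised to the distances
    active = list(range(n))
    next_index = n

    def clamp(length: float, context: str) -> float:
        if length < 0:
            logger.debug("clamped negative branch length %.6g at %s", length, context)
            return 0.0
        return length

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = np.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = clamp(li, f"join({i},{j})"), clamp(lj, f"join({i},{j})")

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        nodes.append(parent)

        if bionj and v[i, j] > 1e-12:
            others = [k for k in active if k not in (i, j)]
            lam = 0.5
            if others:
                lam = 0.5 + sum(v[j, k] - v[i, k] for k in others) / (
                    2 * len(others) * v[i, j]
                )
                lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5

        u = next_index
        next_index += 1
        for k in active:
            if k in (i, j):
                continue
            d[u, k] = d[k, u] = lam * (d[i, k] - li) + (1 - lam) * (d[j, k] - lj)
            v[u, k] = v[k, u] = lam * v[i, k] + (1 - lam) * v[j, k] - lam * (1 - lam) * v[i, j]
        d[u, u] = 0.0
        v[u, u] = 0.0
        active = [k for k in active if k not in (i, j)] + [u]

    # Final three nodes joined at an unrooted central node, closed form.
    a, b, c = active
    center = dendropy.Node()
    la = clamp((d[a, b] + d[a, c] - d[b, c]) / 2, "final")
    lb = clamp((d[a, b] + d[b, c] - d[a, c]) / 2, "final")
    lc = clamp((d[a, c] + d[b, c] - d[a, b]) / 2, "final")
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = lk

    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap


def _leafset(node: dendropy.Node) -> frozenset[str]:
    return frozenset(l.taxon.label for l in node.leaf_iter())


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets.

    Each internal edge splits the leaves in two; the side not containing
    the alphabetically smallest leaf label is the canonical representative,
    making the encoding invariant to rooting.
    """
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = _leafset(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int,
    seed: int,
    bionj: bool = False,
    cap: float = SATURATION_CAP,
    tree_builder: Callable[[DistanceMatrix], dendropy.Tree] | None = None,
) -> dendropy.Tree:
    """Point-estimate NJ tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times;
    replicate ``r`` draws from an independent stream derived from
    ``(seed, r)`` so serial and parallel evaluation agree. Support for each
    bipartition of the point tree is the percentage of replicate trees
    containing it, stored on internal nodes as ``node.support`` (float) and
    on the tree as ``tree.bipartition_support`` (dict).
    """
    if n_reps < 1:
        raise ValueError("bootstrap needs at least 1 replicate")
    build = tree_builder or (lambda dmat: nj_tree(dmat, bionj=bionj))
    point_dm = build_distance_matrix(msa, cap=cap)
    point_tree = build(point_dm)
    target = bipartitions(point_tree)
    counts = {bp: 0 for bp in target}
    length = msa.length
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, length, size=length)
        rep_msa = msa.subsample_columns(cols)
        rep_tree = build(build_distance_matrix(rep_msa, cap=cap))
        rep_bips = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bips:
                counts[bp] += 1
    support = {bp: 100.0 * counts[bp] / n_reps for bp in target}
    point_tree.bipartition_support = support
    annotate_supports(point_tree, support)
    return point_tree


def annotate_supports(
    tree: dendropy.Tree, support: dict[frozenset[str], float]
) -> None:
    """Attach per-node supports from a bipartition->percentage map."""
    all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    anchor = min(all_leaves)
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            node.support = None
            continue
        side = _leafset(node)
        if anchor in side:
            side = all_leaves - side
        node.support = support.get(side)


def root_with_outgroup(tree: dendropy.Tree, outgroup_id: str) -> dendropy.Tree:
    """Root the tree at the midpoint of the branch subtending the outgroup.

    Bootstrap supports (``tree.bipartition_support``) are re-attached to the
    rooted tree's internal nodes; bipartitions are rooting-invariant so the
    values are preserved. The input tree is modified in place and returned.
    """
    leaf = None
    for node in tree.leaf_node_iter():
        if node.taxon.label == outgroup_id:
            leaf = node
            break
    if leaf is None:
        raise TreeError(f"outgroup {outgroup_id!r} is not a leaf of the tree")
    edge_len = leaf.edge.length or 0.0
    tree.reroot_at_edge(
        leaf.edge, length1=edge_len / 2, length2=edge_len / 2,
        update_bipartitions=False,
    )
    tree.is_rooted = True
    support = getattr(tree, "bipartition_support", None)
    if support is not None:
        annotate_supports(tree, support)
    return tree


# ---------------------------------------------------------------------------
# Newick I/O


def to_newick(tree: dendropy.Tree, support_threshold: float | None = None) -> str:
    """Serialise with branch lengths and integer-percent supports as
    internal-node labels. ``support_threshold`` hides (does not delete)
    supports at or below the threshold — display only, topology untouched.
    """
    for node in tree.preorder_node_iter():
        sup = getattr(node, "support", None)
        if node.is_leaf() or sup is None:
            continue
        if support_threshold is not None and sup <= support_threshold:
            node.label = None
        else:
            node.label = str(int(round(sup)))
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    ).strip() + "\n"


def write_newick(tree: dendropy.Tree, path, support_threshold: float | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree, support_threshold))


def read_newick(path_or_string, rooted: bool = True) -> dendropy.Tree:
    """Parse Newick; internal-node labels are interpreted as supports."""
    if isinstance(path_or_string, str) and "(" in path_or_string:
        tree = dendropy.Tree.get(
            data=path_or_string, schema="newick", preserve_underscores=True
        )
    else:
        tree = dendropy.Tree.get(
            path=str(path_or_string), schema="newick", preserve_underscores=True
        )
    tree.is_rooted = rooted
    for node in tree.preorder_node_iter():
        node.support = None
        if not node.is_leaf() and node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass
    return tree


# ---------------------------------------------------------------------------
# Least-squares NNI refinement (optional stage)


def _path_length_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    tns = tree.taxon_namespace
    taxa = {t.label: t for t in tns}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


def least_squares_fit(tree: dendropy.Tree, dm: DistanceMatrix) -> float:
    """Sum of squared differences between tree path lengths and ``dm``,
    after refitting branch lengths by non-negative least squares."""
    _fit_branch_lengths(tree, dm)
    paths = _path_length_matrix(tree, dm.ids)
    diff = paths - dm.matrix
    return float(np.sum(np.triu(diff, 1) ** 2))


def _fit_branch_lengths(tree: dendropy.Tree, dm: DistanceMatrix) -> None:
    """OLS branch lengths (clamped >= 0) for the current topology."""
    from scipy.optimize import nnls

    ids = dm.ids
    index = {name: i for i, name in enumerate(ids)}
    edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
    n = len(ids)
    npairs = n * (n - 1) // 2
    a = np.zeros((npairs, len(edges)))
    b = np.zeros(npairs)
    # membership of each edge: leaves below it
    below = []
    for e in edges:
        below.append(frozenset(index[l.taxon.label] for l in e.head_node.leaf_iter()))
    row = 0
    for i in range(n):
        for j in range(i + 1, n):
            for k, mem in enumerate(below):
                if (i in mem) != (j in mem):
                    a[row, k] = 1.0
            b[row] = dm.matrix[i, j]
            row += 1
    lengths, _ = nnls(a, b)
    for e, ln in zip(edges, lengths):
        e.length = float(ln)


def _nni_moves(tree: dendropy.Tree):
    """The two NNIs around every internal edge.

    For edge tail->head with head's children {A, B} and a sibling C of head
    under tail, the two alternative topologies are reached by swapping A<->C
    and B<->C (swaps involving the remainder of the tree are equivalent).
    """
    for edge in list(tree.preorder_edge_iter()):
        head, tail = edge.head_node, edge.tail_node
        if tail is None or head.is_leaf():
            continue
        head_children = list(head.child_nodes())
        siblings = [c for c in tail.child_nodes() if c is not head]
        if len(head_children) < 2 or not siblings:
            continue
        other = siblings[0]
        for hc in head_children[:2]:
            yield head, tail, hc, other


def _apply_nni(head, tail, head_child, tail_child) -> None:
    head.remove_child(head_child)
    tail.remove_child(tail_child)
    head.add_child(tail_child)
    tail.add_child(head_child)


def nni_refine(
    tree: dendropy.Tree, dm: DistanceMatrix, max_rounds: int = 100
) -> dendropy.Tree:
    """Hill-climb over nearest-neighbor interchanges under a least-squares
    criterion against ``dm``; stops when no move improves the fit. Never
    worsens the criterion. Works on a clone; the input is untouched.
    """
    best_tree = tree.clone(depth=1)
    best_fit = least_squares_fit(best_tree, dm)
    for _ in range(max_rounds):
        improved = False
        for head, tail, hc, other in _nni_moves(best_tree):
            _apply_nni(head, tail, hc, other)
            fit = least_squares_fit(best_tree, dm)
            if fit < best_fit - 1e-12:
                best_fit = fit
                improved = True
                break  # restart enumeration on the modified tree
            _apply_nni(head, tail, other, hc)  # revert
        if not improved:
            break
    least_squares_fit(best_tree, dm)  # leave OLS branch lengths in place
    return best_tree
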
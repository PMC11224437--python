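"""Distance-based gene-tree estimation and tree-space concordance.

Gene trees are estimated by neighbor joining on Jukes-Cantor distances (a
deliberate, documented stand-in for maximum-likelihood inference: the
downstream concordance analysis — Robinson-Foulds distances, classical MDS
of tree space, average bootstrap per gene tree — is the computation of
interest, and it accepts externally estimated Newick trees anywhere a tree
argument appears).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .seqio import Tree
from .supermatrix import LocusAlignment, MISSING_CHARS

log = logging.getLogger(__name__)

JC_SATURATION_CEILING = 5.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray
    saturated_pairs: list[tuple[str, str]] | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")


@dataclass
class RFMatrix:
    tree_ids: list[str]
    rf: np.ndarray


@dataclass
class MDSEmbedding:
    coords: np.ndarray  # (n, dims)
    eigenvalues: np.ndarray


def _comparable_mask(a: str, b: str) -> list[int]:
    valid = {"A", "C", "G", "T"}
    return [i for i, (x, y) in enumerate(zip(a, b)) if x in valid and y in valid]


def jc_distance(aln: LocusAlignment, ceiling: float = JC_SATURATION_CEILING) -> DistanceMatrix:
    """Jukes-Cantor distances d = -3/4 ln(1 - 4p/3) over pairwise-complete
    columns; saturated pairs (p >= 3/4) get the configured ceiling and are
    flagged."""
    taxa = list(aln.rows)
    if len(taxa) < 2:
        raise ValueError("need >= 2 rows")
    n = len(taxa)
    d = np.zeros((n, n))
    saturated = []
    valid = {"A", "C", "G", "T"}
    enc = {t: np.frombuffer(aln.rows[t].encode(), dtype=np.uint8) for t in taxa}
    is_valid = {
        t: np.isin(enc[t], np.frombuffer(b"ACGT", dtype=np.uint8)) for t in taxa
    }
    for i in range(n):
        for j in range(i + 1, n):
            mask = is_valid[taxa[i]] & is_valid[taxa[j]]
            m = int(mask.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {taxa[i]} and {taxa[j]}"
                )
            p = float((enc[taxa[i]][mask] != enc[taxa[j]][mask]).sum()) / m
            if p >= 0.75:
                dist = ceiling
                saturated.append((taxa[i], taxa[j]))
            else:
                dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(taxa, d, saturated_pairs=saturated or None)


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the standard Q criterion.

    Negative branch lengths are clamped to 0. The returned tree is unrooted
    (trifurcating root). Deterministic: ties broken by first minimum in
    row-major order of the current label ordering.
    """
    if not np.all(np.isfinite(D.d)):
        raise ValueError("non-finite distances")
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")

    ns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for lab in D.labels:
        node = dendropy.Node()
        node.taxon = ns.new_taxon(lab)
        nodes.append(node)
    d = D.d.astype(float).copy()
    active = list(range(n))

    def clamp(x: float) -> float:
        return x if x > 0 else 0.0

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        na, nb = nodes[ai], nodes[aj]
        na.edge.length = clamp(li)
        nb.edge.length = clamp(lj)
        parent.add_child(na)
        parent.add_child(nb)
        nodes.append(parent)
        new = np.zeros(d.shape[0] + 1)
        for idx in active:
            if idx in (ai, aj):
                continue
            new[idx] = 0.5 * (d[ai, idx] + d[aj, idx] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new)] = new
        d[: len(new), -1] = new
        active = [x for x in active if x not in (ai, aj)] + [d.shape[0] - 1]

    a, b, c = active
    dab, dac, dbc = d[a, b], d[a, c], d[b, c]
    t = dendropy.Tree(taxon_namespace=ns)
    for idx, ln in (
        (a, 0.5 * (dab + dac - dbc)),
        (b, 0.5 * (dab + dbc - dac)),
        (c, 0.5 * (dac + dbc - dab)),
    ):
        nodes[idx].edge.length = clamp(ln)
        t.seed_node.add_child(nodes[idx])
    t.is_rooted = False
    return Tree(t)


def tree_path_distances(tree: Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances (additive matrix of a tree)."""
    pdm = tree.dtree.phylogenetic_distance_matrix()
    labels = sorted(tree.leaf_labels)
    taxa = {t.label: t for t in tree.dtree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Bootstrap


def _collapse_tiny_edges(tree: Tree, eps: float = 1e-12) -> Tree:
    t = tree.dtree.clone(depth=1)
    for edge in list(t.preorder_edge_iter()):
        head = edge.head_node
        if head.parent_node is not None and not head.is_leaf():
            if (edge.length or 0.0) < eps:
                edge.collapse()
    return Tree(t)


def bootstrap_support(
    aln: LocusAlignment, n_reps: int, seed: int, collapse_eps: float = 1e-12
) -> Tree:
    """Column bootstrap of the NJ gene tree.

    Supports (0-100 scale) on internal nodes of the point-estimate tree are
    the percentage of replicates whose (zero-length-collapsed) NJ tree
    contains the node's bipartition. Collapsing zero-length internal
    branches in replicates means data with no signal yields support 0
    rather than tie-break artifacts.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = neighbor_joining(jc_distance(aln))
    target = point.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    taxa = list(aln.rows)
    L = aln.length
    mat = np.array([list(aln.rows[t]) for t in taxa])
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rows = {t: "".join(mat[i, cols]) for i, t in enumerate(taxa)}
        rep = neighbor_joining(jc_distance(LocusAlignment(aln.locus_id, rows, aln.alphabet)))
        rep_bps = _collapse_tiny_edges(rep, collapse_eps).bipartitions()
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1

    leaves = frozenset(point.leaf_labels)
    anchor = min(leaves)
    n_leaf = len(leaves)
    for node in point.dtree.postorder_internal_node_iter(exclude_seed_node=True):
        cl = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 2 <= len(cl) <= n_leaf - 2:
            key = cl if anchor not in cl else leaves - cl
            node.label = f"{100.0 * counts[key] / n_reps:g}"
    point.support_scale = "0-100"
    return point


def avg_bootstrap(tree: Tree) -> float:
    """Mean of internal-node support values."""
    vals = tree.internal_supports()
    if not vals:
        raise ValueError("tree has no internal support values")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Robinson-Foulds


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unnormalized RF distance: |B1 symmetric-difference B2| over
    non-trivial bipartitions, trees treated as unrooted; polytomies allowed."""
    l1, l2 = set(t1.leaf_labels), set(t2.leaf_labels)
    if l1 != l2:
        raise ValueError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    return len(t1.bipartitions() ^ t2.bipartitions())


def rf_normalized(t1: Tree, t2: Tree) -> float:
    n = len(t1.leaf_labels)
    denom = 2 * (n - 3)
    return robinson_foulds(t1, t2) / denom if denom > 0 else 0.0


def rf_matrix(trees: list[Tree], tree_ids: list[str] | None = None) -> RFMatrix:
    """All pairwise RF distances; trees are pruned to the common leaf set
    (logged) before comparison."""
    if len(trees) < 2:
        raise ValueError("need >= 2 trees")
    ids = tree_ids or [f"tree{i}" for i in range(len(trees))]
    common = set(trees[0].leaf_labels)
    for t in trees[1:]:
        common &= set(t.leaf_labels)
    if len(common) < 4:
        raise ValueError(
            f"common leaf set has {len(common)} taxa; need >= 4 for RF"
        )
    pruned = []
    for tid, t in zip(ids, trees):
        if set(t.leaf_labels) != common:
            log.info("rf_matrix: pruning %s to %d common leaves", tid, len(common))
            t = t.prune_to(common)
        pruned.append(t.bipartitions())
    n = len(pruned)
    rf = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            rf[i, j] = rf[j, i] = len(pruned[i] ^ pruned[j])
    return RFMatrix(ids, rf)


# ---------------------------------------------------------------------------
# Classical MDS


def classical_mds(D: np.ndarray, dims: int = 2) -> MDSEmbedding:
    """Torgerson classical scaling: double-center -0.5 J D^2 J, embed on the
    top eigenvectors scaled by sqrt(eigenvalue) (negatives clamped to 0).

    Sign convention: the first nonzero coordinate of each axis is positive.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("D must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    wc = np.clip(w[:dims], 0.0, None)
    coords = v[:, :dims] * np.sqrt(wc)[None, :]
    for a in range(coords.shape[1]):
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, a] = -col
    return MDSEmbedding(coords=coords, eigenvalues=w)
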
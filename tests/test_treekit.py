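import itertools
import math
import random

import dendropy
import numpy as np
import pytest

from tephrimark.seqio import Tree, parse_newick
from tephrimark.supermatrix import LocusAlignment
from tephrimark.treekit import (
    DistanceMatrix,
    avg_bootstrap,
    bootstrap_support,
    classical_mds,
    jc_distance,
    neighbor_joining,
    rf_matrix,
    robinson_foulds,
    tree_path_distances,
)


# ---------------------------------------------------------------------------
# helpers


def random_binary_tree(labels, rng, min_bl=0.1, max_bl=1.0):
    """Random topology by sequential joining, random branch lengths."""
    parts = [f"{l}:{rng.uniform(min_bl, max_bl):.6f}" for l in labels]
    while len(parts) > 3:
        i, j = sorted(rng.sample(range(len(parts)), 2), reverse=True)
        a, b = parts.pop(i), parts.pop(j)
        parts.append(f"({a},{b}):{rng.uniform(min_bl, max_bl):.6f}")
    return parse_newick("(" + ",".join(parts) + ");")


def brute_force_rf(t1: Tree, t2: Tree) -> int:
    """Independent RF oracle: splits from connected components of the tree
    graph after deleting each internal edge (networkx connectivity)."""
    import networkx as nx

    def splits(tree):
        g = nx.Graph()
        nodes = {}
        for node in tree.dtree.preorder_node_iter():
            nodes[id(node)] = node
            if node.parent_node is not None:
                g.add_edge(id(node.parent_node), id(node))
        leaves = {
            id(n): n.taxon.label for n in tree.dtree.leaf_node_iter()
        }
        all_leaves = frozenset(leaves.values())
        anchor = min(all_leaves)
        out = set()
        for u, v in list(g.edges()):
            h = g.copy()
            h.remove_edge(u, v)
            comp = nx.node_connected_component(h, u)
            side = frozenset(leaves[x] for x in comp if x in leaves)
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side if anchor not in side else all_leaves - side)
        return out

    return len(splits(t1) ^ splits(t2))


# ---------------------------------------------------------------------------
# JC distances


class TestJCDistance:
    def test_identical_rows_zero(self):
        a = LocusAlignment("L", {"a": "ACGTACGT", "b": "ACGTACGT"})
        assert jc_distance(a).d[0, 1] == 0.0

    def test_formula_at_p_03(self):
        # 3 of 10 sites differ -> d = -0.75 ln(0.6)
        a = LocusAlignment("L", {"a": "AAAAAAAAAA", "b": "CCCAAAAAAA"})
        d = jc_distance(a).d[0, 1]
        assert d == pytest.approx(-0.75 * math.log(0.6), abs=1e-12)
        assert d == pytest.approx(0.3831, abs=1e-4)

    def test_saturation_ceiling_flagged(self):
        a = LocusAlignment("L", {"a": "AAAA", "b": "CCCA"})
        dm = jc_distance(a)
        assert dm.d[0, 1] == 5.0
        assert dm.saturated_pairs == [("a", "b")]

    def test_missing_only_overlap_errors(self):
        a = LocusAlignment("L", {"a": "AC--", "b": "--GT"})
        with pytest.raises(ValueError, match="a and b"):
            jc_distance(a)

    def test_comparisons_use_pairwise_complete_columns(self):
        a = LocusAlignment("L", {"a": "ACGT?A", "b": "ACGTTA", "c": "?CGTTA"})
        dm = jc_distance(a)
        assert dm.d[0, 2] == 0.0  # a vs c compare only cols 1-3,5


# ---------------------------------------------------------------------------
# Neighbor joining


class TestNeighborJoining:
    def test_additive_four_taxon_example(self):
        labels = ["a", "b", "c", "d"]
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        t = neighbor_joining(DistanceMatrix(labels, d))
        ref = parse_newick("((a:1,b:2):1,c:3,d:4);")
        assert robinson_foulds(t, ref) == 0
        rec = tree_path_distances(t)
        idx = {l: i for i, l in enumerate(rec.labels)}
        for i, j in itertools.combinations(range(4), 2):
            li, lj = labels[i], labels[j]
            assert rec.d[idx[li], idx[lj]] == pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        t = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        rec = tree_path_distances(t)
        assert np.allclose(rec.d, d[np.ix_([0, 1, 2], [0, 1, 2])], atol=1e-9)

    def test_label_permutation_invariance(self):
        rng = random.Random(3)
        true = random_binary_tree(list("abcdefg"), rng)
        dm = tree_path_distances(true)
        t1 = neighbor_joining(dm)
        perm = list(range(len(dm.labels)))[::-1]
        dm2 = DistanceMatrix(
            [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)]
        )
        t2 = neighbor_joining(dm2)
        assert robinson_foulds(t1, t2) == 0

    def test_consistency_on_random_additive_matrices(self):
        rng = random.Random(17)
        for _ in range(40):
            n = rng.randint(6, 10)
            true = random_binary_tree([f"x{i}" for i in range(n)], rng)
            dm = tree_path_distances(true)
            est = neighbor_joining(dm)
            assert robinson_foulds(est, true) == 0
            rec = tree_path_distances(est)
            assert np.abs(rec.d - dm.d).max() < 1e-9

    def test_nonfinite_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(ValueError, match="finite"):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d))

    def test_agrees_with_skbio_nj_topology(self):
        """Independent cross-check against scikit-bio's NJ on a non-additive
        (noisy) matrix."""
        import skbio

        rng = np.random.default_rng(5)
        labels = [f"t{i}" for i in range(7)]
        true = random_binary_tree(labels, random.Random(9))
        d = tree_path_distances(true).d + rng.uniform(0, 0.01, (7, 7))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        dm = DistanceMatrix(labels, d)
        ours = neighbor_joining(dm)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        theirs = parse_newick(str(theirs))
        assert robinson_foulds(ours, theirs) == 0


# ---------------------------------------------------------------------------
# Bootstrap


class TestBootstrap:
    def test_zero_variation_gives_zero_support(self):
        a = LocusAlignment("L", {t: "A" * 50 for t in "abcde"})
        t = bootstrap_support(a, 20, seed=1)
        assert all(s == 0.0 for s in t.internal_supports())

    def test_same_seed_reproducible(self, clean_dataset):
        _, _, loci, _ = clean_dataset
        t1 = bootstrap_support(loci[0], 25, seed=7)
        t2 = bootstrap_support(loci[0], 25, seed=7)
        assert t1.to_newick() == t2.to_newick()

    def test_longer_locus_better_supported(self):
        """Support for true bipartitions grows with alignment length."""
        from tephrimark.simulate import SimConfig, simulate_dataset

        def mean_true_support(length, seed):
            cfg = SimConfig(
                n_taxa=6, n_loci=1, locus_length_mean=length, locus_length_sd=0,
                tree_depth=0.1, dropout_prob=0.0, per_site_rate_shape=0.0,
                per_locus_rate_shape=0.0, n_unique_regions=0,
                background_length=8_000, seed=seed,
            )
            _, _, loci, truth = simulate_dataset(cfg)
            bt = bootstrap_support(loci[0], 100, seed=13)
            true_bps = truth.true_tree.bipartitions()
            leaves = frozenset(bt.leaf_labels)
            anchor = min(leaves)
            vals = []
            for node in bt.dtree.postorder_internal_node_iter(exclude_seed_node=True):
                cl = frozenset(l.taxon.label for l in node.leaf_iter())
                if 2 <= len(cl) <= len(leaves) - 2 and node.label:
                    key = cl if anchor not in cl else leaves - cl
                    if key in true_bps:
                        vals.append(float(node.label))
            return np.mean(vals) if vals else 0.0

        assert mean_true_support(5000, 41) > mean_true_support(100, 41)

    def test_avg_bootstrap_mean(self):
        t = parse_newick("(((a,b)90,(c,d)100)80,(e,f));", support_scale="0-100")
        assert avg_bootstrap(t) == pytest.approx(90.0)


# ---------------------------------------------------------------------------
# Robinson-Foulds


class TestRobinsonFoulds:
    def test_self_distance_zero(self):
        rng = random.Random(2)
        t = random_binary_tree(list("abcdef"), rng)
        assert robinson_foulds(t, t) == 0

    def test_five_taxon_example(self):
        t1 = parse_newick("((a,b),(c,d),e);")
        t2 = parse_newick("((a,c),(b,d),e);")
        assert robinson_foulds(t1, t2) == 4

    def test_maximally_different_six_taxon_pair(self):
        # no internal bipartition shared between the two topologies
        t1 = parse_newick("(((a,b),(c,d)),(e,f));")
        t2 = parse_newick("(((a,c),(b,e)),(d,f));")
        assert robinson_foulds(t1, t2) == 2 * (6 - 3)

    def test_leaf_set_mismatch_errors(self):
        t1 = parse_newick("((a,b),(c,d));")
        t2 = parse_newick("((a,b),(c,e));")
        with pytest.raises(ValueError, match="leaf sets differ"):
            robinson_foulds(t1, t2)

    def test_matches_brute_force_and_dendropy(self):
        rng = random.Random(11)
        trees = [
            random_binary_tree([f"x{i}" for i in range(rng.randint(4, 7))], rng)
            for _ in range(25)
        ]
        ns = dendropy.TaxonNamespace()
        for t1, t2 in itertools.combinations(trees, 2):
            if set(t1.leaf_labels) != set(t2.leaf_labels):
                continue
            ours = robinson_foulds(t1, t2)
            assert ours == brute_force_rf(t1, t2)
            d1 = dendropy.Tree.get(
                data=t1.to_newick(), schema="newick", taxon_namespace=ns
            )
            d2 = dendropy.Tree.get(
                data=t2.to_newick(), schema="newick", taxon_namespace=ns
            )
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            assert ours == dendropy.calculate.treecompare.symmetric_difference(d1, d2)

    def test_rf_matrix_identical_trees_zero(self):
        rng = random.Random(4)
        t = random_binary_tree(list("abcdef"), rng)
        m = rf_matrix([t, t, t])
        assert np.all(m.rf == 0)

    def test_rf_matrix_prunes_to_common_leafset(self):
        t1 = parse_newick("(((a,b),(c,d)),e);")
        t2 = parse_newick("((a,b),(c,d));")
        m = rf_matrix([t1, t2])
        assert m.rf[0, 1] == 0

    def test_rf_matrix_requires_two_trees(self):
        with pytest.raises(ValueError, match=">= 2"):
            rf_matrix([parse_newick("((a,b),(c,d));")])


# ---------------------------------------------------------------------------
# Classical MDS


class TestClassicalMDS:
    def test_zero_distances_collapse_to_origin(self):
        emb = classical_mds(np.zeros((4, 4)))
        assert np.allclose(emb.coords, 0)

    def test_planar_configuration_recovered(self):
        pts = np.array([[0, 0], [3, 0], [0, 4]], dtype=float)
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = classical_mds(D)
        rec = np.linalg.norm(emb.coords[:, None] - emb.coords[None, :], axis=-1)
        assert np.allclose(rec, D, atol=1e-9)

    def test_centroid_at_origin(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10, (6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        emb = classical_mds(D)
        assert np.allclose(emb.coords.mean(axis=0), 0, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 5, (5, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        perm = [4, 2, 0, 1, 3]
        e1 = classical_mds(D)
        e2 = classical_mds(D[np.ix_(perm, perm)])
        r1 = np.linalg.norm(e1.coords[:, None] - e1.coords[None, :], axis=-1)
        r2 = np.linalg.norm(e2.coords[:, None] - e2.coords[None, :], axis=-1)
        assert np.allclose(r1[np.ix_(perm, perm)], r2, atol=1e-9)

    def test_asymmetric_rejected(self):
        D = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(D)


# ---------------------------------------------------------------------------
# Pipeline-level concordance property


def test_fast_long_loci_track_species_tree_better():
    """Gene trees from longer alignments sit closer (RF) to the true
    species tree and carry higher average bootstrap than short ones."""
    from tephrimark.simulate import SimConfig, simulate_dataset

    def run(length, seed):
        cfg = SimConfig(
            n_taxa=8, n_loci=6, locus_length_mean=length, locus_length_sd=0,
            tree_depth=0.1, dropout_prob=0.0, per_site_rate_shape=0.0,
            per_locus_rate_shape=0.0, n_unique_regions=0,
            background_length=30_000, seed=seed,
        )
        _, _, loci, truth = simulate_dataset(cfg)
        rfs, sups = [], []
        for i, aln in enumerate(loci):
            bt = bootstrap_support(aln, 50, seed=100 + i)
            rfs.append(robinson_foulds(bt, truth.true_tree))
            sups.append(avg_bootstrap(bt))
        return np.mean(rfs), np.mean(sups)

    rf_long, sup_long = run(3000, 71)
    rf_short, sup_short = run(150, 71)
    assert rf_long < rf_short
    assert sup_long > sup_short
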
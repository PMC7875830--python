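"""Euclidean genotype distances and Neighbor-Joining reconstruction."""

import dendropy
import numpy as np
import pytest

from introkit import distclust
from introkit.distclust import (
    DistanceMatrix,
    euclidean_distances,
    neighbor_joining,
    write_newick,
)
from conftest import make_matrix


def random_additive_tree(rng, n_taxa):
    """Random binary topology with uniform branch lengths; returns
    (dendropy tree, taxon labels, path-distance matrix)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=ns)
    # start from a 2-leaf tree and attach remaining leaves to random edges
    a = tree.seed_node.new_child(taxon=ns[0], edge_length=rng.uniform(0.1, 1.0))
    tree.seed_node.new_child(taxon=ns[1], edge_length=rng.uniform(0.1, 1.0))
    for i in range(2, n_taxa):
        edges = [e for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
        edge = edges[rng.integers(len(edges))]
        head = edge.head_node
        parent = head.parent_node
        split = dendropy.Node(edge_length=edge.length * rng.uniform(0.2, 0.8))
        head.edge.length -= split.edge.length
        parent.remove_child(head)
        parent.add_child(split)
        split.add_child(head)
        split.new_child(taxon=ns[i], edge_length=rng.uniform(0.1, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    d = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(n_taxa):
            d[i, j] = pdm.patristic_distance(ns[i], ns[j])
    return tree, labels, d


def rf_distance(tree1: dendropy.Tree, newick2: str, ns: dendropy.TaxonNamespace) -> int:
    t2 = dendropy.Tree.get(data=newick2, schema="newick", taxon_namespace=ns)
    tree1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(tree1, t2)


class TestEuclideanDistances:
    def test_identical_samples_distance_zero(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        d = euclidean_distances(m)
        assert d.values[0, 1] == 0.0

    def test_hand_computed_distance(self):
        m = make_matrix([[0, 0], [2, 2]])
        d = euclidean_distances(m)
        assert d.values[0, 1] == pytest.approx(np.sqrt(8.0), abs=1e-12)

    def test_missing_rescaling_is_unbiased(self):
        # masking loci and rescaling reproduces the complete-data distance on average
        rng = np.random.default_rng(0)
        ratios = []
        for _ in range(300):
            x = rng.integers(0, 3, size=(2, 30))
            full = np.sqrt(((x[0] - x[1]) ** 2).sum())
            if full == 0:
                continue
            drop = rng.integers(0, 30)
            m = make_matrix(x, missing=[(0, drop)])
            d = euclidean_distances(m, missing="rescale")
            ratios.append((d.values[0, 1] / full) ** 2)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.05)

    def test_disjoint_missing_pair_raises_with_names(self):
        m = make_matrix([[0, 1], [1, 2], [1, 1]], missing=[(0, 0), (1, 1)])
        with pytest.raises(distclust.DistanceError, match="s1.*s2"):
            euclidean_distances(m)

    def test_multiallelic_input_rejected(self):
        m = make_matrix([[0, 1], [1, 2]], alt_counts=[1, 2])
        with pytest.raises(distclust.DistanceError, match="multiallelic"):
            euclidean_distances(m)

    def test_complete_only_mode_uses_shared_loci(self):
        m = make_matrix([[0, 1, 2], [2, 1, 0], [1, 1, 1]], missing=[(2, 0)])
        d = euclidean_distances(m, missing="complete-only")
        # locus 0 (missing in s3) is excluded for every pair
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree: ((A:2,B:3):1,C:4,D:5) with internal edge 1
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 0, 0],
            ],
            dtype=float,
        )
        d[3, 2] = d[2, 3] = 9
        tree = neighbor_joining(DistanceMatrix(ids, d))
        t = tree.as_dendropy()
        pdm = t.phylogenetic_distance_matrix()
        ns = t.taxon_namespace
        for i in range(4):
            for j in range(4):
                ti = ns.get_taxon(ids[i])
                tj = ns.get_taxon(ids[j])
                assert pdm.patristic_distance(ti, tj) == pytest.approx(d[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        lengths = {
            c.label: l for c, l in tree.root.children
        }
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_random_additive_topologies_recovered(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            true_tree, labels, d = random_additive_tree(rng, 8)
            nj = neighbor_joining(DistanceMatrix(labels, d))
            hits += rf_distance(true_tree, nj.to_newick(), true_tree.taxon_namespace) == 0
        assert hits == 20

    def test_agrees_with_independent_nj_implementation(self):
        rng = np.random.default_rng(123)
        _, labels, d = random_additive_tree(rng, 7)
        mine = neighbor_joining(DistanceMatrix(labels, d))
        # dendropy's own NJ as the independent oracle
        csv = "," + ",".join(labels) + "\n"
        for i, lab in enumerate(labels):
            csv += lab + "," + ",".join(str(x) for x in d[i]) + "\n"
        import io

        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv))
        oracle = pdm.nj_tree()
        assert (
            rf_distance(oracle, mine.to_newick(), oracle.taxon_namespace) == 0
        )

    def test_sample_order_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(5)
        _, labels, d = random_additive_tree(rng, 6)
        t1 = neighbor_joining(DistanceMatrix(labels, d))
        perm = rng.permutation(6)
        t2 = neighbor_joining(
            DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)])
        )
        ns = dendropy.TaxonNamespace(labels)
        a = dendropy.Tree.get(data=t1.to_newick(), schema="newick", taxon_namespace=ns)
        assert rf_distance(a, t2.to_newick(), ns) == 0

    def test_too_few_samples_rejected(self):
        with pytest.raises(distclust.DistanceError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_nonfinite_distances_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.inf
        with pytest.raises(distclust.DistanceError):
            neighbor_joining(DistanceMatrix(["a", "b", "c"], d))

    def test_species_form_clades_on_simulated_data(self, sim_separated):
        _, matrix, _ = sim_separated
        dist = euclidean_distances(matrix)
        tree = neighbor_joining(dist)
        t = tree.as_dendropy()
        t.encode_bipartitions()
        leafsets = {
            frozenset(tx.label for tx in b.leafset_taxa(t.taxon_namespace))
            for b in t.bipartition_encoding
        }
        a_clade = frozenset(s for s in matrix.sample_ids if s.startswith("A"))
        b_clade = frozenset(s for s in matrix.sample_ids if s.startswith("B"))
        all_taxa = frozenset(matrix.sample_ids)
        assert a_clade in leafsets or (all_taxa - a_clade) in leafsets
        assert b_clade in leafsets or (all_taxa - b_clade) in leafsets


class TestNewick:
    def test_round_trip_preserves_topology_and_lengths(self, tmp_path):
        rng = np.random.default_rng(9)
        _, labels, d = random_additive_tree(rng, 6)
        tree = neighbor_joining(DistanceMatrix(labels, d))
        path = str(tmp_path / "t.nwk")
        write_newick(tree, path)
        ns = dendropy.TaxonNamespace(labels)
        a = dendropy.Tree.get(data=tree.to_newick(), schema="newick", taxon_namespace=ns)
        b = dendropy.Tree.get(path=path, schema="newick", taxon_namespace=ns)
        assert rf_distance(a, b.as_string(schema="newick"), ns) == 0
        pa = a.phylogenetic_distance_matrix()
        pb = b.phylogenetic_distance_matrix()
        for i in ns:
            for j in ns:
                assert pa.patristic_distance(i, j) == pytest.approx(
                    pb.patristic_distance(i, j), abs=1e-9
                )

    def test_labels_with_spaces_are_quoted(self):
        d = np.array([[0, 1, 2], [1, 0, 2], [2, 2, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["sample one", "b", "c"], d))
        nwk = tree.to_newick()
        assert "'sample one'" in nwk
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert {lf.taxon.label for lf in t.leaf_node_iter()} == {"sample one", "b", "c"}

    def test_three_leaf_tree_is_trifurcating(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["a", "b", "c"], d))
        assert len(tree.root.children) == 3
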
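import itertools

import dendropy
import numpy as np
import pytest

from pks3 import jtt
from pks3.errors import DistanceError, TreeError
from pks3.msa import MultipleAlignment
from pks3.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    build_distance_matrix,
    jtt_distance,
    least_squares_fit,
    nj_tree,
    nni_refine,
    read_newick,
    root_with_outgroup,
    to_newick,
)

from conftest import random_protein


class TestJttModel:
    def test_rate_matrix_is_a_proper_generator(self):
        q = jtt.rate_matrix()
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert np.all(q - np.diag(np.diag(q)) >= 0)
        # normalised to one expected substitution per unit time
        assert np.isclose(-(jtt.JTT_FREQS * np.diag(q)).sum(), 1.0)

    def test_detailed_balance(self):
        q = jtt.rate_matrix()
        flux = jtt.JTT_FREQS[:, None] * q
        assert np.allclose(flux, flux.T, atol=1e-12)

    def test_transition_matrix_properties(self):
        assert np.allclose(jtt.transition_matrix(0.0), np.eye(20), atol=1e-10)
        p = jtt.transition_matrix(0.7)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all(p >= 0)
        # Chapman-Kolmogorov
        assert np.allclose(
            jtt.transition_matrix(0.3) @ jtt.transition_matrix(0.4), p, atol=1e-10
        )
        # stationarity of the equilibrium frequencies
        assert np.allclose(jtt.JTT_FREQS @ p, jtt.JTT_FREQS, atol=1e-10)


def _grid_search_distance(row_a, row_b, grid):
    from pks3.phylo import _pair_count_matrix

    counts = _pair_count_matrix(row_a, row_b)
    log_pi = np.log(jtt.JTT_FREQS)

    def loglik(t):
        p = np.maximum(jtt.transition_matrix(t), 1e-300)
        return float(np.sum(counts * (log_pi[:, None] + np.log(p))))

    values = [loglik(t) for t in grid]
    return grid[int(np.argmax(values))]


class TestJttDistance:
    def test_identical_rows_zero(self):
        assert jtt_distance("MKTAY", "MKTAY").distance == 0.0

    def test_all_columns_different_saturates(self):
        res = jtt_distance("A" * 30, "W" * 30)
        assert res.saturated and res.distance == pytest.approx(10.0)

    def test_matches_grid_search_oracle(self, rng):
        """ML optimiser agrees with a brute-force likelihood grid (1e-4 step)."""
        seq = [jtt.AA_ORDER[i] for i in rng.integers(0, 20, 100)]
        mutant = list(seq)
        for pos in rng.choice(100, size=10, replace=False):
            mutant[pos] = jtt.AA_ORDER[(jtt.AA_INDEX[mutant[pos]] + 7) % 20]
        row_a, row_b = "".join(seq), "".join(mutant)
        est = jtt_distance(row_a, row_b).distance
        oracle = _grid_search_distance(row_a, row_b, np.arange(1e-4, 1.0, 1e-4))
        assert est == pytest.approx(oracle, abs=1e-3)

    def test_gap_only_overlap_rejected(self):
        with pytest.raises(DistanceError):
            jtt_distance("AA--", "--AA")

    def test_pairwise_deletion_ignores_gapped_columns(self):
        full = jtt_distance("MKTA", "MKTA")
        gapped = jtt_distance("MKTA-W", "MKTA-C".replace("C", "-") + "")
        assert full.distance == 0.0
        assert gapped.n_sites == 4

    def test_distance_increases_with_differences(self):
        base = "ADKLMNPQRSTVWYACDEFG" * 5
        prev = 0.0
        for k in (2, 5, 10, 20):
            mutant = list(base)
            for pos in range(k):
                mutant[pos] = "W" if base[pos] != "W" else "Y"
            d = jtt_distance(base, "".join(mutant)).distance
            assert d > prev
            prev = d


class TestDistanceMatrix:
    def test_identical_rows_give_zero_matrix(self):
        msa = MultipleAlignment(rows=[(i, "MKTAYIAK") for i in "abc"])
        dm = build_distance_matrix(msa)
        assert np.allclose(dm.matrix, 0.0)

    def test_symmetric_and_consistent_with_pairwise_calls(self, rng):
        rows = [(f"t{i}", random_protein(rng, 50)) for i in range(4)]
        dm = build_distance_matrix(MultipleAlignment(rows=rows))
        assert np.allclose(dm.matrix, dm.matrix.T)
        for i, j in itertools.combinations(range(4), 2):
            expected = jtt_distance(rows[i][1], rows[j][1]).distance
            assert dm.matrix[i, j] == pytest.approx(expected)

    def test_phylip_output(self, tmp_path):
        msa = MultipleAlignment(rows=[(i, "MKTAYIAK") for i in "abc"])
        dm = build_distance_matrix(msa)
        out = tmp_path / "d.tsv"
        dm.write_phylip(out)
        lines = out.read_text().splitlines()
        assert lines[0] == "3" and lines[1].startswith("a\t")


def _random_additive_matrix(n, rng):
    """Distance matrix generated from a random binary tree with known topology."""
    tree = _random_binary_tree(n, rng)
    ids = sorted(l.taxon.label for l in tree.leaf_node_iter())
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return DistanceMatrix(ids=ids, matrix=mat), tree


def _random_binary_tree(n, rng):
    from pks3.simulate import random_tree

    tree = random_tree([f"t{i}" for i in range(n)], height=1.0, rng=rng)
    # randomise branch lengths away from ultrametricity
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.1, 1.0))
    return tree


def _all_unrooted_topologies(ids):
    """Every unrooted binary topology over ids, by sequential leaf insertion."""
    base = dendropy.Tree.get(
        data=f"({ids[0]},{ids[1]},{ids[2]});", schema="newick", preserve_underscores=True
    )
    trees = [base]
    for label in ids[3:]:
        nxt = []
        for tree in trees:
            edges = [
                e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None
            ]
            for k in range(len(edges)):
                clone = tree.clone(depth=1)
                cedges = [
                    e for e in clone.preorder_edge_iter() if e.head_node.parent_node is not None
                ]
                edge = cedges[k]
                head, tail = edge.head_node, edge.tail_node
                mid = dendropy.Node()
                tail.remove_child(head)
                tail.add_child(mid)
                mid.add_child(head)
                leaf = dendropy.Node()
                leaf.taxon = clone.taxon_namespace.require_taxon(label=label)
                mid.add_child(leaf)
                nxt.append(clone)
        trees = nxt
    for t in trees:
        t.is_rooted = False
    return trees


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(
            ids=list("abc"), matrix=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        )
        tree = nj_tree(dm)
        lengths = {
            l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_additive_matrix_reproduced_exactly(self, n, rng):
        dm, source = _random_additive_matrix(n, rng)
        tree = nj_tree(dm)
        pdm = tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in tree.taxon_namespace}
        for i, j in itertools.combinations(range(n), 2):
            path = pdm.distance(taxa[dm.ids[i]], taxa[dm.ids[j]])
            assert path == pytest.approx(dm.matrix[i, j], abs=1e-9)
        assert bipartitions(tree) == bipartitions(source)

    @pytest.mark.parametrize("n", [5, 6])
    def test_topology_matches_exhaustive_least_squares_oracle(self, n, rng):
        dm, _ = _random_additive_matrix(n, rng)
        best_fit, best_tree = np.inf, None
        for cand in _all_unrooted_topologies(dm.ids):
            fit = least_squares_fit(cand, dm)
            if fit < best_fit:
                best_fit, best_tree = fit, cand
        nj = nj_tree(dm)
        assert bipartitions(nj) == bipartitions(best_tree)
        assert least_squares_fit(nj, dm) == pytest.approx(0.0, abs=1e-12)

    def test_equidistant_matrix_deterministic(self):
        mat = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(ids=list("abcd"), matrix=mat)
        assert to_newick(nj_tree(dm)) == to_newick(nj_tree(dm))

    def test_invalid_matrices_rejected(self):
        bad = np.array([[0, 1, 2], [1, 0, 3], [2, 3.5, 0]])
        with pytest.raises((TreeError, ValueError)):
            nj_tree(DistanceMatrix(ids=list("abc"), matrix=bad))
        nan = np.zeros((3, 3))
        nan[0, 1] = nan[1, 0] = np.nan
        dm = DistanceMatrix.__new__(DistanceMatrix)
        dm.ids = list("abc")
        dm.matrix = nan
        with pytest.raises(TreeError):
            nj_tree(dm)

    def test_topology_agrees_with_scikit_bio_nj(self, rng):
        """Independent cross-check against scikit-bio's NJ implementation."""
        import dendropy as _dp
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sknj

        for _ in range(3):
            n = int(rng.integers(5, 8))
            pts = rng.random((n, 4))
            mat = np.round(np.linalg.norm(pts[:, None] - pts[None, :], axis=2), 3)
            ids = [f"t{i}" for i in range(n)]
            mine = nj_tree(DistanceMatrix(ids=ids, matrix=mat))
            theirs = _dp.Tree.get(
                data=str(sknj(SkDM(mat, ids))),
                schema="newick",
                preserve_underscores=True,
            )
            theirs.is_rooted = False
            assert bipartitions(mine) == bipartitions(theirs)

    def test_bionj_also_reproduces_additive_matrices(self, rng):
        dm, source = _random_additive_matrix(5, rng)
        tree = nj_tree(dm, bionj=True)
        assert bipartitions(tree) == bipartitions(source)


class TestBootstrap:
    def _signal_msa(self):
        return MultipleAlignment(
            rows=[
                ("a", "AAAAAAAAAACCCCCCCCCC"),
                ("b", "AAAAAAAAAACCCCCCCCCC"),
                ("c", "AAAAAAAAAADDDDDDDDDD"),
                ("d", "WWWWWWWWWWDDDDDDDDDD"),
            ]
        )

    def test_clade_supported_by_every_column_scores_100(self):
        tree = bootstrap_support(self._signal_msa(), n_reps=25, seed=3)
        assert set(tree.bipartition_support.values()) == {100.0}

    def test_same_seed_reproducible_byte_exact(self):
        t1 = bootstrap_support(self._signal_msa(), n_reps=25, seed=9)
        t2 = bootstrap_support(self._signal_msa(), n_reps=25, seed=9)
        assert to_newick(t1) == to_newick(t2)

    def test_supports_bounded_on_random_alignments(self, rng):
        rows = [(f"t{i}", random_protein(rng, 40)) for i in range(5)]
        tree = bootstrap_support(MultipleAlignment(rows=rows), n_reps=10, seed=1)
        assert all(0.0 <= v <= 100.0 for v in tree.bipartition_support.values())

    def test_zero_replicates_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self._signal_msa(), n_reps=0, seed=1)


class TestRooting:
    def test_three_taxon_star_rooted_on_outgroup(self):
        dm = DistanceMatrix(
            ids=list("abc"), matrix=np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float)
        )
        tree = root_with_outgroup(nj_tree(dm), "a")
        children = tree.seed_node.child_nodes()
        sides = [frozenset(l.taxon.label for l in c.leaf_iter()) for c in children]
        assert frozenset("a") in sides and frozenset("bc") in sides

    def test_rerooting_preserves_leaf_path_lengths(self, rng):
        dm, _ = _random_additive_matrix(5, rng)
        unrooted = nj_tree(dm)
        before = _paths(unrooted, dm.ids)
        rooted = root_with_outgroup(unrooted, dm.ids[0])
        after = _paths(rooted, dm.ids)
        assert np.allclose(before, after, atol=1e-9)

    def test_unknown_outgroup_rejected(self):
        dm = DistanceMatrix(ids=list("abc"), matrix=np.ones((3, 3)) - np.eye(3))
        with pytest.raises(TreeError):
            root_with_outgroup(nj_tree(dm), "zzz")


def _paths(tree, ids):
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    return [
        pdm.distance(taxa[i], taxa[j]) for i, j in itertools.combinations(ids, 2)
    ]


class TestNewickRoundTrip:
    def test_topology_lengths_and_supports_preserved(self):
        msa = MultipleAlignment(
            rows=[
                ("a_1", "AAAAAAAAAACCCCCCCCCC"),
                ("b.2", "AAAAAAAAAACCCCCCCCCC"),
                ("c|3", "AAAAAAAAAADDDDDDDDDD"),
                ("d", "WWWWWWWWWWDDDDDDDDDD"),
            ]
        )
        tree = bootstrap_support(msa, n_reps=20, seed=2)
        tree = root_with_outgroup(tree, "d")
        text = to_newick(tree)
        back = read_newick(text)
        assert {l.taxon.label for l in back.leaf_node_iter()} == {"a_1", "b.2", "c|3", "d"}
        assert bipartitions(back) == bipartitions(tree)
        orig = sorted(
            e.length for e in tree.preorder_edge_iter() if e.length is not None
        )
        parsed = sorted(
            e.length for e in back.preorder_edge_iter() if e.length is not None
        )
        assert np.allclose(orig, parsed, atol=1e-9)
        supports = [
            n.support for n in back.preorder_node_iter() if n.support is not None
        ]
        assert supports and all(0 <= s <= 100 for s in supports)


class TestNniRefinement:
    def test_optimal_tree_returned_unchanged(self, rng):
        dm, source = _random_additive_matrix(4, rng)
        tree = nj_tree(dm)
        refined = nni_refine(tree, dm)
        assert bipartitions(refined) == bipartitions(tree)

    def test_swapped_topology_restored(self, rng):
        dm, source = _random_additive_matrix(4, rng)
        wrong = None
        for cand in _all_unrooted_topologies(dm.ids):
            if bipartitions(cand) != bipartitions(source):
                wrong = cand
                break
        refined = nni_refine(wrong, dm)
        assert bipartitions(refined) == bipartitions(source)

    def test_criterion_never_worsens(self, rng):
        rows = [(f"t{i}", random_protein(rng, 40)) for i in range(6)]
        dm = build_distance_matrix(MultipleAlignment(rows=rows))
        tree = nj_tree(dm)
        before = least_squares_fit(tree.clone(depth=1), dm)
        refined = nni_refine(tree, dm)
        assert least_squares_fit(refined, dm) <= before + 1e-9
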
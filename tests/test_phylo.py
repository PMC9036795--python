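"""Newick round-trips, Fitch-Margoliash fitting, topology search."""

import itertools

import numpy as np
import pandas as pd
import pytest

from komaflux.phylo import (PhyloTree, build_tree, enumerate_topologies,
                            evaluate_tree)
from komaflux.synth import gen_tree_distances, komagataella_preset


def quartet_matrix():
    """Additive distances for topology ((A,B),(C,D)) with internal edge 2."""
    # A-x:1, B-x:2, x-y:2, y-C:3, y-D:4
    d = {("A", "B"): 3, ("A", "C"): 6, ("A", "D"): 7,
         ("B", "C"): 7, ("B", "D"): 8, ("C", "D"): 7}
    labels = ["A", "B", "C", "D"]
    D = pd.DataFrame(0.0, index=labels, columns=labels)
    for (i, j), v in d.items():
        D.loc[i, j] = D.loc[j, i] = float(v)
    return D


class TestNewick:
    def test_three_taxon_star(self):
        t = PhyloTree.from_newick("(A:1,B:1,C:1);")
        assert t.leaves == ["A", "B", "C"]

    def test_round_trip_preserves_path_lengths(self):
        bundle = gen_tree_distances(seed=4, n_taxa=8, noise_sd=0.0)
        t = bundle.tree
        back = PhyloTree.from_newick(t.to_newick())
        assert back.leaves == t.leaves
        P1 = t.path_lengths()
        P2 = back.path_lengths()
        np.testing.assert_allclose(P1.to_numpy(), P2.loc[P1.index, P1.columns]
                                   .to_numpy(), atol=1e-9)

    def test_zero_length_branch_survives_round_trip(self):
        t = PhyloTree.from_newick("((A:0,B:1):1,C:1,D:2);")
        back = PhyloTree.from_newick(t.to_newick())
        assert back.path_lengths().loc["A", "B"] == pytest.approx(1.0)

    def test_unbalanced_parentheses_error(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("((A:1,B:1;")


class TestEvaluateTree:
    def test_additive_matrix_on_true_topology_fits_exactly(self):
        D = quartet_matrix()
        tree = PhyloTree.from_newick("((A:1,B:2):2,C:3,D:4);")
        fitted = evaluate_tree(tree, D)
        assert fitted.criterion == pytest.approx(0.0, abs=1e-20)
        P = fitted.path_lengths()
        np.testing.assert_allclose(P.loc[D.index, D.columns].to_numpy(),
                                   D.to_numpy(), atol=1e-9)

    def test_wrong_topology_has_positive_criterion(self):
        D = quartet_matrix()
        wrong = PhyloTree.from_newick("((A:1,C:1):1,B:1,D:1);")
        fitted = evaluate_tree(wrong, D)
        assert fitted.criterion > 1e-4

    def test_three_taxon_closed_form(self):
        # three-point formulas: a=(dAB+dAC-dBC)/2 etc.
        labels = ["A", "B", "C"]
        D = pd.DataFrame([[0, 5, 7], [5, 0, 8], [7, 8, 0]], dtype=float,
                         index=labels, columns=labels)
        fitted = evaluate_tree(PhyloTree.star(labels), D)
        assert fitted.criterion == pytest.approx(0.0, abs=1e-20)
        g = fitted.g
        center = [n for n in g.nodes if isinstance(n, int)][0]
        assert g.edges["A", center]["length"] == pytest.approx(2.0)
        assert g.edges["B", center]["length"] == pytest.approx(3.0)
        assert g.edges["C", center]["length"] == pytest.approx(5.0)

    def test_optimal_lengths_invariant_to_label_permutation(self, rng):
        bundle = gen_tree_distances(seed=9, n_taxa=6, noise_sd=0.01)
        D = bundle.distances
        perm = list(rng.permutation(D.index))
        t1 = evaluate_tree(bundle.tree, D)
        t2 = evaluate_tree(bundle.tree, D.loc[perm, perm])
        assert t1.criterion == pytest.approx(t2.criterion, rel=1e-9)


class TestBuildTree:
    def test_recovers_additive_six_leaf_topology(self):
        bundle = gen_tree_distances(seed=21, n_taxa=6, noise_sd=0.0)
        built = build_tree(bundle.distances, n_jumbles=3, jumble_seed=23893)
        assert built.criterion == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(
            built.path_lengths().loc[bundle.distances.index,
                                     bundle.distances.columns].to_numpy(),
            bundle.distances.to_numpy(), atol=1e-6)

    def test_matches_exhaustive_enumeration_for_five_taxa(self):
        bundle = gen_tree_distances(seed=33, n_taxa=5, noise_sd=0.02)
        D = bundle.distances
        best_exhaustive = min(
            (evaluate_tree(t, D).criterion for t in
             enumerate_topologies(list(D.index))))
        built = build_tree(D, n_jumbles=5, jumble_seed=23893)
        assert built.criterion == pytest.approx(best_exhaustive, abs=1e-10)

    def test_deterministic_for_fixed_seed(self):
        bundle = gen_tree_distances(seed=2, n_taxa=7, noise_sd=0.01)
        t1 = build_tree(bundle.distances, n_jumbles=3, jumble_seed=23893)
        t2 = build_tree(bundle.distances, n_jumbles=3, jumble_seed=23893)
        assert t1.to_newick() == t2.to_newick()

    def test_fewer_than_three_taxa_errors(self):
        D = pd.DataFrame([[0.0, 1.0], [1.0, 0.0]], index=["A", "B"],
                         columns=["A", "B"])
        with pytest.raises(ValueError):
            build_tree(D)


def clade_leafsets(tree: PhyloTree):
    """All leaf bipartition halves induced by internal edges."""
    import networkx as nx

    leaves = set(tree.leaves)
    out = set()
    for u, v in tree.internal_edges():
        g = tree.g.copy()
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        half = frozenset(x for x in comp if isinstance(x, str))
        out.add(half)
        out.add(frozenset(leaves - half))
    return out


class TestKomagataellaPreset:
    def test_sister_pairs_recovered_from_noisy_distances(self):
        bundle = komagataella_preset(seed=8, noise_sd=0.002)
        built = build_tree(bundle.distances, n_jumbles=10, jumble_seed=23893)
        clades = clade_leafsets(built)
        phaffii_clade = frozenset({"phaffii_a", "phaffii_b", "kurtzmanii"})
        pastoris_clade = frozenset({"pastoris_a", "pastoris_b", "pastoris_c",
                                    "ulmi"})
        assert phaffii_clade in clades
        assert pastoris_clade in clades
        assert phaffii_clade | pastoris_clade in clades  # sister subtrees
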
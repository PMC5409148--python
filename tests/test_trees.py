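"""Tree I/O, neighbor joining, monophyly and ultrametric bookkeeping."""

import numpy as np
import pytest

from otudelim import (
    DistanceMatrix,
    UltrametricTree,
    branching_times,
    is_monophyletic,
    neighbor_joining,
    read_tree,
    tree_from_string,
    write_tree,
)
from otudelim.errors import TreeError, UltrametricError
from otudelim.trees import patristic_distance, tip_labels


def test_read_tree_and_round_trip(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1):1,C:2);")
    tree = read_tree(p)
    assert sorted(tip_labels(tree)) == ["A", "B", "C"]
    q = tmp_path / "t2.nwk"
    write_tree(tree, q)
    again = read_tree(q)
    for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
        assert patristic_distance(again, a, b) == pytest.approx(
            patristic_distance(tree, a, b), abs=1e-10
        )


def test_read_tree_duplicate_tips(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,A:1):1,C:2);")
    with pytest.raises(TreeError, match="duplicate"):
        read_tree(p)


def test_read_tree_malformed(tmp_path):
    p = tmp_path / "t.nwk"
    p.write_text("((A:1,B:1:1,C:2);")
    with pytest.raises(TreeError):
        read_tree(p)


def _dm_from_tree(newick, ids):
    tree = tree_from_string(newick)
    n = len(ids)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = patristic_distance(tree, ids[i], ids[j])
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(ids, vals, "p")


def test_nj_recovers_additive_four_taxon_tree():
    ids = ["A", "B", "C", "D"]
    newick = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.0);"
    dm = _dm_from_tree(newick, ids)
    tree = neighbor_joining(dm)
    for i in range(4):
        for j in range(i + 1, 4):
            assert patristic_distance(tree, ids[i], ids[j]) == pytest.approx(
                dm.values[i, j], abs=1e-10
            )


def test_nj_random_ultrametric_matrices_are_recovered():
    """NJ on additive (here ultrametric) matrices reproduces all path lengths."""
    from otudelim import SimulationConfig, simulate_species_tree

    for seed in range(5):
        cfg = SimulationConfig(
            n_species=int(np.random.default_rng(seed).integers(4, 11)),
            crown_age=10.0,
            min_species_separation=0.0,
            seed=seed,
        )
        tree = simulate_species_tree(cfg)
        ids = sorted(tip_labels(tree))
        n = len(ids)
        vals = np.zeros((n, n))
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        for i in range(n):
            for j in range(i + 1, n):
                d = pdm.distance(tax[ids[i]], tax[ids[j]])
                vals[i, j] = vals[j, i] = d
        dm = DistanceMatrix(ids, vals, "p")
        nj_tree = neighbor_joining(dm)
        for i in range(n):
            for j in range(i + 1, n):
                assert patristic_distance(nj_tree, ids[i], ids[j]) == pytest.approx(
                    vals[i, j], abs=1e-8
                )


def test_nj_outgroup_rooting():
    ids = ["A", "B", "C", "O"]
    newick = "(((A:0.1,B:0.1):0.1,C:0.2):0.3,O:0.5);"
    dm = _dm_from_tree(newick, ids)
    tree = neighbor_joining(dm, outgroup="O")
    kids = tree.seed_node.child_nodes()
    sides = [sorted(l.taxon.label for l in k.leaf_nodes()) for k in kids]
    assert ["O"] in sides


def test_nj_three_taxa():
    dm = DistanceMatrix(
        ["A", "B", "C"],
        np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]], dtype=float),
        "p",
    )
    tree = neighbor_joining(dm)
    assert sorted(tip_labels(tree)) == ["A", "B", "C"]


def test_nj_rejects_nonfinite():
    vals = np.zeros((3, 3))
    vals[0, 1] = vals[1, 0] = np.nan
    with pytest.raises(TreeError, match="non-finite"):
        neighbor_joining(DistanceMatrix(["a", "b", "c"], vals, "k2p"))


def test_monophyly_cherries_and_counterexample():
    tree = tree_from_string("((A:1,B:1):1,(C:1,D:1):1);")
    assert is_monophyletic(tree, {"A", "B"}) == (True, 2)
    ok, size = is_monophyletic(tree, {"A", "C"})
    assert not ok and size == 4
    assert is_monophyletic(tree, {"A"}) == (True, 1)
    assert is_monophyletic(tree, {"A", "B", "C", "D"}) == (True, 4)
    with pytest.raises(TreeError, match="unknown"):
        is_monophyletic(tree, {"E"})


def test_monophyly_agrees_with_exhaustive_node_scan():
    from otudelim import SimulationConfig, simulate_species_tree

    rng = np.random.default_rng(17)
    for seed in range(4):
        tree = simulate_species_tree(
            SimulationConfig(n_species=8, crown_age=5.0,
                             min_species_separation=0.0, seed=seed)
        )
        tips = tip_labels(tree)
        clades = [
            frozenset(l.taxon.label for l in node.leaf_nodes())
            for node in tree.preorder_node_iter()
        ]
        for _ in range(20):
            k = int(rng.integers(1, len(tips) + 1))
            subset = frozenset(rng.choice(tips, size=k, replace=False))
            expected = subset in clades
            got, size = is_monophyletic(tree, subset)
            assert got == expected
            assert size >= len(subset)


def test_branching_times_read_off():
    ult = UltrametricTree(tree_from_string("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"))
    assert np.allclose(ult.branching_times(), [1.0, 1.5, 2.0])
    assert ult.root_height == pytest.approx(2.0)


def test_branching_times_counts_on_simulated_trees():
    from otudelim import SimulationConfig, simulate_species_tree

    for n in (5, 9, 17):
        tree = simulate_species_tree(
            SimulationConfig(n_species=n, crown_age=7.0,
                             min_species_separation=0.0, seed=n)
        )
        ult = UltrametricTree(tree)
        assert len(ult.branching_times()) == n - 1
        assert (ult.branching_times() > 0).all()


def test_non_ultrametric_rejected():
    with pytest.raises(UltrametricError, match="deviates"):
        UltrametricTree(tree_from_string("((A:1,B:2):1,C:3);"))


def test_tied_branching_times_perturbed():
    with pytest.warns(UserWarning, match="perturbed"):
        ult = UltrametricTree(tree_from_string("((A:1,B:1):2,(C:1,D:1):2);"))
    times = ult.branching_times()
    assert len(set(times.tolist())) == 3
    assert max(abs(times - np.array(sorted([1.0, 1.0, 3.0])))) <= 1e-9


def test_branching_times_invariant_to_label_permutation():
    a = UltrametricTree(tree_from_string("((A:1,B:1):1,(C:1.5,D:1.5):0.5);"))
    b = UltrametricTree(tree_from_string("((D:1,C:1):1,(B:1.5,A:1.5):0.5);"))
    assert np.allclose(a.branching_times(), b.branching_times())
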
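"""Synthetic-data generator: species trees, coalescent gene trees,
sequence evolution, regions and partition scoring."""

import numpy as np
import pytest

from otudelim import (
    Partition,
    SimulationConfig,
    UltrametricTree,
    assign_regions,
    distance_matrix,
    evolve_sequences,
    score_partition,
    simulate_dataset,
    simulate_gene_tree,
    simulate_species_tree,
    tree_from_string,
)
from otudelim.trees import tip_labels


def test_species_tree_two_species_single_divergence():
    cfg = SimulationConfig(n_species=2, crown_age=13.0, seed=4)
    tree = simulate_species_tree(cfg)
    ult = UltrametricTree(tree)
    assert len(ult.branching_times()) == 1
    assert ult.branching_times()[0] == pytest.approx(13.0)


def test_species_tree_root_height_and_topology():
    for seed in range(5):
        cfg = SimulationConfig(n_species=10, crown_age=16.6,
                               min_species_separation=1.0, seed=seed)
        ult = UltrametricTree(simulate_species_tree(cfg))
        assert ult.n_tips == 10
        assert len(ult.branching_times()) == 9
        assert ult.root_height == pytest.approx(16.6)
        assert ult.branching_times().min() >= 1.0  # separation conditioning


def test_gene_tree_congruent_at_vanishing_depth():
    sp = simulate_species_tree(SimulationConfig(n_species=6, crown_age=12.8, seed=1))
    gt = simulate_gene_tree(sp, 1, 1e-9, seed=2)
    ult_sp = UltrametricTree(sp)
    sp_times = np.sort(ult_sp.branching_times())
    gt_times = np.sort(gt.branching_times())
    assert np.allclose(sp_times, gt_times, atol=1e-4)


def test_gene_tree_mean_pairwise_time_matches_depth():
    """Monte-Carlo calibration of the coalescent time scale (2 samples,
    1 species: exponential with the configured mean)."""
    sp = tree_from_string("(A:50.0,B:50.0);")
    depth = 0.2
    times = [
        simulate_gene_tree(sp, {"A": 2, "B": 0}, depth, seed=s).root_height
        for s in range(1, 1001)
    ]
    assert np.mean(times) == pytest.approx(depth, rel=0.05)


def test_gene_tree_censoring_keeps_species_monophyletic():
    sp = simulate_species_tree(
        SimulationConfig(n_species=5, crown_age=14.0, seed=9)
    )
    gt = simulate_gene_tree(sp, 4, 0.01, seed=9)  # depth << branch lengths
    from otudelim import is_monophyletic

    for s in tip_labels(sp):
        tips = {f"{s}_{i:02d}" for i in range(1, 5)}
        assert is_monophyletic(gt.tree, tips)[0]


def test_sequences_zero_rate_identical():
    sp = tree_from_string("(A:5.0,B:5.0);")
    gt = simulate_gene_tree(sp, 2, 0.1, seed=5)
    aln = evolve_sequences(gt, seq_length=100, clock_rate=0.0, seed=1)
    assert len(set(aln.sequences)) == 1


def test_sequences_deterministic_from_seed():
    sp = tree_from_string("(A:5.0,B:5.0);")
    gt = simulate_gene_tree(sp, 3, 0.1, seed=5)
    a1 = evolve_sequences(gt, seed=42)
    a2 = evolve_sequences(gt, seed=42)
    a3 = evolve_sequences(gt, seed=43)
    assert a1.sequences == a2.sequences
    assert a1.sequences != a3.sequences


def test_estimated_k2p_tracks_generating_distance():
    """Estimator-generator consistency: two tips at divergence t have
    expected K2P distance ~ 2 * t * clock_rate in the small-distance regime."""
    t_div, rate = 1.0, 0.01
    sp = tree_from_string(f"(A:{t_div},B:{t_div});")
    gt = simulate_gene_tree(sp, {"A": 1, "B": 1}, 1e-9, seed=1)
    ds = []
    for s in range(1, 501):
        aln = evolve_sequences(gt, seq_length=618, clock_rate=rate, seed=s)
        dm = distance_matrix(aln, "k2p")
        ds.append(dm.values[0, 1])
    assert np.mean(ds) == pytest.approx(2 * t_div * rate, rel=0.1)


def test_assign_regions_scenarios():
    truth = Partition(
        {f"{u}_{i}": u for u in ("A", "B", "C", "D") for i in range(4)},
        method="truth",
    )
    meta = assign_regions(truth, "allopatric_split", seed=1,
                          sister_pairs=[("A", "B"), ("C", "D")])
    by_unit = {}
    for m in meta:
        by_unit.setdefault(m.species_label, set()).add(m.region)
    assert by_unit["A"].isdisjoint(by_unit["B"])
    assert by_unit["C"].isdisjoint(by_unit["D"])

    meta_s = assign_regions(truth, "sympatric", seed=1)
    by_unit = {}
    for m in meta_s:
        by_unit.setdefault(m.species_label, set()).add(m.region)
    units = list(by_unit)
    for i, a in enumerate(units):
        for b in units[i + 1:]:
            assert by_unit[a] & by_unit[b]

    assert assign_regions(truth, "random", seed=7) == assign_regions(
        truth, "random", seed=7
    )


def test_score_partition_identity_and_degenerate():
    truth = Partition.from_sets([{"a", "b"}, {"c", "d"}], method="truth")
    same = Partition.from_sets([{"a", "b"}, {"c", "d"}])
    rep = score_partition(same, truth)
    assert rep.adjusted_rand_index == pytest.approx(1.0)
    assert rep.n_exact_species_matches == 2
    assert rep.n_lumped == rep.n_split == 0

    singletons = Partition.from_sets([{s} for s in "abcd"])
    one_block = Partition.from_sets([{"a", "b", "c", "d"}], method="truth")
    assert score_partition(singletons, one_block).adjusted_rand_index == pytest.approx(0.0)


def test_score_partition_lump_and_split_bookkeeping():
    truth = Partition.from_sets([{"a", "b"}, {"c", "d"}, {"e", "f"}], method="truth")
    inferred = Partition.from_sets([{"a", "b", "c", "d"}, {"e"}, {"f"}])
    rep = score_partition(inferred, truth)
    assert rep.n_exact_species_matches == 0
    assert rep.n_lumped == 2  # both lumped species wholly inside one OTU
    assert rep.n_split == 1  # {e,f} spread over two OTUs


def _ari_bruteforce(p1, p2):
    """Pair-counting adjusted Rand index, enumerated over all sample pairs."""
    from math import comb

    samples = sorted(p1.samples)
    n = len(samples)
    both = one = two = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = p1.otu_of(samples[i]) == p1.otu_of(samples[j])
            b = p2.otu_of(samples[i]) == p2.otu_of(samples[j])
            both += a and b
            one += a
            two += b
    total = comb(n, 2)
    expected = one * two / total
    max_index = (one + two) / 2
    if max_index == expected:
        return 1.0
    return (both - expected) / (max_index - expected)


def test_ari_matches_pair_counting_bruteforce():
    rng = np.random.default_rng(13)
    samples = [f"s{i}" for i in range(12)]
    for _ in range(30):
        p1 = Partition({s: f"g{rng.integers(4)}" for s in samples}, method="truth")
        p2 = Partition({s: f"h{rng.integers(4)}" for s in samples})
        rep = score_partition(p2, p1)
        assert rep.adjusted_rand_index == pytest.approx(
            _ari_bruteforce(p1, p2), abs=1e-12
        )


def test_dataset_consistency_and_manifest(tmp_path):
    cfg = SimulationConfig(n_species=4, samples_per_species=3, crown_age=14.0,
                           seed=21)
    ds = simulate_dataset(cfg)
    ids = set(ds.alignment.sample_ids)
    assert ids == set(ds.gene_tree.tip_labels())
    assert ids == {m.sample_id for m in ds.metadata}
    assert ids == ds.truth.samples
    assert ds.manifest["seed"] == 21
    ds.write(tmp_path / "out")
    assert (tmp_path / "out" / "manifest.json").exists()
    assert (tmp_path / "out" / "alignment.fasta").exists()

    again = simulate_dataset(cfg)
    assert again.alignment.sequences == ds.alignment.sequences  # reproducible


def test_barcode_gap_exists_in_separated_regime():
    """Max intra-species < min inter-species K2P for nearly all species."""
    from otudelim import partition_divergences

    ok = total = 0
    for seed in range(5):
        ds = simulate_dataset(SimulationConfig(
            n_species=10, samples_per_species=5,
            min_species_separation=1.0, seed=900 + seed))
        dm = distance_matrix(ds.alignment, "k2p")
        max_intra, inter = partition_divergences(dm, ds.truth)
        for otu, mi in max_intra.items():
            lo = min(v[0] for k, v in inter.items() if otu in k)
            total += 1
            ok += mi < lo
    assert ok / total >= 0.95


def test_cryptic_pairs_structure():
    cfg = SimulationConfig(n_species=3, samples_per_species=3, crown_age=14.0,
                           cryptic_pairs=True, cryptic_split_depth=1.0,
                           min_species_separation=3.0, seed=3)
    ds = simulate_dataset(cfg)
    assert ds.truth.n_groups == 3  # truth at species rank
    assert len(ds.alignment.sample_ids) == 18  # 3 species x 2 pops x 3
    species = {m.species_label for m in ds.metadata}
    assert species == {"S01", "S02", "S03"}
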
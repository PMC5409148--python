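"""Coalescent benchmark datasets with known species truth.

The generator emulates a multi-species barcode survey: a Yule species tree
rescaled to a crown age in the calibration window of Indo-West Pacific
sciaenids (12.8-16.6 My), within-species gene genealogies from a censored
multispecies coalescent (msprime; lineages coalesce within their species
branch and continue in ancestral species, so incomplete lineage sorting can
be dialed in via the coalescent depth), clock-like two-parameter (K80)
sequence evolution at barcode length, and per-sample region labels drawn
from the four-region frame used for sympatry decisions.

A ``cryptic_pairs`` mode grafts a shallow population split onto every
species tip, producing recognized species that contain two geographically
structured populations -- the situation the geography step of the
reconciliation procedure exists to resolve.

Every stochastic run is reproducible from (config, seed) alone.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import msprime
import numpy as np
from scipy.linalg import expm
from sklearn.metrics import adjusted_rand_score

from .alignment_io import (
    REGIONS,
    AlignedSequenceSet,
    SampleMetadata,
    write_alignment,
    write_metadata,
)
from .errors import InputError, PartitionError
from .partition import Partition
from .trees import UltrametricTree, tree_from_string, write_tree

_NUC = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic barcode dataset.

    Defaults mirror the scale of a regional barcode survey: about fifty
    species with six samples each (~300 sequences), crown age drawn from
    the 12.8-16.6 My calibration window, mean within-species pairwise
    coalescent time 0.1 My, 618 bp evolving at 0.01 substitutions/site/My
    (about 2%/My pairwise) with transition bias 4.  Setting
    ``min_species_separation`` > 0 conditions the Yule tree on a clean
    two-regime structure (used by the benchmark experiments); the default
    leaves recent splits in, as real faunas have them.
    """

    n_species: int = 50
    samples_per_species: int | tuple[int, int] = 6
    speciation_rate: float = 1.0
    crown_age: float | None = None  # None: draw from U(12.8, 16.6) My
    coalescent_depth: float = 0.1  # expected within-species pairwise time, My
    min_species_separation: float = 0.0  # youngest split at least this, My
    seq_length: int = 618
    kappa: float = 4.0
    clock_rate: float = 0.01  # substitutions/site/My
    region_scenario: str = "random"  # allopatric_split | sympatric | random
    cryptic_pairs: bool = False
    cryptic_split_depth: float = 1.0  # My, population split within species
    unequal_base_freqs: bool = False  # HKY misspecification mode
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise InputError("n_species must be >= 2")
        for name in ("speciation_rate", "coalescent_depth", "clock_rate", "kappa"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.region_scenario not in ("allopatric_split", "sympatric", "random"):
            raise InputError(f"unknown region scenario {self.region_scenario!r}")


@dataclass
class SyntheticDataset:
    truth: Partition
    species_tree: dendropy.Tree
    gene_tree: UltrametricTree
    alignment: AlignedSequenceSet
    metadata: list[SampleMetadata]
    manifest: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_alignment(self.alignment, outdir / "alignment.fasta")
        write_tree(self.species_tree, outdir / "species_tree.nwk")
        write_tree(self.gene_tree.tree, outdir / "gene_tree.nwk")
        write_metadata(self.metadata, outdir / "metadata.tsv")
        self.truth.write_tsv(outdir / "truth.tsv")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class ScoreReport:
    adjusted_rand_index: float
    n_exact_species_matches: int
    n_lumped: int
    n_split: int


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

class _SimNode:
    __slots__ = ("children", "depth", "label")

    def __init__(self, depth: float, label: str | None = None):
        self.children: list[_SimNode] = []
        self.depth = depth
        self.label = label

    def newick(self, parent_depth: float) -> str:
        bl = self.depth - parent_depth
        if not self.children:
            return f"{self.label}:{bl:.10f}"
        inner = ",".join(c.newick(self.depth) for c in self.children)
        return f"({inner}):{bl:.10f}"


def _yule_forward(n: int, rate: float, rng: np.random.Generator) -> _SimNode:
    root = _SimNode(0.0)
    active = [_SimNode(0.0), _SimNode(0.0)]
    root.children = list(active)
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (rate * len(active)))
        idx = int(rng.integers(len(active)))
        node = active[idx]
        node.depth = t
        kids = [_SimNode(t), _SimNode(t)]
        node.children = kids
        active[idx] = kids[0]
        active.append(kids[1])
    t_end = t + rng.exponential(1.0 / (rate * n))
    for leaf in active:
        leaf.depth = t_end
    return root


def _rescale(root: _SimNode, crown_age: float) -> None:
    def depth_max(n: _SimNode) -> float:
        return n.depth if not n.children else max(depth_max(c) for c in n.children)

    f = crown_age / depth_max(root)

    def scale(n: _SimNode) -> None:
        n.depth *= f
        for c in n.children:
            scale(c)

    scale(root)


def _youngest_split(root: _SimNode, crown_age: float) -> float:
    """Height (time before present) of the most recent speciation event."""
    heights: list[float] = []

    def collect(n: _SimNode) -> None:
        if n.children:
            heights.append(crown_age - n.depth)
            for c in n.children:
                collect(c)

    collect(root)
    return min(heights)


def simulate_species_tree(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> dendropy.Tree:
    """Yule species tree conditioned on tip count, rescaled to the crown age.

    When ``min_species_separation`` > 0 the tree is resimulated until the
    youngest split clears it, conditioning the regime on interspecific
    divergences that dominate the coalescent depth.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    crown = cfg.crown_age if cfg.crown_age is not None else rng.uniform(12.8, 16.6)
    for attempt in range(10_000):
        root = _yule_forward(cfg.n_species, cfg.speciation_rate, rng)
        _rescale(root, crown)
        if (
            cfg.n_species == 2
            or _youngest_split(root, crown) >= cfg.min_species_separation
        ):
            break
    else:
        raise InputError(
            "could not satisfy min_species_separation; lower it or the species count"
        )
    labels = [f"S{i + 1:02d}" for i in range(cfg.n_species)]
    i = 0

    def assign(n: _SimNode) -> None:
        nonlocal i
        if not n.children:
            n.label = labels[i]
            i += 1
        for c in n.children:
            assign(c)

    assign(root)
    if cfg.cryptic_pairs:
        _graft_population_pairs(root, crown, cfg.cryptic_split_depth)
    newick = "(" + ",".join(c.newick(0.0) for c in root.children) + ");"
    return tree_from_string(newick)


def _graft_population_pairs(root: _SimNode, crown: float, split_depth: float) -> None:
    """Replace each species tip with a cherry of two populations."""

    def walk(n: _SimNode) -> None:
        if not n.children:
            label = n.label
            n.label = None
            n.depth = crown - split_depth
            a = _SimNode(crown, f"{label}a")
            b = _SimNode(crown, f"{label}b")
            n.children = [a, b]
        else:
            for c in n.children:
                walk(c)

    walk(root)


# ---------------------------------------------------------------------------
# Gene tree (censored multispecies coalescent)
# ---------------------------------------------------------------------------

def simulate_gene_tree(
    species_tree: dendropy.Tree,
    samples_per_species: int | Mapping[str, int],
    coalescent_depth: float,
    seed: int = 1,
) -> UltrametricTree:
    """Kingman coalescent within species branches, continuing in ancestors.

    ``coalescent_depth`` is the expected pairwise within-species coalescent
    time, in the species tree's time units.
    """
    tips = [lf.taxon.label for lf in species_tree.leaf_node_iter()]
    if isinstance(samples_per_species, int):
        per = {t: samples_per_species for t in tips}
    else:
        per = dict(samples_per_species)
    newick = species_tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    ).strip()
    demography = msprime.Demography.from_species_tree(
        newick, initial_size=max(coalescent_depth, 1e-9)
    )
    sample_sets = [
        msprime.SampleSet(per[t], population=t, ploidy=1) for t in tips if per[t] > 0
    ]
    ts = msprime.sim_ancestry(
        samples=sample_sets,
        demography=demography,
        ploidy=1,
        random_seed=max(1, seed % (2**31 - 1)),
    )
    labels: dict[int, str] = {}
    node_id = 0
    for t in tips:
        for i in range(per.get(t, 0)):
            labels[node_id] = f"{t}_{i + 1:02d}"
            node_id += 1
    newick_gene = ts.first().as_newick(node_labels=labels)
    return UltrametricTree(tree_from_string(newick_gene))


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

def _k80_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P_transition, P_each_transversion) after expected distance d."""
    beta_t = d / (kappa + 2.0)
    e1 = np.exp(-4.0 * beta_t)
    e2 = np.exp(-2.0 * beta_t * (kappa + 1.0))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1
    return float(p_ts), float(p_tv)


def _hky_matrix(d: float, kappa: float, freqs: np.ndarray) -> np.ndarray:
    """HKY transition-probability matrix scaled to expected distance d."""
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            ts = (i, j) in ((0, 2), (2, 0), (1, 3), (3, 1))
            Q[i, j] = (kappa if ts else 1.0) * freqs[j]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -float(np.dot(freqs, np.diagonal(Q)))
    return expm(Q * (d / mu))


def evolve_sequences(
    gene_tree: UltrametricTree | dendropy.Tree,
    seq_length: int = 618,
    kappa: float = 4.0,
    clock_rate: float = 0.01,
    seed: int = 1,
    base_freqs: Sequence[float] | None = None,
) -> AlignedSequenceSet:
    """Simulate a gap-free alignment along the gene tree.

    The default generator is the two-parameter (K80) process the distance
    estimator assumes; supplying ``base_freqs`` switches to HKY, a deliberate
    misspecification mode.
    """
    tree = gene_tree.tree if isinstance(gene_tree, UltrametricTree) else gene_tree
    rng = np.random.default_rng(seed)
    freqs = None if base_freqs is None else np.asarray(base_freqs, dtype=float)
    if freqs is not None and (freqs.shape != (4,) or abs(freqs.sum() - 1) > 1e-9):
        raise InputError("base_freqs must be 4 frequencies summing to 1")

    root_p = freqs if freqs is not None else np.full(4, 0.25)
    seqs: dict[int, np.ndarray] = {}
    root = tree.seed_node
    seqs[id(root)] = rng.choice(4, size=seq_length, p=root_p)

    ts_partner = np.array([2, 3, 0, 1])
    tv1 = np.array([1, 2, 3, 0])
    tv2 = np.array([3, 0, 1, 2])

    out_ids: list[str] = []
    out_seqs: list[str] = []
    for node in tree.preorder_node_iter():
        if node is root:
            parent_seq = seqs[id(root)]
        else:
            bl = node.edge.length or 0.0
            d = clock_rate * bl
            parent_seq = seqs[id(node.parent_node)]
            if d <= 0:
                child = parent_seq.copy()
            elif freqs is None:
                p_ts, p_tv = _k80_probs(d, kappa)
                u = rng.random(seq_length)
                child = parent_seq.copy()
                child = np.where(u < p_ts, ts_partner[parent_seq], child)
                child = np.where(
                    (u >= p_ts) & (u < p_ts + p_tv), tv1[parent_seq], child
                )
                child = np.where(
                    (u >= p_ts + p_tv) & (u < p_ts + 2 * p_tv),
                    tv2[parent_seq],
                    child,
                )
            else:
                P = _hky_matrix(d, kappa, freqs)
                child = np.empty(seq_length, dtype=parent_seq.dtype)
                for s in range(4):
                    mask = parent_seq == s
                    child[mask] = rng.choice(4, size=int(mask.sum()), p=P[s])
            seqs[id(node)] = child
            parent_seq = child
        if node.is_leaf():
            out_ids.append(node.taxon.label)
            out_seqs.append("".join(_NUC[s] for s in parent_seq))
    return AlignedSequenceSet("COI_sim", out_ids, out_seqs)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def assign_regions(
    truth: Partition,
    scenario: str,
    seed: int = 1,
    sister_pairs: Sequence[tuple[str, str]] | None = None,
    species_of_unit: Mapping[str, str] | None = None,
) -> list[SampleMetadata]:
    """Per-sample region labels under a geographic scenario.

    ``allopatric_split`` gives sister units disjoint single regions;
    ``sympatric`` gives every unit an overlapping set; ``random`` draws
    uniformly.  ``truth`` groups are the units; ``species_of_unit`` maps a
    unit to its recognized species label (defaults to the unit itself).
    """
    rng = np.random.default_rng(seed)
    groups = truth.groups()
    units = sorted(groups)
    species_of_unit = dict(species_of_unit or {u: u for u in units})
    region_sets: dict[str, list[str]] = {}

    if scenario == "sympatric":
        # one shared region for every sample: overlap then holds for any
        # subsample of any unit, not just for whole units
        for u in units:
            region_sets[u] = ["SCS+CT"]
    elif scenario == "allopatric_split":
        paired: set[str] = set()
        pairs = list(sister_pairs or [])
        for i, (a, b) in enumerate(pairs):
            ra = REGIONS[(2 * i) % len(REGIONS)]
            rb = REGIONS[(2 * i + 1) % len(REGIONS)]
            region_sets[a] = [ra]
            region_sets[b] = [rb]
            paired |= {a, b}
        for u in units:
            if u not in paired:
                region_sets[u] = [REGIONS[int(rng.integers(len(REGIONS)))]]
    elif scenario == "random":
        for u in units:
            k = 1 + int(rng.integers(2))
            region_sets[u] = sorted(
                rng.choice(REGIONS, size=k, replace=False).tolist()
            )
    else:
        raise InputError(f"unknown region scenario {scenario!r}")

    meta: list[SampleMetadata] = []
    for u in units:
        rset = region_sets[u]
        # round-robin so every region of the unit's set is realized whenever
        # the unit has at least as many samples as regions
        for i, s in enumerate(sorted(groups[u])):
            region = rset[i % len(rset)]
            meta.append(
                SampleMetadata(
                    sample_id=s,
                    species_label=species_of_unit.get(u, u),
                    region=region,
                )
            )
    return meta


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_partition(inferred: Partition, truth: Partition) -> ScoreReport:
    """Adjusted Rand index plus exact/lumped/split species bookkeeping."""
    if inferred.samples != truth.samples:
        diff = sorted(inferred.samples ^ truth.samples)
        raise PartitionError(f"partitions cover different samples: {diff}")
    order = sorted(truth.samples)
    ari = float(
        adjusted_rand_score(
            [truth.otu_of(s) for s in order], [inferred.otu_of(s) for s in order]
        )
    )
    inf_sets = inferred.as_sets()
    n_exact = sum(1 for g in truth.as_sets() if g in inf_sets)
    inferred_of = inferred.assignments
    n_split = 0
    n_lumped = 0
    inf_groups = inferred.groups()
    for g in truth.as_sets():
        labels = {inferred_of[s] for s in g}
        if len(labels) > 1:
            n_split += 1
        elif len(inf_groups[next(iter(labels))]) > len(g):
            n_lumped += 1
    return ScoreReport(ari, n_exact, n_lumped, n_split)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Generate one complete dataset (trees, alignment, metadata, truth)."""
    rng = np.random.default_rng(cfg.seed)
    crown = cfg.crown_age if cfg.crown_age is not None else float(rng.uniform(12.8, 16.6))
    cfg_fixed = SimulationConfig(**{**asdict(cfg), "crown_age": crown})
    species_tree = simulate_species_tree(cfg_fixed, rng)
    units = [lf.taxon.label for lf in species_tree.leaf_node_iter()]

    if isinstance(cfg.samples_per_species, int):
        per_unit = {u: cfg.samples_per_species for u in units}
    else:
        lo, hi = cfg.samples_per_species
        per_unit = {u: int(rng.integers(lo, hi + 1)) for u in units}

    gene_tree = simulate_gene_tree(
        species_tree,
        per_unit,
        cfg.coalescent_depth,
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    alignment = evolve_sequences(
        gene_tree,
        seq_length=cfg.seq_length,
        kappa=cfg.kappa,
        clock_rate=cfg.clock_rate,
        seed=int(rng.integers(1, 2**31 - 1)),
        base_freqs=(0.30, 0.20, 0.15, 0.35) if cfg.unequal_base_freqs else None,
    )

    if cfg.cryptic_pairs:
        species_of_unit = {u: u[:-1] for u in units}  # "S03a" -> "S03"
        sister_pairs = [
            (f"{sp}a", f"{sp}b") for sp in sorted({u[:-1] for u in units})
        ]
    else:
        species_of_unit = {u: u for u in units}
        sister_pairs = _species_tree_cherries(species_tree)

    unit_of_sample = {
        f"{u}_{i + 1:02d}": u for u in units for i in range(per_unit[u])
    }
    unit_partition = Partition(
        {s: u for s, u in unit_of_sample.items()}, method="truth"
    )
    meta = assign_regions(
        unit_partition,
        cfg.region_scenario,
        seed=int(rng.integers(1, 2**31 - 1)),
        sister_pairs=sister_pairs,
        species_of_unit=species_of_unit,
    )
    truth = Partition(
        {s: species_of_unit[u] for s, u in unit_of_sample.items()}, method="truth"
    )

    manifest = {**asdict(cfg), "crown_age": crown, "samples_per_unit": per_unit}
    return SyntheticDataset(
        truth=truth,
        species_tree=species_tree,
        gene_tree=gene_tree,
        alignment=alignment,
        metadata=meta,
        manifest=manifest,
    )


def _species_tree_cherries(tree: dendropy.Tree) -> list[tuple[str, str]]:
    pairs = []
    for node in tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            pairs.append((kids[0].taxon.label, kids[1].taxon.label))
    return pairs
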
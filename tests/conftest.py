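"""Shared fixtures: tiny alignments, toy trees and a hand-built
reconciliation scenario with three well-behaved species plus one species
whose delimitation the similarity rule must repair and one whose
delimitation the geography rule must decide."""

from __future__ import annotations

import numpy as np
import pytest

from otudelim import (
    AlignedSequenceSet,
    DistanceMatrix,
    Partition,
    SampleMetadata,
    tree_from_string,
)

SAMPLES = ["x1", "x2", "x3", "y1", "y2", "z1", "w1", "w2"]
SPECIES = {
    "x1": "X", "x2": "X", "x3": "X",
    "y1": "Y", "y2": "Y",
    "z1": "Z",
    "w1": "W", "w2": "W",
}


@pytest.fixture
def tiny_alignment() -> AlignedSequenceSet:
    return AlignedSequenceSet(
        "toy",
        ["a", "b", "c", "d"],
        ["AAAA", "AAAT", "AATT", "AATA"],
    )


def _toy_distance(a: str, b: str) -> float:
    """Within X: <= 0.01; within Y: 0.02; within W: 0.05; across species 0.2."""
    if a == b:
        return 0.0
    sa, sb = SPECIES[a], SPECIES[b]
    if sa != sb:
        return 0.2
    if sa == "X":
        return 0.01 if "x1" in (a, b) else 0.008
    if sa == "Y":
        return 0.02
    return 0.05  # W


@pytest.fixture
def toy_dm() -> DistanceMatrix:
    n = len(SAMPLES)
    vals = np.zeros((n, n))
    for i, a in enumerate(SAMPLES):
        for j, b in enumerate(SAMPLES):
            vals[i, j] = _toy_distance(a, b)
    return DistanceMatrix(list(SAMPLES), vals, "k2p")


@pytest.fixture
def toy_coi_tree():
    # X is a clade with (x2,x3) a cherry; W a cherry of singleton OTUs;
    # Y a cherry; z1 the outermost tip.
    return tree_from_string(
        "((((x1:1,(x2:0.5,x3:0.5):0.5):1,(w1:1.5,w2:1.5):0.5):1,"
        "(y1:1,y2:1):2):1,z1:4);"
    )


@pytest.fixture
def toy_rag1_tree():
    # x2/x3 are NOT monophyletic here (x1 nested between them); w1/w2 absent,
    # emulating a locus that failed to sequence for that species.
    return tree_from_string(
        "(((x2:1,(x1:0.5,x3:0.5):0.5):2,(y1:1,y2:1):2):1,z1:4);"
    )


@pytest.fixture
def toy_abgd_partition() -> Partition:
    return Partition.from_sets(
        [{"x1", "x2", "x3"}, {"y1", "y2"}, {"z1"}, {"w1", "w2"}], method="abgd"
    )


@pytest.fixture
def toy_gmyc_partition() -> Partition:
    return Partition.from_sets(
        [{"x1"}, {"x2", "x3"}, {"y1", "y2"}, {"z1"}, {"w1"}, {"w2"}],
        method="gmyc",
    )


def toy_metadata(
    w_regions: tuple[str, str] = ("IO", "ECS"),
    w_morph_flag: bool = False,
) -> list[SampleMetadata]:
    regions = {
        "x1": "ECS", "x2": "ECS", "x3": "ECS",
        "y1": "ECS", "y2": "ECS",
        "z1": "IO",
        "w1": w_regions[0], "w2": w_regions[1],
    }
    return [
        SampleMetadata(
            sample_id=s,
            species_label=SPECIES[s],
            region=regions[s],
            morphology_distinct_from=(
                frozenset({"w2"}) if (w_morph_flag and s == "w1") else frozenset()
            ),
        )
        for s in SAMPLES
    ]


@pytest.fixture
def toy_meta_allopatric():
    return toy_metadata(("IO", "ECS"))


@pytest.fixture
def toy_meta_sympatric():
    return toy_metadata(("SCS+CT", "SCS+CT"))


@pytest.fixture
def toy_meta_morphology():
    return toy_metadata(("IO", "ECS"), w_morph_flag=True)
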
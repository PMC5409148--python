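"""Sample-to-OTU assignments with method provenance.

A :class:`Partition` maps every sample in its declared sample set to exactly
one OTU label.  Partitions are produced by the barcode-gap clustering, by the
mixed Yule-coalescent threshold model, by the reconciliation procedure, and by
the synthetic-data generator (truth); the ``method`` field records which.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import PartitionError

METHODS = ("abgd", "gmyc", "reconciled", "truth", "other")


@dataclass(frozen=True)
class Partition:
    """A total mapping sample_id -> otu_id with provenance."""

    assignments: Mapping[str, str]
    method: str = "other"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise PartitionError(
                f"unknown method {self.method!r}; expected one of {METHODS}"
            )
        object.__setattr__(self, "assignments", dict(self.assignments))

    # -- constructors ------------------------------------------------------
    @classmethod
    def from_sets(cls, groups: Iterable[Iterable[str]], method: str = "other",
                  prefix: str = "OTU") -> "Partition":
        """Build from an iterable of disjoint sample groups.

        OTU ids are contiguous ``{prefix}_001`` ... in order of the smallest
        member of each group, making the labelling deterministic.
        """
        norm = sorted((sorted(g) for g in groups), key=lambda g: g[0])
        assignments: dict[str, str] = {}
        for i, g in enumerate(norm, start=1):
            otu = f"{prefix}_{i:03d}"
            for s in g:
                if s in assignments:
                    raise PartitionError(f"sample {s!r} appears in two groups")
                assignments[s] = otu
        return cls(assignments, method=method)

    @classmethod
    def read_tsv(cls, path: str | Path, method: str = "other") -> "Partition":
        assignments: dict[str, str] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample_id", "otu_id"]:
                raise PartitionError(
                    f"{path}: expected header 'sample_id\\totu_id', got {header[:2]}"
                )
            for line in fh:
                if not line.strip():
                    continue
                sample, otu = line.rstrip("\n").split("\t")[:2]
                if sample in assignments:
                    raise PartitionError(f"{path}: duplicate sample {sample!r}")
                assignments[sample] = otu
        return cls(assignments, method=method)

    # -- views -------------------------------------------------------------
    @property
    def samples(self) -> frozenset[str]:
        return frozenset(self.assignments)

    @property
    def n_groups(self) -> int:
        return len(set(self.assignments.values()))

    def groups(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for s, o in self.assignments.items():
            out.setdefault(o, set()).add(s)
        return {o: frozenset(ss) for o, ss in out.items()}

    def as_sets(self) -> frozenset[frozenset[str]]:
        """Label-free signature; equal signatures == identical clusterings."""
        return frozenset(self.groups().values())

    def otu_of(self, sample: str) -> str:
        return self.assignments[sample]

    def restrict(self, samples: Iterable[str], method: str | None = None) -> "Partition":
        keep = set(samples)
        missing = keep - self.samples
        if missing:
            raise PartitionError(f"samples not in partition: {sorted(missing)}")
        return Partition(
            {s: o for s, o in self.assignments.items() if s in keep},
            method=method or self.method,
        )

    def relabelled(self, method: str | None = None, prefix: str = "OTU") -> "Partition":
        return Partition.from_sets(
            self.as_sets(), method=method or self.method, prefix=prefix
        )

    def write_tsv(self, path: str | Path, extra: Mapping[str, str] | None = None) -> None:
        """Write sample/OTU table; ``extra`` adds a third per-OTU column."""
        with open(path, "w") as fh:
            cols = ["sample_id", "otu_id"] + (["note"] if extra else [])
            fh.write("\t".join(cols) + "\n")
            for s in sorted(self.assignments):
                row = [s, self.assignments[s]]
                if extra:
                    row.append(extra.get(self.assignments[s], ""))
                fh.write("\t".join(row) + "\n")

    def same_clustering(self, other: "Partition") -> bool:
        return self.samples == other.samples and self.as_sets() == other.as_sets()
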
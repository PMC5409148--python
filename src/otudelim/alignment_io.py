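"""Aligned-FASTA and sample-metadata I/O plus descriptive site statistics.

The central container is :class:`AlignedSequenceSet`: a per-locus multiple
alignment over IUPAC nucleotide codes plus ``-`` (gap) and ``?`` (missing).
Site statistics follow the usual conventions for barcode datasets: a column is
*variable* when at least two distinct unambiguous nucleotides occur in it, and
*parsimony-informative* when at least two states each occur in at least two
sequences.  Ambiguity codes are treated as missing for state counting and base
composition (the conservative convention for Sanger barcode data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .errors import AlignmentError, InputError

IUPAC_CODES = frozenset("ACGTURYSWKMBDHVN-?")
UNAMBIGUOUS = "ACGT"
REGIONS = ("IO", "ECS", "SCS+CT", "SAS")

# byte-code table: A,C,G,T -> 0..3, everything else -> 255 (missing)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_CODE[ord("U")] = 3  # RNA alphabet folds onto T


@dataclass
class AlignedSequenceSet:
    """A validated per-locus multiple sequence alignment.

    Parameters
    ----------
    locus_name:
        Label of the locus (e.g. ``"COI"``).
    sample_ids:
        Ordered, unique sample identifiers; one per sequence.
    sequences:
        Equal-length uppercase strings over IUPAC codes plus ``-``/``?``.
    codon_offset:
        Reading-frame position of column 1, in ``{0, 1, 2}``; 0 means the
        first column is a first codon position (coding loci in frame).
    partitions:
        Optional ``(locus, start, end)`` half-open column ranges recording
        locus boundaries of a concatenated alignment.
    """

    locus_name: str
    sample_ids: list[str]
    sequences: list[str]
    codon_offset: int = 0
    partitions: list[tuple[str, int, int]] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError(f"{self.locus_name}: alignment has no records")
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError(
                f"{self.locus_name}: {len(self.sample_ids)} ids for "
                f"{len(self.sequences)} sequences"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen, dups = set(), set()
            for s in self.sample_ids:
                (dups if s in seen else seen).add(s)
            raise InputError(f"{self.locus_name}: duplicate sample ids {sorted(dups)}")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        if length < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        for sid, seq in zip(self.sample_ids, self.sequences):
            if len(seq) != length:
                raise AlignmentError(
                    f"{self.locus_name}: record {sid!r} has length {len(seq)}, "
                    f"expected {length}"
                )
            for col, ch in enumerate(seq):
                if ch not in IUPAC_CODES:
                    raise InputError(
                        f"{self.locus_name}: illegal character {ch!r} in record "
                        f"{sid!r} at column {col}"
                    )
        if self.codon_offset not in (0, 1, 2):
            raise InputError(f"codon_offset must be 0, 1 or 2, got {self.codon_offset}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def encoded(self) -> np.ndarray:
        """(n_samples, length) uint8 matrix; A,C,G,T -> 0..3, other -> 255."""
        raw = np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(self.n_samples, self.length)
        return _CODE[raw]

    def sequence_of(self, sample_id: str) -> str:
        return self.sequences[self.sample_ids.index(sample_id)]

    def subset(self, sample_ids: Sequence[str]) -> "AlignedSequenceSet":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise InputError(f"{self.locus_name}: unknown samples {missing}")
        return AlignedSequenceSet(
            self.locus_name,
            list(sample_ids),
            [self.sequences[idx[s]] for s in sample_ids],
            codon_offset=self.codon_offset,
            partitions=self.partitions,
        )


@dataclass(frozen=True)
class SampleMetadata:
    """Recognized-species label, region code and optional annotations."""

    sample_id: str
    species_label: str
    region: str
    morphology_distinct_from: frozenset[str] = frozenset()
    source: str = ""

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise InputError(
                f"sample {self.sample_id!r}: unknown region {self.region!r}; "
                f"allowed codes are {', '.join(REGIONS)}"
            )


@dataclass(frozen=True)
class SiteStats:
    """Descriptive per-alignment site statistics."""

    length: int
    variable_sites: int
    parsimony_informative_sites: int
    per_codon_position: tuple[tuple[int, int], ...]  # (variable, informative) x3
    base_composition: dict[str, float]

    def as_tsv(self) -> str:
        lines = [
            "statistic\tvalue",
            f"length\t{self.length}",
            f"variable_sites\t{self.variable_sites}",
            f"parsimony_informative_sites\t{self.parsimony_informative_sites}",
        ]
        for i, (v, pi) in enumerate(self.per_codon_position, start=1):
            lines.append(f"codon_pos{i}_variable\t{v}")
            lines.append(f"codon_pos{i}_informative\t{pi}")
        for b in UNAMBIGUOUS:
            lines.append(f"freq_{b}\t{self.base_composition[b]:.6f}")
        return "\n".join(lines) + "\n"


def read_alignment(path: str | Path, locus_name: str | None = None) -> AlignedSequenceSet:
    """Read an aligned FASTA file.

    Identifiers are the FASTA header token up to the first whitespace.
    Ragged records, duplicate ids and non-IUPAC characters are fatal.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return AlignedSequenceSet(
        locus_name or path.stem,
        [r.id for r in records],
        [str(r.seq) for r in records],
    )


def write_alignment(aln: AlignedSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(aln.sample_ids, aln.sequences):
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read a tab-separated metadata table.

    Mandatory columns: ``sample_id``, ``species_label``, ``region``.
    Optional: ``morphology_distinct_from`` (comma-separated ids), ``source``.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        warnings.warn(f"{path}: empty metadata file")
        return []
    header = lines[0].split("\t")
    required = ["sample_id", "species_label", "region"]
    for col in required:
        if col not in header:
            raise InputError(f"{path}: missing mandatory column {col!r}")
    idx = {c: i for i, c in enumerate(header)}
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for ln in lines[1:]:
        cells = ln.split("\t")

        def get(col: str, default: str = "") -> str:
            i = idx.get(col)
            return cells[i].strip() if i is not None and i < len(cells) else default

        sid = get("sample_id")
        if sid in seen:
            raise InputError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        flags = frozenset(
            f.strip() for f in get("morphology_distinct_from").split(",") if f.strip()
        )
        out.append(
            SampleMetadata(
                sample_id=sid,
                species_label=get("species_label"),
                region=get("region"),
                morphology_distinct_from=flags,
                source=get("source"),
            )
        )
    return out


def write_metadata(meta: Iterable[SampleMetadata], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tspecies_label\tregion\tmorphology_distinct_from\tsource\n")
        for m in meta:
            fh.write(
                f"{m.sample_id}\t{m.species_label}\t{m.region}\t"
                f"{','.join(sorted(m.morphology_distinct_from))}\t{m.source}\n"
            )


def sequence_stats(aln: AlignedSequenceSet) -> SiteStats:
    """Variable/parsimony-informative site counts and base composition.

    Ambiguity codes, gaps and ``?`` are excluded from state counting.
    """
    codes = aln.encoded()
    # per-column counts of each unambiguous state: (4, length)
    counts = np.stack([(codes == s).sum(axis=0) for s in range(4)])
    n_states = (counts > 0).sum(axis=0)
    variable = n_states >= 2
    informative = (counts >= 2).sum(axis=0) >= 2

    positions = (np.arange(aln.length) + aln.codon_offset) % 3
    per_codon = tuple(
        (int(variable[positions == p].sum()), int(informative[positions == p].sum()))
        for p in range(3)
    )
    totals = counts.sum(axis=1).astype(float)
    grand = totals.sum()
    if grand > 0:
        freqs = {b: float(totals[i] / grand) for i, b in enumerate(UNAMBIGUOUS)}
    else:
        freqs = {b: float("nan") for b in UNAMBIGUOUS}
    return SiteStats(
        length=aln.length,
        variable_sites=int(variable.sum()),
        parsimony_informative_sites=int(informative.sum()),
        per_codon_position=per_codon,
        base_composition=freqs,
    )


def concatenate(
    alns: Sequence[AlignedSequenceSet], join: str = "outer"
) -> AlignedSequenceSet:
    """Concatenate per-locus alignments into a combined matrix.

    ``inner`` keeps samples present in every locus; ``outer`` keeps the union
    and pads missing loci with ``?`` (the standard treatment of samples whose
    sequencing failed at one locus).
    """
    if len(alns) < 2:
        raise InputError("concatenate needs at least two alignments")
    if join not in ("inner", "outer"):
        raise InputError(f"join must be 'inner' or 'outer', got {join!r}")

    if join == "inner":
        shared = set(alns[0].sample_ids)
        for a in alns[1:]:
            shared &= set(a.sample_ids)
        if not shared:
            raise InputError("inner join: no samples shared by all loci")
        order = [s for s in alns[0].sample_ids if s in shared]
    else:
        order, seen = [], set()
        for a in alns:
            for s in a.sample_ids:
                if s not in seen:
                    seen.add(s)
                    order.append(s)

    parts: list[tuple[str, int, int]] = []
    blocks: list[list[str]] = []
    start = 0
    for a in alns:
        idx = {s: i for i, s in enumerate(a.sample_ids)}
        pad = "?" * a.length
        blocks.append([a.sequences[idx[s]] if s in idx else pad for s in order])
        parts.append((a.locus_name, start, start + a.length))
        start += a.length

    combined = ["".join(row) for row in zip(*blocks)]
    return AlignedSequenceSet(
        "+".join(a.locus_name for a in alns),
        order,
        combined,
        codon_offset=alns[0].codon_offset,
        partitions=parts,
    )
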
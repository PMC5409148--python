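"""Integrative reconciliation of barcode-gap and mixed Yule-coalescent OTUs.

The procedure mirrors standard integrative-taxonomy practice for barcode
surveys:

1. *Congruence.*  OTUs with identical sample membership in both delimitation
   methods are robust and pass through unmodified.
2. *Similarity + monophyly.*  Within each recognized species, incongruent
   OTUs are merged when every cross pair is genetically close (maximum K2P
   below a threshold tau, derived as the largest within-OTU distance among
   the congruent OTUs unless supplied) AND at least one of them fails
   monophyly in at least one gene tree.
3. *Geography.*  Sister OTUs on the barcode tree (each a clade, union a
   clade) are merged when their four-region distributions are disjoint
   (allopatry) and no morphological distinctness flag separates them;
   sympatric sisters are kept apart and recorded as such.  Applied
   iteratively to a fixpoint.

Every final OTU carries exactly one decision label; re-running on identical
inputs is deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

from .alignment_io import REGIONS, SampleMetadata
from .distances import DistanceMatrix
from .errors import InputError, PartitionError
from .partition import Partition
from .trees import is_monophyletic, prune_to, tip_labels

LABELS = (
    "robust_congruent",
    "merged_similarity",
    "merged_allopatric_sister",
    "split_sympatric",
    "unresolved_flagged",
)


@dataclass(frozen=True)
class ReconcileConfig:
    merge_threshold_tau: float | None = None  # derive from congruent OTUs if None
    require_both_gene_trees: bool = True
    honor_morphology_flags: bool = True

    def __post_init__(self) -> None:
        tau = self.merge_threshold_tau
        if tau is not None and not (0 < tau < 1):
            raise InputError("tau must lie in (0, 1)")


@dataclass
class SpeciesHypothesis:
    """Final partition with a per-OTU decision trail and summary counts."""

    partition: Partition
    decision_trail: dict[str, str]
    notes: dict[str, str]
    tau: float
    n_robust: int = 0
    n_revised: int = 0
    n_final: int = 0
    n_matching_recognized: int = 0

    def summary(self) -> dict[str, float | int]:
        return {
            "n_robust": self.n_robust,
            "n_revised": self.n_revised,
            "n_final": self.n_final,
            "n_matching_recognized": self.n_matching_recognized,
            "tau": self.tau,
        }

    def write(self, partition_path: str | Path, summary_path: str | Path) -> None:
        self.partition.write_tsv(partition_path, extra=self.decision_trail)
        with open(summary_path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def congruent_otus(p_abgd: Partition, p_gmyc: Partition) -> frozenset[frozenset[str]]:
    """Groups whose exact membership appears in both partitions."""
    if p_abgd.samples != p_gmyc.samples:
        diff = sorted(p_abgd.samples ^ p_gmyc.samples)
        raise PartitionError(f"partitions cover different samples: {diff}")
    return frozenset(p_abgd.as_sets() & p_gmyc.as_sets())


def derive_merge_threshold(
    dm: DistanceMatrix, congruent: Iterable[frozenset[str]]
) -> float:
    """tau = maximum within-OTU distance over congruent multi-sample OTUs."""
    best = None
    for otu in congruent:
        members = sorted(otu)
        if len(members) < 2:
            continue
        sub = dm.submatrix(members)
        vals = sub.condensed()
        if vals.size:
            m = float(vals.max())
            best = m if best is None else max(best, m)
    if best is None:
        raise InputError(
            "all congruent OTUs are singletons; set the merge threshold tau "
            "manually"
        )
    return best


def regions_of(
    otu: Iterable[str], meta: Mapping[str, SampleMetadata]
) -> set[str]:
    otu = list(otu)
    if not otu:
        raise InputError("empty OTU")
    out = set()
    for s in otu:
        if s not in meta:
            raise InputError(f"no region metadata for sample {s!r}")
        out.add(meta[s].region)
    return out


def _max_cross_distance(dm: DistanceMatrix, groups: Sequence[frozenset[str]]) -> float:
    members = sorted(set().union(*groups))
    sub = dm.submatrix(members)
    iu = np.triu_indices(sub.n, k=1)
    vals = sub.values[iu]
    if np.isnan(vals).any():
        return np.inf  # a saturated pair can never satisfy a closeness test
    return float(vals.max()) if vals.size else 0.0


def _non_monophyletic_somewhere(
    group: frozenset[str],
    coi_tree: dendropy.Tree,
    rag1_tree: dendropy.Tree | None,
) -> bool:
    mono_coi, _ = is_monophyletic(coi_tree, group)
    if not mono_coi:
        return True
    if rag1_tree is not None:
        present = group & set(tip_labels(rag1_tree))
        if present:  # samples without the nuclear locus abstain
            mono_rag, _ = is_monophyletic(rag1_tree, present)
            if not mono_rag:
                return True
    return False


def merge_by_similarity(
    p_gmyc: Partition,
    species_of: Mapping[str, str],
    dm: DistanceMatrix,
    coi_tree: dendropy.Tree,
    rag1_tree: dendropy.Tree | None,
    tau: float,
    robust: frozenset[frozenset[str]] = frozenset(),
) -> tuple[list[frozenset[str]], dict[frozenset[str], str]]:
    """Merge incongruent OTUs of one recognized species when genetically
    close (strictly below tau) and non-monophyletic in at least one gene tree.

    Returns the revised group list and a per-group status map using the
    internal status ``pending`` for groups no rule has touched yet.
    """
    groups = sorted(p_gmyc.as_sets(), key=lambda g: min(g))
    status: dict[frozenset[str], str] = {}
    by_species: dict[str, list[frozenset[str]]] = {}
    passthrough: list[frozenset[str]] = []

    for g in groups:
        labelled = {species_of.get(s) for s in g}
        missing = {s for s in g if species_of.get(s) is None}
        if missing:
            warnings.warn(f"samples without species label excluded from merge "
                          f"tests: {sorted(missing)}")
        labelled.discard(None)
        if g in robust:
            status[g] = "robust_congruent"
            passthrough.append(g)
        elif len(labelled) != 1:
            status[g] = "unresolved_flagged"
            passthrough.append(g)
        else:
            by_species.setdefault(labelled.pop(), []).append(g)

    revised: list[frozenset[str]] = list(passthrough)
    for sp in sorted(by_species):
        cands = by_species[sp]
        parent = list(range(len(cands)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(cands)):
            for j in range(i + 1, len(cands)):
                close = _max_cross_distance(dm, [cands[i], cands[j]]) < tau
                if close and (
                    _non_monophyletic_somewhere(cands[i], coi_tree, rag1_tree)
                    or _non_monophyletic_somewhere(cands[j], coi_tree, rag1_tree)
                ):
                    parent[find(i)] = find(j)
        merged: dict[int, set[str]] = {}
        for i, g in enumerate(cands):
            merged.setdefault(find(i), set()).update(g)
        for root_i, members in sorted(merged.items(), key=lambda kv: min(kv[1])):
            g = frozenset(members)
            n_parts = sum(1 for i in range(len(cands)) if find(i) == root_i)
            status[g] = "merged_similarity" if n_parts > 1 else "pending"
            revised.append(g)
    return revised, status


def _sister_pairs(
    groups: Sequence[frozenset[str]], tree: dendropy.Tree
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """Pairs of groups that are each a clade and whose union is a clade."""
    mono = {g: is_monophyletic(tree, g)[0] for g in groups}
    pairs = []
    for i, a in enumerate(groups):
        if not mono[a]:
            continue
        for b in groups[i + 1 :]:
            if not mono[b]:
                continue
            if is_monophyletic(tree, a | b)[0]:
                pairs.append((a, b))
    return pairs


def _morphology_linked(
    a: frozenset[str],
    b: frozenset[str],
    meta: Mapping[str, SampleMetadata],
    otu_ids: Mapping[str, str],
) -> bool:
    def linked(src: frozenset[str], dst: frozenset[str]) -> bool:
        dst_ids = dst | {otu_ids[s] for s in dst if s in otu_ids}
        for s in src:
            m = meta.get(s)
            if m and m.morphology_distinct_from & dst_ids:
                return True
        return False

    return linked(a, b) or linked(b, a)


def merge_allopatric_sisters(
    groups: Sequence[frozenset[str]],
    status: Mapping[frozenset[str], str],
    coi_tree: dendropy.Tree,
    meta: Mapping[str, SampleMetadata],
    cfg: ReconcileConfig,
    gmyc_otu_ids: Mapping[str, str] | None = None,
    species_of: Mapping[str, str] | None = None,
) -> tuple[list[frozenset[str]], dict[frozenset[str], str], dict[frozenset[str], str]]:
    """Iteratively merge allopatric sister OTUs; mark sympatric sisters.

    Robust OTUs never merge, and a sister pair is only eligible when both
    OTUs carry the same recognized-species labels -- a label difference is
    itself evidence against lumping.  Returns (groups, status, notes).
    """
    groups = sorted(groups, key=lambda g: min(g))
    status = dict(status)
    notes: dict[frozenset[str], str] = {}
    otu_ids = gmyc_otu_ids or {}
    species_of = species_of or {}

    def labels_of(g: frozenset[str]) -> frozenset[str]:
        return frozenset(
            species_of[s] for s in g if species_of.get(s) is not None
        )

    changed = True
    while changed:
        changed = False
        candidates = [g for g in groups if status.get(g) != "robust_congruent"]
        for a, b in _sister_pairs(candidates, coi_tree):
            if species_of and labels_of(a) != labels_of(b):
                continue
            ra, rb = regions_of(a, meta), regions_of(b, meta)
            if ra & rb:
                for g in (a, b):
                    if status.get(g) == "pending":
                        status[g] = "split_sympatric"
                continue
            if cfg.honor_morphology_flags and _morphology_linked(a, b, meta, otu_ids):
                for g in (a, b):
                    notes[g] = "allopatric sisters kept separate: morphology distinct"
                continue
            union = a | b
            groups = [g for g in groups if g not in (a, b)] + [union]
            groups.sort(key=lambda g: min(g))
            for g in (a, b):
                status.pop(g, None)
            status[union] = "merged_allopatric_sister"
            changed = True
            break
    return groups, status, notes


def summarize(
    final_groups: Sequence[frozenset[str]],
    status: Mapping[frozenset[str], str],
    species_of: Mapping[str, str],
) -> dict[str, int]:
    """Summary counts; a final OTU matches a recognized species when its
    membership equals that species' full sampled membership."""
    members_by_species: dict[str, set[str]] = {}
    for s, sp in species_of.items():
        members_by_species.setdefault(sp, set()).add(s)
    species_sets = {frozenset(v) for v in members_by_species.values()}
    n_matching = sum(1 for g in final_groups if g in species_sets)
    return {
        "n_robust": sum(1 for g in final_groups if status.get(g) == "robust_congruent"),
        "n_revised": sum(1 for g in final_groups if status.get(g) == "merged_similarity"),
        "n_final": len(final_groups),
        "n_matching_recognized": n_matching,
    }


# ---------------------------------------------------------------------------
# Full procedure
# ---------------------------------------------------------------------------

def reconcile(
    p_abgd: Partition,
    p_gmyc: Partition,
    dm: DistanceMatrix,
    meta: Sequence[SampleMetadata],
    coi_tree: dendropy.Tree,
    rag1_tree: dendropy.Tree | None = None,
    cfg: ReconcileConfig | None = None,
) -> SpeciesHypothesis:
    """Run congruence, similarity-merge and geography steps in order."""
    cfg = cfg or ReconcileConfig()
    meta_map = {m.sample_id: m for m in meta}
    species_of = {
        m.sample_id: m.species_label
        for m in meta
        if m.species_label and m.species_label.lower() != "indet"
    }
    samples = sorted(p_gmyc.samples)

    coi_pruned = prune_to(coi_tree, samples)
    rag1_pruned = None
    if rag1_tree is not None and cfg.require_both_gene_trees:
        shared = sorted(set(tip_labels(rag1_tree)) & set(samples))
        if shared:
            rag1_pruned = prune_to(rag1_tree, shared)

    robust = congruent_otus(p_abgd, p_gmyc)
    tau = (
        cfg.merge_threshold_tau
        if cfg.merge_threshold_tau is not None
        else derive_merge_threshold(dm, robust)
    )

    revised, status = merge_by_similarity(
        p_gmyc, species_of, dm, coi_pruned, rag1_pruned, tau, robust=robust
    )
    gmyc_ids = {s: p_gmyc.otu_of(s) for s in p_gmyc.samples}
    final_groups, status, notes = merge_allopatric_sisters(
        revised, status, coi_pruned, meta_map, cfg, gmyc_otu_ids=gmyc_ids,
        species_of=species_of,
    )
    for g in final_groups:  # no rule fired: flag for manual work
        if status.get(g, "pending") == "pending":
            status[g] = "unresolved_flagged"
            notes.setdefault(g, "incongruent OTU with no qualifying merge evidence")

    partition = Partition.from_sets(final_groups, method="reconciled")
    otu_by_group = {
        frozenset(v): k for k, v in partition.groups().items()
    }
    trail = {otu_by_group[g]: status[g] for g in final_groups}
    note_by_id = {otu_by_group[g]: n for g, n in notes.items() if g in otu_by_group}
    counts = summarize(final_groups, status, species_of)

    return SpeciesHypothesis(
        partition=partition,
        decision_trail=trail,
        notes=note_by_id,
        tau=float(tau),
        n_robust=counts["n_robust"],
        n_revised=counts["n_revised"],
        n_final=counts["n_final"],
        n_matching_recognized=counts["n_matching_recognized"],
    )
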
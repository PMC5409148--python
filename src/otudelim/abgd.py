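"""Automatic barcode-gap discovery.

The method scans a range of prior intraspecific divergences; for each prior
it looks for the first significant discontinuity ("barcode gap") in the
ranked pairwise distances, partitions the samples by single linkage below the
gap, and refines each group recursively with the same rule.  The significance
rule is deterministic: a jump between consecutive unique distances counts as
a gap when it exceeds ``X`` times the largest consecutive difference seen
among the smaller distances (with a small floor when there is none) and the
gap ends above the prior.  A stable plateau of identical partitions across
priors is the signature of a real barcode gap; the partition chosen for
downstream work is the modal one over the scan, taken at the largest prior
that attains it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix
from .errors import InputError
from .partition import Partition

SLOPE_FLOOR = 1e-6


@dataclass(frozen=True)
class AbgdConfig:
    """Prior-scan settings; defaults follow common barcode practice."""

    prior_min: float = 0.001
    prior_max: float = 0.1
    steps: int = 50
    relative_gap_width_X: float = 1.5
    model: str = "k2p"
    spacing: str = "log"

    def __post_init__(self) -> None:
        if not (0 < self.prior_min < self.prior_max < 1):
            raise InputError("need 0 < prior_min < prior_max < 1")
        if self.steps < 2:
            raise InputError("steps must be >= 2")
        if self.relative_gap_width_X <= 0:
            raise InputError("relative gap width X must be > 0")
        if self.spacing not in ("log", "linear"):
            raise InputError("spacing must be 'log' or 'linear'")

    def priors(self) -> np.ndarray:
        if self.spacing == "log":
            return np.logspace(
                np.log10(self.prior_min), np.log10(self.prior_max), self.steps
            )
        return np.linspace(self.prior_min, self.prior_max, self.steps)


@dataclass
class AbgdResult:
    """Per-prior partitions and the partition selected by the plateau rule."""

    priors: np.ndarray
    initial: list[Partition]
    recursive: list[Partition]
    gaps: list[tuple[float, float] | None]
    chosen_prior: float
    chosen_partition: Partition

    def group_counts(self) -> tuple[list[int], list[int]]:
        return (
            [p.n_groups for p in self.initial],
            [p.n_groups for p in self.recursive],
        )

    def summary_rows(self) -> list[tuple[float, int, int]]:
        return [
            (float(p), i.n_groups, r.n_groups)
            for p, i, r in zip(self.priors, self.initial, self.recursive)
        ]


def find_barcode_gap(
    sorted_distances: Sequence[float], prior_P: float, X: float = 1.5
) -> tuple[float, float] | None:
    """Locate the first significant gap ending above the prior.

    ``sorted_distances`` must be ascending.  Returns ``(lower, upper)`` of the
    gap, or ``None`` when no jump qualifies.
    """
    d = np.asarray(sorted_distances, dtype=float)
    if d.size == 0:
        raise InputError("empty distance list")
    if (np.diff(d) < 0).any():
        raise InputError("distances must be sorted ascending")
    u = np.unique(d)
    if u.size < 2:
        return None
    diffs = np.diff(u)
    running_slope = SLOPE_FLOOR
    for i in range(u.size - 1):
        if diffs[i] > X * running_slope and u[i + 1] > prior_P:
            return float(u[i]), float(u[i + 1])
        running_slope = max(running_slope, diffs[i])
    return None


def single_linkage_partition(dm: DistanceMatrix, threshold: float) -> Partition:
    """Connected components of the graph with edges where distance < threshold.

    Saturated (nan) entries never create an edge.
    """
    if threshold < 0:
        raise InputError("threshold must be >= 0")
    with np.errstate(invalid="ignore"):
        adj = dm.values < threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=False, connection="weak"
    )
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(dm.sample_ids, labels):
        groups.setdefault(int(lab), []).append(sid)
    return Partition.from_sets(groups.values(), method="abgd")


def _gap_threshold(gap: tuple[float, float]) -> float:
    lower, upper = gap
    return lower + min(1e-9, (upper - lower) / 2.0)


def abgd_partition(
    dm: DistanceMatrix, prior_P: float, X: float = 1.5, max_depth: int = 10
) -> tuple[Partition, Partition]:
    """Initial and recursively refined partitions at one prior.

    The initial partition is single linkage just above the gap's lower bound;
    the recursive pass re-applies gap finding within each group using only
    intra-group distances until no group splits (depth capped).
    """
    dists = np.sort(dm.condensed())
    gap = find_barcode_gap(dists, prior_P, X)
    if gap is None:
        initial = Partition.from_sets([dm.sample_ids], method="abgd")
        return initial, initial
    initial = single_linkage_partition(dm, _gap_threshold(gap))

    groups = [sorted(g) for g in initial.as_sets()]
    depth = 0
    while depth < max_depth:
        new_groups: list[list[str]] = []
        split_any = False
        for g in groups:
            if len(g) < 3:
                new_groups.append(g)
                continue
            sub = dm.submatrix(g)
            sub_d = np.sort(sub.condensed())
            if sub_d.size == 0:
                new_groups.append(g)
                continue
            sub_gap = find_barcode_gap(sub_d, prior_P, X)
            if sub_gap is None:
                new_groups.append(g)
                continue
            parts = single_linkage_partition(sub, _gap_threshold(sub_gap))
            if parts.n_groups == 1:
                new_groups.append(g)
            else:
                split_any = True
                new_groups.extend(sorted(s) for s in parts.as_sets())
        groups = new_groups
        depth += 1
        if not split_any:
            break
    else:
        warnings.warn(f"recursive refinement stopped at depth cap {max_depth}")
    recursive = Partition.from_sets(groups, method="abgd")
    return initial, recursive


def abgd_scan(dm: DistanceMatrix, cfg: AbgdConfig | None = None) -> AbgdResult:
    """Run the full prior scan and select the plateau partition.

    The chosen prior is the largest prior whose recursive partition equals
    the modal recursive partition across the scan.
    """
    cfg = cfg or AbgdConfig()
    priors = cfg.priors()
    dists = np.sort(dm.condensed())
    initial: list[Partition] = []
    recursive: list[Partition] = []
    gaps: list[tuple[float, float] | None] = []
    for P in priors:
        gap = find_barcode_gap(dists, float(P), cfg.relative_gap_width_X)
        gaps.append(gap)
        ini, rec = abgd_partition(dm, float(P), cfg.relative_gap_width_X)
        initial.append(ini)
        recursive.append(rec)

    signatures = [p.as_sets() for p in recursive]
    counts: dict[frozenset, int] = {}
    for sig in signatures:
        counts[sig] = counts.get(sig, 0) + 1
    best_count = max(counts.values())
    # tie on modality -> the plateau reaching the largest prior wins
    modal = max(
        (sig for sig, c in counts.items() if c == best_count),
        key=lambda sig: max(
            p for p, s in zip(priors, signatures) if s == sig
        ),
    )
    chosen_idx = max(i for i, s in enumerate(signatures) if s == modal)
    return AbgdResult(
        priors=priors,
        initial=initial,
        recursive=recursive,
        gaps=gaps,
        chosen_prior=float(priors[chosen_idx]),
        chosen_partition=recursive[chosen_idx],
    )
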
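"""Pairwise genetic distances (p, JC69, K2P) and partition summaries.

Distances are expressed in substitutions per site.  Columns with a gap,
missing symbol or ambiguity code in either sequence are excluded pair by pair
(pairwise deletion), which preserves per-pair information when full-length
and shorter database sequences are mixed in one alignment.  Transitions are
A<->G and C<->T; every other mismatch is a transversion.

Pairs whose observed divergence falls outside the domain of the requested
correction (1-2P-Q <= 0 or 1-2Q <= 0 for K2P, p >= 3/4 for JC69) are flagged
as saturated rather than silently clamped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .alignment_io import AlignedSequenceSet, _CODE
from .errors import InputError, SaturationError, UndefinedDistanceError
from .partition import Partition

MODELS = ("p", "jc69", "k2p")

# purine flag for transition/transversion classification of codes 0..3
_PURINE = np.array([True, False, True, False])


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Comparable-site count and transition/transversion proportions."""

    compared_sites: int
    transitions_P: float
    transversions_Q: float

    def __post_init__(self) -> None:
        P, Q = self.transitions_P, self.transversions_Q
        if P < 0 or Q < 0 or P + Q > 1 + 1e-12:
            raise InputError(f"invalid proportions P={P}, Q={Q}")


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def pairwise_counts(a: str | np.ndarray, b: str | np.ndarray) -> PairwiseSiteCounts:
    """Count comparable sites and classify mismatches for one pair."""
    ca = _encode(a) if isinstance(a, str) else a
    cb = _encode(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise InputError("sequences have different lengths")
    ok = (ca != 255) & (cb != 255)
    n = int(ok.sum())
    if n == 0:
        raise UndefinedDistanceError("no comparable sites in pair")
    xa, xb = ca[ok], cb[ok]
    diff = xa != xb
    ts = diff & (_PURINE[xa] == _PURINE[xb])
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairwiseSiteCounts(n, n_ts / n, n_tv / n)


def p_distance(counts: PairwiseSiteCounts) -> float:
    return counts.transitions_P + counts.transversions_Q


def jc69(p: float) -> float:
    """Jukes-Cantor correction d = -(3/4) ln(1 - 4p/3)."""
    if not 0 <= p:
        raise InputError(f"proportion p must be >= 0, got {p}")
    if p >= 0.75:
        raise SaturationError(f"p-distance {p} >= 3/4: JC69 undefined (saturated)")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def k2p(counts_or_P: PairwiseSiteCounts | float, Q: float | None = None) -> float:
    """Kimura two-parameter distance d = -ln(1-2P-Q)/2 - ln(1-2Q)/4.

    Accepts either a :class:`PairwiseSiteCounts` or the raw ``(P, Q)``
    proportions of transition- and transversion-differing sites.
    """
    if isinstance(counts_or_P, PairwiseSiteCounts):
        P, Q = counts_or_P.transitions_P, counts_or_P.transversions_Q
    else:
        if Q is None:
            raise InputError("k2p needs (P, Q) or a PairwiseSiteCounts")
        P, Q = float(counts_or_P), float(Q)
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P domain violation for P={P}, Q={Q} (saturated)")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix under a named model.

    Saturated pairs carry ``nan`` in ``values`` and ``True`` in ``saturated``;
    everything downstream that consumes maxima skips them with a warning.
    """

    sample_ids: list[str]
    values: np.ndarray
    model: str
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise InputError(f"matrix shape {self.values.shape} != ({n}, {n})")
        if self.model not in MODELS:
            raise InputError(f"unknown model {self.model!r}; expected one of {MODELS}")
        if self.saturated is None:
            self.saturated = np.zeros((n, n), dtype=bool)
        if not np.allclose(np.diagonal(self.values), 0.0):
            raise InputError("distance matrix diagonal must be zero")
        finite = ~np.isnan(self.values)
        if not np.array_equal(self.values[finite] >= 0, np.full(finite.sum(), True)):
            raise InputError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def index_of(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise InputError(f"unknown sample {sample_id!r}") from None

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    def submatrix(self, sample_ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(sample_ids)
        idx = [self.index_of(s) for s in ids]
        return DistanceMatrix(
            ids,
            self.values[np.ix_(idx, idx)].copy(),
            self.model,
            self.saturated[np.ix_(idx, idx)].copy(),
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances (finite only), unsorted."""
        iu = np.triu_indices(self.n, k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i, sid in enumerate(self.sample_ids):
                row = " ".join(f"{v:.8f}" for v in self.values[i])
                fh.write(f"{sid:<12s}{row}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, model: str = "k2p") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float), model)


def distance_matrix(aln: AlignedSequenceSet, model: str = "k2p") -> DistanceMatrix:
    """All-pairs distances with pairwise deletion.

    Raises on a pair with zero comparable sites (naming the pair); flags
    saturated pairs and continues.
    """
    if model not in MODELS:
        raise InputError(f"unknown model {model!r}; expected one of {MODELS}")
    if aln.n_samples < 2:
        raise InputError("distance matrix needs at least two samples")
    codes = aln.encoded()
    n = aln.n_samples
    values = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    n_sat = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                cnt = pairwise_counts(codes[i], codes[j])
            except UndefinedDistanceError:
                raise UndefinedDistanceError(
                    f"pair ({aln.sample_ids[i]!r}, {aln.sample_ids[j]!r}) has "
                    "no comparable sites"
                ) from None
            try:
                if model == "p":
                    d = p_distance(cnt)
                elif model == "jc69":
                    d = jc69(p_distance(cnt))
                else:
                    d = k2p(cnt)
            except SaturationError:
                d = np.nan
                saturated[i, j] = saturated[j, i] = True
                n_sat += 1
            values[i, j] = values[j, i] = d
    if n_sat:
        warnings.warn(f"{n_sat} saturated pair(s) flagged in {model} matrix")
    return DistanceMatrix(list(aln.sample_ids), values, model, saturated)


def partition_divergences(
    dm: DistanceMatrix, part: Partition
) -> tuple[dict[str, float], dict[tuple[str, str], tuple[float, float]]]:
    """Per-OTU maximum intra-group and pairwise min/max inter-group distances.

    Saturated entries are skipped from the maxima with a warning; singleton
    OTUs have max-intra 0 by convention.
    """
    groups = part.groups()
    if not groups:
        raise InputError("empty partition")
    idx = {o: [dm.index_of(s) for s in sorted(ss)] for o, ss in groups.items()}

    skipped = 0

    def _stats(vals: np.ndarray) -> tuple[float, float] | None:
        nonlocal skipped
        finite = vals[~np.isnan(vals)]
        skipped += vals.size - finite.size
        if finite.size == 0:
            return None
        return float(finite.min()), float(finite.max())

    max_intra: dict[str, float] = {}
    for o, ix in idx.items():
        if len(ix) == 1:
            max_intra[o] = 0.0
            continue
        sub = dm.values[np.ix_(ix, ix)]
        iu = np.triu_indices(len(ix), k=1)
        st = _stats(sub[iu])
        max_intra[o] = st[1] if st else 0.0

    inter: dict[tuple[str, str], tuple[float, float]] = {}
    otus = sorted(idx)
    for a_i, oa in enumerate(otus):
        for ob in otus[a_i + 1 :]:
            cross = dm.values[np.ix_(idx[oa], idx[ob])].ravel()
            st = _stats(cross)
            if st is not None:
                inter[(oa, ob)] = st
    if skipped:
        warnings.warn(f"{skipped} saturated distance(s) excluded from divergence summaries")
    return max_intra, inter
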
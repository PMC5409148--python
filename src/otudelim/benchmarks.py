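"""Seeded benchmark experiments for the delimitation pipeline.

These are the calibration studies the package ships with: type-I error of
the threshold model's likelihood-ratio test on pure-birth trees, species-
count recovery in a clean two-regime coalescent setting (youngest species
split ten times the mean within-species pairwise coalescent time), full-
pipeline partition recovery, and the behavior of the geography rule under
allopatric versus sympatric scenarios.  Every experiment is reproducible
from its seed alone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .gmyc import GmycConfig, fit_single_threshold
from .pipeline import run_pipeline
from .synthetic import SimulationConfig, simulate_dataset, simulate_species_tree
from .trees import UltrametricTree

# the clean two-regime study conditions used by the recovery experiments:
# ten species, five samples each, youngest split >= 10x coalescent depth
TWO_REGIME = dict(
    n_species=10,
    samples_per_species=5,
    coalescent_depth=0.1,
    min_species_separation=1.0,
)

# cryptic-structure conditions for the geography-rule experiment: each
# species holds two populations split well above the coalescent depth and
# well below the species separation, so the threshold model resolves
# populations while the distance scan stays at (or near) species rank
CRYPTIC = dict(
    n_species=6,
    samples_per_species=4,
    cryptic_pairs=True,
    cryptic_split_depth=1.0,
    coalescent_depth=0.05,
    min_species_separation=3.0,
)


def _spawn(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(1, 2**31 - 1, size=n)


def type1_error_rate(
    n_reps: int = 100, seed: int = 0, n_tips: int = 50, alpha: float = 0.05
) -> float:
    """Rejection rate of the LRT on pure-birth (single-regime) trees."""
    seeds = _spawn(seed, n_reps)
    rejections = 0
    for i, s in enumerate(seeds):
        cfg = SimulationConfig(
            n_species=n_tips, crown_age=14.0, min_species_separation=0.0,
            seed=int(s),
        )
        ult = UltrametricTree(simulate_species_tree(cfg))
        fit = fit_single_threshold(ult, GmycConfig(seed=int(s)))
        rejections += fit.p_value < alpha
    return rejections / n_reps


def species_count_recovery(n_reps: int = 50, seed: int = 0) -> float:
    """Fraction of two-regime replicates with entities == true species."""
    seeds = _spawn(seed, n_reps)
    hits = 0
    for s in seeds:
        ds = simulate_dataset(SimulationConfig(**TWO_REGIME, seed=int(s)))
        fit = fit_single_threshold(ds.gene_tree, GmycConfig(seed=int(s)))
        hits += fit.n_entities == ds.truth.n_groups
    return hits / n_reps


def pipeline_recovery(n_reps: int = 50, seed: int = 0) -> dict:
    """Adjusted Rand index of the final hypothesis vs truth, per replicate."""
    seeds = _spawn(seed, n_reps)
    aris = []
    for s in seeds:
        ds = simulate_dataset(SimulationConfig(**TWO_REGIME, seed=int(s)))
        result = run_pipeline(ds, gmyc_cfg=GmycConfig(seed=int(s)))
        aris.append(result.scores["final"].adjusted_rand_index)
    return {"median_ari": float(np.median(aris)), "aris": aris}


def geography_scenarios(n_reps: int = 6, seed: int = 0) -> dict:
    """Decision-trail behavior under allopatric vs sympatric structure.

    Returns per-scenario replicate counts of merged-allopatric-sister and
    sympatric-split labels in the final decision trail.
    """
    n_species = CRYPTIC["n_species"]
    out = {}
    for scenario in ("allopatric_split", "sympatric"):
        seeds = _spawn(seed + (0 if scenario == "allopatric_split" else 1), n_reps)
        merged = split = eligible = merged_total = 0
        for s in seeds:
            ds = simulate_dataset(
                SimulationConfig(**CRYPTIC, region_scenario=scenario, seed=int(s))
            )
            result = run_pipeline(ds, gmyc_cfg=GmycConfig(seed=int(s)))
            labels = Counter(result.hypothesis.decision_trail.values())
            merged_total += labels.get("merged_allopatric_sister", 0)
            # the geography rule only has work when the distance scan stays
            # at species rank while the threshold model resolves populations
            # (population OTUs found by both methods are robust and final)
            if not (
                result.abgd.chosen_partition.n_groups == n_species
                and result.gmyc.n_entities > n_species
            ):
                continue
            eligible += 1
            merged += labels.get("merged_allopatric_sister", 0) > 0
            split += labels.get("split_sympatric", 0) > 0
        out[scenario] = {
            "eligible": eligible,
            "with_allopatric_merge": merged,
            "with_sympatric_split": split,
            "total_allopatric_merges": merged_total,
        }
    return out
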
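"""Single-threshold generalized mixed Yule-coalescent model.

The model assumes an ultrametric gene tree whose branching events switch, at
an unknown time threshold T, from a between-species pure-birth (Yule) process
to within-species neutral coalescence.  Cutting the tree at T yields the
delimited entities: clusters (>= 2 samples) plus singletons.

Likelihood.  Order the n-1 branching events from the root toward the tips and
let x_i be the waiting time between events i and i+1.  During each interval
the total event rate is

    b_i = lambda_Y * n_i**p_Y + lambda_C * (sum_j n_ij * (n_ij - 1))**p_C

where n_i is the number of species-level (Yule) lineages -- the running
lineage count above T, frozen at the entity count below T -- and n_ij is the
number of gene lineages of cluster j crossing the interval.  The scaling
exponents p_Y and p_C absorb departures from the strict linear (Yule) and
quadratic (coalescent) dependence on lineage numbers.  Each inter-event gap
contributes b_i * exp(-b_i * x_i); the final gap from the youngest node to
the present contains no event and contributes the survival term
exp(-b * x) only.  The null model uses a single rate class
b_i = lambda * n_i**p over the whole tree with n_i the running lineage
count; it coincides with the mixed model when T lies below every node.

The threshold is profiled over candidate values at midpoints between
consecutive branching times (plus one candidate below the youngest node);
for each candidate the four remaining parameters are optimized numerically,
and a likelihood-ratio test against the null assesses significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .errors import InputError, OptimizationError, TreeError
from .partition import Partition
from .trees import UltrametricTree

_LOGLAM_BOUNDS = (-25.0, 25.0)
# scaling exponents are optimized over [0, 5], the conventional interval for
# this model; negative exponents (event rate falling with lineage count)
# are biologically unmotivated and let the mixed model overfit pure-birth trees
_P_BOUNDS = (0.0, 5.0)


@dataclass(frozen=True)
class GmycConfig:
    scaling_exponents_free: bool = True
    lrt_df: int = 3
    tol: float = 1e-8
    n_restarts: int = 5
    threshold_candidates: Sequence[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lrt_df not in (1, 2, 3):
            raise InputError("lrt_df must be 1, 2 or 3")


@dataclass(frozen=True)
class Interval:
    """One inter-event interval of the sweep, rootward to tipward."""

    waiting_time: float
    n_yule: int
    cluster_counts: tuple[int, ...]
    ends_with_event: bool

    @property
    def coalescent_sum(self) -> int:
        return sum(n * (n - 1) for n in self.cluster_counts)


@dataclass
class GmycFit:
    threshold_T: float
    null_logL: float
    mixed_logL: float
    LR_statistic: float
    p_value: float
    n_clusters: int
    n_entities: int
    partition: Partition
    lambda_yule: float
    p_yule: float
    lambda_coal: float
    p_coal: float
    candidates: list[tuple[float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Tree sweep
# ---------------------------------------------------------------------------

def _sorted_events(t: UltrametricTree) -> list[dendropy.Node]:
    events = sorted(t.tree.preorder_internal_node_iter(), key=lambda n: -n.height)
    heights = [e.height for e in events]
    if len(set(heights)) != len(heights):
        raise TreeError("tied event times; perturb heights upstream")
    for node in events:
        if len(node.child_nodes()) != 2:
            raise TreeError("tree must be strictly bifurcating")
    return events


def cut_at_threshold(t: UltrametricTree, T: float) -> Partition:
    """Entities obtained by cutting all branches crossing height T."""
    groups: list[list[str]] = []

    def collect(node: dendropy.Node) -> list[str]:
        if node.is_leaf():
            return [node.taxon.label]
        return [lab for ch in node.child_nodes() for lab in collect(ch)]

    def walk(node: dendropy.Node) -> None:
        if node.is_leaf() or node.height <= T:
            groups.append(collect(node))
        else:
            for ch in node.child_nodes():
                walk(ch)

    root = t.tree.seed_node
    if root.height <= T:
        groups.append(collect(root))
    else:
        for ch in root.child_nodes():
            walk(ch)
    return Partition.from_sets(groups, method="gmyc")


def _interval_arrays(
    t: UltrametricTree, T: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(x, n_yule, coalescent_sum, ends_with_event) per interval, root->tips."""
    events = _sorted_events(t)
    n_ev = len(events)
    heights = np.array([e.height for e in events])
    k = int((heights > T).sum())  # events above the threshold

    # assign every below-threshold event to its entity (cluster)
    cluster_of: dict[int, int] = {}
    next_cluster = 0

    def seed(node: dendropy.Node, cl: int | None) -> None:
        nonlocal next_cluster
        if node.is_leaf():
            return
        if node.height <= T:
            if cl is None:
                cl = next_cluster
                next_cluster += 1
            cluster_of[id(node)] = cl
            for ch in node.child_nodes():
                seed(ch, cl)
        else:
            for ch in node.child_nodes():
                seed(ch, None)

    seed(t.tree.seed_node, None)

    x = np.empty(n_ev)
    x[:-1] = heights[:-1] - heights[1:]
    x[-1] = heights[-1]
    n_yule = np.minimum(np.arange(2, n_ev + 2), k + 1)
    coalsum = np.zeros(n_ev)
    counts: dict[int, int] = {}
    running = 0.0
    for i, ev in enumerate(events):
        if ev.height <= T:
            cl = cluster_of[id(ev)]
            q = counts.get(cl, 1)
            running += 2 * q
            counts[cl] = q + 1
        coalsum[i] = running
    ends = np.ones(n_ev, dtype=bool)
    ends[-1] = False  # final gap runs to the present: survival only
    return x, n_yule.astype(float), coalsum, ends


def interval_rates(t: UltrametricTree, T: float) -> list[Interval]:
    """Readable per-interval table (waiting time, Yule count, cluster counts)."""
    if not (0 <= T <= t.root_height):
        raise InputError("threshold must lie between 0 and the root height")
    events = _sorted_events(t)
    x, n_yule, _, ends = _interval_arrays(t, T)

    # reconstruct per-cluster counts for the readable view
    cluster_members: dict[int, int] = {}
    out: list[Interval] = []
    cluster_of: dict[int, int] = {}
    next_cluster = 0

    def seed(node: dendropy.Node, cl: int | None) -> None:
        nonlocal next_cluster
        if node.is_leaf():
            return
        if node.height <= T:
            if cl is None:
                cl = next_cluster
                next_cluster += 1
            cluster_of[id(node)] = cl
            for ch in node.child_nodes():
                seed(ch, cl)
        else:
            for ch in node.child_nodes():
                seed(ch, None)

    seed(t.tree.seed_node, None)
    for i, ev in enumerate(events):
        if ev.height <= T:
            cl = cluster_of[id(ev)]
            cluster_members[cl] = cluster_members.get(cl, 1) + 1
        out.append(
            Interval(
                waiting_time=float(x[i]),
                n_yule=int(n_yule[i]),
                cluster_counts=tuple(sorted(cluster_members.values())),
                ends_with_event=bool(ends[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Likelihoods
# ---------------------------------------------------------------------------

def _loglik_arrays(
    x: np.ndarray,
    n_yule: np.ndarray,
    coalsum: np.ndarray,
    ends: np.ndarray,
    lam_y: float,
    p_y: float,
    lam_c: float,
    p_c: float,
) -> float:
    if not np.isfinite([lam_y, p_y, lam_c, p_c]).all():
        raise InputError("non-finite parameters")
    if lam_y < 0 or lam_c < 0:
        raise InputError("rates must be non-negative")
    with np.errstate(divide="ignore"):
        a = n_yule ** p_y
        c = np.where(coalsum > 0, coalsum, 1.0) ** p_c * (coalsum > 0)
    b = lam_y * a + lam_c * c
    ll = -float(np.dot(b, x))
    bev = b[ends]
    if (bev <= 0).any():
        # zero-rate interval can only contribute survival, never an event
        return -np.inf
    return ll + float(np.log(bev).sum())


def mixed_log_likelihood(
    intervals: Sequence[Interval],
    lambda_yule: float,
    p_yule: float,
    lambda_coal: float,
    p_coal: float,
) -> float:
    """Mixed-model log-likelihood from an :func:`interval_rates` table."""
    x = np.array([iv.waiting_time for iv in intervals])
    n_yule = np.array([float(iv.n_yule) for iv in intervals])
    coalsum = np.array([float(iv.coalescent_sum) for iv in intervals])
    ends = np.array([iv.ends_with_event for iv in intervals])
    return _loglik_arrays(x, n_yule, coalsum, ends, lambda_yule, p_yule,
                          lambda_coal, p_coal)


def null_log_likelihood(t: UltrametricTree, lam: float, p: float) -> float:
    """Single-class likelihood b_i = lam * n_i**p over the whole tree."""
    x, n_yule, coalsum, ends = _interval_arrays(t, -1.0)  # T below all nodes
    return _loglik_arrays(x, n_yule, coalsum, ends, lam, p, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Optimization
# ---------------------------------------------------------------------------

def _neg_loglik_and_grad(
    theta: np.ndarray,
    x: np.ndarray,
    n_yule: np.ndarray,
    coalsum: np.ndarray,
    ends: np.ndarray,
    mixed: bool,
    free_p: bool,
) -> tuple[float, np.ndarray]:
    if mixed:
        if free_p:
            llam_y, p_y, llam_c, p_c = theta
        else:
            llam_y, llam_c = theta
            p_y = p_c = 1.0
    else:
        if free_p:
            llam_y, p_y = theta
        else:
            (llam_y,) = theta
            p_y = 1.0
        llam_c, p_c = -np.inf, 1.0
    lam_y = np.exp(llam_y)
    lam_c = np.exp(llam_c) if mixed else 0.0

    log_n = np.log(n_yule)
    a = np.exp(p_y * log_n)
    pos = coalsum > 0
    log_c = np.where(pos, np.log(np.where(pos, coalsum, 1.0)), 0.0)
    c = np.where(pos, np.exp(p_c * log_c), 0.0)
    b = lam_y * a + lam_c * c
    if (b[ends] <= 0).any():
        return np.inf, np.zeros_like(theta)

    inv_b_ev = 1.0 / b[ends]
    # d logL / d b_i = [1/b_i for event intervals] - x_i
    dl_db = -x.copy()
    dl_db[ends] += inv_b_ev

    ll = float(np.log(b[ends]).sum()) - float(np.dot(b, x))
    g_llam_y = float(np.dot(dl_db, lam_y * a))
    g_p_y = float(np.dot(dl_db, lam_y * a * log_n))
    if mixed:
        g_llam_c = float(np.dot(dl_db, lam_c * c))
        g_p_c = float(np.dot(dl_db, lam_c * c * log_c))
        grad = (
            np.array([g_llam_y, g_p_y, g_llam_c, g_p_c])
            if free_p
            else np.array([g_llam_y, g_llam_c])
        )
    else:
        grad = np.array([g_llam_y, g_p_y]) if free_p else np.array([g_llam_y])
    return -ll, -grad


def _maximize(
    x: np.ndarray,
    n_yule: np.ndarray,
    coalsum: np.ndarray,
    ends: np.ndarray,
    mixed: bool,
    free_p: bool,
    rng: np.random.Generator,
    n_restarts: int,
    tol: float,
    extra_starts: Sequence[np.ndarray] = (),
) -> tuple[float, np.ndarray]:
    n_events = int(ends.sum())
    lam0 = max(n_events, 1) / max(float(np.dot(n_yule, x)), 1e-12)
    denom_c = float(np.dot(coalsum, x))
    lamc0 = max((coalsum > 0).sum(), 1) / denom_c if denom_c > 0 else lam0

    if mixed:
        base = [np.log(lam0), 1.0, np.log(lamc0), 1.0]
        if not free_p:
            base = [base[0], base[2]]
    else:
        base = [np.log(lam0), 1.0] if free_p else [np.log(lam0)]
    base = np.array(base)

    if mixed:
        bounds = (
            [_LOGLAM_BOUNDS, _P_BOUNDS, _LOGLAM_BOUNDS, _P_BOUNDS]
            if free_p
            else [_LOGLAM_BOUNDS, _LOGLAM_BOUNDS]
        )
    else:
        bounds = [_LOGLAM_BOUNDS, _P_BOUNDS] if free_p else [_LOGLAM_BOUNDS]

    starts = [base] + [np.asarray(s, dtype=float) for s in extra_starts]
    for _ in range(n_restarts):
        jit = base + rng.normal(0.0, 0.5, size=base.size)
        starts.append(jit)

    best_ll, best_theta = -np.inf, base
    for s in starts:
        s = np.clip(s, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _neg_loglik_and_grad,
            s,
            args=(x, n_yule, coalsum, ends, mixed, free_p),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_ll, best_theta = -float(res.fun), res.x
    if not np.isfinite(best_ll):
        raise OptimizationError("likelihood optimization failed from all starts")
    return best_ll, best_theta


def fit_single_threshold(t: UltrametricTree, cfg: GmycConfig | None = None) -> GmycFit:
    """Profile the threshold, optimize rates, and test against the null.

    Candidate thresholds sit at midpoints between consecutive branching times
    plus one candidate below the youngest node (the all-Yule configuration,
    which nests the null model and guarantees mixed_logL >= null_logL).
    """
    cfg = cfg or GmycConfig()
    if t.n_tips < 4:
        raise InputError("single-threshold fit needs at least 4 tips")
    rng = np.random.default_rng(cfg.seed)
    free_p = cfg.scaling_exponents_free

    heights = np.sort(t.branching_times())[::-1]  # descending
    if cfg.threshold_candidates is not None:
        candidates = [float(T) for T in cfg.threshold_candidates]
    else:
        mids = (heights[:-1] + heights[1:]) / 2.0
        candidates = list(mids) + [heights[-1] / 2.0]

    # null fit (single rate class over the whole tree)
    xn, nyn, csn, endsn = _interval_arrays(t, -1.0)
    null_ll, null_theta = _maximize(
        xn, nyn, csn, endsn, mixed=False, free_p=free_p,
        rng=rng, n_restarts=cfg.n_restarts, tol=cfg.tol,
    )

    if free_p:
        null_as_mixed = np.array([null_theta[0], null_theta[1], -20.0, 1.0])
    else:
        null_as_mixed = np.array([null_theta[0], -20.0])

    best = None
    prev_theta: np.ndarray | None = None
    cand_table: list[tuple[float, float]] = []
    for T in candidates:
        x, nyule, coalsum, ends = _interval_arrays(t, T)
        extra = [null_as_mixed] + ([prev_theta] if prev_theta is not None else [])
        try:
            ll, theta = _maximize(
                x, nyule, coalsum, ends, mixed=True, free_p=free_p,
                rng=rng, n_restarts=cfg.n_restarts, tol=cfg.tol,
                extra_starts=extra,
            )
        except OptimizationError as exc:
            raise OptimizationError(f"non-convergence at candidate T={T}") from exc
        cand_table.append((float(T), ll))
        prev_theta = theta
        if best is None or ll > best[1]:
            best = (float(T), ll, theta)

    T_best, mixed_ll, theta = best
    lr = max(2.0 * (mixed_ll - null_ll), 0.0)
    p_value = float(chi2.sf(lr, cfg.lrt_df))

    partition = cut_at_threshold(t, T_best)
    sizes = [len(g) for g in partition.as_sets()]
    n_clusters = sum(1 for s in sizes if s >= 2)

    if free_p:
        lam_y, p_y, lam_c, p_c = np.exp(theta[0]), theta[1], np.exp(theta[2]), theta[3]
    else:
        lam_y, p_y, lam_c, p_c = np.exp(theta[0]), 1.0, np.exp(theta[1]), 1.0

    return GmycFit(
        threshold_T=T_best,
        null_logL=null_ll,
        mixed_logL=mixed_ll,
        LR_statistic=lr,
        p_value=p_value,
        n_clusters=n_clusters,
        n_entities=len(sizes),
        partition=partition,
        lambda_yule=float(lam_y),
        p_yule=float(p_y),
        lambda_coal=float(lam_c),
        p_coal=float(p_c),
        candidates=cand_table,
    )
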
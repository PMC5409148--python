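"""Single-threshold mixed Yule-coalescent model: oracle likelihoods,
nesting, entity extraction and fit contracts."""

import warnings

import numpy as np
import pytest

from otudelim import (
    GmycConfig,
    UltrametricTree,
    fit_single_threshold,
    interval_rates,
    mixed_log_likelihood,
    null_log_likelihood,
    simulate_gene_tree,
    simulate_species_tree,
    SimulationConfig,
    tree_from_string,
)
from otudelim.gmyc import cut_at_threshold

FIXTURE = "((A:1,B:1):2.2,(C:1.4,D:1.4):1.8);"  # heights 3.2, 1.4, 1.0


@pytest.fixture
def fixture_tree():
    return UltrametricTree(tree_from_string(FIXTURE))


def bruteforce_loglik(ult, T, lam_y, p_y, lam_c, p_c):
    """From-scratch product-formula evaluation by direct tree interrogation.

    Counts crossing lineages per entity at interval midpoints instead of
    sweeping event-by-event; shares only the node heights with the
    implementation under test.
    """
    tree = ult.tree
    heights = sorted(
        (n.height for n in tree.preorder_internal_node_iter()), reverse=True
    )

    entities = []
    stack = [tree.seed_node]
    while stack:
        n = stack.pop()
        h = 0.0 if n.is_leaf() else n.height
        if n.is_leaf() or h <= T:
            entities.append(
                frozenset(l.taxon.label for l in ([n] if n.is_leaf() else n.leaf_nodes()))
            )
        else:
            stack.extend(n.child_nodes())

    def crossing_edges(t):
        out = []
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            lo = 0.0 if node.is_leaf() else node.height
            hi = node.parent_node.height
            if lo < t < hi:
                out.append(frozenset(l.taxon.label for l in node.leaf_nodes()))
        return out

    bounds = heights + [0.0]
    logL = 0.0
    for i in range(len(bounds) - 1):
        hi, lo = bounds[i], bounds[i + 1]
        x = hi - lo
        t_mid = (hi + lo) / 2.0
        edges = crossing_edges(t_mid)
        if t_mid > T:
            n_yule = len(edges)
            coal = 0.0
        else:
            n_yule = len(entities)
            coal = 0.0
            for e in entities:
                k = sum(1 for leafset in edges if leafset <= e)
                coal += k * (k - 1)
        b = lam_y * n_yule ** p_y + (lam_c * coal ** p_c if coal > 0 else 0.0)
        logL -= b * x
        ends_with_event = i < len(bounds) - 2
        if ends_with_event:
            logL += np.log(b)
    return logL


def test_mixed_loglik_matches_bruteforce_oracle(fixture_tree):
    rng = np.random.default_rng(99)
    for _ in range(20):
        T = float(rng.uniform(0.05, 3.1))
        lam_y, lam_c = rng.uniform(0.05, 5.0, 2)
        p_y, p_c = rng.uniform(0.2, 2.0, 2)
        ours = mixed_log_likelihood(
            interval_rates(fixture_tree, T), lam_y, p_y, lam_c, p_c
        )
        oracle = bruteforce_loglik(fixture_tree, T, lam_y, p_y, lam_c, p_c)
        assert ours == pytest.approx(oracle, abs=1e-8)


def test_null_is_nested_special_case(fixture_tree):
    """Threshold below every node turns the mixed model into the null."""
    rng = np.random.default_rng(5)
    T = 0.5 * fixture_tree.branching_times().min()
    for _ in range(10):
        lam, p = rng.uniform(0.05, 4.0), rng.uniform(0.2, 2.0)
        mixed = mixed_log_likelihood(
            interval_rates(fixture_tree, T), lam, p, rng.uniform(0.1, 5.0), 1.0
        )
        assert mixed == pytest.approx(
            null_log_likelihood(fixture_tree, lam, p), abs=1e-9
        )


def test_null_pure_birth_closed_form(fixture_tree):
    """With p = 1 the null reduces to the standard pure-birth likelihood."""
    lam = 0.7
    h = sorted(fixture_tree.branching_times(), reverse=True)  # 3.2, 1.4, 1.0
    x = [h[0] - h[1], h[1] - h[2], h[2]]
    n = [2, 3, 4]
    expected = sum(
        np.log(lam * n[i]) - lam * n[i] * x[i] for i in range(2)
    ) - lam * n[2] * x[2]
    assert null_log_likelihood(fixture_tree, lam, 1.0) == pytest.approx(
        expected, abs=1e-10
    )


def test_likelihood_invariant_to_tip_relabelling():
    a = UltrametricTree(tree_from_string(FIXTURE))
    b = UltrametricTree(tree_from_string("((D:1,C:1):2.2,(B:1.4,A:1.4):1.8);"))
    la = mixed_log_likelihood(interval_rates(a, 1.2), 0.5, 1.0, 2.0, 1.0)
    lb = mixed_log_likelihood(interval_rates(b, 1.2), 0.5, 1.0, 2.0, 1.0)
    assert la == pytest.approx(lb, abs=1e-12)


def test_cut_at_threshold_degenerate_and_readoff():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ult = UltrametricTree(tree_from_string("((A:1,B:1):2,(C:1,D:1):2);"))
    assert cut_at_threshold(ult, 5.0).n_groups == 1  # above the root
    assert cut_at_threshold(ult, 0.5).n_groups == 4  # below every node
    part = cut_at_threshold(ult, 1.5)
    assert part.as_sets() == frozenset(
        {frozenset({"A", "B"}), frozenset({"C", "D"})}
    )


def test_entities_monotone_in_threshold(fixture_tree):
    ts = np.linspace(0.01, 3.19, 25)
    counts = [cut_at_threshold(fixture_tree, t).n_groups for t in ts]
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_fit_two_deep_clusters():
    """Species divergence far exceeding coalescent depth: two entities,
    significant likelihood-ratio test."""
    sp = tree_from_string("(S01:10.0,S02:10.0);")
    gt = simulate_gene_tree(sp, 10, 0.05, seed=3)
    fit = fit_single_threshold(gt, GmycConfig(seed=0))
    assert fit.n_entities == 2
    assert fit.n_clusters == 2
    assert fit.p_value < 0.05
    assert fit.partition.as_sets() == frozenset({
        frozenset(f"S01_{i:02d}" for i in range(1, 11)),
        frozenset(f"S02_{i:02d}" for i in range(1, 11)),
    })


def test_fit_argmax_contract_and_bound(fixture_tree):
    ds = simulate_species_tree(
        SimulationConfig(n_species=8, crown_age=10.0,
                         min_species_separation=0.0, seed=8)
    )
    ult = UltrametricTree(ds)
    fit = fit_single_threshold(ult, GmycConfig(seed=1))
    best = max(ll for _, ll in fit.candidates)
    assert fit.mixed_logL == pytest.approx(best)
    assert fit.mixed_logL >= fit.null_logL - 1e-6
    assert fit.n_entities >= fit.n_clusters
    assert fit.partition.samples == frozenset(ult.tip_labels())


def test_null_rate_recovery_on_forward_yule():
    """Fixed-exponent null MLE recovers the generating speciation rate.

    Forward pure-birth simulation written independently here; the estimate
    averaged over replicates must fall within two standard errors.
    """
    from otudelim.gmyc import _interval_arrays, _maximize

    lam_true, n_tips, reps = 1.0, 200, 100
    rng = np.random.default_rng(2024)
    estimates = []
    for _ in range(reps):
        # forward simulation: waiting time Exp(k*lam), uniform lineage splits
        depths = {}
        children = {}
        nxt = [0, 1]
        counter = 2
        t = 0.0
        birth = {0: 0.0, 1: 0.0}
        while len(nxt) < n_tips:
            t += rng.exponential(1.0 / (lam_true * len(nxt)))
            i = int(rng.integers(len(nxt)))
            node = nxt[i]
            depths[node] = t
            a, b = counter, counter + 1
            counter += 2
            children[node] = (a, b)
            birth[a] = birth[b] = t
            nxt[i] = a
            nxt.append(b)
        t_end = t + rng.exponential(1.0 / (lam_true * n_tips))

        def newick(node):
            if node in children:
                a, b = children[node]
                bl = depths[node] - birth[node]
                return f"({newick(a)},{newick(b)}):{bl:.10f}"
            return f"t{node}:{t_end - birth[node]:.10f}"

        nwk = f"({newick(0)},{newick(1)});"
        ult = UltrametricTree(tree_from_string(nwk))
        x, ny, cs, ends = _interval_arrays(ult, -1.0)
        ll, theta = _maximize(
            x, ny, cs, ends, mixed=False, free_p=False,
            rng=rng, n_restarts=2, tol=1e-10,
        )
        estimates.append(np.exp(theta[0]))
    mean = np.mean(estimates)
    se = np.std(estimates, ddof=1) / np.sqrt(reps)
    assert abs(mean - lam_true) < 2 * se + 0.02 * lam_true


def test_fit_requires_four_tips():
    ult = UltrametricTree(tree_from_string("((A:1,B:1):1,C:2);"))
    from otudelim.errors import InputError

    with pytest.raises(InputError):
        fit_single_threshold(ult)
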
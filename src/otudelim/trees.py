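"""Tree I/O, neighbor joining, monophyly tests and ultrametric bookkeeping.

Trees are dendropy objects throughout.  Neighbor joining is provided as a
lightweight stand-in inference for testing and simulation work; user-supplied
trees (e.g. from ML or Bayesian programs) always take precedence in the
pipeline.  :class:`UltrametricTree` validates tip-height equality and exposes
the branching times the mixed Yule-coalescent model consumes; exact ties
between event times are perturbed by a negligible amount (<= 1e-9) because
the model requires distinct event times.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .distances import DistanceMatrix
from .errors import TreeError, UltrametricError


def read_tree(path: str | Path, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree from Newick or NEXUS; underscores are literal."""
    if schema not in ("newick", "nexus"):
        raise TreeError(f"unsupported schema {schema!r}")
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema=schema, preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises assorted parse errors
        raise TreeError(f"{path}: cannot parse {schema} tree: {exc}") from exc
    tree.is_rooted = True  # the pipeline treats all input trees as rooted
    _check_unique_tips(tree)
    return tree


def tree_from_string(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:
        raise TreeError(f"cannot parse newick string: {exc}") from exc
    tree.is_rooted = True
    _check_unique_tips(tree)
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path, schema: str = "newick") -> None:
    tree.write(path=str(path), schema=schema, unquoted_underscores=True)


def _check_unique_tips(tree: dendropy.Tree) -> None:
    labels = [lf.taxon.label for lf in tree.leaf_node_iter() if lf.taxon]
    if len(set(labels)) != len(labels):
        dups = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate tip labels: {dups}")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def prune_to(tree: dendropy.Tree, keep: Iterable[str]) -> dendropy.Tree:
    """Copy of ``tree`` retaining only the listed tips."""
    keep = set(keep)
    have = set(tip_labels(tree))
    missing = keep - have
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(sorted(keep))
    return pruned


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(
    dm: DistanceMatrix, outgroup: str | None = None
) -> dendropy.Tree:
    """Classic NJ agglomeration from a distance matrix.

    Ties in the Q criterion are broken by the lowest-index pair.  A negative
    branch length is clamped to zero with the deficit transferred to its
    sibling so the pair's total length is preserved.  The result is rooted on
    ``outgroup`` when given, at the midpoint otherwise.
    """
    n = dm.n
    if n < 3:
        raise TreeError("neighbor joining needs at least 3 samples")
    if np.isnan(dm.values).any() or not np.isfinite(dm.values).all():
        raise TreeError("distance matrix contains non-finite entries")
    if outgroup is not None and outgroup not in dm.sample_ids:
        raise TreeError(f"outgroup {outgroup!r} not in distance matrix")

    taxa = dendropy.TaxonNamespace(dm.sample_ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for sid in dm.sample_ids:
        node = dendropy.Node(taxon=taxa.get_taxon(sid))
        nodes.append(node)
    D = dm.values.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie rule: first (i, j) in row-major order of the minimum
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        elif lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0) + 0.0, max(lj, 0.0) + 0.0  # also normalizes -0.0

        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = float(li)
        nodes[j].edge.length = float(lj)

        # distances from the new node to every other active node
        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_d
        D[:, i] = new_d
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    i, j = active
    root = dendropy.Node()
    half = 0.5 * D[i, j]
    root.add_child(nodes[i])
    root.add_child(nodes[j])
    nodes[i].edge.length = float(half)
    nodes[j].edge.length = float(half)
    tree.seed_node = root
    tree.is_rooted = True

    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        edge_len = og.edge.length or 0.0
        tree.reroot_at_edge(og.edge, update_bipartitions=False)
        # split the outgroup edge evenly around the new root
        for child in tree.seed_node.child_nodes():
            child.edge.length = edge_len / 2.0 if child is og else (
                (child.edge.length or 0.0)
            )
        tree.suppress_unifurcations()
    else:
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.suppress_unifurcations()
    return tree


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------

def is_monophyletic(tree: dendropy.Tree, tips: Iterable[str]) -> tuple[bool, int]:
    """Whether ``tips`` form an exclusive clade on the rooted tree.

    Returns ``(monophyletic, size_of_smallest_containing_clade)``.
    """
    tips = set(tips)
    if not tips:
        raise TreeError("empty tip set")
    have = set(tip_labels(tree))
    unknown = tips - have
    if unknown:
        raise TreeError(f"unknown tips: {sorted(unknown)}")
    if len(tips) == 1:
        return True, 1
    mrca = tree.mrca(taxon_labels=sorted(tips))
    size = len(mrca.leaf_nodes())
    return size == len(tips), size


# ---------------------------------------------------------------------------
# Ultrametric trees
# ---------------------------------------------------------------------------

class UltrametricTree:
    """A rooted ultrametric tree with node heights (time before present).

    Tip heights must be 0 within ``rel_tol`` of the root height.  Heights of
    internal nodes are stored on each node as ``node.height``; exact ties are
    perturbed downward by at most 1e-9 (with a warning) so every branching
    event has a distinct time.
    """

    def __init__(self, tree: dendropy.Tree, rel_tol: float = 1e-6):
        _check_unique_tips(tree)
        self.tree = tree
        depths: dict[dendropy.Node, float] = {}
        for node in tree.preorder_node_iter():
            parent = node.parent_node
            edge = node.edge.length if node.edge.length is not None else 0.0
            if edge < 0:
                raise TreeError("negative branch length")
            depths[node] = (depths[parent] if parent else 0.0) + (
                edge if parent else 0.0
            )
        tips = [n for n in tree.leaf_node_iter()]
        tip_depths = np.array([depths[t] for t in tips])
        H = float(tip_depths.max())
        if H <= 0:
            raise UltrametricError("tree has zero height")
        worst = int(np.argmax(np.abs(tip_depths - H)))
        if np.abs(tip_depths - H).max() > rel_tol * H:
            raise UltrametricError(
                f"tree not ultrametric: tip {tips[worst].taxon.label!r} deviates "
                f"by {abs(tip_depths[worst] - H):.6g} from root height {H:.6g}"
            )
        self.root_height = H
        for node in tree.preorder_node_iter():
            node.height = 0.0 if node.is_leaf() else H - depths[node]
        self._break_ties()

    def _break_ties(self) -> None:
        internals = sorted(
            self.tree.preorder_internal_node_iter(), key=lambda n: -n.height
        )
        perturbed = 0
        prev = np.inf
        for node in internals:
            if node.height >= prev:
                new = np.nextafter(prev, -np.inf)
                # keep perturbation far below any meaningful scale
                new = min(new, prev - 1e-12 * max(1.0, self.root_height))
                if prev - new > 1e-9:
                    raise UltrametricError("cannot break height ties within 1e-9")
                node.height = new
                perturbed += 1
            prev = node.height
        if perturbed:
            warnings.warn(
                f"{perturbed} tied branching time(s) perturbed by <= 1e-9"
            )

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def branching_times(self) -> np.ndarray:
        """Internal-node heights, sorted ascending; length n_tips-1 when binary."""
        times = np.sort(
            [n.height for n in self.tree.preorder_internal_node_iter()]
        )
        if (times <= 0).any():
            raise UltrametricError("non-positive branching time after tie-breaking")
        return times

    def tip_labels(self) -> list[str]:
        return tip_labels(self.tree)


def branching_times(t: UltrametricTree) -> np.ndarray:
    return t.branching_times()


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    pdm = tree.phylogenetic_distance_matrix()
    ta = tree.taxon_namespace.get_taxon(a)
    tb = tree.taxon_namespace.get_taxon(b)
    return float(pdm.distance(ta, tb))
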
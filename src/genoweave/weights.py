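"""Topology weighting: subtree-topology counts for grouped samples.

For g predefined groups there are (2g-3)!! = (2g-3)!/(2^(g-2) (g-2)!) distinct
rooted bifurcating topologies (3 for g=3, 15 for g=4, 105 for g=5).  The
weight of each topology in a local tree is the fraction of subtrees — one tip
drawn from every group, all prod_j sum_i k_ij combinations — whose induced
rooted topology matches it.  Combinations whose induced subtree passes
through a polytomy are tallied in a separate "unresolved" bin; weights can be
reported either over all combinations or renormalized over resolved ones.

Counting is exact.  Two equivalent routes are provided: exhaustive
enumeration (optionally collapsing monophyletic single-group clades, which
leaves counts unchanged but shrinks the enumeration), and for g=3 a
linear-time scan over internal nodes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from ._treeview import TreeView, tskit_tip_labels

__all__ = [
    "TopologySet",
    "enumerate_topologies",
    "count_topologies",
    "TopologyWeightTrack",
    "weight_tree_sequence",
    "load_groups_tsv",
    "tip_groups_from_individuals",
]


def _canon(shape) -> str:
    """Canonical string for a nested-tuple rooted topology."""
    if isinstance(shape, str):
        return shape
    return "(" + ",".join(sorted(_canon(s) for s in shape)) + ")"


@dataclass(frozen=True)
class TopologySet:
    """All rooted bifurcating leaf-labeled topologies for a tuple of groups."""

    groups: tuple[str, ...]
    topologies: tuple[str, ...]  # canonical newick-like strings, sorted

    @property
    def T(self) -> int:
        return len(self.topologies)

    def index(self, canonical: str) -> int:
        return self.topologies.index(canonical)

    def newicks(self) -> list[str]:
        return [t + ";" for t in self.topologies]


def enumerate_topologies(groups) -> TopologySet:
    """Enumerate rooted bifurcating topologies on the given group labels.

    The count matches the closed form (2g-3)!/(2^(g-2) (g-2)!).
    """
    labels = tuple(groups)
    g = len(labels)
    if g < 3:
        raise ValueError("need at least 3 groups")
    trees = [labels[0]]
    for lab in labels[1:]:
        nxt = []
        for t in trees:
            nxt.extend(_insert_everywhere(t, lab))
        trees = nxt
    canon = sorted({_canon(t) for t in trees})
    expected = factorial(2 * g - 3) // (2 ** (g - 2) * factorial(g - 2))
    assert len(canon) == expected, (len(canon), expected)
    return TopologySet(labels, tuple(canon))


def _insert_everywhere(tree, label):
    """All ways to attach a new tip: onto any edge or above the root."""
    out = [(tree, label)]  # new root above the old one

    def rec(node):
        if isinstance(node, str):
            return []
        results = []
        a, b = node
        for sub, other, flip in ((a, b, False), (b, a, True)):
            # graft onto the edge above `sub`
            grafted = ((sub, label), other) if not flip else (other, (sub, label))
            results.append(grafted)
            for r in rec(sub):
                results.append((r, other) if not flip else (other, r))
        return results

    out.extend(rec(tree))
    return out


# ---------------------------------------------------------------------------
# counting


def _group_tip_nodes(view: TreeView, tip_groups: dict[str, str], groups) -> dict:
    by_group: dict[str, list[int]] = {g: [] for g in groups}
    for label, node in view.tips.items():
        g = tip_groups.get(label)
        if g in by_group:
            by_group[g].append(node)
    empty = [g for g, tips in by_group.items() if not tips]
    if empty:
        raise ValueError(f"groups with no tips in tree: {empty}")
    return by_group


def _induced_topology(view: TreeView, units: list[tuple[int, str]]):
    """Canonical induced topology of the chosen units, or None if unresolved."""
    if len(units) == 1:
        return units[0][1]
    m = view.mrca_many([u for u, _ in units])
    parts: dict[int, list[tuple[int, str]]] = {}
    for u, lab in units:
        parts.setdefault(view.child_toward(m, u), []).append((u, lab))
    if len(parts) != 2:
        return None
    subs = []
    for part in parts.values():
        s = _induced_topology(view, part)
        if s is None:
            return None
        subs.append(s)
    return "(" + ",".join(sorted(subs)) + ")"


def _collapse_units(view: TreeView, by_group: dict[str, list[int]]):
    """Merge maximal clades whose tips all belong to one group.

    Returns per-group lists of (representative node, multiplicity).  Counting
    over these weighted units equals exhaustive enumeration because all tips
    of a pure clade are interchangeable in any induced topology.
    """
    group_of_node = {}
    for g, tips in by_group.items():
        for t in tips:
            group_of_node[t] = g
    pure: dict[int, str | None] = {}
    size: dict[int, int] = {}
    for u in reversed(view.preorder):
        kids = view.children[u]
        if not kids:
            pure[u] = group_of_node.get(u)
            size[u] = 1 if u in group_of_node else 0
        else:
            gs = {pure[c] for c in kids}
            pure[u] = gs.pop() if len(gs) == 1 else None
            size[u] = sum(size[c] for c in kids)
    units: dict[str, list[tuple[int, int]]] = {g: [] for g in by_group}
    stack = [view.root]
    while stack:
        u = stack.pop()
        g = pure[u]
        if g is not None:
            units[g].append((u, size[u]))
        else:
            stack.extend(view.children[u])
    return units


def _count_enumerate(view, by_group, groups, topo_set, collapse=True):
    counts = np.zeros(topo_set.T, dtype=np.int64)
    unresolved = 0
    if collapse:
        units = _collapse_units(view, by_group)
    else:
        units = {g: [(t, 1) for t in tips] for g, tips in by_group.items()}
    for combo in itertools.product(*(units[g] for g in groups)):
        weight = 1
        chosen = []
        for (node, mult), g in zip(combo, groups):
            weight *= mult
            chosen.append((node, g))
        topo = _induced_topology(view, chosen)
        if topo is None:
            unresolved += weight
        else:
            counts[topo_set.index(topo)] += weight
    return counts, int(unresolved)


def _count_triples(view, by_group, groups, topo_set):
    """Linear-time exact counts for g = 3.

    For each internal node u, the pairs (a, b) whose MRCA is exactly u number
    n_a(u) n_b(u) - sum_children n_a(c) n_b(c); each such pair forms the
    resolved triple ((a,b),c) with every c-tip outside u's subtree.  The
    remainder of the N_a N_b N_c combinations is unresolved.
    """
    a, b, c = groups
    n = {g: np.zeros(view.n_nodes, dtype=np.int64) for g in groups}
    for g, tips in by_group.items():
        for t in tips:
            n[g][t] = 1
    for u in reversed(view.preorder):
        for child in view.children[u]:
            for g in groups:
                n[g][u] += n[g][child]
    N = {g: int(n[g][view.root]) for g in groups}
    counts = np.zeros(topo_set.T, dtype=np.int64)
    for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
        ti = topo_set.index(_canon(((x, y), z)))
        tot = 0
        for u in view.preorder:
            kids = view.children[u]
            if not kids:
                continue
            split = int(n[x][u]) * int(n[y][u]) - sum(
                int(n[x][ch]) * int(n[y][ch]) for ch in kids
            )
            if split:
                tot += split * (N[z] - int(n[z][u]))
        counts[ti] = tot
    total = N[a] * N[b] * N[c]
    return counts, int(total - counts.sum())


def count_topologies(
    tree,
    tip_groups: dict[str, str],
    topology_set: TopologySet | None = None,
    method: str = "auto",
) -> tuple[np.ndarray, int, TopologySet]:
    """Count subtree topologies over all one-tip-per-group combinations.

    ``tree`` may be a GenTree, a tskit tree, a TreeView or a newick string.
    Returns (counts per topology, unresolved count, topology set).
    """
    view = _as_view(tree)
    if topology_set is None:
        topology_set = enumerate_topologies(sorted(set(tip_groups.values())))
    groups = topology_set.groups
    by_group = _group_tip_nodes(view, tip_groups, groups)
    if method == "auto":
        method = "triples" if len(groups) == 3 else "collapse"
    if method == "triples":
        if len(groups) != 3:
            raise ValueError("the triples method applies to exactly 3 groups")
        counts, unresolved = _count_triples(view, by_group, groups, topology_set)
    elif method == "collapse":
        counts, unresolved = _count_enumerate(view, by_group, groups, topology_set)
    elif method == "exhaustive":
        counts, unresolved = _count_enumerate(
            view, by_group, groups, topology_set, collapse=False
        )
    else:
        raise ValueError(f"unknown method: {method}")
    return counts, unresolved, topology_set


def _as_view(tree) -> TreeView:
    if isinstance(tree, TreeView):
        return tree
    if isinstance(tree, str):
        return TreeView.from_newick(tree)
    if hasattr(tree, "nodes") and hasattr(tree, "canonical"):
        return TreeView.from_gentree(tree)
    if hasattr(tree, "tree_sequence"):
        return TreeView.from_tskit(tree)
    raise TypeError(f"cannot adapt {type(tree)} to a tree view")


# ---------------------------------------------------------------------------
# tracks


@dataclass
class TopologyWeightTrack:
    """Per-interval topology counts over a chromosome span."""

    breakpoints: np.ndarray  # (m + 1,)
    counts: np.ndarray  # (m, T)
    unresolved: np.ndarray  # (m,)
    topology_set: TopologySet
    chrom: str = "chr"

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.unresolved = np.asarray(self.unresolved, dtype=np.int64)

    @property
    def num_intervals(self) -> int:
        return self.counts.shape[0]

    @property
    def L(self) -> float:
        return float(self.breakpoints[-1])

    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1) + self.unresolved

    def spans(self) -> np.ndarray:
        return np.diff(self.breakpoints)

    def weights(self, renormalize: str = "all") -> np.ndarray:
        """Per-interval weights.

        ``renormalize="all"``: counts (plus the unresolved bin as a final
        column) divided by the total combination count, summing to 1.
        ``renormalize="resolved"``: resolved counts only, renormalized;
        intervals with no resolved combination yield NaN rows.
        """
        if renormalize == "all":
            tot = self.totals().astype(float)[:, None]
            w = np.hstack([self.counts, self.unresolved[:, None]]) / tot
            return w
        if renormalize == "resolved":
            res = self.counts.sum(axis=1).astype(float)[:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(res > 0, self.counts / res, np.nan)
        raise ValueError("renormalize must be 'all' or 'resolved'")

    def interval_at(self, x: float) -> int:
        i = int(np.searchsorted(self.breakpoints, x, side="right") - 1)
        return min(max(i, 0), self.num_intervals - 1)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.breakpoints[:-1],
                "end": self.breakpoints[1:],
            }
        )
        for j in range(self.topology_set.T):
            df[f"topo{j + 1}"] = self.counts[:, j]
        df["unresolved"] = self.unresolved
        return df

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for j, nwk in enumerate(self.topology_set.newicks()):
                fh.write(f"#topo{j + 1}\t{nwk}\n")
            fh.write(f"#groups\t{','.join(self.topology_set.groups)}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TopologyWeightTrack":
        topos, groups = [], None
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, val = line[1:].rstrip("\n").split("\t")
                if key == "groups":
                    groups = tuple(val.split(","))
                else:
                    topos.append(val.rstrip(";"))
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        ts = TopologySet(groups, tuple(topos))
        T = ts.T
        counts = df[[f"topo{j + 1}" for j in range(T)]].to_numpy(dtype=np.int64)
        bps = np.concatenate([df["start"].to_numpy(), [df["end"].iloc[-1]]])
        return cls(
            bps,
            counts,
            df["unresolved"].to_numpy(dtype=np.int64),
            ts,
            chrom=str(df["chrom"].iloc[0]),
        )


def weight_tree_sequence(
    ts,
    tip_groups: dict[str, str],
    topology_set: TopologySet | None = None,
    method: str = "auto",
) -> TopologyWeightTrack:
    """Topology counts for every local tree of an ARG.

    ``ts`` may be a LocalTreeSequence, a tskit TreeSequence, or a list of
    ``(start, end, newick)`` intervals.
    """
    if topology_set is None:
        topology_set = enumerate_topologies(sorted(set(tip_groups.values())))
    views: list[TreeView] = []
    bps: list[float] = []
    chrom = "chr"
    if hasattr(ts, "trees") and hasattr(ts, "breakpoints") and hasattr(ts, "ploidy_map"):
        views = [TreeView.from_gentree(t) for t in ts.trees]
        bps = list(ts.breakpoints)
        chrom = ts.chrom
    elif hasattr(ts, "num_trees") and hasattr(ts, "tables"):
        labels = tskit_tip_labels(ts)
        bps = [0.0]
        for tree in ts.trees():
            views.append(TreeView.from_tskit(tree, labels))
            bps.append(float(tree.interval.right))
    else:
        intervals = list(ts)
        bps = [intervals[0][0]]
        for start, end, nwk in intervals:
            if abs(start - bps[-1]) > 1e-9:
                raise ValueError("newick intervals must tile the span contiguously")
            views.append(TreeView.from_newick(nwk))
            bps.append(end)
    counts = np.zeros((len(views), topology_set.T), dtype=np.int64)
    unresolved = np.zeros(len(views), dtype=np.int64)
    for i, view in enumerate(views):
        c, u, _ = count_topologies(view, tip_groups, topology_set, method)
        counts[i] = c
        unresolved[i] = u
    return TopologyWeightTrack(np.asarray(bps), counts, unresolved, topology_set, chrom)


def load_groups_tsv(path) -> dict[str, str]:
    """Two-column TSV (individual, group; no header) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "group"])
    return dict(zip(df["individual"].astype(str), df["group"].astype(str)))


def tip_groups_from_individuals(
    group_of_individual: dict[str, str], ploidy_map
) -> dict[str, str]:
    """Expand an individual->group map to tip labels ``<ind>_<slot>``.

    Individuals absent from the map (e.g. outgroups) get no tips.
    """
    out = {}
    for ind, k in zip(ploidy_map.individuals, ploidy_map.ploidies):
        g = group_of_individual.get(ind)
        if g is None:
            continue
        for j in range(k):
            out[f"{ind}_{j + 1}"] = g
    return out
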
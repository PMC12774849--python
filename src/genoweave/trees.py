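"""Perfect-phylogeny tree building for any (mixed) ploidy.

A ``GenTree`` is a rooted tree with one leaf per haplotype (leaves of the same
individual are interchangeable) and internal nodes that each carry a site
pattern.  The defining invariant is child-sum conservation: the element-wise
sum of the children's patterns equals the parent's pattern.  Nodes are added
greedily: to place a pattern, descend to the deepest existing node whose
pattern contains it, then accumulate children from that node's current
children (leaves first, then internal nodes by decreasing derived total)
while the running element-wise sum stays within the pattern; the node commits
exactly when the sum matches.  A pattern whose child search fails is
discarded.  After the first pass, extra passes re-attempt "duplicable"
patterns (those that may legitimately correspond to several nodes in one
tree) until nothing more can be added.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .collect import SiteCollection
from .patterns import PloidyMap, SitePattern

__all__ = ["GenTree", "build_tree", "star_tree"]


@dataclass
class _Node:
    id: int
    pattern: np.ndarray
    parent: int | None
    children: list[int] = field(default_factory=list)
    label: str | None = None  # leaves only
    individual: int | None = None  # leaves only


class GenTree:
    """Rooted genealogy with per-node derived-count patterns.

    Node ids are persistent: when a tree seeds the next site's tree during
    sequential building, retained nodes keep their ids, which is what lets the
    output be expressed as a succinct tree sequence with shared nodes.
    """

    def __init__(self, ploidy_map: PloidyMap, id_counter: itertools.count | None = None):
        self.ploidy_map = ploidy_map
        self._ids = id_counter if id_counter is not None else itertools.count()
        n = ploidy_map.n
        self.nodes: dict[int, _Node] = {}
        self.root = next(self._ids)
        self.nodes[self.root] = _Node(
            self.root, ploidy_map.array().copy(), None
        )
        self.leaves: list[int] = []
        for i, (ind, k) in enumerate(
            zip(ploidy_map.individuals, ploidy_map.ploidies)
        ):
            for j in range(k):
                nid = next(self._ids)
                pat = np.zeros(n, dtype=np.int64)
                pat[i] = 1
                self.nodes[nid] = _Node(
                    nid, pat, self.root, label=f"{ind}_{j + 1}", individual=i
                )
                self.nodes[self.root].children.append(nid)
                self.leaves.append(nid)

    # -- structure queries ------------------------------------------------

    def is_leaf(self, nid: int) -> bool:
        return self.nodes[nid].label is not None

    def internal_ids(self) -> list[int]:
        """Internal nodes: not leaves and not the root."""
        return [
            nid
            for nid, node in self.nodes.items()
            if node.label is None and nid != self.root
        ]

    def internal_patterns(self) -> list[tuple[int, ...]]:
        return [tuple(self.nodes[nid].pattern) for nid in self.internal_ids()]

    def pattern_copies(self, counts) -> int:
        t = tuple(counts)
        return sum(1 for p in self.internal_patterns() if p == t)

    def check_sums(self) -> None:
        """Assert child-sum conservation at every non-leaf node."""
        for nid, node in self.nodes.items():
            if node.label is not None:
                continue
            total = np.zeros(self.ploidy_map.n, dtype=np.int64)
            for c in node.children:
                total += self.nodes[c].pattern
            if not np.array_equal(total, node.pattern):
                raise AssertionError(f"child-sum violated at node {nid}")

    # -- editing ----------------------------------------------------------

    def copy(self) -> "GenTree":
        new = GenTree.__new__(GenTree)
        new.ploidy_map = self.ploidy_map
        new._ids = self._ids  # share the counter so new ids stay unique
        new.root = self.root
        new.leaves = list(self.leaves)
        new.nodes = {
            nid: _Node(
                nid,
                node.pattern.copy(),
                node.parent,
                list(node.children),
                node.label,
                node.individual,
            )
            for nid, node in self.nodes.items()
        }
        return new

    def splice_out(self, nid: int) -> None:
        """Remove an internal node, promoting its children to its parent."""
        node = self.nodes[nid]
        if node.label is not None or nid == self.root:
            raise ValueError("can only splice out internal nodes")
        parent = self.nodes[node.parent]
        at = parent.children.index(nid)
        parent.children[at:at + 1] = node.children
        for c in node.children:
            self.nodes[c].parent = parent.id
        del self.nodes[nid]

    def _host_for(self, pattern: np.ndarray) -> tuple[int, bool]:
        """Deepest node strictly containing ``pattern``; flags a seen exact copy.

        The host is where a node for ``pattern`` would be inserted (its chosen
        children must currently be siblings under the host).  Equal-pattern
        nodes are never descended into: a duplicate copy must be a sibling of
        the existing one, not its child.
        """
        host = self.root
        exact = False
        while True:
            descend = None
            for c in self.nodes[host].children:
                node = self.nodes[c]
                if node.label is not None:
                    continue
                if np.all(node.pattern >= pattern):
                    if np.array_equal(node.pattern, pattern):
                        exact = True
                    else:
                        descend = c
                        break
            if descend is None:
                return host, exact
            host = descend

    def try_add(self, pattern, allow_existing: bool = False) -> int | None:
        """Attempt to add an internal node for ``pattern``; return its id or None.

        With ``allow_existing`` (multipass), an exact-pattern node already in
        the tree does not stop the search for an additional disjoint copy.
        """
        pattern = np.asarray(pattern, dtype=np.int64)
        host, exact = self._host_for(pattern)
        if exact and not allow_existing:
            return None
        parent = self.nodes[host]
        chosen: list[int] = []
        total = np.zeros(self.ploidy_map.n, dtype=np.int64)
        for c in self._candidate_order(parent.children):
            cpat = self.nodes[c].pattern
            if np.array_equal(cpat, pattern):
                continue  # a single equal child would make a unary node
            if np.all(total + cpat <= pattern):
                chosen.append(c)
                total += cpat
                if np.array_equal(total, pattern):
                    break
        if len(chosen) < 2 or not np.array_equal(total, pattern):
            return None
        nid = next(self._ids)
        self.nodes[nid] = _Node(nid, pattern.copy(), host, chosen)
        for c in chosen:
            parent.children.remove(c)
            self.nodes[c].parent = nid
        parent.children.append(nid)
        return nid

    def _candidate_order(self, children: list[int]) -> list[int]:
        """Greedy child order: leaves (in leaf order), then internal nodes by
        decreasing derived total (ties by id, for determinism)."""
        leaves = [c for c in children if self.nodes[c].label is not None]
        leaves.sort(key=lambda c: self.leaves.index(c))
        internals = [c for c in children if self.nodes[c].label is None]
        internals.sort(key=lambda c: (-int(self.nodes[c].pattern.sum()), c))
        return leaves + internals

    def has_pattern(self, counts) -> bool:
        t = np.asarray(counts, dtype=np.int64)
        _, exact = self._host_for(t)
        return exact

    # -- rendering --------------------------------------------------------

    def newick(self, nid: int | None = None) -> str:
        if nid is None:
            return self._nwk(self.root) + ";"
        return self._nwk(nid)

    def _nwk(self, nid: int) -> str:
        node = self.nodes[nid]
        if node.label is not None:
            return node.label
        return "(" + ",".join(self._nwk(c) for c in node.children) + ")"

    def canonical(self) -> str:
        """Order-independent topology string (children sorted recursively)."""
        return self._canon(self.root)

    def _canon(self, nid: int) -> str:
        node = self.nodes[nid]
        if node.label is not None:
            return node.label
        parts = sorted(self._canon(c) for c in node.children)
        return "(" + ",".join(parts) + ")"

    def unordered_topology(self) -> frozenset:
        """Topology as nested frozensets of leaf labels (rotation-invariant)."""
        return self._fs(self.root)

    def _fs(self, nid: int):
        node = self.nodes[nid]
        if node.label is not None:
            return node.label
        return frozenset(self._fs(c) for c in node.children)


def star_tree(ploidy_map: PloidyMap) -> GenTree:
    """Unresolved starting tree: a root plus one leaf per haplotype."""
    return GenTree(ploidy_map)


def _attempt_order(members) -> list:
    """Internal-eligible patterns in order of nearest-variant distance from the
    focal site; ties by genomic position, then by larger derived total."""
    elig = [m for m in members if m.pattern.internal_eligible]
    elig.sort(
        key=lambda m: (m.distance, m.pattern.position, -m.pattern.derived_total)
    )
    return elig


def build_tree(
    collection: SiteCollection,
    ploidy_map: PloidyMap,
    seed_tree: GenTree | None = None,
    max_passes: int = 8,
) -> GenTree:
    """Build the local genealogy for one site from its pattern collection."""
    tree = seed_tree.copy() if seed_tree is not None else star_tree(ploidy_map)
    ordered = _attempt_order(collection.members)
    H = ploidy_map.H
    for m in ordered:
        tree.try_add(m.counts, allow_existing=False)
    # multipass: re-attempt duplicable patterns until nothing new fits
    duplicable = [m for m in ordered if m.pattern.duplicable]
    for _ in range(max_passes):
        added = False
        for m in duplicable:
            cap = H // max(m.pattern.derived_total, 1)
            if tree.pattern_copies(m.counts) >= cap:
                continue
            if tree.try_add(m.counts, allow_existing=True) is not None:
                added = True
        if not added:
            break
    return tree
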
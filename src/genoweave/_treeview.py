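"""Lightweight rooted-tree adapter over GenTree, tskit and newick trees.

Gives the weighting and metric code one array-based view (parent pointers,
depths, labeled tips) regardless of where a tree came from.  Tip labels follow
the ``<individual>_<slot>`` convention, so the individual a tip belongs to is
recoverable with ``label.rsplit("_", 1)[0]``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["TreeView", "tskit_tip_labels"]


class TreeView:
    def __init__(self, parent: list[int], children: list[list[int]], tips: dict[str, int]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.children = children
        self.tips = tips  # label -> node index
        n = len(parent)
        self.depth = np.zeros(n, dtype=np.int64)
        roots = [i for i in range(n) if parent[i] == -1]
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, got {len(roots)}")
        self.root = roots[0]
        stack = [self.root]
        order = []
        while stack:
            u = stack.pop()
            order.append(u)
            for c in children[u]:
                self.depth[c] = self.depth[u] + 1
                stack.append(c)
        self.preorder = order

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def tip_individual(self, label: str) -> str:
        return label.rsplit("_", 1)[0]

    def mrca(self, u: int, v: int) -> int:
        du, dv = self.depth[u], self.depth[v]
        while du > dv:
            u = self.parent[u]
            du -= 1
        while dv > du:
            v = self.parent[v]
            dv -= 1
        while u != v:
            u = self.parent[u]
            v = self.parent[v]
        return u

    def mrca_many(self, nodes) -> int:
        it = iter(nodes)
        m = next(it)
        for v in it:
            m = self.mrca(m, v)
        return m

    def child_toward(self, ancestor: int, node: int) -> int:
        """The child of ``ancestor`` on the path down to ``node``."""
        target = self.depth[ancestor] + 1
        while self.depth[node] > target:
            node = self.parent[node]
        return node

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_gentree(cls, tree) -> "TreeView":
        ids = sorted(tree.nodes)
        idx = {nid: i for i, nid in enumerate(ids)}
        parent = [
            idx[tree.nodes[nid].parent] if tree.nodes[nid].parent is not None else -1
            for nid in ids
        ]
        children = [[idx[c] for c in tree.nodes[nid].children] for nid in ids]
        tips = {
            tree.nodes[nid].label: idx[nid]
            for nid in ids
            if tree.nodes[nid].label is not None
        }
        return cls(parent, children, tips)

    @classmethod
    def from_tskit(cls, tree, labels: dict[int, str] | None = None) -> "TreeView":
        """Adapter over one tskit local tree.

        ``labels`` maps sample node id to tip label; defaults to the
        individual-based labels of :func:`tskit_tip_labels`.
        """
        if labels is None:
            labels = tskit_tip_labels(tree.tree_sequence)
        nodes = list(tree.preorder())
        idx = {u: i for i, u in enumerate(nodes)}
        parent = [
            idx[tree.parent(u)] if tree.parent(u) != -1 else -1 for u in nodes
        ]
        children = [[idx[c] for c in tree.children(u)] for u in nodes]
        tips = {labels[u]: idx[u] for u in nodes if u in labels}
        return cls(parent, children, tips)

    @classmethod
    def from_newick(cls, newick: str) -> "TreeView":
        import dendropy

        t = dendropy.Tree.get(data=newick, schema="newick")
        nodes = list(t.preorder_node_iter())
        idx = {id(n): i for i, n in enumerate(nodes)}
        parent = [
            idx[id(n.parent_node)] if n.parent_node is not None else -1 for n in nodes
        ]
        children = [[idx[id(c)] for c in n.child_nodes()] for n in nodes]
        tips = {
            n.taxon.label.replace(" ", "_"): idx[id(n)]
            for n in nodes
            if n.is_leaf() and n.taxon is not None
        }
        return cls(parent, children, tips)


def tskit_tip_labels(ts, individual_names: list[str] | None = None) -> dict[int, str]:
    """Label each sample node ``<individual>_<slot>``.

    Individual names come from individual metadata (``{"name": ...}``) when
    present, then from ``individual_names`` by table index, falling back to
    ``ind<i>``.  Samples without an individual are labeled ``hap<j>_1``.
    """
    names: dict[int, str] = {}
    for i, ind in enumerate(ts.individuals()):
        name = None
        md = ind.metadata
        if isinstance(md, dict):
            name = md.get("name")
        if name is None and individual_names is not None and i < len(individual_names):
            name = individual_names[i]
        names[i] = name if name is not None else f"ind{i}"
    labels: dict[int, str] = {}
    slot: dict[int, int] = {}
    for u in ts.samples():
        i = ts.node(u).individual
        if i == -1:
            labels[u] = f"hap{u}_1"
        else:
            slot[i] = slot.get(i, 0) + 1
            labels[u] = f"{names[i]}_{slot[i]}"
    return labels
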
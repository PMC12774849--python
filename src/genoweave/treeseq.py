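"""Sequential tree building along a chromosome and tree-sequence export.

A tree is built at every variant site, seeding each build with the previous
site's tree minus internal nodes whose patterns are absent from the new
site's collection (and minus all but one copy of any duplicated pattern,
which the multipass step may re-add).  Consecutive sites whose trees are
identical are merged into one genomic span.  Breakpoints are the midpoints
between the last variant of one span and the first variant of the next; the
first span starts at 0 and the last ends at the chromosome length.

Node identities persist across adjacent trees wherever nodes are retained,
so the result maps directly onto tskit's succinct tree sequence tables.
Internal node times are NOT inferred — the method reconstructs topology only.
Export uses each node's derived-allele total as its time (child-sum
conservation guarantees parents strictly exceed children), which is valid for
tskit but carries no temporal meaning.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
import tskit

from .collect import SiteCollection, collect_sites
from .patterns import GenotypeMatrix, PloidyMap, SitePattern, extract_patterns
from .trees import GenTree, build_tree, star_tree

__all__ = [
    "LocalTreeSequence",
    "sequential_build",
    "infer_local_trees",
    "write_newick",
    "read_newick",
]


@dataclass
class LocalTreeSequence:
    """Ordered local trees with half-open genomic spans tiling [0, L)."""

    trees: list[GenTree]
    breakpoints: np.ndarray  # length len(trees) + 1; [0, ..., L]
    ploidy_map: PloidyMap
    chrom: str = "chr"

    def __post_init__(self):
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        if len(self.breakpoints) != len(self.trees) + 1:
            raise ValueError("need len(trees) + 1 breakpoints")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("spans must have positive length")

    @property
    def L(self) -> float:
        return float(self.breakpoints[-1])

    @property
    def num_trees(self) -> int:
        return len(self.trees)

    def spans(self) -> list[tuple[float, float]]:
        return [
            (float(self.breakpoints[i]), float(self.breakpoints[i + 1]))
            for i in range(self.num_trees)
        ]

    def tree_at(self, x: float) -> GenTree:
        i = int(np.searchsorted(self.breakpoints, x, side="right") - 1)
        return self.trees[min(max(i, 0), self.num_trees - 1)]

    def to_tskit(self) -> tskit.TreeSequence:
        """Export as a succinct tree sequence (node times non-inferential)."""
        tables = tskit.TableCollection(sequence_length=self.L)
        tables.individuals.metadata_schema = tskit.MetadataSchema.permissive_json()
        pm = self.ploidy_map
        for ind in pm.individuals:
            tables.individuals.add_row(metadata={"name": ind})
        H = pm.H
        node_map: dict[int, int] = {}

        def tsk_node(tree: GenTree, nid: int) -> int:
            if nid in node_map:
                return node_map[nid]
            node = tree.nodes[nid]
            if node.label is not None:
                tid = tables.nodes.add_row(
                    flags=tskit.NODE_IS_SAMPLE, time=0.0, individual=node.individual
                )
            else:
                time = float(node.pattern.sum()) if nid != tree.root else float(H + 1)
                tid = tables.nodes.add_row(flags=0, time=time)
            node_map[nid] = tid
            return tid

        # ensure sample nodes are allocated first, in haplotype order
        first = self.trees[0]
        tsk_node(first, first.root)
        for leaf in first.leaves:
            tsk_node(first, leaf)

        for tree, (left, right) in zip(self.trees, self.spans()):
            for nid, node in tree.nodes.items():
                if node.parent is None:
                    continue
                tables.edges.add_row(
                    left=left,
                    right=right,
                    parent=tsk_node(tree, node.parent),
                    child=tsk_node(tree, nid),
                )
        tables.sort()
        tables.edges.squash()
        tables.sort()
        tables.build_index()
        return tables.tree_sequence()

    def node_sharing_stats(self) -> dict:
        """How many internal nodes each adjacent tree pair shares (by id)."""
        shared = []
        for a, b in zip(self.trees[:-1], self.trees[1:]):
            ia, ib = set(a.internal_ids()), set(b.internal_ids())
            shared.append(len(ia & ib))
        return {"shared_internal_nodes": shared}


def _strip_for_seed(tree: GenTree, collection: SiteCollection) -> GenTree:
    """Previous tree minus non-shared internal nodes and duplicate extras."""
    seed = tree.copy()
    wanted = Counter(tuple(m.counts) for m in collection.members)
    seen: Counter = Counter()
    # deterministic order: smaller id = older node, kept preferentially
    for nid in sorted(seed.internal_ids()):
        pat = tuple(seed.nodes[nid].pattern)
        if wanted[pat] == 0:
            seed.splice_out(nid)
        else:
            seen[pat] += 1
            if seen[pat] > 1:  # strip multipass copies; rebuilt if still wanted
                seed.splice_out(nid)
    return seed


def sequential_build(
    collections: list[SiteCollection],
    ploidy_map: PloidyMap,
    L: float,
    chrom: str = "chr",
) -> LocalTreeSequence:
    """Build per-site trees left to right with node reuse; merge equal trees."""
    if not collections:
        return LocalTreeSequence(
            [star_tree(ploidy_map)], np.array([0.0, float(L)]), ploidy_map, chrom
        )
    trees: list[GenTree] = []
    first_site: list[int] = []
    last_site: list[int] = []
    prev: GenTree | None = None
    for i, coll in enumerate(collections):
        if prev is None:
            t = build_tree(coll, ploidy_map)
        else:
            seed = _strip_for_seed(prev, coll)
            t = build_tree(coll, ploidy_map, seed_tree=seed)
        if prev is not None and t.canonical() == prev.canonical():
            last_site[-1] = i  # same topology: extend the current span
        else:
            trees.append(t)
            first_site.append(i)
            last_site.append(i)
            prev = t
    positions = [c.focal_position for c in collections]
    bps = [0.0]
    for j in range(1, len(trees)):
        left_pos = positions[last_site[j - 1]]
        right_pos = positions[first_site[j]]
        bps.append((left_pos + right_pos) / 2.0)
    bps.append(float(L))
    return LocalTreeSequence(trees, np.array(bps), ploidy_map, chrom)


def infer_local_trees(
    matrix: GenotypeMatrix,
    L: float | None = None,
    second_chances: bool = True,
) -> LocalTreeSequence:
    """Full pipeline from a polarized matrix: patterns -> collections -> trees."""
    patterns = extract_patterns(matrix)
    if L is None:
        L = float(matrix.positions[-1]) + 1 if matrix.n_sites else 1.0
    collections = collect_sites(patterns, matrix.ploidy_map, second_chances)
    return sequential_build(collections, matrix.ploidy_map, L, matrix.chrom)


def write_newick(lts: LocalTreeSequence, path) -> None:
    """Per-interval newick: TSV with chrom, start, end, newick columns."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tnewick\n")
        for tree, (left, right) in zip(lts.trees, lts.spans()):
            fh.write(f"{lts.chrom}\t{left:g}\t{right:g}\t{tree.newick()}\n")


def read_newick(path) -> list[tuple[float, float, str]]:
    """Read an interval+newick TSV into (start, end, newick) tuples."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        ci = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append((float(f[ci["start"]]), float(f[ci["end"]]), f[ci["newick"]]))
    return out
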
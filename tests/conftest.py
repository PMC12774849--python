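import itertools

import numpy as np
import pytest

from genoweave.collect import CollectionMember, SiteCollection
from genoweave.patterns import PloidyMap, SitePattern


@pytest.fixture
def diploid3() -> PloidyMap:
    """Three diploid individuals A, B, C (six haplotypes)."""
    return PloidyMap.uniform(["A", "B", "C"], 2)


@pytest.fixture
def haploid6() -> PloidyMap:
    return PloidyMap.uniform([f"h{i}" for i in range(6)], 1)


def make_patterns(specs, ploidy_map):
    """[(position, counts), ...] -> list of SitePattern."""
    k = ploidy_map.array()
    return [SitePattern.from_counts(pos, c, k) for pos, c in specs]


def collection_of(specs, ploidy_map, focal_pos=None):
    """A SiteCollection with distances measured from the first position."""
    pats = make_patterns(specs, ploidy_map)
    if focal_pos is None:
        focal_pos = pats[0].position
    members = [
        CollectionMember(p, abs(p.position - focal_pos), p.position) for p in pats
    ]
    return SiteCollection(0, focal_pos, members)


def random_binary_newick(labels, rng) -> str:
    """Random resolved rooted tree over the given tip labels."""
    nodes = list(labels)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b})")
    return nodes[0] + ";"


def ind_topology(tree):
    """Nested structure with leaves replaced by their individual, as a
    canonical string — equal for trees differing only by within-individual
    tip rotation."""

    def rec(nid):
        node = tree.nodes[nid]
        if node.label is not None:
            return node.label.rsplit("_", 1)[0]
        return "(" + ",".join(sorted(rec(c) for c in node.children)) + ")"

    return rec(tree.root)


def brute_force_phase_assignments(p, q, k):
    """All two-site haplotype-count totals (n11, n10, n01, n00) consistent with
    unphased counts p (site 1) and q (site 2) under per-individual ploidy k."""
    per = []
    for a, b, kk in zip(p, q, k):
        opts = []
        for j in range(max(0, a + b - kk), min(a, b) + 1):
            opts.append((j, a - j, b - j, kk - a - b + j))
        per.append(opts)
    for combo in itertools.product(*per):
        yield tuple(sum(c[i] for c in combo) for i in range(4))
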
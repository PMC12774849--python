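"""Accuracy metrics for inferred ARGs and topology-weight tracks.

Tree accuracy uses a normalized rooted quartet similarity: each quartet is 3
tips plus the root, i.e. a rooted triplet.  The similarity between two trees
on the same tips is the fraction of triples that induce the same rooted
triplet topology in both (a triple unresolved in both trees counts as a
match; unresolved against resolved is a mismatch).  All C(H,3) triples are
scored when H <= 8; above that a random sample of triples (default 100) is
used.  Because unphased inference treats the tips of one individual as
interchangeable, triplet topologies are compared at the individual level:
a resolved triple is summarized by which individuals form the cherry and
which is the outlier.

Because within-individual tip placement in an inferred tree is arbitrary,
a triple drawn across individuals cannot be compared slot-by-slot (that
would grade phase assignment, which the method does not attempt).  Each
sampled triple is therefore scored at the level of its individuals: over
all ways of realizing the individual multiset with distinct tips, the two
trees' triplet-signature multisets are intersected, and the triple scores
the overlap fraction.  For phased/haploid data every individual has one
tip and this reduces to the classical 0/1 triplet comparison.

Whole-ARG similarity and weight-track distance are span-weighted means over
every maximal tract on which both inputs are constant.  The weight distance
per tract is the Euclidean distance between weight vectors divided by sqrt(2)
(its maximum between probability vectors), giving a value in [0, 1].
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np

from ._treeview import TreeView, tskit_tip_labels

__all__ = [
    "rooted_quartet_similarity",
    "arg_similarity",
    "weight_track_distance",
    "triplet_signature",
]


def triplet_signature(view: TreeView, labels: tuple[str, str, str]):
    """Rooted triplet topology at the individual level, or None if unresolved.

    A resolved signature is ``(frozenset-free sorted cherry individuals,
    outlier individual)``; invariant to within-individual tip relabeling.
    """
    a, b, c = (view.tips[l] for l in labels)
    ia, ib, ic = (view.tip_individual(l) for l in labels)
    m_ab, m_ac, m_bc = view.mrca(a, b), view.mrca(a, c), view.mrca(b, c)
    d_ab, d_ac, d_bc = view.depth[m_ab], view.depth[m_ac], view.depth[m_bc]
    if d_ab == d_ac == d_bc:
        return None
    if d_ab > d_ac and d_ab > d_bc:
        cherry, out = (ia, ib), ic
    elif d_ac > d_ab and d_ac > d_bc:
        cherry, out = (ia, ic), ib
    else:
        cherry, out = (ib, ic), ia
    return (tuple(sorted(cherry)), out)


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


def _triple_overlap(v1: TreeView, v2: TreeView, inds: tuple[str, ...],
                    by_ind: dict[str, list[str]]) -> float:
    """Agreement for one individual multiset: overlap of the two trees'
    triplet-signature multisets over every distinct-tip realization."""
    from collections import Counter

    need = Counter(inds)
    per_ind = [
        list(itertools.combinations(by_ind[ind], c)) for ind, c in need.items()
    ]
    sigs1: Counter = Counter()
    sigs2: Counter = Counter()
    for chosen in itertools.product(*per_ind):
        labels = tuple(itertools.chain.from_iterable(chosen))
        sigs1[triplet_signature(v1, labels)] += 1
        sigs2[triplet_signature(v2, labels)] += 1
    total = sum(sigs1.values())
    inter = sum((sigs1 & sigs2).values())
    return inter / total


def rooted_quartet_similarity(
    t1,
    t2,
    n_sample: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Fraction of rooted triplets (3 tips + root) agreeing between two trees.

    Exact over all C(H, 3) triples for H <= 8; otherwise estimated from
    ``n_sample`` uniformly drawn triples (seeded via ``rng``).  Tips of one
    individual are interchangeable: each triple contributes the overlap of
    the trees' triplet-topology multisets over its individuals' tips, so the
    score never depends on arbitrary within-individual labeling.
    """
    v1, v2 = _as_view(t1), _as_view(t2)
    tips = sorted(v1.tips)
    if sorted(v2.tips) != tips:
        raise ValueError("trees have different tip sets")
    H = len(tips)
    if H < 3:
        raise ValueError("need at least 3 tips")
    by_ind: dict[str, list[str]] = {}
    for lab in tips:
        by_ind.setdefault(v1.tip_individual(lab), []).append(lab)
    if H <= 8:
        triples = list(itertools.combinations(tips, 3))
    else:
        if rng is None:
            rng = np.random.default_rng()
        idx = np.array([rng.choice(H, size=3, replace=False) for _ in range(n_sample)])
        triples = [tuple(tips[j] for j in row) for row in idx]
    cache: dict[tuple[str, ...], float] = {}
    acc = 0.0
    for tr in triples:
        key = tuple(sorted(v1.tip_individual(l) for l in tr))
        if key not in cache:
            cache[key] = _triple_overlap(v1, v2, key, by_ind)
        acc += cache[key]
    return acc / len(triples)


def _tree_views_and_breaks(ts) -> tuple[list[TreeView], np.ndarray]:
    if hasattr(ts, "trees") and hasattr(ts, "ploidy_map"):  # LocalTreeSequence
        return [TreeView.from_gentree(t) for t in ts.trees], np.asarray(
            ts.breakpoints, dtype=float
        )
    if hasattr(ts, "num_trees") and hasattr(ts, "tables"):  # tskit
        labels = tskit_tip_labels(ts)
        views, bps = [], [0.0]
        for tree in ts.trees():
            views.append(TreeView.from_tskit(tree, labels))
            bps.append(float(tree.interval.right))
        return views, np.asarray(bps)
    intervals = list(ts)  # (start, end, newick)
    views = [TreeView.from_newick(nwk) for _, _, nwk in intervals]
    bps = np.asarray([intervals[0][0]] + [e for _, e, _ in intervals], dtype=float)
    return views, bps


def arg_similarity(
    ts1,
    ts2,
    n_sample: int = 100,
    seed: int | None = None,
) -> float:
    """Span-weighted mean rooted quartet similarity between two ARGs.

    The sequence span is decomposed into maximal tracts on which both ARGs
    hold a constant tree; the per-tract similarity is averaged weighted by
    tract length.  Distinct tree pairs are each scored once (cached), with an
    independent triple sample per pair when sampling applies.
    """
    v1, b1 = _tree_views_and_breaks(ts1)
    v2, b2 = _tree_views_and_breaks(ts2)
    if abs(b1[-1] - b2[-1]) > 1e-6:
        raise ValueError(f"sequence lengths differ: {b1[-1]} vs {b2[-1]}")
    rng = np.random.default_rng(seed)
    cuts = np.unique(np.concatenate([b1, b2]))
    cache: dict[tuple[int, int], float] = {}
    total = 0.0
    acc = 0.0
    for left, right in zip(cuts[:-1], cuts[1:]):
        mid = (left + right) / 2.0
        i = min(int(np.searchsorted(b1, mid, side="right") - 1), len(v1) - 1)
        j = min(int(np.searchsorted(b2, mid, side="right") - 1), len(v2) - 1)
        key = (i, j)
        if key not in cache:
            cache[key] = rooted_quartet_similarity(v1[i], v2[j], n_sample, rng)
        span = right - left
        acc += span * cache[key]
        total += span
    return acc / total


def weight_track_distance(w1, w2, renormalize: str = "resolved") -> float:
    """Span-weighted scaled Euclidean distance between two weight tracks.

    Per overlap tract, ||w1 - w2||_2 / sqrt(2), which lies in [0, 1] for
    probability vectors; tracts where either track has no resolved
    combination (NaN weights under ``renormalize="resolved"``) are excluded
    from the weighted mean.
    """
    if w1.topology_set.topologies != w2.topology_set.topologies:
        raise ValueError("weight tracks use different topology sets")
    if abs(w1.L - w2.L) > 1e-6:
        raise ValueError("weight tracks cover different spans")
    a = w1.weights(renormalize)
    b = w2.weights(renormalize)
    if renormalize == "all":
        a, b = a[:, :-1], b[:, :-1]  # compare over the topology columns
    cuts = np.unique(np.concatenate([w1.breakpoints, w2.breakpoints]))
    total = 0.0
    acc = 0.0
    for left, right in zip(cuts[:-1], cuts[1:]):
        mid = (left + right) / 2.0
        wa = a[w1.interval_at(mid)]
        wb = b[w2.interval_at(mid)]
        if np.any(np.isnan(wa)) or np.any(np.isnan(wb)):
            continue
        span = right - left
        acc += span * float(np.linalg.norm(wa - wb)) / sqrt(2.0)
        total += span
    if total == 0:
        raise ValueError("no tract with resolved weights in both tracks")
    return acc / total
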
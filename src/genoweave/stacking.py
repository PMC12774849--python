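"""Topology weighting by stacking sub-ARGs ("sticcstack"-style).

Local-tree inference from collected site patterns is accurate only for small
sample sizes, but topology weighting can be decomposed: infer a small ARG
for each minimal subset (one individual per group), count subtree topologies
per sub-ARG, then stack — partition the chromosome at the union of all
sub-ARG breakpoints and sum the topology counts per interval.  Every subset
re-filters the sites on its own members, which is what lets stacking use
variants with missing data or extra alleles that whole-dataset inference
must discard.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np

from .patterns import GenotypeMatrix
from .treeseq import infer_local_trees
from .weights import (
    TopologySet,
    TopologyWeightTrack,
    enumerate_topologies,
    tip_groups_from_individuals,
    weight_tree_sequence,
)

__all__ = ["make_subsets", "stack", "run_sticcstack"]


def make_subsets(
    group_of_individual: dict[str, str],
    n_subsets: int,
    seed: int | None = None,
) -> list[tuple[str, ...]]:
    """Minimal one-individual-per-group subsets.

    All prod_j n_j subsets when there are at most ``n_subsets`` of them,
    otherwise ``n_subsets`` distinct subsets sampled uniformly without
    replacement.  Deterministic for a fixed seed.
    """
    groups = sorted(set(group_of_individual.values()))
    if not groups:
        raise ValueError("no groups in the assignment")
    members = {
        g: sorted(i for i, gg in group_of_individual.items() if gg == g)
        for g in groups
    }
    empty = [g for g in groups if not members[g]]
    if empty:
        raise ValueError(f"empty groups: {empty}")
    sizes = [len(members[g]) for g in groups]
    total = int(np.prod(sizes))
    if total <= n_subsets:
        return [tuple(c) for c in itertools.product(*(members[g] for g in groups))]
    rng = np.random.default_rng(seed)
    chosen: set[int] = set()
    while len(chosen) < n_subsets:
        chosen.add(int(rng.integers(total)))
    out = []
    for flat in sorted(chosen):
        combo = []
        for g, size in zip(groups, sizes):
            flat, j = divmod(flat, size)
            combo.append(members[g][j])
        out.append(tuple(combo))
    return out


def stack(sub_tracks: Sequence[TopologyWeightTrack]) -> TopologyWeightTrack:
    """Sum topology counts over the union of all sub-track breakpoints."""
    if not sub_tracks:
        raise ValueError("no tracks to stack")
    first = sub_tracks[0]
    for t in sub_tracks[1:]:
        if t.topology_set.topologies != first.topology_set.topologies:
            raise ValueError("tracks use different topology sets")
        if abs(t.L - first.L) > 1e-6 or abs(t.breakpoints[0] - first.breakpoints[0]) > 1e-6:
            raise ValueError("tracks cover different spans")
    cuts = np.unique(np.concatenate([t.breakpoints for t in sub_tracks]))
    mids = (cuts[:-1] + cuts[1:]) / 2.0
    counts = np.zeros((len(mids), first.topology_set.T), dtype=np.int64)
    unresolved = np.zeros(len(mids), dtype=np.int64)
    for t in sub_tracks:
        idx = np.clip(
            np.searchsorted(t.breakpoints, mids, side="right") - 1,
            0,
            t.num_intervals - 1,
        )
        counts += t.counts[idx]
        unresolved += t.unresolved[idx]
    return TopologyWeightTrack(
        cuts, counts, unresolved, first.topology_set, chrom=first.chrom
    )


def run_sticcstack(
    matrix: GenotypeMatrix,
    group_of_individual: dict[str, str],
    n_subsets: int = 512,
    seed: int | None = None,
    L: float | None = None,
    topology_set: TopologySet | None = None,
    second_chances: bool = True,
) -> TopologyWeightTrack:
    """Stacked topology weights from a polarized genotype matrix.

    For every sampled subset the matrix is re-filtered on the subset's
    members (missing data, per-subset biallelism and segregation), a small
    ARG is inferred, topology counts are computed per local tree, and all
    sub-tracks are stacked.  Sub-ARG spans all cover [0, L), so the stack is
    total.
    """
    if topology_set is None:
        topology_set = enumerate_topologies(sorted(set(group_of_individual.values())))
    if L is None:
        L = float(matrix.positions[-1]) + 1 if matrix.n_sites else 1.0
    subsets = make_subsets(group_of_individual, n_subsets, seed)
    tracks = []
    for subset in subsets:
        sub = matrix.subset_individuals(list(subset))
        lts = infer_local_trees(sub, L=L, second_chances=second_chances)
        tips = tip_groups_from_individuals(group_of_individual, sub.ploidy_map)
        tracks.append(weight_tree_sequence(lts, tips, topology_set))
    return stack(tracks)
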
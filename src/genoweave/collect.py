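"""Collecting compatible site patterns along a chromosome.

Each variant site gets its own "collection": the set of patterns from
surrounding sites that can coexist with the focal pattern in one genealogy.
Rather than testing every pair of sites, two directional knockout sweeps are
used.  Moving left to right, the pattern at each site is added to a running
collection and existing members incompatible with it are knocked out; the
surviving set is recorded as that site's left-collection.  The mirror-image
sweep yields right-collections.  Under the second-chances rule a knocked-out
pattern becomes eligible again as soon as the pattern that knocked it out is
itself knocked out (haplotype blocks can be disjunct along the genome).
Finally the two collections are reconciled: where members conflict, the one
whose nearest supporting variant is closer to the focal site wins.

Distances are measured in base pairs between variant positions, and identical
patterns occurring at several sites are merged with the nearest supporting
position tracked per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .compat import incompatible
from .patterns import PloidyMap, SitePattern

__all__ = ["SiteCollection", "CollectionMember", "collect_sites", "naive_collect"]


@dataclass(frozen=True)
class CollectionMember:
    pattern: SitePattern  # representative occurrence of this pattern
    distance: int  # focal position to the nearest supporting variant
    nearest_pos: int

    @property
    def counts(self) -> tuple[int, ...]:
        return self.pattern.counts


@dataclass
class SiteCollection:
    focal_index: int
    focal_position: int
    members: list[CollectionMember]  # sorted: focal first, then by distance

    def member_counts(self) -> list[tuple[int, ...]]:
        return [m.counts for m in self.members]


class _PairCache:
    """Memoized generalized four-gamete test between unique patterns."""

    def __init__(self, ploidies: np.ndarray):
        self.k = ploidies
        self.cache: dict[tuple[int, int], bool] = {}

    def incompat(self, a: int, b: int, counts: list[np.ndarray]) -> bool:
        if a == b:
            return False
        key = (a, b) if a < b else (b, a)
        hit = self.cache.get(key)
        if hit is None:
            hit = incompatible(counts[a], counts[b], self.k)
            self.cache[key] = hit
        return hit


def _unique_patterns(patterns: list[SitePattern]):
    """Map each site to a unique-pattern id; return id arrays and count vectors."""
    ids: dict[tuple[int, ...], int] = {}
    site_pid = np.empty(len(patterns), dtype=np.int64)
    counts: list[np.ndarray] = []
    for s, p in enumerate(patterns):
        pid = ids.get(p.counts)
        if pid is None:
            pid = len(ids)
            ids[p.counts] = pid
            counts.append(np.asarray(p.counts, dtype=np.int64))
        site_pid[s] = pid
    return site_pid, counts


def _directional_pass(
    order: list[int],
    site_pid: np.ndarray,
    positions: np.ndarray,
    counts: list[np.ndarray],
    cache: _PairCache,
    second_chances: bool,
) -> list[dict[int, int]]:
    """One knockout sweep; returns, per site (in sweep order), {pid: nearest_pos}."""
    active: dict[int, int] = {}
    knocked_by: dict[int, int] = {}  # pid -> pid that most recently knocked it out
    last_seen: dict[int, int] = {}
    snapshots: list[dict[int, int]] = []
    for s in order:
        pid = int(site_pid[s])
        pos = int(positions[s])
        last_seen[pid] = pos
        if pid in active:
            active[pid] = pos
        else:
            losers = [m for m in active if cache.incompat(m, pid, counts)]
            for m in losers:
                del active[m]
                knocked_by[m] = pid
            knocked_by.pop(pid, None)
            if second_chances and losers:
                loser_set = set(losers)
                restorable = [
                    m for m, kn in knocked_by.items()
                    if kn in loser_set and m != pid
                ]
                for m in restorable:
                    if cache.incompat(m, pid, counts):
                        knocked_by[m] = pid  # knocked right back by the incomer
                    else:
                        active[m] = last_seen[m]
                        del knocked_by[m]
            active[pid] = pos
        snapshots.append(dict(active))
    return snapshots


def collect_sites(
    patterns: list[SitePattern],
    ploidy_map: PloidyMap,
    second_chances: bool = True,
) -> list[SiteCollection]:
    """Build the reconciled collection of compatible patterns for every site."""
    if not patterns:
        return []
    positions = np.asarray([p.position for p in patterns], dtype=np.int64)
    if np.any(np.diff(positions) <= 0):
        raise ValueError("patterns must be sorted by strictly increasing position")
    site_pid, counts = _unique_patterns(patterns)
    cache = _PairCache(ploidy_map.array())
    S = len(patterns)

    left = _directional_pass(
        list(range(S)), site_pid, positions, counts, cache, second_chances
    )
    right_rev = _directional_pass(
        list(range(S - 1, -1, -1)), site_pid, positions, counts, cache, second_chances
    )
    right = right_rev[::-1]

    rep: dict[int, SitePattern] = {}
    for s, p in enumerate(patterns):
        rep.setdefault(int(site_pid[s]), p)

    collections: list[SiteCollection] = []
    for s in range(S):
        focal_pid = int(site_pid[s])
        focal_pos = int(positions[s])
        # candidate pid -> (distance, side 0=left, nearest supporting position)
        cand: dict[int, tuple[int, int, int]] = {}
        for side, coll in ((0, left[s]), (1, right[s])):
            for pid, npos in coll.items():
                d = abs(focal_pos - npos)
                entry = (d, side, npos)
                if pid not in cand or entry < cand[pid]:
                    cand[pid] = entry
        # the focal pattern always wins; then greedy by distance (ties: left first)
        ordered = sorted(
            cand.items(),
            key=lambda kv: (kv[0] != focal_pid, kv[1][0], kv[1][1], kv[1][2]),
        )
        accepted: list[int] = []
        members: list[CollectionMember] = []
        for pid, (d, side, npos) in ordered:
            if any(cache.incompat(pid, a, counts) for a in accepted):
                continue
            accepted.append(pid)
            members.append(CollectionMember(rep[pid], d, npos))
        collections.append(SiteCollection(s, focal_pos, members))
    return collections


def naive_collect(
    patterns: list[SitePattern],
    ploidy_map: PloidyMap,
) -> list[SiteCollection]:
    """Direct per-site collection (independent oracle; quadratic in sites).

    For site i, consider every site j in order of distance and add its pattern
    provided it is compatible with all patterns already collected.
    """
    positions = np.asarray([p.position for p in patterns], dtype=np.int64)
    site_pid, counts = _unique_patterns(patterns)
    cache = _PairCache(ploidy_map.array())
    rep: dict[int, SitePattern] = {}
    for s, p in enumerate(patterns):
        rep.setdefault(int(site_pid[s]), p)
    out = []
    for s in range(len(patterns)):
        focal_pos = int(positions[s])
        order = sorted(
            range(len(patterns)), key=lambda j: (abs(int(positions[j]) - focal_pos), j)
        )
        accepted: list[int] = []
        best: dict[int, tuple[int, int]] = {}
        for j in order:
            pid = int(site_pid[j])
            if pid in best:
                continue
            if any(cache.incompat(pid, a, counts) for a in accepted):
                continue
            accepted.append(pid)
            best[pid] = (abs(int(positions[j]) - focal_pos), int(positions[j]))
        members = [
            CollectionMember(rep[pid], d, npos) for pid, (d, npos) in best.items()
        ]
        members.sort(key=lambda m: (m.counts != rep[int(site_pid[s])].counts, m.distance))
        out.append(SiteCollection(s, focal_pos, members))
    return out
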
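"""Knockout collection sweeps, second chances and reconciliation."""

import numpy as np
import pytest

from genoweave.collect import collect_sites, naive_collect
from genoweave.compat import incompatible
from genoweave.patterns import PloidyMap

from .conftest import make_patterns


def member_counts(coll):
    return {m.counts for m in coll.members}


@pytest.fixture
def hap4():
    return PloidyMap.uniform([f"h{i}" for i in range(4)], 1)


class TestDirectionalPasses:
    def test_all_compatible_collects_everything(self, hap4):
        # mutually compatible: nested/disjoint haploid clades
        specs = [(10, [1, 1, 0, 0]), (20, [1, 0, 0, 0]), (30, [1, 1, 1, 0])]
        pats = make_patterns(specs, hap4)
        colls = collect_sites(pats, hap4)
        expected = {tuple(c) for _, c in specs}
        for coll in colls:
            assert member_counts(coll) == expected

    def test_second_chances_restores_pattern(self, hap4):
        # A (pos 10) and B (pos 20) are incompatible; C (pos 40) knocks out B,
        # which restores A for sites at and beyond C.
        A, B, C = [1, 1, 0, 0], [0, 1, 1, 0], [1, 1, 0, 1]
        D = [0, 0, 0, 1]  # compatible filler
        assert incompatible(A, B, hap4.array())
        assert incompatible(B, C, hap4.array())
        assert not incompatible(A, C, hap4.array())
        specs = [(10, A), (20, B), (30, D), (40, C)]
        pats = make_patterns(specs, hap4)
        colls = collect_sites(pats, hap4, second_chances=True)
        # at site 30 (moving left to right) A is knocked out
        left_only = collect_sites(pats[:3], hap4)
        assert tuple(A) not in member_counts(left_only[2])
        # at site 40, C kills B and A returns
        got = member_counts(colls[3])
        assert tuple(A) in got and tuple(C) in got and tuple(B) not in got

    def test_no_second_chances_flag(self, hap4):
        A, B, C = [1, 1, 0, 0], [0, 1, 1, 0], [1, 1, 0, 1]
        specs = [(10, A), (20, B), (40, C)]
        pats = make_patterns(specs, hap4)
        colls = collect_sites(pats, hap4, second_chances=False)
        got = member_counts(colls[2])
        assert tuple(A) not in got  # stays knocked out without the rule


class TestReconcile:
    def test_distance_rule(self, hap4):
        # incompatible patterns at 40 (left of focal 50) and 70 (right):
        # the closer one (distance 10 < 20) wins at the focal site.
        A, B = [1, 1, 0, 0], [0, 1, 1, 0]
        F = [0, 0, 0, 1]  # focal pattern, compatible with both
        assert incompatible(A, B, hap4.array())
        pats = make_patterns([(40, A), (50, F), (70, B)], hap4)
        colls = collect_sites(pats, hap4)
        got = member_counts(colls[1])
        assert tuple(A) in got and tuple(B) not in got

    def test_tie_keeps_left(self, hap4):
        A, B = [1, 1, 0, 0], [0, 1, 1, 0]
        F = [0, 0, 0, 1]
        pats = make_patterns([(40, A), (50, F), (60, B)], hap4)
        colls = collect_sites(pats, hap4)
        got = member_counts(colls[1])
        assert tuple(A) in got and tuple(B) not in got

    def test_identity_when_sides_agree(self, hap4):
        specs = [(10, [1, 1, 0, 0]), (20, [1, 0, 0, 0]), (30, [0, 0, 1, 1])]
        pats = make_patterns(specs, hap4)
        colls = collect_sites(pats, hap4)
        for coll in colls:
            assert member_counts(coll) == {tuple(c) for _, c in specs}


class TestInvariants:
    def _random_instance(self, rng, hap4, n_sites=10):
        positions = np.sort(rng.choice(np.arange(1, 500), n_sites, replace=False))
        specs = []
        for pos in positions:
            c = rng.integers(0, 2, size=4)
            if c.sum() in (0, 4):
                c[0] = 1 - c[0]
            specs.append((int(pos), [int(x) for x in c]))
        return make_patterns(specs, hap4)

    def test_focal_always_member_and_compatible(self, hap4):
        rng = np.random.default_rng(0)
        for _ in range(25):
            pats = self._random_instance(rng, hap4)
            colls = collect_sites(pats, hap4)
            k = hap4.array()
            for s, coll in enumerate(colls):
                focal = pats[s].counts
                assert focal in member_counts(coll)
                for m in coll.members:
                    assert not incompatible(focal, m.counts, k)

    def _sidon_positions(self, rng, n):
        """Positions with all pairwise differences distinct, so reconciliation
        never faces a distance tie (the only point where mirroring may differ)."""
        while True:
            pos = np.sort(rng.choice(np.arange(1, 2000), n, replace=False))
            diffs = [b - a for i, a in enumerate(pos) for b in pos[i + 1 :]]
            if len(set(diffs)) == len(diffs):
                return pos

    def test_mirror_symmetry(self, hap4):
        """Reversing the chromosome and swapping sweep directions mirrors the
        collections exactly when no distance ties arise."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            positions = self._sidon_positions(rng, 8)
            specs = []
            for pos in positions:
                c = rng.integers(0, 2, size=4)
                if c.sum() in (0, 4):
                    c[0] = 1 - c[0]
                specs.append((int(pos), [int(x) for x in c]))
            pats = make_patterns(specs, hap4)
            Lmax = max(p.position for p in pats) + 7
            from genoweave.patterns import SitePattern

            mirrored = [
                SitePattern.from_counts(Lmax - p.position, p.counts, hap4.array())
                for p in reversed(pats)
            ]
            f = collect_sites(pats, hap4)
            r = collect_sites(mirrored, hap4)
            for s in range(len(pats)):
                assert member_counts(f[s]) == member_counts(r[len(pats) - 1 - s])

    def test_oracle_equivalence_when_all_compatible(self, hap4):
        """With no incompatibilities the knockout procedure must agree exactly
        with the direct per-site collection oracle."""
        rng = np.random.default_rng(2)
        k = hap4.array()
        for _ in range(20):
            pats = self._random_instance(rng, hap4)
            pairs_ok = all(
                not incompatible(a.counts, b.counts, k)
                for i, a in enumerate(pats)
                for b in pats[i + 1 :]
            )
            fast = collect_sites(pats, hap4)
            slow = naive_collect(pats, hap4)
            for s in range(len(pats)):
                if pairs_ok:
                    assert member_counts(fast[s]) == member_counts(slow[s])
                else:
                    # documented divergence allowed; both must contain the focal
                    assert pats[s].counts in member_counts(fast[s])
                    assert pats[s].counts in member_counts(slow[s])

    def test_nearest_distance_tracking(self, hap4):
        # the same pattern at several sites is merged, nearest support tracked
        A = [1, 1, 0, 0]
        F = [1, 0, 0, 0]
        pats = make_patterns([(10, A), (30, F), (90, A)], hap4)
        colls = collect_sites(pats, hap4)
        m = {mm.counts: mm for mm in colls[1].members}
        assert m[tuple(A)].distance == 20  # 30-10, not 90-30
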
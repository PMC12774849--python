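"""Synthetic data: coalescent ARGs with recombination, mutations, ploidy
pairing and parametric error models.

The generator wraps msprime behind a contract defined purely by its outputs
(a true tree sequence plus 0/1 haplotypes).  Defaults emulate a neutral
panmictic population with per-site mutation and recombination rates of 1e-8
and Ne = 10,000, i.e. a recombination-to-mutation ratio rho/theta = 1.
Infinite-sites data is produced by removing all but the first (oldest)
mutation at any site hit recurrently.

Individuals are named ``ind0 .. ind{n-1}`` and haplotypes are assigned to
them in sample order, so tip labels agree between the true tree sequence and
matrices built here (``ind3_2`` is the second haplotype of individual 3).
"""

from __future__ import annotations

from typing import Sequence

import msprime
import numpy as np
import tskit

from .patterns import GenotypeMatrix, PloidyMap

__all__ = [
    "simulate_arg",
    "matrix_from_ts",
    "group_into_individuals",
    "corrupt",
    "split_admixture_demography",
    "simulate_admixture_dataset",
    "duplicate_node_fraction",
]


def _msprime_seeds(seed: int | None, n: int = 2) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(1, 2**31 - 1, size=n)]


def simulate_arg(
    ploidies: int | Sequence[int],
    L: float,
    mu: float = 1e-8,
    r: float = 1e-8,
    Ne: float = 10_000,
    seed: int | None = None,
    demography: msprime.Demography | None = None,
    populations: Sequence[str] | None = None,
    infinite_sites: bool = True,
) -> tskit.TreeSequence:
    """Simulate a neutral coalescent-with-recombination ARG with mutations.

    ``ploidies`` is either a haplotype count (individuals are then haploid)
    or a per-individual ploidy list; each individual's haplotypes are drawn
    from one msprime individual so tip labels line up.  ``populations``
    optionally assigns each individual to a demography population.
    """
    if isinstance(ploidies, (int, np.integer)):
        ploidies = [1] * int(ploidies)
    samples = [
        msprime.SampleSet(
            1,
            ploidy=int(k),
            population=populations[i] if populations is not None else None,
        )
        for i, k in enumerate(ploidies)
    ]
    s_anc, s_mut = _msprime_seeds(seed)
    kwargs = dict(
        samples=samples,
        sequence_length=float(L),
        recombination_rate=r,
        random_seed=s_anc,
        ploidy=2,
    )
    if demography is not None:
        kwargs["demography"] = demography
    else:
        kwargs["population_size"] = Ne
    ts = msprime.sim_ancestry(**kwargs)
    ts = msprime.sim_mutations(
        ts,
        rate=mu,
        model=msprime.BinaryMutationModel(),
        random_seed=s_mut,
        discrete_genome=True,
    )
    if infinite_sites:
        ts = _keep_first_mutation(ts)
    return ts


def _keep_first_mutation(ts: tskit.TreeSequence) -> tskit.TreeSequence:
    """Enforce infinite sites: keep only the oldest mutation at each site."""
    keep: dict[int, tuple[int, float]] = {}
    for m in ts.mutations():
        t = m.time
        cur = keep.get(m.site)
        if cur is None or t > cur[1]:
            keep[m.site] = (m.node, t)
    tables = ts.dump_tables()
    tables.mutations.clear()
    for site in range(ts.num_sites):
        node, t = keep[site]
        tables.mutations.add_row(
            site=site, node=node, derived_state="1", parent=-1, time=t
        )
    return tables.tree_sequence()


def _ploidy_map_for(ploidies: Sequence[int]) -> PloidyMap:
    return PloidyMap(
        tuple(f"ind{i}" for i in range(len(ploidies))),
        tuple(int(k) for k in ploidies),
    )


def matrix_from_ts(
    ts: tskit.TreeSequence,
    ploidies: Sequence[int] | None = None,
    chrom: str = "chr",
) -> GenotypeMatrix:
    """Derived-allele count matrix from a simulated tree sequence.

    Haplotype columns are combined per individual (phase disregarded).  When
    ``ploidies`` is omitted it is taken from the tree sequence's individuals.
    Positions are 1-based (VCF convention).
    """
    if ploidies is None:
        ind = np.array([ts.node(u).individual for u in ts.samples()])
        if np.any(ind < 0):
            ploidies = [1] * ts.num_samples
        else:
            _, counts = np.unique(ind, return_counts=True)
            ploidies = [int(c) for c in counts]
    haps = ts.genotype_matrix()  # (S, H), 0/1
    positions = np.array([int(s.position) + 1 for s in ts.sites()], dtype=np.int64)
    return group_into_individuals(haps, positions, list(ploidies), chrom=chrom)


def group_into_individuals(
    haplotypes: np.ndarray,
    positions: np.ndarray,
    ploidies: Sequence[int],
    phased: bool = False,
    chrom: str = "chr",
) -> GenotypeMatrix:
    """Combine 0/1 haplotype columns into per-individual derived counts.

    With ``phased=True`` every haplotype stays its own (haploid) column; the
    individual naming then matches what the unphased grouping would call the
    same individuals is NOT preserved — phased mode simply treats haplotypes
    as haploid individuals.
    """
    haps = np.asarray(haplotypes)
    S, H = haps.shape
    if phased:
        ploidies = [1] * H
    if sum(ploidies) != H:
        raise ValueError(f"ploidies sum to {sum(ploidies)}, need {H}")
    pm = _ploidy_map_for(ploidies)
    offsets = np.concatenate([[0], np.cumsum(ploidies)])
    counts = np.add.reduceat(haps, offsets[:-1], axis=1)
    ac = [counts[s][None, :].astype(np.int64) for s in range(S)]
    alleles = [("A", "T")] * S
    missing = np.zeros((S, pm.n), dtype=bool)
    return GenotypeMatrix(
        chrom, positions, pm, alleles, ac, missing, polarized=True
    )


def corrupt(
    matrix: GenotypeMatrix,
    genotype_error_rate: float = 0.0,
    polarization_error_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Perturb a polarized biallelic matrix with simple parametric errors.

    Each genotype independently moves to an adjacent allele count (+-1 within
    [0, ploidy]) with probability ``genotype_error_rate``; each site's
    polarity flips (counts c -> k - c) with ``polarization_error_rate``.
    """
    if not matrix.polarized:
        raise ValueError("corrupt expects a polarized matrix")
    rng = np.random.default_rng(seed)
    k = matrix.ploidy_map.array()
    ac = []
    for s in range(matrix.n_sites):
        if matrix.ac[s].shape[0] != 1:
            ac.append(matrix.ac[s].copy())
            continue
        c = matrix.ac[s][0].copy()
        hit = rng.random(len(c)) < genotype_error_rate
        for i in np.flatnonzero(hit):
            if c[i] == 0:
                c[i] = 1
            elif c[i] == k[i]:
                c[i] = k[i] - 1
            else:
                c[i] += 1 if rng.random() < 0.5 else -1
        if rng.random() < polarization_error_rate:
            c = k - c
        ac.append(c[None, :])
    return GenotypeMatrix(
        matrix.chrom,
        matrix.positions.copy(),
        matrix.ploidy_map,
        list(matrix.alleles),
        ac,
        matrix.missing.copy(),
        polarized=True,
    )


def split_admixture_demography(
    n_groups: int = 3,
    Ne: float = 10_000,
    split_interval: float = 20_000,
    admix_time: float = 4_000,
    admix_fraction: float = 0.3,
    admix_source: str | None = None,
    admix_dest: str | None = None,
) -> msprime.Demography:
    """Caterpillar species tree with one admixture pulse.

    Populations P1..Pg split pectinately — (((P1,P2),P3),P4) for g=4 — with
    successive split times ``split_interval`` generations apart.  A pulse at
    ``admix_time`` moves ``admix_fraction`` of ``admix_dest`` (default P2)
    from ``admix_source`` (default P3): introgression between non-sisters,
    the classic topology-weighting scenario.
    """
    if n_groups < 2:
        raise ValueError("need at least 2 populations")
    demog = msprime.Demography()
    names = [f"P{i + 1}" for i in range(n_groups)]
    for name in names:
        demog.add_population(name=name, initial_size=Ne)
    anc = names[0]
    for j in range(1, n_groups):
        new = f"A{j}"
        demog.add_population(name=new, initial_size=Ne)
        demog.add_population_split(
            time=split_interval * j, derived=[anc, names[j]], ancestral=new
        )
        anc = new
    src = admix_source or names[min(2, n_groups - 1)]
    dst = admix_dest or names[1]
    if admix_fraction > 0:
        # backwards in time: lineages in dst trace to src with this probability
        demog.add_mass_migration(
            time=admix_time, source=dst, dest=src, proportion=admix_fraction
        )
    demog.sort_events()
    return demog


def simulate_admixture_dataset(
    n_per_group: int = 10,
    ploidy: int = 2,
    n_groups: int = 3,
    L: float = 100_000,
    mu: float = 1e-8,
    r: float = 1e-8,
    Ne: float = 10_000,
    seed: int | None = None,
    admix_fraction: float = 0.3,
    split_interval: float = 20_000,
) -> tuple[tskit.TreeSequence, PloidyMap, dict[str, str]]:
    """Multispecies dataset for topology-weighting tests.

    Returns the mutated true tree sequence, the ploidy map, and the
    individual-to-group assignment.
    """
    demog = split_admixture_demography(
        n_groups=n_groups,
        Ne=Ne,
        admix_fraction=admix_fraction,
        split_interval=split_interval,
    )
    n = n_per_group * n_groups
    ploidies = [ploidy] * n
    populations = [f"P{j + 1}" for j in range(n_groups) for _ in range(n_per_group)]
    ts = simulate_arg(
        ploidies,
        L,
        mu=mu,
        r=r,
        seed=seed,
        demography=demog,
        populations=populations,
    )
    pm = _ploidy_map_for(ploidies)
    group_map = {f"ind{i}": populations[i] for i in range(n)}
    return ts, pm, group_map


def duplicate_node_fraction(
    ts: tskit.TreeSequence, ploidies: Sequence[int] | None = None
) -> tuple[int, int]:
    """Duplicate internal nodes in the true local genealogies.

    For every local tree, each internal node (not a leaf, not the root) is
    mapped to its unphased site pattern — the count of its descendant
    haplotypes per individual.  A node is a *duplicate node* when its pattern
    already belongs to another node of the same tree, i.e. the tree holds
    redundant copies that the pattern alone cannot distinguish; with ``v``
    same-pattern nodes, ``v - 1`` are duplicates.  Returns (duplicate nodes,
    total internal nodes), summed over all local trees.
    """
    samples = list(ts.samples())
    if ploidies is None:
        ind = [ts.node(u).individual for u in samples]
        if min(ind) < 0:
            raise ValueError("tree sequence has no individuals; pass ploidies")
        remap = {v: i for i, v in enumerate(dict.fromkeys(ind))}
        ind_of = np.array([remap[v] for v in ind])
        n = len(remap)
    else:
        ind_of = np.repeat(np.arange(len(ploidies)), ploidies)
        n = len(ploidies)
    col = {u: i for i, u in enumerate(samples)}
    dup = 0
    total = 0
    for tree in ts.trees():
        roots = set(tree.roots)
        pats = []
        for u in tree.nodes():
            if u in roots or tree.is_leaf(u):
                continue
            pat = np.zeros(n, dtype=np.int64)
            for s in tree.samples(u):
                pat[ind_of[col[s]]] += 1
            pats.append(tuple(pat))
        from collections import Counter

        c = Counter(pats)
        dup += sum(v - 1 for v in c.values() if v >= 2)
        total += len(pats)
    return dup, total
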
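"""Site patterns: per-site derived-allele counts per individual, with flags.

The unit of inference throughout the package is the variant site "pattern" —
the vector giving how many copies of the derived allele each individual
carries.  Under the infinite-sites model each distinct pattern identifies one
node of the local genealogy.  Three classifications matter downstream:

ambiguous
    some individual carries more than zero but fewer than ploidy derived
    alleles, so which of its haplotypes carry them is unknown;
duplicable
    no individual carries more than half its ploidy of derived alleles, so the
    same pattern could correspond to more than one distinct node in one tree;
internal_eligible
    derived total between 2 and H-1 (H = total haplotypes), i.e. the pattern
    can be realised as an internal node (singletons are leaves' own patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PloidyMap",
    "SitePattern",
    "GenotypeMatrix",
    "polarize",
    "extract_patterns",
    "write_patterns",
    "read_patterns",
]


@dataclass(frozen=True)
class PloidyMap:
    """Per-individual ploidy: individual ``i`` contributes ``ploidies[i]`` haplotypes."""

    individuals: tuple[str, ...]
    ploidies: tuple[int, ...]

    def __post_init__(self):
        if len(self.individuals) != len(self.ploidies):
            raise ValueError("individuals and ploidies differ in length")
        if any(k < 1 for k in self.ploidies):
            raise ValueError("all ploidies must be >= 1")
        if sum(self.ploidies) < 2:
            raise ValueError("need at least 2 haplotypes in total")

    @property
    def n(self) -> int:
        return len(self.individuals)

    @property
    def H(self) -> int:
        """Total haplotype count."""
        return int(sum(self.ploidies))

    def array(self) -> np.ndarray:
        return np.asarray(self.ploidies, dtype=np.int64)

    def tip_labels(self) -> list[str]:
        """One label per haplotype: ``<individual>_<slot>`` with 1-based slots."""
        return [
            f"{ind}_{j + 1}"
            for ind, k in zip(self.individuals, self.ploidies)
            for j in range(k)
        ]

    def subset(self, individuals: Sequence[str]) -> "PloidyMap":
        idx = {ind: i for i, ind in enumerate(self.individuals)}
        missing = [s for s in individuals if s not in idx]
        if missing:
            raise KeyError(f"unknown individuals: {missing}")
        return PloidyMap(
            tuple(individuals), tuple(self.ploidies[idx[s]] for s in individuals)
        )

    @classmethod
    def uniform(cls, individuals: Sequence[str], ploidy: int = 2) -> "PloidyMap":
        return cls(tuple(individuals), tuple([ploidy] * len(individuals)))

    @classmethod
    def from_tsv(cls, path) -> "PloidyMap":
        """Two-column TSV: individual, ploidy (no header)."""
        df = pd.read_csv(path, sep="\t", header=None, names=["individual", "ploidy"])
        return cls(tuple(df["individual"].astype(str)), tuple(int(k) for k in df["ploidy"]))


@dataclass(frozen=True)
class SitePattern:
    """Derived-allele counts for one variant site, plus classification flags."""

    position: int
    counts: tuple[int, ...]
    ambiguous: bool
    duplicable: bool
    internal_eligible: bool

    @property
    def derived_total(self) -> int:
        return int(sum(self.counts))

    @classmethod
    def from_counts(cls, position: int, counts, ploidies) -> "SitePattern":
        c = np.asarray(counts, dtype=np.int64)
        k = np.asarray(ploidies, dtype=np.int64)
        if c.shape != k.shape:
            raise ValueError("counts/ploidy length mismatch")
        if np.any(c < 0) or np.any(c > k):
            raise ValueError(f"counts out of [0, ploidy] at position {position}")
        tot = int(c.sum())
        return cls(
            position=int(position),
            counts=tuple(int(x) for x in c),
            ambiguous=bool(np.any((c > 0) & (c < k))),
            duplicable=bool(np.all(2 * c <= k)),
            internal_eligible=bool(2 <= tot <= int(k.sum()) - 1),
        )


class GenotypeMatrix:
    """Per-site allele counts for a set of individuals on one chromosome.

    ``ac`` holds, for every site, one row per non-reference allele giving the
    number of copies each individual carries (ragged list of ``(n_alt, n)``
    arrays).  After :func:`polarize`, allele index 0 of ``alleles[s]`` is the
    ancestral state and the rows of ``ac[s]`` count *derived* alleles; sites
    with a single derived allele are the biallelic sites used for pattern
    extraction, while multiallelic sites are retained for the per-subset
    re-testing done by the stacking procedure.
    """

    def __init__(
        self,
        chrom: str,
        positions: np.ndarray,
        ploidy_map: PloidyMap,
        alleles: list[tuple[str, ...]],
        ac: list[np.ndarray],
        missing: np.ndarray,
        polarized: bool = False,
        ancestral: list[str] | None = None,
    ):
        self.chrom = chrom
        self.positions = np.asarray(positions, dtype=np.int64)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        self.ploidy_map = ploidy_map
        self.alleles = alleles
        self.ac = ac
        self.missing = np.asarray(missing, dtype=bool)
        self.polarized = polarized
        self.ancestral = ancestral  # AA tags from input, pre-polarization
        if len(self.alleles) != self.n_sites or len(self.ac) != self.n_sites:
            raise ValueError("per-site field lengths disagree")
        if self.missing.shape != (self.n_sites, self.n_ind):
            raise ValueError("missing mask has wrong shape")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    @property
    def n_ind(self) -> int:
        return self.ploidy_map.n

    @property
    def individuals(self) -> tuple[str, ...]:
        return self.ploidy_map.individuals

    def n_derived(self, s: int) -> int:
        """Number of non-ancestral alleles present at site ``s`` (polarized only)."""
        if not self.polarized:
            raise ValueError("matrix is not polarized")
        return self.ac[s].shape[0]

    def derived_counts(self, s: int) -> np.ndarray:
        """Derived-allele counts per individual at a biallelic polarized site."""
        if not self.polarized:
            raise ValueError("matrix is not polarized")
        if self.ac[s].shape[0] != 1:
            raise ValueError(f"site index {s} is not biallelic after polarization")
        return self.ac[s][0]

    def take_sites(self, index: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(index, dtype=np.int64)
        return GenotypeMatrix(
            self.chrom,
            self.positions[idx],
            self.ploidy_map,
            [self.alleles[i] for i in idx],
            [self.ac[i] for i in idx],
            self.missing[idx],
            polarized=self.polarized,
            ancestral=[self.ancestral[i] for i in idx] if self.ancestral else None,
        )

    def subset_individuals(self, individuals: Sequence[str]) -> "GenotypeMatrix":
        """Restrict to a subset of individuals, re-filtering sites for that subset.

        Applied by the stacking procedure: sites with missing genotypes in the
        subset are dropped for that subset only; multiallelic sites are kept
        only when exactly one derived allele segregates within the subset (it
        is then re-coded as the biallelic derived allele); subset-monomorphic
        sites are dropped.  Requires a polarized matrix.
        """
        if not self.polarized:
            raise ValueError("subset_individuals requires a polarized matrix")
        pm = self.ploidy_map.subset(individuals)
        col = np.array([self.individuals.index(s) for s in individuals])
        k = pm.array()
        positions, alleles, ac, missing = [], [], [], []
        for s in range(self.n_sites):
            if self.missing[s, col].any():
                continue
            sub = self.ac[s][:, col]
            present = np.flatnonzero(sub.sum(axis=1) > 0)
            if len(present) != 1:
                continue  # subset-monomorphic or >1 derived allele in subset
            row = sub[present[0]]
            if row.sum() >= k.sum():
                continue  # derived fixed in the subset
            positions.append(self.positions[s])
            alleles.append((self.alleles[s][0], self.alleles[s][present[0] + 1]))
            ac.append(row[None, :].copy())
            missing.append(np.zeros(len(col), dtype=bool))
        S = len(positions)
        return GenotypeMatrix(
            self.chrom,
            np.asarray(positions, dtype=np.int64),
            pm,
            alleles,
            ac,
            np.asarray(missing, dtype=bool).reshape(S, len(col)),
            polarized=True,
        )


def polarize(
    matrix: GenotypeMatrix,
    outgroup: Sequence[str] = (),
    use_aa_tag: bool = True,
) -> GenotypeMatrix:
    """Re-express genotypes as derived-allele counts.

    The ancestral allele at each site is taken from the VCF ``AA`` INFO tag
    when present (and ``use_aa_tag``), otherwise from the outgroup: the allele
    fixed among non-missing outgroup calls is ancestral.  Sites where the
    outgroup is polymorphic, entirely missing, or fixed for an allele that no
    ingroup individual carries are dropped.  Outgroup columns are removed.
    """
    import warnings

    out_idx = np.array(
        [matrix.individuals.index(s) for s in outgroup], dtype=np.int64
    )
    in_ids = [s for s in matrix.individuals if s not in set(outgroup)]
    in_idx = np.array([matrix.individuals.index(s) for s in in_ids])
    pm = matrix.ploidy_map.subset(in_ids)
    out_k = matrix.ploidy_map.array()[out_idx] if len(out_idx) else np.array([], int)

    positions, alleles, ac, missing = [], [], [], []
    for s in range(matrix.n_sites):
        site_alleles = matrix.alleles[s]
        anc: str | None = None
        from_outgroup = False
        if use_aa_tag and matrix.ancestral is not None and matrix.ancestral[s]:
            aa = matrix.ancestral[s]
            if aa in site_alleles:
                anc = aa
        if anc is None and len(out_idx):
            from_outgroup = True
            ok = ~matrix.missing[s, out_idx]
            if not ok.any():
                continue  # outgroup entirely missing
            # counts of each non-ref allele among usable outgroup calls
            alt_out = matrix.ac[s][:, out_idx][:, ok]
            k_out = out_k[ok]
            alt_tot = alt_out.sum(axis=1)
            ref_tot = k_out.sum() - alt_tot.sum()
            fixed_alt = np.flatnonzero(alt_tot == k_out.sum())
            if ref_tot == k_out.sum():
                anc = site_alleles[0]
            elif len(fixed_alt) == 1 and alt_tot.sum() == k_out.sum():
                anc = site_alleles[fixed_alt[0] + 1]
            else:
                continue  # outgroup polymorphic
        if anc is None:
            continue

        anc_j = site_alleles.index(anc)
        # derived counts for every allele other than the ancestral one
        n_all = len(site_alleles)
        k_in = pm.array()
        rows, row_alleles = [], []
        for j in range(n_all):
            if j == anc_j:
                continue
            if j == 0:
                # reference is derived: count = ploidy - sum(alt counts)
                row = k_in - matrix.ac[s][:, in_idx].sum(axis=0)
            else:
                row = matrix.ac[s][j - 1, in_idx]
            rows.append(row)
            row_alleles.append(site_alleles[j])
        m = matrix.missing[s, in_idx]
        stacked = (
            np.asarray(rows, dtype=np.int64)
            if rows
            else np.zeros((0, len(in_idx)), dtype=np.int64)
        )
        if len(stacked):
            stacked[:, m] = 0
        # keep only derived alleles actually present in the ingroup
        seg = np.flatnonzero(stacked.sum(axis=1) > 0) if len(stacked) else np.array([], int)
        stacked = stacked[seg]
        row_alleles = [row_alleles[j] for j in seg]
        if from_outgroup:
            # drop if the outgroup's allele is absent from the ingroup ("third allele")
            if anc_j == 0:
                anc_in = k_in[~m] - matrix.ac[s][:, in_idx].sum(axis=0)[~m]
            else:
                anc_in = matrix.ac[s][anc_j - 1, in_idx][~m]
            if not np.any(anc_in > 0):
                continue
        positions.append(matrix.positions[s])
        alleles.append(tuple([anc] + row_alleles))
        ac.append(stacked if len(stacked) else np.zeros((0, len(in_idx)), dtype=np.int64))
        missing.append(m)

    if not positions:
        warnings.warn("no site could be polarized; output matrix is empty")
    S = len(positions)
    return GenotypeMatrix(
        matrix.chrom,
        np.asarray(positions, dtype=np.int64),
        pm,
        alleles,
        ac,
        np.asarray(missing, dtype=bool).reshape(S, pm.n),
        polarized=True,
    )


def extract_patterns(matrix: GenotypeMatrix) -> list[SitePattern]:
    """Ordered site patterns from a polarized matrix.

    Excludes sites with any missing ingroup genotype, sites with more than one
    derived allele, and monomorphic sites (derived total 0 or H).  Singletons
    are retained: they never become internal nodes but carry knockout
    information during collection.
    """
    if not matrix.polarized:
        raise ValueError("extract_patterns requires a polarized matrix")
    k = matrix.ploidy_map.array()
    H = matrix.ploidy_map.H
    out: list[SitePattern] = []
    for s in range(matrix.n_sites):
        if matrix.missing[s].any():
            continue
        if matrix.ac[s].shape[0] != 1:
            continue
        counts = matrix.ac[s][0]
        tot = int(counts.sum())
        if tot == 0 or tot >= H:
            continue
        out.append(SitePattern.from_counts(matrix.positions[s], counts, k))
    return out


def write_patterns(patterns: Iterable[SitePattern], ploidy_map: PloidyMap, path) -> None:
    """TSV with position, per-individual derived counts, and flags."""
    rows = [
        {
            "position": p.position,
            **{ind: c for ind, c in zip(ploidy_map.individuals, p.counts)},
            "ambiguous": int(p.ambiguous),
            "duplicable": int(p.duplicable),
            "internal_eligible": int(p.internal_eligible),
        }
        for p in patterns
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_patterns(path, ploidy_map: PloidyMap) -> list[SitePattern]:
    df = pd.read_csv(path, sep="\t")
    k = ploidy_map.array()
    return [
        SitePattern.from_counts(
            int(row["position"]),
            [int(row[ind]) for ind in ploidy_map.individuals],
            k,
        )
        for _, row in df.iterrows()
    ]
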
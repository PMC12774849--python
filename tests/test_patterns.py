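"""Site patterns, polarization and VCF round trips."""

import numpy as np
import pytest

from genoweave.patterns import (
    GenotypeMatrix,
    PloidyMap,
    SitePattern,
    extract_patterns,
    polarize,
    read_patterns,
    write_patterns,
)
from genoweave.vcfio import read_genotypes, write_vcf
from genoweave import sim


def matrix_from_counts(specs, ploidy_map, alleles=("A", "T"), polarized=True):
    """[(pos, counts-per-individual), ...] with optional None for missing."""
    positions, ac, missing = [], [], []
    for pos, counts in specs:
        positions.append(pos)
        row = np.array([0 if c is None else c for c in counts], dtype=np.int64)
        ac.append(row[None, :])
        missing.append([c is None for c in counts])
    return GenotypeMatrix(
        "chr",
        np.array(positions),
        ploidy_map,
        [tuple(alleles)] * len(specs),
        ac,
        np.array(missing, dtype=bool).reshape(len(specs), ploidy_map.n),
        polarized=polarized,
    )


class TestSitePattern:
    @pytest.mark.parametrize(
        "counts,amb,dup,internal",
        [
            ([1, 0, 1], True, True, True),
            ([2, 0, 0], False, False, True),
            ([1, 0, 0], True, True, False),  # singleton: never internal
            ([2, 1, 0], True, False, True),
            ([2, 2, 1], True, False, True),
        ],
    )
    def test_flags(self, diploid3, counts, amb, dup, internal):
        p = SitePattern.from_counts(100, counts, diploid3.array())
        assert (p.ambiguous, p.duplicable, p.internal_eligible) == (amb, dup, internal)

    def test_counts_bounded_by_ploidy(self, diploid3):
        with pytest.raises(ValueError):
            SitePattern.from_counts(1, [3, 0, 0], diploid3.array())


class TestPloidyMap:
    def test_invariants(self):
        with pytest.raises(ValueError):
            PloidyMap(("a",), (0,))
        with pytest.raises(ValueError):
            PloidyMap(("a",), (1,))  # H < 2
        pm = PloidyMap(("a", "b"), (2, 4))
        assert pm.H == 6
        assert pm.tip_labels() == ["a_1", "a_2", "b_1", "b_2", "b_3", "b_4"]

    def test_tsv_roundtrip(self, tmp_path):
        path = tmp_path / "ploidy.tsv"
        path.write_text("a\t2\nb\t4\n")
        pm = PloidyMap.from_tsv(path)
        assert pm.ploidies == (2, 4)


class TestExtractPatterns:
    def test_filters(self, diploid3):
        m = matrix_from_counts(
            [
                (10, [1, 0, 1]),  # kept
                (20, [2, 2, 2]),  # monomorphic derived: dropped
                (30, [0, 0, 0]),  # monomorphic ancestral: dropped
                (40, [1, None, 0]),  # missing: dropped
                (50, [1, 0, 0]),  # singleton: kept, not internal-eligible
            ],
            diploid3,
        )
        pats = extract_patterns(m)
        assert [p.position for p in pats] == [10, 50]
        assert pats[0].internal_eligible and not pats[1].internal_eligible

    def test_totals_in_range(self, diploid3):
        ts = sim.simulate_arg([2, 2, 2], 20_000, mu=5e-8, seed=3)
        m = sim.matrix_from_ts(ts)
        H = m.ploidy_map.H
        for p in extract_patterns(m):
            assert 1 <= p.derived_total <= H - 1

    def test_phased_haploid_never_ambiguous(self):
        ts = sim.simulate_arg(8, 20_000, mu=5e-8, seed=4)
        m = sim.matrix_from_ts(ts)
        assert all(not p.ambiguous for p in extract_patterns(m))

    def test_roundtrip(self, tmp_path, diploid3):
        m = matrix_from_counts([(10, [1, 0, 1]), (25, [2, 1, 0])], diploid3)
        pats = extract_patterns(m)
        path = tmp_path / "patterns.tsv"
        write_patterns(pats, diploid3, path)
        back = read_patterns(path, diploid3)
        assert back == pats


class TestPolarize:
    def diploid_vcf_matrix(self, specs, individuals=("A", "B", "OUT")):
        """Unpolarized matrix: specs are per-site ALT counts (None=missing)."""
        pm = PloidyMap.uniform(list(individuals), 2)
        return matrix_from_counts(specs, pm, polarized=False)

    def test_outgroup_hom_ref(self):
        m = self.diploid_vcf_matrix([(10, [1, 0, 0])])
        p = polarize(m, outgroup=["OUT"])
        assert p.individuals == ("A", "B")
        assert list(p.derived_counts(0)) == [1, 0]

    def test_outgroup_hom_alt_flips_polarity(self):
        m = self.diploid_vcf_matrix([(10, [0, 1, 2])])
        p = polarize(m, outgroup=["OUT"])
        # ALT is ancestral: A has 0 ALT = 2 derived REF copies
        assert list(p.derived_counts(0)) == [2, 1]
        assert p.alleles[0] == ("T", "A")

    def test_outgroup_het_drops_site(self):
        m = self.diploid_vcf_matrix([(10, [1, 0, 1]), (20, [1, 1, 0])])
        p = polarize(m, outgroup=["OUT"])
        assert list(p.positions) == [20]

    def test_outgroup_missing_drops_site(self):
        m = self.diploid_vcf_matrix([(10, [1, 0, None]), (20, [1, 1, 0])])
        p = polarize(m, outgroup=["OUT"])
        assert list(p.positions) == [20]

    def test_empty_output_warns(self):
        m = self.diploid_vcf_matrix([(10, [1, 0, 1])])
        with pytest.warns(UserWarning):
            p = polarize(m, outgroup=["OUT"])
        assert p.n_sites == 0

    def test_aa_tag_preferred(self):
        m = self.diploid_vcf_matrix([(10, [1, 2, 1])])
        m.ancestral = ["T"]  # ALT declared ancestral by annotation
        p = polarize(m, outgroup=["OUT"])
        assert list(p.derived_counts(0)) == [1, 0]  # REF copies are derived


class TestVcf:
    def test_gt_parsing_and_roundtrip(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/1/1/1\t./.\n"
            "chr1\t200\t.\tG\tC\t.\tPASS\t.\tGT\t1|1\t0/0/0/1\t0/0\n"
            "chr1\t300\t.\tG\tGA\t.\tPASS\t.\tGT\t0/1\t0/0/0/0\t0/0\n"  # indel
        )
        pm = PloidyMap(("S1", "S2", "S3"), (2, 4, 2))
        m = read_genotypes(vcf, pm)
        assert m.n_sites == 2  # indel skipped
        assert list(m.ac[0][0]) == [1, 3, 0]
        assert m.missing[0, 2] and not m.missing[1].any()
        assert list(m.ac[1][0]) == [2, 1, 0]  # phase separators ignored

        out = tmp_path / "rt.vcf"
        write_vcf(m, out, contig_length=1000)
        m2 = read_genotypes(out)
        assert [list(a[0]) for a in m2.ac] == [list(a[0]) for a in m.ac]
        assert m2.ploidy_map.ploidies == (2, 4, 2)  # inferred from GT arity

    def test_gt_arity_conflict_raises(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n"
        )
        pm = PloidyMap(("S1",), (4,))
        with pytest.raises(ValueError, match="S1"):
            read_genotypes(vcf, pm)

    def test_polarized_roundtrip_via_aa(self, tmp_path):
        ts = sim.simulate_arg([2, 2, 2], 20_000, mu=5e-8, seed=11)
        m = sim.matrix_from_ts(ts)
        path = tmp_path / "sim.vcf"
        write_vcf(m, path, contig_length=20_000)
        back = polarize(read_genotypes(path))
        assert [p.counts for p in extract_patterns(back)] == [
            p.counts for p in extract_patterns(m)
        ]
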
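"""VCF input/output for genotype matrices (plain or bgzipped VCF 4.x, via pysam)."""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pysam

from .patterns import GenotypeMatrix, PloidyMap

__all__ = ["read_genotypes", "write_vcf"]

logger = logging.getLogger(__name__)


def read_genotypes(
    vcf_path,
    ploidy_map: PloidyMap | None = None,
    chrom: str | None = None,
    default_ploidy: int = 2,
) -> GenotypeMatrix:
    """Read per-individual alternate-allele counts from a VCF.

    Phase separators are ignored.  Non-SNP records (indels, symbolic alleles)
    are skipped with a logged count.  A sample whose GT arity conflicts with
    its declared ploidy raises a hard error naming the sample and site.  When
    ``ploidy_map`` is omitted, ploidy is inferred from the first record's GT
    arity (falling back to ``default_ploidy`` for samples missing there).
    """
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)

    records = [
        rec for rec in vf.fetch(chrom) if chrom is None or rec.chrom == chrom
    ] if _is_indexed(vf) else [
        rec for rec in vf if chrom is None or rec.chrom == chrom
    ]
    if ploidy_map is None:
        ploidies = []
        for s in samples:
            gt = records[0].samples[s].get("GT") if records else None
            ploidies.append(len(gt) if gt is not None and len(gt) else default_ploidy)
        ploidy_map = PloidyMap(tuple(samples), tuple(ploidies))
    else:
        missing_samples = [s for s in ploidy_map.individuals if s not in samples]
        if missing_samples:
            raise ValueError(f"samples not in VCF: {missing_samples}")

    k = ploidy_map.array()
    n = ploidy_map.n
    chrom_seen: str | None = chrom
    positions, alleles, ac, missing, ancestral = [], [], [], [], []
    n_skipped = 0
    has_aa = False
    for rec in records:
        if chrom_seen is None:
            chrom_seen = rec.chrom
        elif rec.chrom != chrom_seen:
            raise ValueError(
                f"multiple chromosomes in input ({chrom_seen}, {rec.chrom}); "
                "pass chrom= to select one"
            )
        allelestrs = (rec.ref,) + tuple(rec.alts or ())
        if any(a is None or len(a) != 1 or a not in "ACGTacgt" for a in allelestrs):
            n_skipped += 1
            continue
        n_alt = len(allelestrs) - 1
        site_ac = np.zeros((n_alt, n), dtype=np.int64)
        site_missing = np.zeros(n, dtype=bool)
        for i, ind in enumerate(ploidy_map.individuals):
            gt = rec.samples[ind].get("GT")
            calls = tuple(a for a in (gt or ()))
            if len(calls) != k[i]:
                raise ValueError(
                    f"GT arity {len(calls)} != ploidy {k[i]} for sample {ind} "
                    f"at {rec.chrom}:{rec.pos}"
                )
            if any(a is None for a in calls):
                site_missing[i] = True
                continue
            for a in calls:
                if a > 0:
                    site_ac[a - 1, i] += 1
        aa = rec.info.get("AA") if "AA" in rec.info else None
        if isinstance(aa, tuple):
            aa = aa[0]
        if aa:
            has_aa = True
        positions.append(rec.pos)
        alleles.append(tuple(a.upper() for a in allelestrs))
        ac.append(site_ac)
        missing.append(site_missing)
        ancestral.append(str(aa).upper() if aa else None)
    if n_skipped:
        logger.info("skipped %d non-SNP records", n_skipped)
    S = len(positions)
    return GenotypeMatrix(
        chrom_seen if chrom_seen is not None else "chr",
        np.asarray(positions, dtype=np.int64),
        ploidy_map,
        alleles,
        ac,
        np.asarray(missing, dtype=bool).reshape(S, n),
        polarized=False,
        ancestral=ancestral if has_aa else None,
    )


def _is_indexed(vf: pysam.VariantFile) -> bool:
    try:
        return vf.index is not None
    except Exception:
        return False


def write_vcf(matrix: GenotypeMatrix, path, contig_length: int | None = None) -> None:
    """Write a GenotypeMatrix as an unphased plain-text VCF.

    For a polarized matrix the REF column holds the ancestral allele and an
    ``AA`` INFO tag is emitted, so polarization round-trips.
    """
    pm = matrix.ploidy_map
    L = contig_length or int(matrix.positions[-1]) + 1 if matrix.n_sites else 1
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.chrom},length={L}>\n")
        fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(pm.individuals)
            + "\n"
        )
        for s in range(matrix.n_sites):
            al = matrix.alleles[s]
            ref, alts = al[0], al[1:]
            info = f"AA={al[0]}" if matrix.polarized else "."
            gts = []
            for i, kk in enumerate(pm.ploidies):
                if matrix.missing[s, i]:
                    gts.append("/".join(["."] * kk))
                    continue
                counts = matrix.ac[s][:, i]
                calls = []
                for j, c in enumerate(counts):
                    calls.extend([str(j + 1)] * int(c))
                calls = ["0"] * (kk - len(calls)) + calls
                gts.append("/".join(calls))
            fh.write(
                f"{matrix.chrom}\t{matrix.positions[s]}\t.\t{ref}\t"
                f"{','.join(alts) if alts else '.'}\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )
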
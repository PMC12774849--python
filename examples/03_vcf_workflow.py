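"""VCF in, polarized site patterns and local trees out.

Simulates 4 diploid ingroup individuals plus one diploid outgroup, writes a
plain-text VCF without ancestral-allele annotation, then reads it back,
polarizes against the outgroup and infers local trees — the workflow for
real resequencing data.
"""

import tempfile
from pathlib import Path

import numpy as np

import genoweave as gw
from genoweave import sim

# individual ind4 will serve as the outgroup
ts = sim.simulate_arg([2, 2, 2, 2, 2], L=50_000, mu=2e-8, r=1e-8, seed=12)
matrix = sim.matrix_from_ts(ts)

with tempfile.TemporaryDirectory() as d:
    vcf = Path(d) / "cohort.vcf"
    gw.write_vcf(matrix, vcf, contig_length=50_000)
    # strip the AA tag the writer emits, to force outgroup polarization
    lines = [l for l in vcf.read_text().splitlines() if not l.startswith("##INFO")]
    lines = [l.replace("AA=A", ".").replace("AA=T", ".") for l in lines]
    vcf.write_text("\n".join(lines) + "\n")

    raw = gw.read_genotypes(vcf)
    print(f"read {raw.n_sites} SNPs for {raw.n_ind} individuals "
          f"(ploidies {raw.ploidy_map.ploidies})")

    polarized = gw.polarize(raw, outgroup=["ind4"], use_aa_tag=False)
    print(f"{polarized.n_sites} sites polarizable against the outgroup")
    print("(dropped sites: outgroup heterozygous or missing — ancestral state unknowable)")

    patterns = gw.extract_patterns(polarized)
    n_amb = sum(p.ambiguous for p in patterns)
    n_dup = sum(p.duplicable for p in patterns)
    print(f"{len(patterns)} usable patterns; {n_amb} ambiguous, {n_dup} duplicable")

    lts = gw.infer_local_trees(polarized, L=50_000)
    print(f"inferred {lts.num_trees} local trees over [0, 50000)")
    out = Path(d) / "trees.tsv"
    gw.write_newick(lts, out)
    print("\nfirst lines of the interval+newick export:")
    print("\n".join(out.read_text().splitlines()[:3]))
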
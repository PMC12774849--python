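"""The polarized four-gamete test generalized to unphased genotypes.

Two polarized sites conflict with a single genealogy when haplotypes 01, 10
and 11 all provably exist.  With unphased counts, presence is proven per
individual: count a at site 1, b at site 2, ploidy k gives 10 if a > b,
01 if b > a, and 11 if a + b > k.
"""

from genoweave import haplotype_certificates, incompatible

print("diploid genotype (0,1):", haplotype_certificates([0], [1], [2]),
      " -> haplotype 01 present (plus ancestral 00)")
print("diploid genotype (2,1):", haplotype_certificates([2], [1], [2]),
      " -> haplotypes 11 and 10 present")
print("diploid genotype (1,1):", haplotype_certificates([1], [1], [2]),
      " -> ambiguous: could be 00+11 or 01+10")

# two individuals with two-site genotypes 12 and 11: certainty about all
# three derived haplotypes is impossible, so the sites pass the test
p, q, k = [1, 1], [2, 1], [2, 2]
print("\ngenotypes 12,11  incompatible?", incompatible(p, q, k))

# four haploids where 10, 01 and 11 are all observed directly
p, q, k = [1, 1, 0, 0], [0, 1, 1, 0], [1, 1, 1, 1]
print("haploid 10/11/01 case incompatible?", incompatible(p, q, k))

# mixed ploidy: a tetraploid with 3 + 2 derived alleles proves 11 exists
p, q, k = [3, 0], [2, 1], [4, 2]
print("tetraploid+diploid case:", haplotype_certificates(p, q, k),
      "incompatible?", incompatible(p, q, k))
print("\nincompatible sites imply a recombination breakpoint between them")
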
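# Methods

## Model and assumptions

genoweave reconstructs the sequence of local genealogical *topologies* along
a chromosome from polarized genotype calls. The governing assumptions:

- **Infinite sites.** Each variant arose once; all carriers of a derived
  allele descend from one ancestor. A site's evidence is its *pattern*: the
  vector of derived-allele counts per individual. Recurrent mutation
  violates this and shows up as spurious incompatibility; in practice it
  behaves like a low rate of genotyping error.
- **Polarization.** Derived vs ancestral must be known, either from an `AA`
  INFO annotation or from an outgroup (the allele fixed among non-missing
  outgroup calls is ancestral; sites with a polymorphic, missing or
  ingroup-absent outgroup allele are dropped — conservative where the
  ancestral state is unknowable).
- **Unphased counts suffice, labels do not.** Every inferred tree carries
  one tip per haplotype, but tips of the same individual are interchangeable.
  Nothing downstream (topology weighting in particular) may depend on
  within-individual labels, and the package's metrics are constructed to be
  invariant under them.
- **No times.** Branch lengths are never inferred. Exported tree sequences
  carry node "times" equal to derived-allele totals purely to satisfy the
  parent-older-than-child table constraint; they have no temporal meaning.

Three consequences of unphased data shape the algorithm: patterns with a
count strictly between 0 and ploidy are *ambiguous* (which of the
individual's tips descend from the node is unknowable); patterns in which no
individual exceeds half its ploidy are *duplicable* (one pattern may
correspond to several nodes of one tree); and pairwise compatibility is only
maximum-parsimony (a jointly unrealizable set can be pairwise compatible),
so conflicts are finally resolved at tree building, where a pattern whose
child search fails is discarded.

## Pipeline

1. **Patterns** (`patterns.py`): sites with missing ingroup calls, more than
   one derived allele, or monomorphic counts are excluded; singletons are
   kept (they cannot become internal nodes but still knock out conflicting
   patterns).
2. **Collection** (`collect.py`): two directional knockout sweeps build,
   for every site, the set of patterns compatible with it; identical
   patterns from different sites are merged, tracking the nearest
   supporting position per sweep. *Second chances*: a knocked-out pattern
   becomes eligible again once its knocker is itself knocked out; the
   restored pattern is re-screened against the incoming pattern only
   (restoration is non-transitive and resolved once per sweep step — linear
   cost). Left- and right-collections are reconciled greedily in order of
   nearest-variant distance (base pairs, not variant ranks), the focal
   pattern first; at equal distance the left pattern wins (determinism).
3. **Tree building** (`trees.py`): internal-eligible patterns are attempted
   in order of nearest-variant distance (ties: position, then larger derived
   total). A pattern is inserted below the deepest node strictly containing
   it, accumulating children greedily from that node's current children —
   leaves in individual order first, then internal nodes by decreasing
   derived total — committing exactly when the child patterns sum to the
   pattern (with at least two children). After the first pass, duplicable
   patterns are re-attempted until nothing fits, capped at
   floor(H / total) copies; re-adding is attempted whether or not several
   sites support the pattern, mirroring the resolve-polytomies-if-possible
   behaviour of the second pass.
4. **Sequential building** (`treeseq.py`): each site's build is seeded with
   the previous site's tree minus internal nodes absent from the new
   collection and minus all but the oldest copy of each duplicated pattern
   (the multipass re-adds the rest if still warranted). Runs of sites with
   identical trees form one span; breakpoints are midpoints between the
   flanking variants (kept fractional), the first span starting at 0 and
   the last ending at the chromosome length. Node identities persist where
   trees are shared, which is what makes the tskit table export succinct.
5. **Weighting** (`weights.py`): counts are exact over all one-tip-per-group
   combinations. Two independent routes exist — exhaustive enumeration
   (optionally collapsing monophyletic single-group clades, which provably
   leaves counts unchanged) and, for three groups, a linear-time scan that
   counts, at each node, tip pairs whose MRCA is exactly that node times
   the third group's tips outside it. Combinations whose induced subtree
   meets a polytomy go to an `unresolved` bin; weights can be reported over
   all combinations or renormalized over resolved ones (the default for
   comparisons, since truth ARGs are fully resolved).
6. **Stacking** (`stacking.py`): minimal subsets (one individual per group)
   are enumerated exhaustively when few, otherwise sampled uniformly
   *without replacement* (distinct subsets maximize information per run).
   Per subset, sites are re-filtered — missing data, biallelism and
   segregation are re-evaluated within the subset, which is why stacking
   can use sites whole-dataset inference must discard. Sub-ARG spans cover
   the full chromosome by construction, so stacked counts are defined
   everywhere.

## Metrics

*Rooted quartet similarity* between two trees on the same tips is the
fraction of agreeing rooted triplets (3 tips + the implicit root): exact
over all C(H,3) triples for H ≤ 8, otherwise estimated from 100 sampled
triples. A triple resolved in one tree and not the other is a mismatch;
unresolved in both is a match (polytomies are penalized against a resolved
truth). Because within-individual tips are interchangeable, a triple is
scored at the individual level: over every distinct-tip realization of its
individual multiset, the two trees' triplet-signature multisets are
intersected and the overlap fraction is the triple's score — identical up
to within-individual relabeling scores 1, and the phased/haploid case
reduces to the classical 0/1 comparison. Whole-ARG similarity and the
weight-track distance are span-weighted means over maximal tracts where
both inputs are constant; the weight distance per tract is ‖Δw‖₂/√2, its
maximum for probability vectors, giving values in [0, 1] ("double-scaled").

## Synthetic data

`sim.py` wraps msprime behind an output-defined contract (true tree
sequence + 0/1 haplotypes), verified independently by a Watterson
segregating-sites test. Defaults describe a neutral panmictic population:
N_e = 10,000 and per-site mutation and recombination rates of 1e-8
(ρ/Θ = 1, the typical genome-wide regime). Infinite-sites data keeps only
the oldest mutation at any multiply-hit site; a finite-sites mode retains
recurrences. Haplotypes are grouped into individuals in sample order, so
tip labels agree between truth and inference. The multispecies generator is
a pectinate split tree (splits 20,000 generations apart by default — one
2N_e unit, enough divergence for a dominant species topology with
substantial incomplete lineage sorting) with a single admixture pulse
(default: 30% from P3 into P2 at 4,000 generations), exposing split times
and admixture fraction as free parameters. The error model is deliberately
parametric and simple — independent moves to an adjacent allele count, and
per-site polarity flips — it probes robustness qualitatively and does not
emulate any platform-specific error process. Green tests on these data
establish algorithmic correctness under the stated model, not performance
on real genotype likelihoods, indels, or structural variation.

## Numerical and design choices

- Compatibility uses each individual's own ploidy in the sum condition, so
  mixed-ploidy datasets need no special casing.
- The greedy child order (leaves first, then large internal nodes) is
  isolated in one function; the construction of the worked examples pins
  its observable behaviour.
- A candidate child equal to the pattern being inserted is skipped — a
  one-child node is meaningless — which is also what forces duplicate
  copies to be built from disjoint nodes.
- Tie-breaks (reconciliation at equal distance, node attempt order, kept
  duplicate copy when seeding) are all fixed and documented above;
  identical inputs give identical outputs, and subset sampling and triple
  sampling take explicit seeds.
- Weight-track comparison excludes tracts where either track has no
  resolved combination (NaN under resolved renormalization); such tracts
  essentially never arise in stacked tracks with hundreds of subsets.

## Mutation density and the resolution limit

A clade can only be recovered if some mutation fell on its branch. For 8
haplotypes with ~200 expected mutations and no recombination, roughly a
quarter of coalescent trees have at least one internal edge with no
mutation, so the inferred tree keeps a polytomy there and exact topology
recovery tops out near ~75% of replicates; essentially all replicates are
exact by ~2,000 mutations. The corresponding test suite entry documents
this boundary: the failure is an information limit of any pattern-based
method, not an algorithmic one (in every imperfect replicate the builder
used every internal-eligible pattern present in the data).

## Known limitations

- Accuracy of whole-dataset inference degrades beyond ~16 haplotypes: with
  many samples, incompatibilities are frequent, knockout collections grow
  short-sighted, and disjunct haplotype blocks are missed beyond what
  second chances recovers. Topology weighting avoids this via stacking.
- The pairwise test's parsimony assumption means some conflicting pattern
  sets reach the tree builder; the builder's discard order (by distance) is
  a heuristic and the second-chances rule is non-transitive by design.
- Genotype likelihoods, imputation and indels are out of scope; multiallelic
  sites are used only by stacking (per-subset), never by whole-dataset
  inference.
- Inferred breakpoint counts underestimate the true number of recombination
  events — breakpoints that do not change the local topology are invisible
  to any topology-only method.
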
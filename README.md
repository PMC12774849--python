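# genoweave

Local genealogy inference from **unphased** genotypes of any ploidy, and
topology weighting by stacking many small sub-ARGs.

## The problem

The genealogy of a sample changes along a recombining chromosome (the
ancestral recombination graph, ARG). Most ARG inference tools require phased
haplotypes, which are rarely available for small multispecies datasets from
non-model organisms — and essentially never for polyploids. genoweave infers
the *topology* of the local genealogy at every variant site directly from
per-individual derived-allele counts, with no phasing, no demographic model
and no coalescence-time inference. It is aimed at population geneticists
studying relatedness, introgression and trait-associated loci in datasets of
mixed or high ploidy.

## The method

Under the infinite-sites model, every variant site's **pattern** — the vector
of derived-allele counts per individual, e.g. `[2,1,0]` for three diploids —
identifies one node of the local genealogy, and a set of mutually compatible
patterns determines a tree (perfect phylogeny). The pieces:

- **Generalized four-gamete test.** Polarized sites *p*, *q* conflict with a
  single tree iff all three derived two-site haplotypes 01, 10, 11 provably
  exist: ∃i p_i > q_i (10), ∃i q_i > p_i (01), ∃i p_i + q_i > k_i (11),
  with k_i the ploidy of individual *i*. Exact for haploids; a
  maximum-parsimony assumption otherwise.
- **Collecting.** For each site, compatible patterns are gathered from
  surrounding sites by two directional knockout sweeps (a pattern knocked out
  by an incompatible incomer becomes eligible again once its knocker is
  itself knocked out — the "second chances" rule), reconciled by keeping, in
  any conflict, the pattern whose nearest supporting variant is closest to
  the focal site.
- **Tree building.** Starting from the previous site's tree (shared nodes are
  reused, so the output is a succinct tree sequence), each pattern is
  committed as a node exactly when a greedily chosen set of existing nodes'
  patterns sums element-wise to it; duplicable patterns (no individual above
  half ploidy) may be instantiated multiple times on later passes.
  Breakpoints emerge as midpoints between sites whose trees differ.
- **Topology weighting.** For g groups there are (2g−3)!! rooted topologies
  (3 for g = 3, 15 for g = 4); a tree's weights are the fractions of
  one-tip-per-group subtrees matching each. Because whole-dataset inference
  degrades beyond ~16 haplotypes, weights are instead computed by inferring a
  minimal sub-ARG per subset (one individual per group), counting subtree
  topologies per sub-ARG, and **stacking**: summing counts over the union of
  all sub-ARG breakpoints.

Tips of one individual are interchangeable labels, not phased haplotypes;
every comparison metric in the package respects that.

## Worked example

`python examples/01_simulate_and_infer.py` simulates 4 diploid individuals
(ρ/Θ = 1), strips phase, and infers the local trees:

```
simulated 141 variant sites, 28 true local trees
inferred 7 local trees:
  [     0.0,   2276.0)  ((ind3_1,(ind0_1,ind1_1)),(ind2_1,ind3_2),(ind1_2,(ind0_2,ind2_2)));
  [  2276.0,  10855.0)  ((ind2_1,ind3_2),((ind3_1,(ind0_1,ind1_1)),(ind1_2,(ind0_2,ind2_2))));
  ...
span-weighted rooted quartet similarity to truth: 0.886
```

The similarity is the fraction of rooted triplets (3 tips + root) agreeing
with the true ARG, averaged over the chromosome with tract-length weights;
0.886 means most local topology is recovered from unphased data. Far fewer
trees are inferred than simulated because most recombination events do not
change the topology detectably.

`python examples/05_stacked_weights.py` runs the stacking route on 10
diploids per group under a 3-species split-with-admixture history:

```
  8 sub-ARGs: distance to truth weights 0.250
 32 sub-ARGs: distance to truth weights 0.234
128 sub-ARGs: distance to truth weights 0.228
```

printing the span-weighted scaled Euclidean distance (0 = identical weights
everywhere) between stacked weights and those of the true ARG — the
Monte-Carlo error shrinks as subsets accumulate.

The other examples cover the generalized four-gamete test (`02`), the
VCF-with-outgroup workflow (`03`), single-ARG weighting (`04`) and error
robustness (`06`).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from fresh simulations, the frequency of *duplicate nodes* —
internal nodes of neutral coalescent genealogies (4 diploid individuals,
ρ/Θ = 1) whose unphased site pattern is a redundant copy of another node's
in the same local tree — the quantity that bounds how often unphased
inference can pick the wrong number of nodes. Results are written as JSON
with the percentage and the number of nodes surveyed.

## Layout

| Path | Contents |
| --- | --- |
| `src/genoweave/patterns.py`, `vcfio.py` | site patterns, ploidy maps, VCF I/O, polarization |
| `src/genoweave/compat.py` | generalized four-gamete test |
| `src/genoweave/collect.py` | knockout collection with second chances |
| `src/genoweave/trees.py`, `treeseq.py` | perfect-phylogeny builder, sequential tree sequence, tskit/newick export |
| `src/genoweave/weights.py`, `stacking.py` | topology enumeration/counting, sub-ARG stacking |
| `src/genoweave/metrics.py` | quartet similarity, ARG and weight-track comparison |
| `src/genoweave/sim.py` | coalescent synthetic data, error models |

See `docs/methods.md` for assumptions, parameter choices and limitations.
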
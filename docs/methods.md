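# Methods

## Scope and model

phylopop implements the post-assembly, post-variant-calling half of a
phylotranscriptomic workflow for sets of closely related samples: homolog
clustering of coding sequences, hygiene of homolog gene trees, orthology by
maximum inclusion, alignment summary statistics, a hard-filter cascade over
multi-sample genotype calls, and PCA-based structure diagnostics. Upstream
steps (read processing, assembly, alignment construction, ML tree
inference, variant calling) are out of scope; the pipeline starts from
sequences, trees — built internally with neighbor joining on Jukes–Cantor
distances when no externally inferred trees are supplied — and a VCF.

## Homolog clustering

Redundancy within a sample is removed by greedy longest-first clustering:
records sorted by descending ungapped length (ties by record id) join an
existing representative when their identity to it is ≥ 0.99, where identity
is matches divided by the shorter length, with exact containment scoring
1.0. This is the cd-hit convention for near-duplicate collapse; no gapped
alignment is attempted because redundancy at this stage means re-assembled
duplicates and truncations, not divergent paralogs.

The all-by-all similarity search is a k-mer-seeded ungapped comparison
(k = 12): only pairs sharing an exact 12-mer are compared, the alignment
offset is chosen by seed voting, and the edge weight is the identity over
the overlap. Edges require identity ≥ 0.7 by default; this cutoff is a
stand-in for a search e-value and is exposed in the config
(`min_identity`). Random unrelated DNA (expected identity ≈ 0.25) never
seeds, so the graph stays family-structured.

Markov clustering uses the standard expansion/inflation iteration
(inflation 1.4) on the column-normalised weighted adjacency with self-loops
set to each node's maximum incident weight (1.0 when isolated). Numerical
settings — prune entries < 1e-8, converge at max change < 1e-6, cap at 100
sweeps, clusters read off the converged matrix support — follow common MCL
defaults. Non-convergence returns the current partition with a warning.
Clusters with fewer than 4 distinct taxa are dropped.

## Gene-tree cleaning

A tip is removed iff its terminal branch b satisfies
(b ≥ 0.02 subs/site AND b ≥ 10 × sister) OR b ≥ 0.03 subs/site.
Two points the two-cutoff rule leaves open were fixed as follows:

* **Sister branch of a tip.** The minimum terminal branch among the other
  tips on the same internal node; when every sibling subtree is internal,
  the sibling edge length itself. This is a concrete, testable reading —
  an interpretation, not the only possible one.
* **No cascading within a sweep.** All removal decisions in one round are
  made against the round's input tree, then applied at once; degree-2 nodes
  left behind are suppressed with their two edges summed. Cascading happens
  only across rounds (two by default). This makes a round order-independent
  and deterministic.

Trees where removal would leave fewer than two tips are discarded and
counted. Splitting treats the tree as unrooted: any internal edge
> 0.2 subs/site whose two sides each contain ≥ 4 distinct taxa is cut,
longest edge first, re-evaluating candidates on the resulting components.
Per-sample removal rates are removed/before, reported per round; on
synthetic batches the second round removes nothing because the planted
offenders are linearly separable from legitimate variation (see below).

## Maximum-inclusion orthology

Orthologs are extracted greedily: after (optionally, per iteration)
re-trimming long tips with the same relative/absolute cutoffs, all subtrees
obtainable by cutting one edge in either direction — plus the whole tree —
are scored; those with at most one tip per taxon qualify. The winner has
the most distinct taxa, ties broken by smaller total internal branch length
(rounded to 12 decimals to make float ties stable), then by the
lexicographically smallest sorted tip-label list. Winners with ≥ 10 taxa
are emitted and their tips deleted; the loop repeats until nothing
qualifies. The greedy order, tie rules and per-iteration re-trim
(`MIParams.retrim_each_iteration`, default on) are this package's
deterministic completion of the method; the whole loop is verified against
a brute-force enumeration oracle in the test suite. Ortholog alignments are
row-subsets of the homolog alignment, re-cleaned at 10% column occupancy,
with copy suffixes dropped from row names.

## Alignment statistics

Column occupancy keeps a column when its non-missing fraction is ≥ the
threshold (boundary inclusive); 'N' counts as missing like '-' by default,
switchable, since tools differ on this. Parsimony-informative columns have
≥ 2 non-missing states each present in ≥ 2 rows. Concatenation gap-fills
absent taxa per gene and emits 1-based inclusive partitions that exactly
invert the operation.

## Genotype filter cascade

A site is removed when any criterion fires; the order 1→6 matters only for
the report's first-failure attribution, and the kept set is provably
order-invariant (removal is an OR). Interpretation choices, all exposed as
config:

* Allele balance is alternate reads / total reads per sample; the
  homozygote rule "AB > 0.05" is read symmetrically as minor-read fraction
  > 0.05 (for 1/1 calls the reference reads are the minor reads).
* MAF is computed over called genotypes only; removal at MAF ≤ 0.05 by
  default with strict < available (`maf_strict`), since both conventions
  appear in practice.
* A missing genotype fails the per-sample depth rule by default
  (`missing_fails_depth`); the lenient reading skips missing samples, which
  is the mode under which the locus-presence rule (≥ 15 of 19 samples
  genotyped at ≥ 1 site of the locus) has independent effect.
* Monomorphic sites are exempt from the QUAL criterion (it applies to
  polymorphic calls) but are still subject to depth and MAF.

One SNP per locus is drawn uniformly among the locus's informative sites
(≥ 2 distinct called genotype values), with a dedicated seeded generator,
so the choice is reproducible and loci with no informative site contribute
nothing.

## PCA and Hardy–Weinberg diagnostic

Genotypes (0/1/2 alt-allele counts) are standardised EIGENSTRAT-style:
centre by 2p̂, scale by √(2p̂(1−p̂)), mean-impute missing to 0 after
centring, drop monomorphic columns with a warning. PCA eigendecomposes the
sample covariance S·Sᵀ/m; coordinates are eigenvectors scaled by the root
eigenvalue, each component oriented so its largest-magnitude entry is
positive (a reproducible sign convention). The HWE table reports per-site
p̂, observed heterozygote fraction and 2p̂(1−p̂). Layer recovery is scored
as best-permutation agreement (Hungarian matching) between k-means on
PC1–2 and the true labels.

## Synthetic data: what it emulates, and what it does not

The family generator emulates a 19-ingroup / 2-outgroup transcriptome
study with minimal within-species divergence: ingroup internal branches
U(0.001, 0.01) subs/site, legitimate terminal branches ≤ 0.01, outgroups on
a 0.05 stem. Families optionally carry one duplicated clade (2–8 taxa;
stem 0.25 subs/site when a deep split is planted, 0.1 otherwise) and one
contaminant tip (terminal branch U(0.05, 0.12), attributed to a random
sample). Sequences evolve under Jukes–Cantor with no indels, so rows are
born aligned; occupancy variation comes from terminal masking (probability
0.2 per row, masking 5–40% of one end). Defaults: 30 families of 500 bp in
the end-to-end run — enough for every stage to act while keeping a full run
in seconds.

Truth separability is by construction: contaminant branches (≥ 0.05) sit
above the absolute cutoff (0.03) while legitimate tips (≤ 0.01) sit below
the relative floor (0.02), so trimming truth is exact, and the config
rejects parameterisations that blur this margin. Consequently a passing
trim test shows threshold logic is correct — it says nothing about
borderline branches in real data, where the cutoffs are judgment calls.

Genotypes follow a Balding–Nichols layered-admixture model with k = 3
layers: per SNP, ancestral frequency p ~ U(0.1, 0.9), layer frequencies
Beta(p(1−Fst)/Fst, (1−p)(1−Fst)/Fst) with Fst = 0.1 by default, per-sample
frequencies mixed by the admixture matrix, genotypes Binomial(2, ·). The
default layout mirrors a two-sided geography: 8 samples pure in one layer,
9 in a second, 2 admixed 40/60; a third layer column is carried for the
k = 3 design and helpers provide pure 3-group layouts. Depths are Poisson
(mean 30), allele depths binomial with a 1% base-error rate, QUAL
U(100, 2000). Default scale is 200 loci × 5 SNPs.

Filter-violation plants are exact by design: control sites are drawn
conditionally on passing every criterion (depths truncated at ≥ 10,
heterozygote allele balance rejected outside [0.25, 0.75], homozygote
minor-read fraction rejected above 0.05, MAF rejected at ≤ 0.05), and each
planted site is constructed to violate its intended criterion while passing
all criteria ordered before it. This is what makes "the kept set equals the
planted clean set" a meaningful exact check; the flip side is that the
generator does not model the marginal, borderline sites that dominate real
filtering decisions, nor linkage within loci, recombination, selection or
spatial kernels.

## Numerical and degenerate-input choices

* Newick output formats branch lengths with 12 significant digits;
  round-trips are exact to 1e-9. Support values after ')' are parsed and
  discarded. Absent lengths default to 0.
* Neighbor joining clamps negative intermediate branch lengths to 0 (the
  usual convention) and breaks Q-matrix ties by smallest index pair.
* Jukes–Cantor distances exclude sites with gaps/N in either sequence and
  are undefined at mismatch ≥ 0.75 or zero comparable sites; the pipeline's
  guide-tree construction caps such pairs at 3.0 subs/site instead of
  aborting a cluster (`saturation_cap`).
* Zero-length sister branches make the 10× relative test vacuously true for
  tips at or above the relative floor.
* The per-stage seeds are CRC32-derived from the single global seed and the
  stage name, keeping every stream independent and below 2^31.

## Known limitations

The similarity search is exact-seed based and ungapped: at identities well
below ~0.7, or with real indels, it under-links relative to blastn, and the
simulator (indel-free, high identity) does not exercise that regime. MCL is
dense-matrix (fine for hundreds of sequences; not for genome-scale graphs).
The maximum-inclusion tie rules are one deterministic completion of the
method; other implementations may emit different, equally valid orthologs
when candidates tie. PCA assumes mean imputation is adequate, which degrades
with very high missingness.
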
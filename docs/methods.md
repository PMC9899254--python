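# Methods

This note documents the models behind `allophylo`: what the simulator
generates, how each estimator is defined, the numerical conventions, and the
design decisions taken where more than one defensible choice existed. It
states no empirical result; the numbers live in the test suite and in
`scripts/acceptance.py` output.

## The simulator

### History model

A scenario is a rooted tree over three kinds of leaves: two *parent tips*
(default `PA`, `PB`), the allopolyploid *crown tips* (the clade under the
internal node labelled `merge`), and diploid *outgroups* (everything else).
Branch lengths are expected synonymous substitutions per synonymous site
(Ks units).

The parent tips stand for the parental gametes at the moment of merger:
subgenome A of the allotetraploid *is* the genome evolved along the path
root → PA, and subgenome B the PB genome. Consequently the homoeologous
divergence at the merger equals the patristic distance d(PA, PB), and the
expected homoeologous Ks at a crown tip is d(PA, PB) + 2 × (depth of the tip
below `merge`). The branch leading into `merge` contributes no evolution
(the parents already carry that time); the crown hangs from `merge` through
a stem branch representing the interval between hybridization and the crown
radiation — fractionation on that stem is what marks each whole subgenome
clade in presence/absence data, as it does in real allopolyploids whose
merger predates their radiation.

The default scenario has five crown tips with a balanced-plus-outlier
topology `(((t1,t2),(t3,t4)),t5)`, two outgroups, two chromosomes of 80
genes (studies raise this; see below), parental divergence 0.30, crown
height 0.08 (stem 0.03), and outgroup depth ~0.25 — i.e. ortholog Ks of a
few percent, homoeolog Ks ≈ 0.46, outgroup Ks ≈ 0.55, the regime of a
Cretaceous allopolyploidy observed from living genomes.

### Sequence model

Genes are independent CDS (default 300 nt) starting with an immutable ATG
and free of stop codons. Along a branch of length `ks` a gene receives
`Poisson(ks·S)` synonymous events (S = its NG86 synonymous site count) and
`Poisson(ω·ks·N)` nonsynonymous events (default ω = 0.2), each placed
uniformly over the currently viable synonymous (resp. nonsynonymous)
single-nucleotide changes; changes through stops never occur. Expected NG86
Ks between two sequences therefore equals their path length, up to a small
(<~2%) upward bias of the Jukes–Cantor correction caused by rate
heterogeneity between two-fold and four-fold degenerate sites; the test
suite's recovery check budgets for exactly this bias, and it partially
cancels in ratios.

### Structural operators

Per branch, `Poisson(rate)` inversions (reverse a random within-chromosome
interval and flip strands) and tandem duplications (insert a lightly
diverged copy at the adjacent rank, fate `tandem-copy`). Loss applies only
below `merge`: per-tip loss probabilities (defaults 0.15 dominant / 0.30
recessive) are distributed along branches as
p_b = 1 − (1 − p_tip)^(ℓ_b/H), with H the crown height, so internal-branch
losses are shared by descendants — exact for ultrametric crowns (the
default), approximate otherwise. A loss probability of 1 is applied wholly
at the tip. Gene-order operators never change gene content; loss never
reorders survivors.

### Introgression

`inject_introgression(dataset, donor, recipient, f, seed)` replaces a
Bernoulli(f) subset of the recipient's CDS with the donor ortholog's CDS
(same ancestral locus; same-subgenome copy preferred). Gene order,
chromosome assignment and presence/absence are untouched by construction.
This sequence-replacement reading of ancient hybridization is one defensible
model among several; it is deliberately the *worst case* for
alignment-based methods and the null case for structural ones, which is the
contrast the package exists to measure.

### Truth and identifiers

`SimulationTruth` records the organismal tree, each emitted gene's
subgenome of origin and ancestral locus, per-lineage gene fates, realized
introgression sets and rate scalars. Gene identifiers encode tip, subgenome,
chromosome and locus for readability, but inference must never parse them:
a scrambling mode replaces all ids with opaque numbers (truth keeps the
map), and tests exercise it.

## Estimators and conventions

- **NG86 Ka/Ks.** Sites per codon position = fraction of viable (non-stop)
  single-nucleotide changes that are synonymous, averaged over the two
  sequences; differences are averaged over substitution pathways that avoid
  stop codons (all pathways as fallback when every order is blocked);
  Jukes–Cantor correction d = −¾ ln(1 − 4p/3). A proportion ≥ 3/4 cannot be
  corrected: the estimate then carries the raw proportion with
  `saturated=True` rather than raising or clipping, and downstream block
  summaries exclude flagged pairs. All 64×64 codon-pair tallies are
  precomputed, making per-pair cost a table lookup.
- **4DTv** = transversions / shared fourfold-degenerate third positions
  (both codons fourfold and identical at the first two positions); raw, no
  multiple-hit correction; undefined (None) without eligible sites.
- **Block summaries** exclude Ks = 0, Ks > 5, 4DTv = 0, 4DTv ≥ 1 per pair
  before taking medians; empty blocks are dropped and counted.
- **Ks peaks**: Gaussian KDE, Silverman bandwidth by default, local maxima
  with prominence ≥ 5% of the maximum density.
- **Relative rate**: Ks_A = (d_AB + d_AO − d_BO)/2 etc.; negatives within
  1e-9 are clamped, larger ones raise. Study summaries use the ratio of
  median branch values over gene triplets (stabler than the median of
  per-triplet ratios, whose denominators are small noisy differences).
- **Homology**: k-mer containment score (shared distinct k-mers / smaller
  k-mer set; default k=8, top 5 subjects, ties by subject id) as the fast
  stand-in for an alignment search; tabular BLAST-style hits are accepted
  as the authoritative path. Orthogroups are connected components of the
  mutual-top-hit graph — a documented simplification of tree-aware
  family inference. Duplicate modes follow the precedence WGD > TD > PD
  (≤10 intervening genes) > TRD (requires an ancestral-locus gene set) >
  DSD.
- **Chaining**: +1 per anchor, no gap penalty below the hard G cutoff;
  strict monotonicity in both genomes; per chromosome pair and orientation
  the maximum chain is peeled greedily until below A. Tie-breaks among
  equal-score chains use genome-1 coordinates; as a consequence, genome
  swap is guaranteed to preserve block *scores* but may emit a different
  member of an equal-score pair — exact symmetry holds whenever the best
  chain is unique. Tandem arrays are collapsed to their first member before
  chaining.
- **Clustering**: per connected component of the synteny network, cliques
  are kept whole; other components are split by seeded asynchronous label
  propagation, best modularity of 10 trials. Deterministic for fixed seed.
- **Binary trees**: Fitch parsimony vectorized over columns; exhaustive
  enumeration ≤ 8 taxa (≤ 5 for the Mk criterion), otherwise NNI
  hill-climbing from an NJ start on row Hamming distances. The Mk
  criterion is a simplified two-state stationary-frequency likelihood with
  discrete-gamma rates and one shared, numerically optimized branch length
  — adequate for ranking topologies on desk-scale matrices, not a
  substitute for a full Mk+R+FO fit (no ascertainment correction).
  Bootstrap support = majority rule over column resamples.
- **Subgenome assignment**: ancestral genes are RBHs against a designated
  unduplicated outgroup (a parameter, not hard-coded). Note that each
  outgroup gene RBHs to exactly *one* homoeolog, so both units' counts are
  roughly halved and anti-correlated; the dominant/recessive separation
  scales as ~0.155·√n per chromosome of n genes, which sets the genome
  sizes used in the studies. Ties are flagged and broken lexicographically.
- **Fractionation test**: paired one-sided Wilcoxon signed-rank of
  dominant − recessive retention across windows. Windows must be
  (approximately) independent, so profiles fed to the test use
  non-overlapping windows (step = window); overlapping step-1 profiles are
  for description and plotting only.
- **Quartet concordance**: under the multispecies coalescent the two minor
  quartet topologies are exchangeable; a two-sided exact binomial on the
  two non-dominant counts, Holm–Bonferroni corrected across quartets,
  flags discord beyond incomplete lineage sorting.
- **Distance comparator**: the sequence-based tree is NJ on *mean* Ks over
  RBH pairs per unit pair — the analog of concatenated alignments, which
  average signal; a median would mask precisely the introgression the
  contrast is designed to expose. Same-genome unit distances use mutual
  best intra-genome hits (homoeologs); missing unit pairs are filled with
  1.2× the largest observed distance. Negative NJ branch lengths are
  clamped to 0 and flagged.

## Study conditions (scripts/acceptance.py, tests/test_acceptance.py)

Problem sizes are chosen so that each effect is comfortably inside its
statistical resolution at desk scale:

- *Mirror recovery*: 20 replicates, 2 chromosomes × 300 genes, 5 tips + 2
  outgroups, loss 0.15/0.30; subgenome units from the pipeline's own
  assignment (not truth).
- *Introgression contrast*: 20 replicates, 2 × 200 genes, donor o1 →
  recipient t1 at f = 0.3; units fixed from the baseline analysis so the
  comparison isolates the structural signal (sequence changes can
  legitimately perturb near-tie dominance calls, which is a labelling
  question, not a topology one).
- *Rate recovery*: one clade, 2 × 400 genes, sister tips of branch 0.15
  with scalar 0.33 on one, outgroup at Quercus-like distance (~0.4).
- *Shared-WGD calibration*: 300 shared- and 100 independent-history
  families, 100-codon bootstrap, support threshold 80, 15% copy loss.
- *Assignment accuracy*: one 16-chromosome × 400-gene tip;
  *fractionation type-I*: 100 unbiased replicates (equal loss 0.2), 20
  non-overlapping 30-gene windows; *quartet type-I*: 500 replicates of 200
  trees at (0.6, 0.2, 0.2).

## What the simulations do and do not show

The generator reproduces the *logical* structure of an allopolyploid
history — two subgenome coalescent paths, biased fractionation with shared
internal-branch losses, order-preserving gene flow — with clean annotations
and complete assemblies. Real data add missing genes, fragmented scaffolds,
tandem arrays larger than one copy, segmental duplications, variable gene
length and composition, and rate variation across loci. Passing these
studies therefore demonstrates that the pipeline's inferences are correct
*given its inputs*, and that structural signal survives processes that
corrupt sequence signal; it does not certify performance on noisy
annotations, which is why every module also accepts externally computed
hits and blocks.

## Known limitations

- The older pan-eudicot triplication is not simulated; scenarios cover one
  allopolyploidy.
- The NG86/JC estimator inherits a small divergence-dependent upward bias
  (site-class rate heterogeneity); relative quantities mostly cancel it.
- Orthogroup construction by graph components can merge families bridged by
  promiscuous hits; the similarity score is containment-based and assumes
  roughly equal-length CDS.
- The Mk likelihood shares one branch length across the tree and applies no
  ascertainment-bias correction.
- θ (heterozygosity) is an input to the Ne formula, never estimated from
  reads.
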
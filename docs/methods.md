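# Methods

This note documents the models, parameter choices and numerical decisions
behind `hgtcodon`, and what the synthetic-data validation does and does not
establish about real data.

## Pan-genome construction

Pairwise gene similarity is computed with an exact 18-mer seed prefilter
followed by an edit-distance alignment (edlib) of the shorter sequence as
an infix of the longer one.  Identity is the fraction of identical aligned
columns; overlap is the aligned span divided by the length of the *longer*
sequence, which deliberately penalises fragments — that is what the
pseudo-accessory filter needs.  Homolog clusters are single-linkage
components over hits with identity ≥ 0.6 AND overlap ≥ 0.7.  Single-copy
clusters present in at least ⌊0.95·n⌋ strains are core; multi-copy
clusters meeting the prevalence rule are first split into single-copy
sub-clusters using the shared insertion locus as the orthology signal
(ties inside a locus fall back to a deterministic greedy split).  An
accessory cluster is pseudo-accessory when any member hits another cluster
with identity > 0.90, overlap < 0.70 and an alignment of ≥ 150 nt; the
alignment-length floor defines "significant" and ignores micro-homologies.
Consequence: decoy fragments shorter than 150 nt can escape the filter by
construction; the generator warns when it emits such fragments.

The seed index samples k-mers every 3 positions and queries every 30; both
steps are multiples of 3 so that codon-aligned homologs co-sample frames.
This presumes in-frame homology without indels, which the generator
guarantees and which is a reasonable first approximation for closely
related strains; for indel-rich inputs the `pairwise_similarity` path
(full seed scan) remains available.

## Strain phylogeny

Core genes are concatenated (gap-filled per missing strain), Jukes–Cantor
distances d = −(3/4)·ln(1 − 4p/3) are computed over shared non-gap
columns (p ≥ 0.75 maps to a saturation ceiling of 5.0 with a warning), and
the tree is built by neighbor joining (scikit-bio) and midpoint-rooted.
Negative NJ branch lengths are clamped to zero with the deficit moved to
the sister branch.  NJ is exact on additive matrices, which the tests
verify; downstream stages consume only topology and branch lengths, and a
user-supplied rooted Newick tree bypasses this module entirely.

## Ancestral state reconstruction

All discrete-character reconstruction (gene presence, tRNA copy numbers,
ancestral nucleotides) uses one engine: marginal posteriors under the
k-state equal-rates Markov model, computed by Felsenstein pruning with an
up–down pass, per-node rescaling for numerical stability, a uniform
(stationary) root prior, and the closed-form ER transition matrix
P_ii(t) = 1/k + (k−1)/k·e^(−krt).  The single rate is fitted by bounded
scalar ML on a log scale, bounds [1e−6, 100] per unit branch length.
Exactness is tested against exhaustive enumeration over all internal-state
assignments on trees of up to 6 tips (tolerance 1e−10).

For gene presence the state space is {0, …, max observed copy number} and
presence probability is 1 − P(state 0).  A transfer is called on a branch
iff P(presence) < 0.5 at the parent and > 0.5 at the child; exact 0.5
calls nothing (strict inequalities).  Clusters with root presence > 0.5
are excluded as ancestral genes eroded by loss.  When one cluster has
several calls at a single insertion locus they merge to the branch ending
at the LCA of the called child nodes; if that LCA is the root the cluster
is reclassified as root-present.  Calls at distinct loci stay independent
transfers.  Residence time of a (cluster, leaf) pair is the path length
from the leaf to the event branch's child node plus half that branch — the
arithmetic branch midpoint.

Note on the rate bound: with branch lengths on a substitutions-per-site
scale (tree heights of order 0.01) the bound is never active; on trees
with unit-scale branches a maximally scattered pattern can drive the
fitted rate to the bound and flatten the posteriors to 0.5, in which case
no call is made.  This is the intended behaviour of the strict call rule.

## Codon-usage metrics

Stop codons are excluded from every codon count and from the 100-codon
length filter.  ENC uses Wright's class decomposition
(2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆); the default "plugin" estimator computes
family homozygosities from raw frequencies and therefore attains 20 and 61
exactly at the boundary usages; the finite-sample-corrected estimator is
also exposed but cannot reach 61 at finite length.  Families absent from a
gene are imputed by their degeneracy class mean (the threefold class
falls back to the mean of the two- and fourfold classes).  CAI smooths
zero-count reference codons to a weight of 0.5/(family count) with a
warning.  COUSIN uses the normalised query-vs-reference-vs-uniform form
given in the README; a reference that is uniform within every family the
query uses makes the denominator vanish and raises.

The residence-time trend uses Kendall's τ over all (residence, COUSIN)
pairs and unweighted OLS of the per-interval minimum, maximum and median
against interval midpoints (interval 0.001, empty intervals skipped; a
single occupied interval leaves the fits undefined while τ is still
reported).  Acquisitions on branches departing from the root can be
excluded via `exclude_root_adjacent`.

## Amelioration

Clusters with ≥ 20 (alternatively ≥ 10) extant sequences from a single
event are eligible.  Gap-containing codon columns are removed, the
ancestral CDS is the per-column maximum-posterior nucleotide at the root
of the guide tree (the strain tree restricted to the carriers; 4-state
symmetric model, one rate fitted over all columns jointly; all-zero-length
guide trees fall back to column majority with a warning).  ΔCOUSIN is
extant minus ancestor, tested two-sided against zero with a one-sample t
at α = 0.05, with no multiple-testing correction; zero-variance nonzero
deltas report p < 1e−15 with a degeneracy flag.  The synonymous-only
variant replaces every non-synonymous extant codon by its ancestral codon
first; by construction the projection translates identically to the
ancestor and projecting twice equals projecting once.  S and N count codon
columns with synonymous-only and any-non-synonymous variation
respectively (a column with any non-synonymous difference counts to N,
else to S when a synonymous difference exists).

A caveat established during calibration: with a shared clonal history,
occasional reconstruction errors at columns whose substitutions sit on
basal branches shift all paired deltas in common, and the t-test — which
assumes independent deltas — then reports a direction in roughly half of
null replicates.  This is a property of the paired design itself.  The
shipped calibration generator therefore uses independent per-lineage
divergence (a star history) with substitutions resampled from the
ancestor's own realised codon usage, a direction-free null under which
the measured false-direction rate is ~7% at α = 0.05, and a 5%
core-ward synonymous bias is detected as "towards" in >90% of
replicates.  Directional results on deep, strongly clonal clusters should
be read with the common-error caveat in mind.

## tRNA compensation

Pairing rules ship as a generated, user-replaceable table (anticodon,
codon, class, s).  Watson–Crick is the exact reverse complement; wobble is
G34:U3 and U34:G3; less-favoured wobble covers extended U34 (U/C-ending)
and inosine-style A34 (C/A-ending) readings; every pairing is restricted
to codons of the tRNA's own amino acid.  Default selective constraints
follow the canonical published tAI values (s = 0 for Watson–Crick, 0.41
for G:U, 0.68 for U:G, 0.28 for I:C-style, ~1 for I:A-style, 0.9 for the
extended U34 readings); none of the validations depend on the specific
values, and a species-optimised table can be substituted via
`read_pairing_rules`.

Node codon tables pool the mean per-copy codon counts of every cluster
present at the node (core clusters everywhere; accessory clusters where
the maximum-posterior state is presence), scaled to occurrences per 1000
coding bases.  The permutation test ranks all (branch, codon) deltas
jointly in descending order (average ranks on ties; branches without
content change contribute zero deltas and occupy bottom ranks), sums the
ranks of gain-matched pairs, and estimates p as the fraction of 10⁴
uniform without-replacement rank draws with a sum ≤ the observed one —
the plain estimator without the +1 correction, kept as stated; its null
uniformity is verified by a KS test in the suite.

`tAI_abs` replaces codons with W = 0 by the geometric mean of the nonzero
W values (the standard tAI convention) and flags affected genes.  A
consequence worth knowing: gaining the *first* copy of a tRNA can lower
the tAI_abs of genes rich in its codon when the real W lands below that
background mean; branch-level tests are therefore most informative for
copy-number increments of already-present tRNAs.  Branches are tested
only when the tRNA change yields a positive mean ΔtAI_abs over all genes,
with a two-sided Mann–Whitney U between genes acquired on the branch and
genes present at the parent.

## The synthetic-data generator

The generator emulates the features the analysis depends on, not the full
biology of a bacterial species:

* a birth–death strain tree (dendropy) conditioned on the tip count,
  rescaled to height 0.02 so branch lengths behave like core-genome
  substitutions per site and residence times live on the 0.001 binning
  scale;
* core genes (default 200 × 300 codons) drawn from a GC-rich profile
  (codon weight ∝ e^(β·GC), β = 1.5) and evolved by within-family
  resampling (rate 6 per codon per unit length) plus rare
  amino-acid-changing resampling (rate 0.3), with no indels, so alignment
  is implicit;
* HGT events (default 100) on uniformly chosen branches at distinct
  intergenic loci, 1–37 genes per event (truncated geometric, ~half
  singletons), donors spanning β ∈ {−2, −1, 0, 1.5, 4} — from
  opposite-bias AT-rich through unbiased to stronger-than-core;
* per-branch Bernoulli losses strictly below the gain branch, with the
  per-gene rate multiplied by 1 + loss_bias·|COUSIN(gene, core) − 1|
  (default base rate 0.03, bias 8) to encode selective retention of
  core-like genes — this is the mechanism that produces the converging
  COUSIN fan;
* pseudo-accessory decoys: contiguous codon-aligned fragments covering
  30–69% of a core gene, copied into 1–3 strains with ~5% of codons
  resampled synonymously (nucleotide identity ≥ 90%);
* tRNA history: a baseline pool derived from the core profile (two copies
  of the Watson–Crick anticodon of each family's top codon, plus one for
  the runner-up in ≥4-fold families), compensated gains (+1 copy of the
  anticodon reading the event's most over-represented codon, on the event
  branch, with probability `compensation_prob`) and a few background
  changes on random branches; tip counts are path sums floored at zero.

All randomness derives from a single seed through named substreams, so a
(config, seed) pair reproduces a dataset byte for byte.

What passing the synthetic validations shows: the statistical machinery
is correct (oracle equivalence), the pipeline recovers planted structure
(≥90% branch-exact event recall and precision at a 5% loss rate; all
decoys ≥150 nt filtered), the permutation test is calibrated, and the
documented retention bias reproduces the qualitative trend (τ > 0,
rising minima, falling maxima).  What it does not show: robustness to
annotation error, recombination within genes, indel-rich homology,
genuinely unknown wobble constraints, or rate heterogeneity across the
tree — none of which the generator emulates.

## Problem sizes used by the validation suite

The recovery check runs at 20 strains / 200 core genes × 300 codons / 50
events; the compensation detection check runs 20 replicates each at
compensation probability 1 and 0 with 20 strains / 50 events over a
60-gene × 200-codon core (the smaller core keeps the 40-replicate design
comfortably interactive without affecting the codon-table contrast the
test measures); trend direction uses the full defaults; calibration uses
500 permutation replicates at 1000 permutations and 300 amelioration
null clusters.
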
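# hgtcodon

Tools for studying how bacterial genomes respond to the codon usage of
horizontally transferred genes: **selective retention** (divergent genes are
lost), **amelioration** (retained genes drift towards the host's codon
usage), and **compensatory evolution** (the host expands the tRNA pool that
decodes the incoming codons).  The package implements the full
phylogeny-based analysis as a reusable library and ships a synthetic
pan-genome generator with known ground truth, so every stage can be
validated by recovery rather than anecdote.

## Who it is for

Researchers in bacterial comparative genomics who have per-strain coding
sequences, gene positions and tRNA gene copy numbers (for example for a
GC-rich species such as *Pseudomonas aeruginosa*) and want a tested,
scriptable version of the analysis chain: pan-genome → strain tree → HGT
events → codon-usage trends → amelioration tests → tRNA compensation tests.

## The models and statistics at its core

* **COUSIN** (Codon Usage Similarity Index).  For each degenerate
  amino-acid family let `q` and `w` be the query's and reference's
  within-family codon frequencies and `k` the degeneracy; aggregated over
  families weighted by the query's amino-acid composition `g`:

      COUSIN = Σ_a g_a (q_a·w_a − 1/k_a) / Σ_a g_a (w_a·w_a − 1/k_a)

  0 = no bias, 1 = the reference's own bias, >1 = stronger same-direction
  bias, <0 = opposite direction.  CAI (geometric mean of `w(c)/w_max`) and
  Wright's ENC (from per-family homozygosities, range 20–61) are also
  provided.

* **HGT inference.**  Each accessory cluster's per-strain copy numbers are
  a phyletic pattern; marginal ancestral state reconstruction under the
  equal-rates Mk model (Felsenstein pruning, rate fitted by ML, uniform
  root prior) yields P(presence) at every node.  A transfer is called on a
  branch when P(presence) < 0.5 at the parent and > 0.5 at the child;
  root-present clusters are removed; scattered patterns at one insertion
  locus merge to the LCA of the calls; physically adjacent genes called on
  one branch form one event.  Each carrying leaf gets a **residence time**:
  path length to the midpoint of the event branch.

* **Retention trend.**  Kendall's τ of COUSIN against residence time, plus
  OLS fits of the per-0.001-interval minimum/maximum/median COUSIN.

* **Amelioration.**  Ancestral CDS reconstruction on the guide tree,
  per-extant ΔCOUSIN tested against zero (one-sample t), repeated after
  converting non-synonymous codons back to the ancestral state.

* **tRNA compensation.**  tRNA gene copy numbers (tGCN) are reconstructed
  per anticodon with the same Mk machinery.  Codon level: per-branch codon
  frequency changes (per 1000 bases) are ranked descending; the rank sum at
  pairs matched by a tRNA gain (Watson–Crick / wobble / less-favoured
  wobble) is compared with 10⁴ random draws (p = fraction of randomised
  sums ≤ observed).  Gene level: absolute adaptiveness
  `W_i = Σ_j (1 − s_ij)·tGCN_ij`, `tAI_abs` = geometric mean of `W` over a
  gene's codons; branches with positive mean ΔtAI_abs are tested with a
  Mann–Whitney U between newly acquired and resident genes.

## Worked example

`examples/` contains one short script per capability.  For instance,
simulating a default synthetic pan-genome (20 strains, 200 core genes of
300 codons, 100 HGT events from donors spanning AT-shifted to
stronger-than-core codon usage, loss rates biased against codon-divergent
genes) and running the full pipeline:

```bash
python examples/05_codon_trend.py
```

prints

```
gene acquisitions scored: 324
Kendall tau = +0.269 (p = 1.7e-12)
min    COUSIN per interval: slope    +63.8  R^2 0.08  p 0.417
max    COUSIN per interval: slope    -24.2  R^2 0.36  p 0.0669
median COUSIN per interval: slope    +76.0  R^2 0.18  p 0.226
```

The positive τ with rising per-interval minima and falling maxima is the
converging-fan signature of selective retention: recently acquired genes
span the whole range of codon usage, old survivors are core-like.
Similarly, `python examples/07_trna_compensation.py` reconstructs tRNA
copy-number history on a fully compensated dataset and prints

```
watson_crick           observed rank sum  14246.0 over 28 pairs  ->  p = 0.0003
```

a significant association between tRNA gains and the influx of their
Watson–Crick codons, plus per-branch ΔtAI_abs ratios showing that the
acquired genes benefit most from the tRNA change.

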
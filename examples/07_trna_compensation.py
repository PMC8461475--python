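"""Do tRNA gene copy-number gains track the codon influx from HGT?

Codon level: per-branch changes in codon frequency (per 1000 bases, child
minus parent genomic content) are ranked; the rank sum at (branch, codon)
pairs matching a tRNA gain is compared with random draws, per pairing
class.  Gene level: for branches where the tRNA change raises the mean
expected translation efficiency (tAI_abs), a Mann-Whitney U-test asks
whether genes acquired on that branch benefit more than resident genes.
"""

from hgtcodon import SimulationConfig, run_pipeline, simulate_dataset
from hgtcodon.pipeline import trna_analysis

ds = simulate_dataset(SimulationConfig(n_strains=14, n_core_genes=60,
                                       core_gene_length=200,
                                       n_hgt_events=40,
                                       compensation_prob=1.0, seed=5))
res = run_pipeline(ds.genes, tree=ds.tree)
out = trna_analysis(res, {g.gene_id: g for g in ds.genes},
                    ds.trna_counts, n_perm=10_000, seed=5)

print(f"tRNA copy-number changes reconstructed: "
      f"{len(out.history.changes)} "
      f"(simulated: {len(ds.truth.trna_changes)})\n")
for cls, r in out.permutation.items():
    print(f"{cls:22s} observed rank sum {r.observed_rank_sum:8.1f} over "
          f"{r.n_flagged} pairs  ->  p = {r.p:.4f}")

tested = [b for b in out.branch_deltas if b.tested]
higher = [b for b in tested if b.classification == "hgt_higher"]
print(f"\nbranches with positive mean dtAI_abs tested: {len(tested)}")
print(f"  HGT genes benefit significantly more:      {len(higher)}")
for b in higher[:3]:
    print(f"  branch {b.branch}: ratio {b.ratio:.2f} (p = {b.p:.2g})")
# With every event compensated, the Watson-Crick permutation p should be
# well below 0.05.
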
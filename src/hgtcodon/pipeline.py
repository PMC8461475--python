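"""End-to-end analysis: pan-genome -> tree -> HGT -> codon usage -> tRNA.

The orchestration mirrors how the stages are meant to be used together:
cluster the genes, classify core/accessory, filter pseudo-accessory
clusters, build (or accept) a rooted strain tree, reconstruct ancestral
presence of every accessory cluster, call and merge transfers, group them
into events, assign residence times, score codon usage against the core
reference, and finally analyse tRNA copy-number compensation.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import codon as codon_mod
from .codon import (CodonUsageTable, ResidenceTrend, build_codon_table,
                    count_codons, residence_trend, sense_codon_length)
from .hgt import (GeneAcquisition, HGTEvent, HGTInference, PhyleticPattern,
                  group_adjacent_into_events, infer_hgt, residence_times)
from .pangenome import GeneRecord, HomologCluster, build_pangenome
from .phylogeny import build_tree
from .tree import Tree
from .trna import (BranchDelta, PairingRule, PermutationResult, TRNAHistory,
                   WATSON_CRICK, WOBBLE, LESS_FAVOURED, asr_trna_counts,
                   branch_compensation_test, default_pairing_rules,
                   delta_codon_freq, flagged_pairs, node_codon_frequencies,
                   rank_permutation_test)

MIN_CODONS = 100


@dataclass
class PipelineResult:
    clusters: list[HomologCluster]
    pseudo_clusters: list[HomologCluster]
    tree: Tree
    inference: HGTInference
    events: list[HGTEvent]
    acquisitions: list[GeneAcquisition]
    core_table: CodonUsageTable
    gene_cousin: dict[str, float]          # gene_id -> COUSIN
    trend: ResidenceTrend | None
    cluster_locus: dict[str, tuple[str, int]] = field(default_factory=dict)

    def cluster(self, cluster_id: str) -> HomologCluster:
        for c in self.clusters:
            if c.cluster_id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def carriers(self) -> dict[str, list[str]]:
        return {c.cluster_id: sorted(c.copy_profile)
                for c in self.clusters if c.status == "accessory"}


def _modal_position(cluster: HomologCluster,
                    genes: Mapping[str, GeneRecord]) -> tuple[str, int]:
    pairs = Counter((genes[g].locus, genes[g].pos) for g in cluster.members)
    return pairs.most_common(1)[0][0]


def run_pipeline(genes: Sequence[GeneRecord], tree: Tree | None = None,
                 min_overlap: float = 0.7, min_identity: float = 0.6,
                 min_codons: int = MIN_CODONS, interval: float = 0.001,
                 exclude_root_adjacent: bool = False) -> PipelineResult:
    """Run the analysis from gene records to the residence-time trend.

    ``tree`` bypasses tree inference with a user-supplied rooted tree
    whose tips are the strain names.
    """
    genes = list(genes)
    by_id = {g.gene_id: g for g in genes}
    clusters, pseudo = build_pangenome(genes, min_overlap=min_overlap,
                                       min_identity=min_identity)
    if tree is None:
        tree = build_tree(clusters, by_id)

    accessory = [c for c in clusters if c.status == "accessory"]
    patterns = [PhyleticPattern(
        cluster_id=c.cluster_id,
        copy_numbers={s: c.copy_profile.get(s, 0)
                      for s in tree.tip_names()})
        for c in accessory]
    positions = {c.cluster_id: _modal_position(c, by_id) for c in accessory}
    loci = {cid: locus for cid, (locus, _) in positions.items()}

    inference = infer_hgt(tree, patterns, loci=loci)
    events = group_adjacent_into_events(inference.calls, positions)

    carriers = {c.cluster_id: sorted(c.copy_profile) for c in accessory}
    acquisitions = residence_times(events, tree, carriers)

    core_seqs = [by_id[g].sequence for c in clusters if c.status == "core"
                 for g in c.members]
    core_table = build_codon_table(core_seqs)

    members_by_cluster_strain: dict[tuple[str, str], str] = {}
    for c in accessory:
        for gid in c.members:
            members_by_cluster_strain[(c.cluster_id, by_id[gid].strain)] = gid

    gene_cousin: dict[str, float] = {}
    pairs_res, pairs_val = [], []
    root_children = {ch.name for ch in tree.root.children}
    for acq in acquisitions:
        if exclude_root_adjacent and acq.branch in root_children:
            continue
        gid = members_by_cluster_strain.get((acq.cluster_id, acq.strain))
        if gid is None:
            continue
        seq = by_id[gid].sequence
        if sense_codon_length(seq) < min_codons:
            continue
        if gid not in gene_cousin:
            gene_cousin[gid] = codon_mod.cousin(seq, core_table)
        pairs_res.append(acq.residence_time)
        pairs_val.append(gene_cousin[gid])

    trend = None
    if len(pairs_res) >= 2:
        trend = residence_trend(pairs_res, pairs_val, interval=interval)

    return PipelineResult(clusters=clusters, pseudo_clusters=pseudo,
                          tree=tree, inference=inference, events=events,
                          acquisitions=acquisitions, core_table=core_table,
                          gene_cousin=gene_cousin, trend=trend,
                          cluster_locus=positions)


def write_results(result: PipelineResult, directory) -> None:
    """Emit the per-stage tables: clusters.tsv, pangenome_summary.tsv,
    tree.nwk, hgt_events.tsv, acquisitions.tsv, root_present.tsv,
    core_codon_table.tsv, codon_metrics.tsv and trend.json."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    rows = [{"cluster_id": c.cluster_id, "gene_id": m, "status": c.status}
            for c in result.clusters + result.pseudo_clusters
            for m in c.members]
    pd.DataFrame(rows).to_csv(directory / "clusters.tsv", sep="\t",
                              index=False)
    counts = Counter(c.status for c in
                     result.clusters + result.pseudo_clusters)
    pd.DataFrame([{"status": s, "n_clusters": n}
                  for s, n in sorted(counts.items())]
                 ).to_csv(directory / "pangenome_summary.tsv", sep="\t",
                          index=False)
    (directory / "tree.nwk").write_text(result.tree.to_newick() + "\n")

    pd.DataFrame([{"event_id": e.event_id, "branch": e.branch,
                   "locus": e.locus, "n_genes": len(e.clusters),
                   "clusters": ",".join(e.clusters)}
                  for e in result.events]
                 ).to_csv(directory / "hgt_events.tsv", sep="\t",
                          index=False)
    pd.DataFrame([{"cluster_id": a.cluster_id, "strain": a.strain,
                   "branch": a.branch,
                   "residence_time": a.residence_time}
                  for a in result.acquisitions]
                 ).to_csv(directory / "acquisitions.tsv", sep="\t",
                          index=False)
    pd.DataFrame({"cluster_id": result.inference.root_present}
                 ).to_csv(directory / "root_present.tsv", sep="\t",
                          index=False)

    result.core_table.to_frame().to_csv(
        directory / "core_codon_table.tsv", sep="\t", index=False)
    pd.DataFrame([{"gene_id": g, "cousin": v}
                  for g, v in sorted(result.gene_cousin.items())]
                 ).to_csv(directory / "codon_metrics.tsv", sep="\t",
                          index=False)
    if result.trend is not None:
        trend = {"kendall_tau": result.trend.kendall_tau,
                 "kendall_p": result.trend.kendall_p,
                 "interval": result.trend.interval,
                 "n_pairs": result.trend.n_pairs}
        if result.trend.fits:
            for name, fit in result.trend.fits.items():
                trend[name] = {"slope": fit.slope, "r2": fit.r2,
                               "p": fit.p}
        (directory / "trend.json").write_text(json.dumps(trend, indent=2))


# ---------------------------------------------------------------------------
# tRNA compensation analysis on top of a pipeline result
# ---------------------------------------------------------------------------

@dataclass
class TRNAAnalysis:
    history: TRNAHistory
    permutation: dict[str, PermutationResult]
    branch_deltas: list[BranchDelta]
    codon_deltas: dict[tuple[str, str], float]


def cluster_codon_counts(clusters: Sequence[HomologCluster],
                         genes: Mapping[str, GeneRecord]) -> dict[str, np.ndarray]:
    """Mean per-copy sense-codon count vector per cluster (the node-level
    representative of the cluster's coding content)."""
    out = {}
    for c in clusters:
        total = np.zeros(61)
        for gid in c.members:
            total += count_codons([genes[gid].sequence])
        out[c.cluster_id] = total / len(c.members)
    return out


def node_gene_content(result: PipelineResult) -> dict[str, list[str]]:
    """Cluster ids present at each node: core clusters everywhere,
    accessory clusters where the maximum-posterior state is presence."""
    core_ids = [c.cluster_id for c in result.clusters if c.status == "core"]
    content = {n.name: list(core_ids)
               for n in result.tree.postorder()}
    for cid, post in result.inference.posteriors.items():
        for node, p in post.presence.items():
            if p > 0.5:
                content[node].append(cid)
    for tips_only in content.values():
        tips_only.sort()
    return content


def trna_analysis(result: PipelineResult,
                  genes: Mapping[str, GeneRecord],
                  tip_pools: Mapping[str, Mapping[str, int]],
                  rules: Sequence[PairingRule] | None = None,
                  n_perm: int = 10_000, seed: int = 0,
                  alpha: float = 0.05) -> TRNAAnalysis:
    """Codon-level permutation tests and gene-level ΔtAI_abs tests."""
    if rules is None:
        rules = default_pairing_rules()
    tree = result.tree
    history = asr_trna_counts(tree, tip_pools)

    counts = cluster_codon_counts(result.clusters, genes)
    content = node_gene_content(result)
    tables = {name: node_codon_frequencies(counts, content[name])
              for name in content}

    from .codon import SENSE_CODONS
    deltas: dict[tuple[str, str], float] = {}
    for node in tree.branches():
        d = delta_codon_freq(tables[node.parent.name], tables[node.name])
        for i, codon in enumerate(SENSE_CODONS):
            deltas[(node.name, codon)] = float(d[i])

    gains = [(branch, ac) for branch, ac, delta in history.changes
             if delta > 0]
    rng = np.random.default_rng(seed)
    permutation: dict[str, PermutationResult] = {}
    for cls in (WATSON_CRICK, WOBBLE, LESS_FAVOURED):
        flagged = flagged_pairs(gains, rules, cls,
                                valid_keys=set(deltas))
        if not flagged:
            continue
        permutation[cls] = rank_permutation_test(
            deltas, flagged, n_perm=n_perm, seed=rng, pairing_class=cls)

    # gene-level tests on branches with any tRNA change
    changed_branches = sorted({branch for branch, _, _ in history.changes})
    min_len_ok = {cid: v for cid, v in counts.items()
                  if v.sum() >= MIN_CODONS}
    branch_deltas = []
    for branch in changed_branches:
        parent = tree.node(branch).parent.name
        hgt_here = [cid for cid, calls in result.inference.calls.items()
                    if branch in calls and cid in min_len_ok]
        resident = [cid for cid in content[parent] if cid in min_len_ok]
        if not hgt_here or not resident:
            continue
        branch_deltas.append(branch_compensation_test(
            branch, history.node_pools[parent],
            history.node_pools[branch],
            {cid: min_len_ok[cid] for cid in hgt_here},
            {cid: min_len_ok[cid] for cid in resident},
            rules, alpha=alpha))

    return TRNAAnalysis(history=history, permutation=permutation,
                        branch_deltas=branch_deltas, codon_deltas=deltas)
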
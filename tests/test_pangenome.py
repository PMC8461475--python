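"""Homolog clustering, core/accessory classification, pseudo filter."""

import numpy as np
import pytest

from conftest import smith_waterman
from hgtcodon.pangenome import (GeneRecord, HomologCluster, PangenomeError,
                                SimilarityHit, classify_core_accessory,
                                cluster_homologs, filter_pseudo_accessory,
                                pairwise_similarity, split_multicopy)

BASES = np.array(list("ACGT"))


def random_gene(rng, length, gene_id="g", strain="s", locus="L", pos=0):
    return GeneRecord(gene_id, strain, locus, pos,
                      "".join(rng.choice(BASES, length)))


def mutate(seq, rng, frac):
    s = list(seq)
    idx = rng.choice(len(s), max(1, int(frac * len(s))), replace=False)
    for i in idx:
        s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
    return "".join(s)


def test_identical_sequences_score_perfectly():
    rng = np.random.default_rng(0)
    a = random_gene(rng, 300, "a")
    b = GeneRecord("b", "s2", "L", 0, a.sequence)
    h = pairwise_similarity(a, b)
    assert h.identity == 1.0
    assert h.overlap == 1.0


def test_unrelated_sequences_share_no_seed():
    rng = np.random.default_rng(1)
    a = random_gene(rng, 300, "a")
    b = random_gene(rng, 300, "b")
    assert pairwise_similarity(a, b) is None


def test_fragment_similarity_matches_smith_waterman_oracle():
    rng = np.random.default_rng(2)
    gene = random_gene(rng, 600, "g")
    frag = mutate(gene.sequence[150:450], rng, 0.05)
    b = GeneRecord("f", "s2", "L", 0, frag)
    h = pairwise_similarity(gene, b)
    sw_identity, sw_overlap, _, _ = smith_waterman(gene.sequence, frag)
    assert h.identity == pytest.approx(sw_identity, abs=0.02)
    assert h.overlap == pytest.approx(0.5, abs=0.02)
    assert h.overlap == pytest.approx(sw_overlap, abs=0.02)
    assert h.identity == pytest.approx(0.95, abs=0.02)


def test_non_acgt_sequence_raises_with_record_name():
    a = GeneRecord("badgene", "s", "L", 0, "ATGNNN")
    b = GeneRecord("b", "s", "L", 0, "ATGAAA")
    with pytest.raises(PangenomeError, match="badgene"):
        pairwise_similarity(a, b)


def _records(n):
    return [GeneRecord(f"g{i}", f"s{i}", "L", 0, "ATG" * 10)
            for i in range(n)]


def test_cluster_thresholds_are_strict_on_both_axes():
    genes = _records(2)
    below_id = [SimilarityHit("g0", "g1", 0.59, 0.9, 300)]
    below_ov = [SimilarityHit("g0", "g1", 0.95, 0.65, 300)]
    for hits in (below_id, below_ov):
        clusters = cluster_homologs(genes, hits)
        assert len(clusters) == 2
    passing = [SimilarityHit("g0", "g1", 0.6, 0.7, 300)]
    assert len(cluster_homologs(genes, passing)) == 1


def test_single_linkage_transitive_closure():
    genes = _records(3)
    hits = [SimilarityHit("g0", "g1", 0.9, 0.9, 300),
            SimilarityHit("g1", "g2", 0.9, 0.9, 300),
            SimilarityHit("g0", "g2", 0.3, 0.3, 300)]
    clusters = cluster_homologs(genes, hits)
    assert len(clusters) == 1
    assert sorted(clusters[0].members) == ["g0", "g1", "g2"]


def test_every_gene_in_exactly_one_cluster():
    rng = np.random.default_rng(3)
    genes = [random_gene(rng, 120, f"g{i}", f"s{i % 4}") for i in range(12)]
    clusters = cluster_homologs(genes)
    members = [m for c in clusters for m in c.members]
    assert sorted(members) == sorted(g.gene_id for g in genes)


def test_raising_identity_threshold_never_merges():
    genes = _records(3)
    hits = [SimilarityHit("g0", "g1", 0.65, 0.9, 300),
            SimilarityHit("g1", "g2", 0.95, 0.9, 300)]
    loose = cluster_homologs(genes, hits, min_identity=0.6)
    strict = cluster_homologs(genes, hits, min_identity=0.9)
    # every strict cluster is contained in some loose cluster
    loose_map = {m: c.cluster_id for c in loose for m in c.members}
    for c in strict:
        assert len({loose_map[m] for m in c.members}) == 1


@pytest.mark.parametrize("n_present,expected", [(89, "core"),
                                                (88, "accessory"),
                                                (94, "core")])
def test_core_prevalence_rule_at_94_strains(n_present, expected):
    cluster = HomologCluster("c", [f"g{i}" for i in range(n_present)],
                             copy_profile={f"s{i}": 1
                                           for i in range(n_present)})
    out = classify_core_accessory([cluster], n_strains=94)
    assert out[0].status == expected


def test_multicopy_cluster_routed_through_split():
    genes = {}
    members = []
    for i in range(94):
        for locus in ("L1", "L2"):
            gid = f"{locus}_g{i}"
            genes[gid] = GeneRecord(gid, f"s{i}", locus, 0, "ATG" * 10)
            members.append(gid)
    cluster = HomologCluster("c", members,
                             copy_profile={f"s{i}": 2 for i in range(94)})
    out = classify_core_accessory([cluster], 94, genes)
    assert len(out) == 2
    assert all(c.status == "core" for c in out)
    assert all(c.is_single_copy for c in out)


def test_split_multicopy_identity_on_single_copy():
    cluster = HomologCluster("c", ["a", "b"],
                             copy_profile={"s1": 1, "s2": 1})
    assert split_multicopy(cluster, {}) == [cluster]


def test_pseudo_filter_rules():
    clusters = [
        HomologCluster("core1", ["g0"], status="core",
                       copy_profile={"s0": 1}),
        HomologCluster("acc1", ["g1"], status="accessory",
                       copy_profile={"s1": 1}),
        HomologCluster("acc2", ["g2"], status="accessory",
                       copy_profile={"s2": 1}),
    ]
    genes = {f"g{i}": GeneRecord(f"g{i}", f"s{i}", "L", 0, "ATG" * 60)
             for i in range(3)}
    # decoy-like hit: high identity, low overlap, long alignment
    hits = [SimilarityHit("g1", "g0", 0.95, 0.5, 300)]
    retained, pseudo = filter_pseudo_accessory(clusters, genes, hits)
    assert [c.cluster_id for c in pseudo] == ["acc1"]
    assert {c.cluster_id for c in retained} == {"core1", "acc2"}


def test_pseudo_filter_ignores_short_or_low_identity_hits():
    clusters = [
        HomologCluster("acc1", ["g1"], status="accessory",
                       copy_profile={"s1": 1}),
        HomologCluster("acc2", ["g2"], status="accessory",
                       copy_profile={"s2": 1}),
    ]
    genes = {f"g{i}": GeneRecord(f"g{i}", f"s{i}", "L", 0, "ATG" * 60)
             for i in (1, 2)}
    short = [SimilarityHit("g1", "g2", 0.95, 0.5, 100)]   # < 150 nt
    weak = [SimilarityHit("g1", "g2", 0.85, 0.5, 300)]    # identity <= 0.9
    for hits in (short, weak):
        retained, pseudo = filter_pseudo_accessory(clusters, genes, hits)
        assert pseudo == []


def test_synthetic_decoys_filtered_and_hgt_retained(small_dataset):
    from hgtcodon.pangenome import build_pangenome

    retained, pseudo = build_pangenome(small_dataset.genes)
    filtered_genes = {m for c in pseudo for m in c.members}
    assert set(small_dataset.truth.pseudo_genes) <= filtered_genes
    hgt_genes = {g.gene_id for g in small_dataset.genes
                 if g.family_truth.startswith("HGT")}
    assert not (hgt_genes & filtered_genes)
    # recovery: clusters coincide with ground-truth families
    by_id = {g.gene_id: g for g in small_dataset.genes}
    for c in retained:
        fams = {by_id[m].family_truth for m in c.members}
        assert len(fams) == 1
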
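"""Synthetic-data generator: determinism, ground-truth consistency,
codon-profile fidelity, decoy structure and the on-disk round trip."""

import numpy as np
import pytest
from scipy import stats

from conftest import smith_waterman
from hgtcodon.codon import STOP_CODONS, SENSE_CODONS, gc3_content
from hgtcodon.simulate import (SimulationConfig, SimulationError,
                               codons_to_str, gc_biased_profile,
                               inject_pseudo_accessory, read_dataset,
                               simulate_core_genome, simulate_dataset,
                               simulate_hgt_history, simulate_strain_tree,
                               simulate_trna_history, validate_profile,
                               write_dataset, _sample_codons, _rng)


def test_tree_tip_and_branch_counts():
    tree = simulate_strain_tree(10, seed=5)
    assert len(tree.tips()) == 10
    assert len(tree.branches()) == 18  # 2n - 2 for a rooted binary tree
    t3 = simulate_strain_tree(3, seed=5)
    internal = [n for n in t3.postorder()
                if not n.is_leaf and n.parent is not None]
    assert len(internal) == 1


def test_tree_determinism_and_validation():
    a = simulate_strain_tree(8, seed=9).to_newick()
    b = simulate_strain_tree(8, seed=9).to_newick()
    assert a == b
    assert a != simulate_strain_tree(8, seed=10).to_newick()
    with pytest.raises(SimulationError):
        simulate_strain_tree(2)
    with pytest.raises(SimulationError):
        simulate_strain_tree(5, birth_rate=0.1, death_rate=0.5)


def test_dataset_determinism_is_byte_identical(tmp_path):
    cfg = SimulationConfig(n_strains=6, n_core_genes=10,
                           core_gene_length=120, n_hgt_events=4,
                           pseudo_accessory_count=2, seed=77)
    d1 = simulate_dataset(cfg)
    d2 = simulate_dataset(cfg)
    assert d1.tree.to_newick() == d2.tree.to_newick()
    assert [(g.gene_id, g.sequence) for g in d1.genes] == \
        [(g.gene_id, g.sequence) for g in d2.genes]
    assert d1.trna_counts == d2.trna_counts


def test_zero_substitution_rate_gives_identical_core_sequences():
    cfg = SimulationConfig(n_strains=5, n_core_genes=3,
                           core_gene_length=100, subst_rate=0.0,
                           nonsyn_rate=0.0, seed=1)
    tree = simulate_strain_tree(5, seed=1)
    core = simulate_core_genome(tree, cfg)
    for fam in core.values():
        seqs = {codons_to_str(c) for c in fam.values()}
        assert len(seqs) == 1


def test_core_profile_zero_family_mass_raises():
    profile = gc_biased_profile(1.0)
    from hgtcodon.codon import FAMILIES, _CODON_INDEX
    for c in FAMILIES["K"]:
        profile[_CODON_INDEX[c]] = 0.0
    with pytest.raises(SimulationError, match="K"):
        validate_profile(profile)


def test_realized_gc3_close_to_profile_gc3():
    cfg = SimulationConfig(n_strains=5, n_core_genes=50,
                           core_gene_length=300, seed=2)
    tree = simulate_strain_tree(5, seed=2).rescale(0.02)
    core = simulate_core_genome(tree, cfg)
    profile = validate_profile(cfg.core_codon_profile)
    expected_gc3 = sum(p for c, p in zip(SENSE_CODONS, profile)
                       if c[2] in "GC")
    seqs = [codons_to_str(c) for fam in core.values()
            for c in fam.values()]
    assert gc3_content(seqs) == pytest.approx(expected_gc3, abs=0.02)


def test_profile_fidelity_chi_square():
    rng = _rng(4, "fidelity")
    profile = validate_profile(gc_biased_profile(1.0))
    draws = _sample_codons(rng, profile, 20_000, start_codon=False)
    counts = np.bincount(draws, minlength=61)
    res = stats.chisquare(counts, profile * counts.sum())
    assert res.pvalue > 0.01


def test_no_internal_stop_codons_anywhere(small_dataset):
    for g in small_dataset.genes:
        codons = {g.sequence[i:i + 3]
                  for i in range(0, len(g.sequence), 3)}
        assert not (codons & STOP_CODONS)


def test_hgt_presence_consistency_with_truth(small_dataset):
    # tip presence equals gain/loss history evaluated along the tree
    tree = small_dataset.tree
    losses_by_fam = {}
    for branch, fam in small_dataset.truth.losses:
        losses_by_fam.setdefault(fam, set()).add(branch)
    present = {}
    for g in small_dataset.genes:
        if g.family_truth.startswith("HGT"):
            present.setdefault(g.family_truth, set()).add(g.strain)
    for ev in small_dataset.truth.events:
        clade = set(tree.clade_tips(ev.branch))
        for fam in ev.gene_families:
            expected = set()
            for tip in clade:
                lost = any(tree.is_descendant(tip, b)
                           for b in losses_by_fam.get(fam, ()))
                if not lost:
                    expected.add(tip)
            assert present.get(fam, set()) == expected, fam


def test_loss_rate_zero_means_full_clades():
    cfg = SimulationConfig(n_strains=8, n_core_genes=10,
                           core_gene_length=100, n_hgt_events=6,
                           loss_rate=0.0, loss_bias=0.0, seed=3)
    tree = simulate_strain_tree(8, seed=3).rescale(0.02)
    events, losses, accessory = simulate_hgt_history(tree, cfg)
    assert losses == []
    for ev in events:
        clade = set(tree.clade_tips(ev.branch))
        for fam in ev.gene_families:
            assert set(accessory[fam]["tips"]) == clade


def test_zero_events_empty_truth():
    cfg = SimulationConfig(n_strains=5, n_core_genes=5,
                           core_gene_length=100, n_hgt_events=0, seed=1)
    tree = simulate_strain_tree(5, seed=1)
    events, losses, accessory = simulate_hgt_history(tree, cfg)
    assert events == [] and losses == [] and accessory == {}


def test_trna_tip_counts_equal_path_sums(small_dataset):
    tree = small_dataset.tree
    from hgtcodon.simulate import baseline_trna_pool

    baseline = baseline_trna_pool(small_dataset.config.core_codon_profile)
    for tip, pool in small_dataset.trna_counts.items():
        path = []
        node = tree.node(tip)
        while node.parent is not None:
            path.append(node.name)
            node = node.parent
        expected = dict(baseline)
        for branch in reversed(path):
            for b, ac, d in small_dataset.truth.trna_changes:
                if b == branch:
                    expected[ac] = max(0, expected.get(ac, 0) + d)
        for ac in set(expected) | set(pool):
            assert pool.get(ac, 0) == expected.get(ac, 0), (tip, ac)


def test_no_compensation_and_no_background_gives_constant_pools():
    cfg = SimulationConfig(n_strains=6, n_core_genes=5,
                           core_gene_length=100, n_hgt_events=5,
                           compensation_prob=0.0,
                           background_trna_changes=0, seed=8)
    tree = simulate_strain_tree(6, seed=8).rescale(0.02)
    events, _, accessory = simulate_hgt_history(tree, cfg)
    baseline, changes, pools = simulate_trna_history(tree, events,
                                                     accessory, cfg)
    assert changes == []
    assert all(p == baseline for p in pools.values())


def test_full_compensation_pairs_every_event_with_a_gain():
    cfg = SimulationConfig(n_strains=6, n_core_genes=10,
                           core_gene_length=100, n_hgt_events=4,
                           compensation_prob=1.0,
                           background_trna_changes=0, seed=5)
    tree = simulate_strain_tree(6, seed=5).rescale(0.02)
    events, _, accessory = simulate_hgt_history(tree, cfg)
    _, changes, _ = simulate_trna_history(tree, events, accessory, cfg)
    gains = {(b, ac) for b, ac, d in changes if d == 1}
    assert len(changes) == len(events)
    assert {b for b, _ in gains} == {e.branch for e in events}


def test_decoy_length_bounds_and_alignment_structure():
    cfg = SimulationConfig(n_strains=5, n_core_genes=10,
                           core_gene_length=300,
                           pseudo_accessory_count=6, seed=6)
    tree = simulate_strain_tree(5, seed=6).rescale(0.02)
    core = simulate_core_genome(tree, cfg)
    decoys = inject_pseudo_accessory(core, cfg)
    assert decoys
    for decoy_id, strain, locus, pos, codons in decoys:
        assert 90 <= codons.shape[0] <= 207
    # exact local alignment of one decoy against its donor strain's gene
    decoy_id, strain, _, _, codons = decoys[0]
    decoy_seq = codons_to_str(codons)
    best = None
    for fam, per_strain in core.items():
        for s, donor in per_strain.items():
            identity, overlap, span_d, span_g = smith_waterman(
                decoy_seq, codons_to_str(donor))
            if best is None or identity > best[0]:
                best = (identity, span_d / len(decoy_seq),
                        span_g / (3 * donor.shape[0]))
    identity, cov_decoy, cov_donor = best
    assert identity >= 0.90
    assert cov_decoy == pytest.approx(1.0, abs=0.05)
    assert cov_donor < 0.70


def test_zero_decoys():
    cfg = SimulationConfig(n_strains=5, n_core_genes=5,
                           core_gene_length=100,
                           pseudo_accessory_count=0, seed=1)
    tree = simulate_strain_tree(5, seed=1)
    core = simulate_core_genome(tree, cfg)
    assert inject_pseudo_accessory(core, cfg) == []


def test_write_read_round_trip(tmp_path, small_dataset):
    write_dataset(small_dataset, tmp_path)
    back = read_dataset(tmp_path)
    assert back.tree.to_newick() == small_dataset.tree.to_newick()
    orig = {(g.gene_id, g.strain, g.locus, g.pos, g.sequence)
            for g in small_dataset.genes}
    assert {(g.gene_id, g.strain, g.locus, g.pos, g.sequence)
            for g in back.genes} == orig
    assert back.trna_counts == small_dataset.trna_counts
    assert back.truth.pseudo_genes == small_dataset.truth.pseudo_genes
    assert [(e.branch, e.locus, e.gene_families)
            for e in back.truth.events] == \
        [(e.branch, e.locus, e.gene_families)
         for e in small_dataset.truth.events]
    # gene count in genes.tsv equals FASTA record count
    n_fasta = sum(line.startswith(">")
                  for f in (tmp_path / "fasta").glob("*.fasta")
                  for line in open(f))
    assert n_fasta == len(small_dataset.genes)
    # headers parse to (strain, gene id, locus)
    for f in (tmp_path / "fasta").glob("*.fasta"):
        for line in open(f):
            if line.startswith(">"):
                strain, gid, locus, pos = line[1:].strip().split("|")
                assert gid.endswith(strain)
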
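"""Synthetic bacterial pan-genomes with known gain/loss/tRNA ground truth.

The generator emulates the statistical structure the analysis stages assume:
a clonal strain phylogeny; GC-rich core genes sharing a strong codon bias;
accessory genes gained on specific branches with variable, often AT-shifted
codon usage; subsequent gene losses (optionally biased against genes whose
codon usage diverges from the core); pseudo-accessory decoys (truncated,
lightly mutated copies of core genes); and tRNA gene copy-number changes
that can co-occur with gains of genes enriched in the matching codons.

All randomness flows from ``SimulationConfig.seed``; each operation draws
from its own named substream, so identical (config, seed) pairs yield
byte-identical datasets.
"""

from __future__ import annotations

import random
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .codon import (CodonUsageTable, FAMILIES, SENSE_CODONS, _CODON_INDEX,
                    cousin)
from .pangenome import GeneRecord
from .tree import Tree

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
START_CODON = "ATG"
_START_IDX = _CODON_INDEX[START_CODON]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Codon profiles
# ---------------------------------------------------------------------------

def gc_biased_profile(beta: float) -> np.ndarray:
    """A 61-codon frequency profile with GC preference of strength ``beta``.

    Codon weight is exp(beta * #GC(codon)), normalised over the sense
    codons.  beta > 0 favours GC-rich codons (core-like for a GC-rich
    genome), beta = 0 is uniform, beta < 0 is AT-shifted.
    """
    w = np.array([np.exp(beta * (c.count("G") + c.count("C")))
                  for c in SENSE_CODONS])
    return w / w.sum()


def validate_profile(profile: np.ndarray) -> np.ndarray:
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (len(SENSE_CODONS),):
        raise SimulationError("profile must cover the 61 sense codons")
    if np.any(profile < 0) or profile.sum() <= 0:
        raise SimulationError("profile must be non-negative with mass")
    for aa, cods in FAMILIES.items():
        if sum(profile[_CODON_INDEX[c]] for c in cods) <= 0:
            raise SimulationError(
                f"profile has zero mass on all codons of {aa!r}")
    return profile / profile.sum()


def profile_table(profile: np.ndarray, scale: float = 1e6
                  ) -> CodonUsageTable:
    """A CodonUsageTable with counts proportional to a profile."""
    return CodonUsageTable(validate_profile(profile) * scale)


# per-amino-acid family member indices, shared by the samplers
_FAM_IDX = {aa: np.array([_CODON_INDEX[c] for c in FAMILIES[aa]])
            for aa in FAMILIES}
_AA_OF_IDX = np.empty(len(SENSE_CODONS), dtype=object)
for _aa, _idx in _FAM_IDX.items():
    _AA_OF_IDX[_idx] = _aa


# ---------------------------------------------------------------------------
# Configuration and ground truth
# ---------------------------------------------------------------------------

@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Branch lengths are in core-genome substitutions-per-site-like units:
    the tree is rescaled to ``tree_height`` so that residence times live on
    the same scale as the default 0.001 binning interval of the trend
    analysis.  ``subst_rate`` and ``nonsyn_rate`` are substitution event
    rates per codon per unit branch length (synonymous resampling within
    the family, and amino-acid-changing resampling, respectively).
    ``loss_bias`` multiplies the per-branch loss probability of an
    accessory gene by 1 + loss_bias * |COUSIN(gene, core profile) - 1|,
    encoding selective retention of core-like genes.
    """

    n_strains: int = 20
    birth_rate: float = 1.0
    death_rate: float = 0.0
    tree_height: float = 0.02
    n_core_genes: int = 200
    core_gene_length: int = 300
    core_codon_profile: np.ndarray = field(
        default_factory=lambda: gc_biased_profile(1.5))
    subst_rate: float = 6.0
    nonsyn_rate: float = 0.3
    n_hgt_events: int = 100
    donor_profiles: tuple[np.ndarray, ...] = field(
        default_factory=lambda: tuple(
            gc_biased_profile(b) for b in (-2.0, -1.0, 0.0, 1.5, 4.0)))
    genes_per_event_p: float = 0.45  # truncated geometric on 1..37
    hgt_gene_length: tuple[int, int] = (100, 400)
    loss_rate: float = 0.03
    loss_bias: float = 8.0
    pseudo_accessory_count: int = 10
    compensation_prob: float = 0.5
    background_trna_changes: int = 5
    seed: int = 0

    def validate(self) -> "SimulationConfig":
        if self.n_strains < 3:
            raise SimulationError("n_strains must be >= 3")
        if not (self.birth_rate > self.death_rate >= 0):
            raise SimulationError("need birth_rate > death_rate >= 0")
        if self.core_gene_length < 100:
            raise SimulationError("core_gene_length must be >= 100 codons")
        for p in (self.loss_rate, self.compensation_prob,
                  self.genes_per_event_p):
            if not (0 <= p <= 1):
                raise SimulationError("probabilities must be in [0, 1]")
        if min(self.subst_rate, self.nonsyn_rate, self.loss_bias,
               self.tree_height) < 0:
            raise SimulationError("rates must be >= 0")
        if self.n_hgt_events < 0 or self.pseudo_accessory_count < 0:
            raise SimulationError("counts must be >= 0")
        validate_profile(self.core_codon_profile)
        if self.n_hgt_events and not self.donor_profiles:
            raise SimulationError("donor_profiles must be non-empty")
        for p in self.donor_profiles:
            validate_profile(p)
        return self


@dataclass
class TrueEvent:
    event_id: str
    branch: str
    locus: str
    gene_families: list[str]
    donor_profile: int


@dataclass
class GroundTruth:
    events: list[TrueEvent] = field(default_factory=list)
    losses: list[tuple[str, str]] = field(default_factory=list)  # branch, fam
    trna_changes: list[tuple[str, str, int]] = field(default_factory=list)
    pseudo_genes: list[str] = field(default_factory=list)  # gene ids


def _rng(seed: int, name: str) -> np.random.Generator:
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(seed,
                                                        spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_strain_tree(n_strains: int, birth_rate: float = 1.0,
                         death_rate: float = 0.0, seed: int = 0) -> Tree:
    """Birth-death tree conditioned on ``n_strains`` extant tips.

    Tips are labelled S01..SNN; internal nodes are named in postorder.
    Identical arguments give byte-identical Newick output.
    """
    if n_strains < 3:
        raise SimulationError("n_strains must be >= 3")
    if not (birth_rate > death_rate >= 0):
        raise SimulationError("need birth_rate > death_rate >= 0")
    rng = random.Random(seed)
    dtree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate, death_rate, num_extant_tips=n_strains, rng=rng,
        repeat_until_success=True)
    dtree.suppress_unifurcations()
    width = max(2, len(str(n_strains)))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:0{width}d}"
    newick = dtree.as_string(schema="newick", suppress_rooting=True,
                             unquoted_underscores=True)
    tree = Tree.from_newick(newick)
    # guard against zero-length branches (downstream divides by path sums)
    for node in tree.branches():
        if node.length <= 0:
            node.length = 1e-9
    return tree


# ---------------------------------------------------------------------------
# Sequence evolution (codon index arrays)
# ---------------------------------------------------------------------------

def _sample_codons(rng: np.random.Generator, profile: np.ndarray,
                   length: int, start_codon: bool = True) -> np.ndarray:
    cods = rng.choice(len(SENSE_CODONS), size=length, p=profile)
    if start_codon:
        cods[0] = _START_IDX
    return cods


def _family_conditionals(profile: np.ndarray) -> dict[str, np.ndarray]:
    cond = {}
    for aa, idx in _FAM_IDX.items():
        w = profile[idx]
        cond[aa] = w / w.sum()
    return cond


def _mutate(codons: np.ndarray, t: float, profile: np.ndarray,
            cond: dict[str, np.ndarray], subst_rate: float,
            nonsyn_rate: float, rng: np.random.Generator,
            protect_first: bool = True) -> np.ndarray:
    """One branch of codon evolution: synonymous resampling within the
    family at rate ``subst_rate``, amino-acid-changing resampling from the
    full profile at rate ``nonsyn_rate`` (events per codon per unit
    length)."""
    out = codons.copy()
    n = out.shape[0]
    p_syn = -np.expm1(-subst_rate * t)
    p_non = -np.expm1(-nonsyn_rate * t)
    syn_mask = rng.random(n) < p_syn
    non_mask = rng.random(n) < p_non
    if protect_first:
        syn_mask[0] = non_mask[0] = False
    # non-synonymous: resample codon freely from the profile
    n_non = int(non_mask.sum())
    if n_non:
        out[non_mask] = rng.choice(len(SENSE_CODONS), size=n_non, p=profile)
    # synonymous: resample within the current codon's family
    pos = np.nonzero(syn_mask & ~non_mask)[0]
    if pos.size:
        aas = _AA_OF_IDX[out[pos]]
        for aa in np.unique(aas):
            sel = pos[aas == aa]
            out[sel] = rng.choice(_FAM_IDX[aa], size=sel.size, p=cond[aa])
    return out


def _evolve_subtree(tree: Tree, root_name: str, root_codons: np.ndarray,
                    profile: np.ndarray, subst_rate: float,
                    nonsyn_rate: float, rng: np.random.Generator
                    ) -> dict[str, np.ndarray]:
    """Evolve a codon array from ``root_name`` down to the subtree's tips.

    The starting sequence is attached at the named node itself (branch
    lengths above it do not contribute)."""
    cond = _family_conditionals(profile)
    start = tree.node(root_name)
    tip_seqs: dict[str, np.ndarray] = {}

    def recurse(node, codons):
        if node.is_leaf:
            tip_seqs[node.name] = codons
            return
        for child in node.children:
            evolved = _mutate(codons, child.length, profile, cond,
                              subst_rate, nonsyn_rate, rng)
            recurse(child, evolved)

    recurse(start, root_codons)
    return tip_seqs


def codons_to_str(codons: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in codons)


# ---------------------------------------------------------------------------
# Core genome
# ---------------------------------------------------------------------------

def simulate_core_genome(tree: Tree, config: SimulationConfig,
                         seed: int | None = None
                         ) -> dict[str, dict[str, np.ndarray]]:
    """Per-family, per-strain core codon arrays.

    Returns {family_id: {strain: codon index array}}; families are
    column-homologous (substitutions only, no indels), start with ATG and
    contain no stop codons (stops never enter the profile).
    """
    profile = validate_profile(config.core_codon_profile)
    rng = _rng(config.seed if seed is None else seed, "core_genome")
    out: dict[str, dict[str, np.ndarray]] = {}
    for g in range(config.n_core_genes):
        fam = f"CORE{g:04d}"
        root = _sample_codons(rng, profile, config.core_gene_length)
        out[fam] = _evolve_subtree(tree, tree.root.name, root, profile,
                                   config.subst_rate, config.nonsyn_rate,
                                   rng)
    return out


# ---------------------------------------------------------------------------
# HGT history
# ---------------------------------------------------------------------------

def _truncated_geometric(rng: np.random.Generator, p: float,
                         hi: int = 37) -> int:
    while True:
        k = int(rng.geometric(p))
        if k <= hi:
            return k


def simulate_hgt_history(tree: Tree, config: SimulationConfig,
                         seed: int | None = None):
    """Accessory gene histories: events, per-tip sequences and losses.

    Returns (truth_events, losses, accessory) where ``accessory`` maps
    family_id -> {"locus", "pos", "donor", "tips": {strain: codon array}}.
    Losses are per-branch Bernoulli draws strictly below the gain branch;
    a gene is present at a tip iff the tip descends from the gain branch
    and no loss intervened on the path.
    """
    config.validate()
    rng = _rng(config.seed if seed is None else seed, "hgt_history")
    core_ref = profile_table(config.core_codon_profile)
    branches = [n.name for n in tree.branches()]
    n_loci = config.n_core_genes + 1
    if config.n_hgt_events > n_loci:
        raise SimulationError(
            f"{config.n_hgt_events} events exceed {n_loci} insertion loci")
    loci = rng.choice(n_loci, size=config.n_hgt_events, replace=False)

    events: list[TrueEvent] = []
    losses: list[tuple[str, str]] = []
    accessory: dict[str, dict] = {}

    for e in range(config.n_hgt_events):
        branch = branches[int(rng.integers(len(branches)))]
        locus = f"L{int(loci[e]):04d}"
        n_genes = _truncated_geometric(rng, config.genes_per_event_p)
        donor_idx = int(rng.integers(len(config.donor_profiles)))
        profile = validate_profile(config.donor_profiles[donor_idx])
        fams = []
        for g in range(n_genes):
            fam = f"HGT{e:03d}G{g:02d}"
            fams.append(fam)
            length = int(rng.integers(config.hgt_gene_length[0],
                                      config.hgt_gene_length[1] + 1))
            root = _sample_codons(rng, profile, length)
            divergence = abs(cousin(np.bincount(
                root, minlength=len(SENSE_CODONS)).astype(float),
                core_ref) - 1.0)
            p_loss = min(0.95, config.loss_rate *
                         (1.0 + config.loss_bias * divergence))

            # which tips retain the gene (losses strictly below the gain)
            present_tips: list[str] = []

            def survive(node, fam=fam, p_loss=p_loss):
                for child in node.children:
                    if rng.random() < p_loss:
                        losses.append((child.name, fam))
                    else:
                        if child.is_leaf:
                            present_tips.append(child.name)
                        else:
                            survive(child)

            gain_node = tree.node(branch)
            if gain_node.is_leaf:
                present_tips.append(gain_node.name)
            else:
                survive(gain_node)

            tip_seqs = _evolve_subtree(
                tree, branch, root, profile, config.subst_rate,
                config.nonsyn_rate, rng) if not gain_node.is_leaf else {
                    gain_node.name: root}
            accessory[fam] = {
                "locus": locus, "pos": g, "donor": donor_idx,
                "tips": {t: tip_seqs[t] for t in present_tips}}
        events.append(TrueEvent(event_id=f"E{e:03d}", branch=branch,
                                locus=locus, gene_families=fams,
                                donor_profile=donor_idx))
    return events, losses, accessory


# ---------------------------------------------------------------------------
# tRNA history
# ---------------------------------------------------------------------------

def baseline_trna_pool(profile: np.ndarray) -> dict[str, int]:
    """A baseline anticodon pool covering all amino acids.

    The Watson-Crick anticodon of each family's most-used codon gets two
    gene copies; families with >= 4 codons also carry one copy for the
    second most-used codon's anticodon."""
    profile = validate_profile(profile)
    pool: dict[str, int] = {}
    for aa, idx in _FAM_IDX.items():
        order = idx[np.argsort(-profile[idx], kind="stable")]
        top = SENSE_CODONS[order[0]]
        pool[revcomp(top)] = pool.get(revcomp(top), 0) + 2
        if len(idx) >= 4:
            second = SENSE_CODONS[order[1]]
            pool[revcomp(second)] = pool.get(revcomp(second), 0) + 1
    return pool


def simulate_trna_history(tree: Tree, events: list[TrueEvent],
                          accessory: dict[str, dict],
                          config: SimulationConfig,
                          seed: int | None = None):
    """tRNA copy-number changes and resulting per-strain pools.

    With probability ``compensation_prob`` an event gains +1 copy of the
    tRNA whose Watson-Crick codon is most enriched in the event's genes
    relative to the core profile, on the event's own branch.  A further
    ``background_trna_changes`` signed unit changes land on random
    branches.  Tip counts are the baseline plus the signed changes along
    the root-to-tip path, floored at zero.
    """
    rng = _rng(config.seed if seed is None else seed, "trna_history")
    baseline = baseline_trna_pool(config.core_codon_profile)
    core_freq = validate_profile(config.core_codon_profile)
    branches = [n.name for n in tree.branches()]
    changes: list[tuple[str, str, int]] = []

    for ev in events:
        if rng.random() >= config.compensation_prob:
            continue
        counts = np.zeros(len(SENSE_CODONS))
        for fam in ev.gene_families:
            tips = accessory[fam]["tips"]
            seq = next(iter(tips.values())) if tips else None
            if seq is None:
                continue
            counts += np.bincount(seq, minlength=len(SENSE_CODONS))
        if counts.sum() == 0:
            continue
        delta = counts / counts.sum() - core_freq
        codon = SENSE_CODONS[int(np.argmax(delta))]
        changes.append((ev.branch, revcomp(codon), 1))

    for _ in range(config.background_trna_changes):
        branch = branches[int(rng.integers(len(branches)))]
        anticodon = sorted(baseline)[int(rng.integers(len(baseline)))]
        delta = 1 if rng.random() < 0.5 else -1
        changes.append((branch, anticodon, delta))

    # accumulate along root-to-tip paths
    per_branch: dict[str, dict[str, int]] = {}
    for branch, anticodon, delta in changes:
        per_branch.setdefault(branch, {})
        per_branch[branch][anticodon] = \
            per_branch[branch].get(anticodon, 0) + delta

    tip_pools: dict[str, dict[str, int]] = {}

    def walk(node, pool):
        if node.name in per_branch:
            pool = dict(pool)
            for ac, d in per_branch[node.name].items():
                pool[ac] = max(0, pool.get(ac, 0) + d)
        if node.is_leaf:
            tip_pools[node.name] = pool
        else:
            for child in node.children:
                walk(child, pool)

    walk(tree.root, dict(baseline))
    return baseline, changes, tip_pools


# ---------------------------------------------------------------------------
# Pseudo-accessory decoys
# ---------------------------------------------------------------------------

def inject_pseudo_accessory(core: dict[str, dict[str, np.ndarray]],
                            config: SimulationConfig,
                            seed: int | None = None):
    """Truncated, lightly mutated copies of core genes.

    Each decoy is a contiguous, codon-aligned fragment covering 30-69 % of
    a core gene, copied into 1-3 strains with ~5 % of codons resampled
    synonymously (nucleotide identity to the donor region stays >= 90 %).
    Returns a list of (gene_id, strain, locus, pos, codon array).
    """
    import warnings as _warnings

    rng = _rng(config.seed if seed is None else seed, "pseudo_accessory")
    cond = _family_conditionals(validate_profile(config.core_codon_profile))
    fams = sorted(core)
    decoys = []
    for i in range(config.pseudo_accessory_count):
        fam = fams[int(rng.integers(len(fams)))]
        strains = sorted(core[fam])
        donor_strain = strains[int(rng.integers(len(strains)))]
        donor = core[fam][donor_strain]
        frac = rng.uniform(0.30, 0.69)
        flen = max(1, int(round(frac * donor.shape[0])))
        start = int(rng.integers(0, donor.shape[0] - flen + 1))
        fragment = donor[start:start + flen]
        if flen < 100:
            _warnings.warn(
                f"pseudo-accessory decoy {i} shorter than 100 codons "
                f"({flen}); emitted anyway", stacklevel=2)
        n_strains = int(rng.integers(1, 4))
        targets = rng.choice(strains, size=min(n_strains, len(strains)),
                             replace=False)
        for strain in sorted(targets):
            copy = fragment.copy()
            mask = rng.random(copy.shape[0]) < 0.05
            pos = np.nonzero(mask)[0]
            if pos.size:
                aas = _AA_OF_IDX[copy[pos]]
                for aa in np.unique(aas):
                    sel = pos[aas == aa]
                    copy[sel] = rng.choice(_FAM_IDX[aa], size=sel.size,
                                           p=cond[aa])
            decoys.append((f"PSE{i:03d}", strain, f"LP{i:03d}", 0, copy))
    return decoys


# ---------------------------------------------------------------------------
# Amelioration calibration clusters
# ---------------------------------------------------------------------------

def star_tree(names: Sequence[str], branch_length: float) -> Tree:
    """A star phylogeny (one root, equal-length terminal branches)."""
    from .tree import Node

    root = Node("R")
    for name in names:
        root.add_child(Node(name, branch_length))
    return Tree(root)


def simulate_amelioration_cluster(n_extant: int = 20, length: int = 300,
                                  donor_beta: float = -1.0,
                                  core_beta: float = 1.5,
                                  sub_frac: float = 0.03,
                                  bias_frac: float = 0.0,
                                  seed: int = 0):
    """One HGT gene cluster for amelioration power/calibration checks.

    An ancestral CDS is drawn from an AT-shifted donor profile; each of the
    ``n_extant`` descendant lineages independently resamples ``sub_frac``
    of its codon positions synonymously from the ancestor's own realised
    within-family usage (a direction-free null: the expected codon usage of
    every descendant equals the ancestor's).  With ``bias_frac`` > 0, an
    additional fraction of positions per lineage is forced to the
    core-preferred synonymous codon, emulating selection-driven
    amelioration.  Returns (extant sequences keyed by tip name, true
    ancestral CDS, star guide tree).
    """
    rng = _rng(seed, "amelioration_cluster")
    donor = validate_profile(gc_biased_profile(donor_beta))
    core = validate_profile(gc_biased_profile(core_beta))
    pref = {aa: idx[int(np.argmax(core[idx]))]
            for aa, idx in _FAM_IDX.items()}

    root = _sample_codons(rng, donor, length)
    emp = np.bincount(root, minlength=len(SENSE_CODONS)).astype(float)
    emp[emp == 0] = 1e-9
    emp = validate_profile(emp)
    cond = {aa: emp[idx] / emp[idx].sum() for aa, idx in _FAM_IDX.items()}

    names = [f"T{i:02d}" for i in range(n_extant)]
    extants: dict[str, str] = {}
    for name in names:
        c = root.copy()
        mask = rng.random(length) < sub_frac
        mask[0] = False
        pos = np.nonzero(mask)[0]
        aas = _AA_OF_IDX[c[pos]]
        for aa in np.unique(aas):
            sel = pos[aas == aa]
            c[sel] = rng.choice(_FAM_IDX[aa], size=sel.size, p=cond[aa])
        if bias_frac > 0:
            bmask = rng.random(length) < bias_frac
            bmask[0] = False
            for p in np.nonzero(bmask)[0]:
                c[p] = pref[_AA_OF_IDX[c[p]]]
        extants[name] = codons_to_str(c)
    guide = star_tree(names, branch_length=sub_frac / 6.0)
    return extants, codons_to_str(root), guide


# ---------------------------------------------------------------------------
# Full dataset
# ---------------------------------------------------------------------------

@dataclass
class Dataset:
    config: SimulationConfig
    tree: Tree
    genes: list[GeneRecord]
    trna_counts: dict[str, dict[str, int]]
    truth: GroundTruth

    def genes_by_strain(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {}
        for g in self.genes:
            out.setdefault(g.strain, []).append(g)
        return out


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """Generate a complete synthetic dataset under ``config``."""
    config.validate()
    tree = simulate_strain_tree(config.n_strains, config.birth_rate,
                                config.death_rate, config.seed)
    tree.rescale(config.tree_height)

    core = simulate_core_genome(tree, config)
    events, losses, accessory = simulate_hgt_history(tree, config)
    baseline, trna_changes, tip_pools = simulate_trna_history(
        tree, events, accessory, config)
    decoys = inject_pseudo_accessory(core, config)

    genes: list[GeneRecord] = []
    truth = GroundTruth(events=events, losses=losses,
                        trna_changes=trna_changes)

    for g, fam in enumerate(sorted(core)):
        for strain, codons in sorted(core[fam].items()):
            genes.append(GeneRecord(
                gene_id=f"{fam}_{strain}", strain=strain,
                locus="core", pos=g, sequence=codons_to_str(codons),
                family_truth=fam, is_core_truth=True))
    for fam in sorted(accessory):
        info = accessory[fam]
        for strain, codons in sorted(info["tips"].items()):
            genes.append(GeneRecord(
                gene_id=f"{fam}_{strain}", strain=strain,
                locus=info["locus"], pos=info["pos"],
                sequence=codons_to_str(codons),
                family_truth=fam, is_core_truth=False))
    for decoy_fam, strain, locus, pos, codons in decoys:
        gene_id = f"{decoy_fam}_{strain}"
        genes.append(GeneRecord(
            gene_id=gene_id, strain=strain, locus=locus, pos=pos,
            sequence=codons_to_str(codons), family_truth=decoy_fam,
            is_core_truth=False))
        truth.pseudo_genes.append(gene_id)

    return Dataset(config=config, tree=tree, genes=genes,
                   trna_counts=tip_pools, truth=truth)


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

def write_dataset(dataset: Dataset, directory: str | Path) -> Path:
    """Emit per-strain FASTA, genes.tsv, tree.nwk, trna_counts.tsv and the
    ground-truth tables."""
    directory = Path(directory)
    (directory / "ground_truth").mkdir(parents=True, exist_ok=True)
    (directory / "fasta").mkdir(exist_ok=True)

    by_strain = dataset.genes_by_strain()
    for strain in sorted(by_strain):
        with open(directory / "fasta" / f"{strain}.fasta", "w") as fh:
            for g in by_strain[strain]:
                fh.write(f">{g.strain}|{g.gene_id}|{g.locus}|{g.pos}\n")
                fh.write(g.sequence + "\n")

    pd.DataFrame(
        [{"gene_id": g.gene_id, "strain": g.strain, "locus": g.locus,
          "pos": g.pos, "family_truth": g.family_truth,
          "is_core_truth": g.is_core_truth} for g in dataset.genes]
    ).to_csv(directory / "genes.tsv", sep="\t", index=False)

    (directory / "tree.nwk").write_text(dataset.tree.to_newick() + "\n")

    rows = [{"strain": s, "anticodon": ac, "copy_number": n}
            for s in sorted(dataset.trna_counts)
            for ac, n in sorted(dataset.trna_counts[s].items())]
    pd.DataFrame(rows).to_csv(directory / "trna_counts.tsv", sep="\t",
                              index=False)

    gt = directory / "ground_truth"
    pd.DataFrame(
        [{"event_id": e.event_id, "branch": e.branch, "locus": e.locus,
          "gene_families": ",".join(e.gene_families),
          "donor_profile": e.donor_profile}
         for e in dataset.truth.events]
    ).to_csv(gt / "events.tsv", sep="\t", index=False)
    pd.DataFrame(dataset.truth.losses,
                 columns=["branch", "gene_family"]
                 ).to_csv(gt / "losses.tsv", sep="\t", index=False)
    pd.DataFrame(dataset.truth.trna_changes,
                 columns=["branch", "anticodon", "delta"]
                 ).to_csv(gt / "trna_changes.tsv", sep="\t", index=False)
    pd.DataFrame({"gene_id": dataset.truth.pseudo_genes}
                 ).to_csv(gt / "pseudo.tsv", sep="\t", index=False)
    return directory


def read_dataset(directory: str | Path) -> Dataset:
    """Re-read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    meta = pd.read_csv(directory / "genes.tsv", sep="\t")
    seqs: dict[str, str] = {}
    for fasta in sorted((directory / "fasta").glob("*.fasta")):
        with open(fasta) as fh:
            header = None
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    header = line[1:].split("|")[1]
                elif header is not None:
                    seqs[header] = seqs.get(header, "") + line
    genes = [GeneRecord(gene_id=row.gene_id, strain=row.strain,
                        locus=row.locus, pos=int(row.pos),
                        sequence=seqs[row.gene_id],
                        family_truth=row.family_truth,
                        is_core_truth=bool(row.is_core_truth))
             for row in meta.itertuples()]

    tree = Tree.from_newick((directory / "tree.nwk").read_text())

    trna = pd.read_csv(directory / "trna_counts.tsv", sep="\t")
    pools: dict[str, dict[str, int]] = {}
    for row in trna.itertuples():
        pools.setdefault(row.strain, {})[row.anticodon] = int(row.copy_number)

    gt = directory / "ground_truth"
    events_df = pd.read_csv(gt / "events.tsv", sep="\t")
    events = [TrueEvent(event_id=r.event_id, branch=r.branch, locus=r.locus,
                        gene_families=r.gene_families.split(","),
                        donor_profile=int(r.donor_profile))
              for r in events_df.itertuples()]
    losses_df = pd.read_csv(gt / "losses.tsv", sep="\t")
    losses = [(r.branch, r.gene_family) for r in losses_df.itertuples()]
    tc_df = pd.read_csv(gt / "trna_changes.tsv", sep="\t")
    trna_changes = [(r.branch, r.anticodon, int(r.delta))
                    for r in tc_df.itertuples()]
    pseudo_df = pd.read_csv(gt / "pseudo.tsv", sep="\t")
    pseudo = ([] if pseudo_df.empty
              else pseudo_df["gene_id"].astype(str).tolist())

    truth = GroundTruth(events=events, losses=losses,
                        trna_changes=trna_changes, pseudo_genes=pseudo)
    return Dataset(config=SimulationConfig(), tree=tree, genes=genes,
                   trna_counts=pools, truth=truth)
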
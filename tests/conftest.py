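"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hgtcodon.simulate import (SimulationConfig, gc_biased_profile,
                               profile_table, simulate_dataset)
from hgtcodon.tree import Node, Tree


@pytest.fixture(scope="session")
def core_reference():
    """A GC-biased reference codon usage table."""
    return profile_table(gc_biased_profile(1.5))


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimulationConfig(n_strains=12, n_core_genes=50,
                           core_gene_length=180, n_hgt_events=15,
                           pseudo_accessory_count=4, seed=42)
    return simulate_dataset(cfg)


def build_tree(newick: str) -> Tree:
    return Tree.from_newick(newick)


def star(names, length):
    root = Node("R")
    for n in names:
        root.add_child(Node(n, length))
    return Tree(root)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def er_matrix(k: int, rate: float, t: float) -> np.ndarray:
    """Transition matrix by explicit matrix exponential (scipy linalg)."""
    from scipy.linalg import expm

    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, -(k - 1) * rate)
    return expm(Q * t)


def enumerate_posteriors(tree: Tree, tip_states: dict[str, int], k: int,
                         rate: float) -> dict[str, np.ndarray]:
    """Marginal posteriors by exhaustive summation over every assignment of
    states to internal nodes (independent of the pruning implementation)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    post = {n.name: np.zeros(k) for n in nodes}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internals)):
        state = {n.name: s for n, s in zip(internals, assign)}
        state.update(tip_states)
        lik = 1.0 / k  # uniform root prior
        for n in nodes:
            if n.parent is None:
                continue
            P = er_matrix(k, rate, n.length)
            lik *= P[state[n.parent.name], state[n.name]]
        total += lik
        for n in nodes:
            post[n.name][state[n.name]] += lik
    return {name: p / total for name, p in post.items()}


def exact_rank_p(values: np.ndarray, flagged_idx: list[int]) -> float:
    """Exact permutation p by enumerating every rank subset."""
    from scipy.stats import rankdata

    ranks = rankdata(-values, method="average")
    observed = ranks[flagged_idx].sum()
    m = len(flagged_idx)
    count = 0
    combos = list(itertools.combinations(range(len(values)), m))
    for combo in combos:
        if ranks[list(combo)].sum() <= observed:
            count += 1
    return count / len(combos)


def smith_waterman(a: str, b: str):
    """Exact local alignment (Biopython dynamic programming) with the
    reference scoring scheme; returns (identity, overlap, span_a, span_b)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    aln = aligner.align(a, b)[0]
    matches = aligned = 0
    for (s1, e1), (s2, e2) in zip(*aln.aligned):
        seg_a, seg_b = a[s1:e1], b[s2:e2]
        aligned += len(seg_a)
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
    span_a = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
    span_b = aln.aligned[1][-1][1] - aln.aligned[1][0][0]
    identity = matches / aligned if aligned else 0.0
    overlap = max(span_a, span_b) / max(len(a), len(b))
    return identity, overlap, span_a, span_b


def tree_splits(tree: Tree) -> set[frozenset]:
    """Non-trivial bipartitions (as the smaller-side tip sets are not
    canonical, both sides keyed by the clade below each internal branch)."""
    tips = frozenset(tree.tip_names())
    splits = set()
    for node in tree.branches():
        clade = frozenset(tree.clade_tips(node.name))
        if 1 < len(clade) < len(tips) - 1:
            splits.add(frozenset((clade, tips - clade)))
    return splits
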
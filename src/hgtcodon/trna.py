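"""tRNA gene copy-number evolution and compensatory-evolution tests.

Two complementary analyses:

* **Codon level** — ancestral tRNA gene copy numbers (tGCN) are
  reconstructed per anticodon with the same equal-rates machinery used for
  accessory genes; per-branch changes in codon frequency (expected
  occurrences per 1000 coding bases, child minus parent, driven by gene
  content change) are ranked in descending order over all (branch, codon)
  pairs, and the rank sum of the pairs matching a tRNA gain (per pairing
  class: Watson-Crick, wobble, less-favoured wobble) is compared against
  randomised rank draws; the p-value is the fraction of randomisations
  with a rank sum at or below the observed one.

* **Gene level** — the absolute adaptiveness of codon i is
  W_i = sum_j (1 - s_ij) tGCN_ij over the isoacceptors that read it, with
  s_ij the pairing-efficiency constraint; tAI_abs of a gene is the
  geometric mean of W over its codons.  For branches where the tRNA change
  yields a positive mean ΔtAI_abs (child minus parent pools), a
  Mann-Whitney U-test compares ΔtAI_abs between genes acquired on that
  branch and genes already present at the parent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .asr import marginal_posteriors
from .codon import CODON_TO_AA, SENSE_CODONS, _CODON_INDEX
from .tree import Tree

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

WATSON_CRICK = "watson_crick"
WOBBLE = "wobble"
LESS_FAVOURED = "less_favoured_wobble"

#: default selective constraints per pairing class (configurable; the
#: canonical published tAI constraints for the wobble interactions)
DEFAULT_S = {
    WATSON_CRICK: 0.0,
    ("G", "T"): 0.41,   # anticodon 34 G : codon 3 U
    ("T", "G"): 0.68,   # anticodon 34 U : codon 3 G
    ("T", "T"): 0.9,    # extended U34 reading
    ("T", "C"): 0.9,
    ("A", "C"): 0.28,   # I34-style reading of C- and A-ending codons
    ("A", "A"): 0.9999,
}


class TRNAError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Pairing rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairingRule:
    anticodon: str
    codon: str
    pairing_class: str
    s: float


def default_pairing_rules(anticodons: Sequence[str] | None = None
                          ) -> list[PairingRule]:
    """The shipped codon:anticodon pairing table.

    Watson-Crick: the exact reverse complement.  Wobble: G34 reading
    U-ending codons and U34 reading G-ending codons.  Less-favoured
    wobble: extended U34 readings (U/C-ending) and I34-style readings by
    A34 (C/A-ending).  Pairings are restricted to codons of the tRNA's own
    amino acid (the amino acid of its Watson-Crick codon).  ``anticodons``
    limits the table; by default all 61 sense anticodons are covered.
    """
    if anticodons is None:
        anticodons = sorted({revcomp(c) for c in SENSE_CODONS})
    rules = []
    for ac in sorted(set(anticodons)):
        wc_codon = revcomp(ac)
        if wc_codon not in CODON_TO_AA:
            continue
        aa = CODON_TO_AA[wc_codon]
        rules.append(PairingRule(ac, wc_codon, WATSON_CRICK,
                                 DEFAULT_S[WATSON_CRICK]))
        wob34 = ac[0]
        wobble_thirds = {"G": ("T",), "T": ("G",)}.get(wob34, ())
        for third in wobble_thirds:
            codon = wc_codon[:2] + third
            if CODON_TO_AA.get(codon) == aa and codon != wc_codon:
                rules.append(PairingRule(ac, codon, WOBBLE,
                                         DEFAULT_S[(wob34, third)]))
        if wob34 == "T":
            for third in ("T", "C"):
                codon = wc_codon[:2] + third
                if CODON_TO_AA.get(codon) == aa and codon != wc_codon:
                    rules.append(PairingRule(ac, codon, LESS_FAVOURED,
                                             DEFAULT_S[(wob34, third)]))
        elif wob34 == "A":
            for third in ("C", "A"):
                codon = wc_codon[:2] + third
                if CODON_TO_AA.get(codon) == aa and codon != wc_codon:
                    rules.append(PairingRule(ac, codon, LESS_FAVOURED,
                                             DEFAULT_S[(wob34, third)]))
    return rules


def write_pairing_rules(rules: Sequence[PairingRule], path) -> None:
    """Write a pairing table as TSV (anticodon, codon, class, s)."""
    import pandas as pd

    pd.DataFrame([{"anticodon": r.anticodon, "codon": r.codon,
                   "pairing_class": r.pairing_class, "s": r.s}
                  for r in rules]).to_csv(path, sep="\t", index=False)


def read_pairing_rules(path) -> list[PairingRule]:
    """Read a pairing table written by :func:`write_pairing_rules` (or a
    user-substituted scheme in the same format)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [PairingRule(r.anticodon, r.codon, r.pairing_class, float(r.s))
            for r in df.itertuples()]


def rules_by_class(rules: Sequence[PairingRule]
                   ) -> dict[str, dict[str, list[PairingRule]]]:
    """pairing class -> anticodon -> rules."""
    out: dict[str, dict[str, list[PairingRule]]] = {}
    for r in rules:
        out.setdefault(r.pairing_class, {}).setdefault(r.anticodon,
                                                       []).append(r)
    return out


# ---------------------------------------------------------------------------
# Ancestral tRNA copy numbers
# ---------------------------------------------------------------------------

@dataclass
class TRNAHistory:
    node_pools: dict[str, dict[str, int]]   # node -> anticodon -> tGCN
    changes: list[tuple[str, str, int]]     # (branch, anticodon, delta)


def asr_trna_counts(tree: Tree, tip_pools: Mapping[str, Mapping[str, int]],
                    rate: float | None = None) -> TRNAHistory:
    """Equal-rates ASR of per-anticodon copy numbers.

    Node counts are the maximum-posterior states; a branch change is the
    child count minus the parent count.
    """
    anticodons = sorted({ac for pool in tip_pools.values() for ac in pool})
    tips = tree.tip_names()
    missing = set(tips) - set(tip_pools)
    if missing:
        raise TRNAError(f"no tRNA pool for strains {sorted(missing)}")

    node_pools: dict[str, dict[str, int]] = {
        n.name: {} for n in tree.postorder()}
    for ac in anticodons:
        observed = [int(tip_pools[t].get(ac, 0)) for t in tips]
        k = max(observed) + 1
        if k == 1:
            for name in node_pools:
                node_pools[name][ac] = 0
            continue
        if min(observed) == max(observed):
            for name in node_pools:
                node_pools[name][ac] = observed[0]
            continue
        states = {t: np.array([int(tip_pools[t].get(ac, 0))]) for t in tips}
        asr = marginal_posteriors(tree, states, k=k, rate=rate)
        for name, post in asr.posteriors.items():
            node_pools[name][ac] = int(np.argmax(post[0]))

    changes = []
    for node in tree.branches():
        for ac in anticodons:
            delta = (node_pools[node.name][ac]
                     - node_pools[node.parent.name][ac])
            if delta != 0:
                changes.append((node.name, ac, delta))
    return TRNAHistory(node_pools=node_pools, changes=changes)


# ---------------------------------------------------------------------------
# Node codon frequencies
# ---------------------------------------------------------------------------

def node_codon_frequencies(gene_counts: Mapping[str, np.ndarray],
                           content: Sequence[str]) -> np.ndarray:
    """Pooled codon usage of the genes present at a node, scaled to
    expected occurrences per 1000 coding bases.

    ``gene_counts`` maps gene/cluster ids to 61-long sense-codon count
    vectors (one representative copy per cluster).
    """
    if not content:
        raise TRNAError("node with zero genes: codon table undefined")
    total = np.zeros(len(SENSE_CODONS))
    for gid in content:
        total += gene_counts[gid]
    bases = 3.0 * total.sum()
    if bases == 0:
        raise TRNAError("node content has zero codons")
    return total / bases * 1000.0


def delta_codon_freq(parent_table: np.ndarray,
                     child_table: np.ndarray) -> np.ndarray:
    """Child minus parent, elementwise (per 1000 bases)."""
    return np.asarray(child_table) - np.asarray(parent_table)


# ---------------------------------------------------------------------------
# Rank permutation test
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    pairing_class: str
    observed_rank_sum: float
    p: float
    n_flagged: int
    n_total: int


def rank_permutation_test(deltas: Mapping[tuple[str, str], float],
                          flagged: set[tuple[str, str]],
                          n_perm: int = 10_000,
                          seed: int | np.random.Generator = 0,
                          pairing_class: str = WATSON_CRICK
                          ) -> PermutationResult:
    """Rank-sum permutation test of codon-frequency increases at tRNA gains.

    All (branch, codon) deltas are ranked in descending order (rank 1 =
    largest increase; ties get average ranks).  The observed value is the
    rank sum over ``flagged`` pairs; each permutation draws the same number
    of ranks uniformly without replacement, and p is the fraction of
    permutations with a rank sum at or below the observed value.
    """
    if not flagged:
        raise TRNAError(f"empty flagged set for class {pairing_class!r}")
    keys = sorted(deltas)
    missing = flagged - set(keys)
    if missing:
        raise TRNAError(f"flagged pairs missing from deltas: "
                        f"{sorted(missing)[:3]}")
    values = np.array([deltas[k] for k in keys])
    ranks = stats.rankdata(-values, method="average")
    key_index = {k: i for i, k in enumerate(keys)}
    observed = float(sum(ranks[key_index[k]] for k in flagged))

    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    m = len(flagged)
    n = len(keys)
    count = 0
    chunk = max(1, min(n_perm, int(2e7 // max(n, 1))))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        u = rng.random((size, n))
        idx = np.argpartition(u, m - 1, axis=1)[:, :m]
        sums = ranks[idx].sum(axis=1)
        count += int(np.sum(sums <= observed))
        done += size
    return PermutationResult(pairing_class=pairing_class,
                             observed_rank_sum=observed,
                             p=count / n_perm, n_flagged=m, n_total=n)


def flagged_pairs(gains: Sequence[tuple[str, str]],
                  rules: Sequence[PairingRule],
                  pairing_class: str,
                  valid_keys: set[tuple[str, str]] | None = None
                  ) -> set[tuple[str, str]]:
    """(branch, codon) pairs matched by tRNA gains under one pairing class.

    ``gains`` lists (branch, anticodon) copy-number increases."""
    per_ac = rules_by_class(rules).get(pairing_class, {})
    out = set()
    for branch, anticodon in gains:
        for rule in per_ac.get(anticodon, ()):
            key = (branch, rule.codon)
            if valid_keys is None or key in valid_keys:
                out.add(key)
    return out


# ---------------------------------------------------------------------------
# Absolute adaptiveness and tAI_abs
# ---------------------------------------------------------------------------

def absolute_adaptiveness(pool: Mapping[str, int],
                          rules: Sequence[PairingRule]) -> np.ndarray:
    """W_i = sum_j (1 - s_ij) tGCN_ij per sense codon (61-vector); zero
    when no tRNA in the pool reads the codon."""
    W = np.zeros(len(SENSE_CODONS))
    for rule in rules:
        n = pool.get(rule.anticodon, 0)
        if n > 0:
            W[_CODON_INDEX[rule.codon]] += (1.0 - rule.s) * n
    return W


def tai_abs(gene_counts: np.ndarray, W: np.ndarray
            ) -> tuple[float, bool]:
    """Geometric mean of W over a gene's sense codons.

    Codons with W = 0 are replaced by the geometric mean of the nonzero
    entries of the full W map (the tAI convention); the returned flag marks
    genes where the replacement was used.  All-zero W raises.
    """
    counts = np.asarray(gene_counts, dtype=float)
    nonzero = W > 0
    if not np.any(nonzero):
        raise TRNAError("all codon adaptiveness values are zero")
    geo_bg = math.exp(float(np.mean(np.log(W[nonzero]))))
    Weff = np.where(nonzero, W, geo_bg)
    used = counts > 0
    flagged = bool(np.any(used & ~nonzero))
    total = counts.sum()
    if total == 0:
        raise TRNAError("gene with zero codons")
    return (math.exp(float((counts @ np.log(Weff)) / total)), flagged)


# ---------------------------------------------------------------------------
# Branch-level compensation test
# ---------------------------------------------------------------------------

@dataclass
class BranchDelta:
    branch: str
    mean_delta_hgt: float
    mean_delta_resident: float
    mean_delta_all: float
    ratio: float
    p: float
    classification: str  # hgt_higher | resident_higher | no_difference
    n_hgt: int
    n_resident: int
    tested: bool = True


def branch_compensation_test(branch: str,
                             parent_pool: Mapping[str, int],
                             child_pool: Mapping[str, int],
                             hgt_genes: Mapping[str, np.ndarray],
                             resident_genes: Mapping[str, np.ndarray],
                             rules: Sequence[PairingRule],
                             alpha: float = 0.05) -> BranchDelta:
    """ΔtAI_abs (child pool minus parent pool) per gene; branches with a
    positive mean over all genes are tested with a two-sided Mann-Whitney
    U comparing genes acquired on the branch against genes already present
    at the parent."""
    W_parent = absolute_adaptiveness(parent_pool, rules)
    W_child = absolute_adaptiveness(child_pool, rules)

    def deltas(group: Mapping[str, np.ndarray]) -> np.ndarray:
        return np.array([tai_abs(c, W_child)[0] - tai_abs(c, W_parent)[0]
                         for _, c in sorted(group.items())])

    d_hgt = deltas(hgt_genes)
    d_res = deltas(resident_genes)
    all_d = np.concatenate([d_hgt, d_res]) if (d_hgt.size or d_res.size) \
        else np.array([])
    if all_d.size == 0:
        raise TRNAError(f"branch {branch}: no genes to test")
    mean_all = float(all_d.mean())

    if mean_all <= 0 or d_hgt.size == 0 or d_res.size == 0:
        return BranchDelta(
            branch=branch,
            mean_delta_hgt=float(d_hgt.mean()) if d_hgt.size else float("nan"),
            mean_delta_resident=(float(d_res.mean()) if d_res.size
                                 else float("nan")),
            mean_delta_all=mean_all, ratio=float("nan"), p=float("nan"),
            classification="untestable" if mean_all > 0 else "not_tested",
            n_hgt=int(d_hgt.size), n_resident=int(d_res.size), tested=False)

    if np.ptp(np.concatenate([d_hgt, d_res])) == 0:
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(d_hgt, d_res,
                                     alternative="two-sided").pvalue)
    mean_res = float(d_res.mean())
    ratio = float(d_hgt.mean() / mean_res) if mean_res != 0 else float("inf")
    if p < alpha:
        cls = ("hgt_higher" if d_hgt.mean() > mean_res
               else "resident_higher")
    else:
        cls = "no_difference"
    return BranchDelta(branch=branch, mean_delta_hgt=float(d_hgt.mean()),
                       mean_delta_resident=mean_res, mean_delta_all=mean_all,
                       ratio=ratio, p=p, classification=cls,
                       n_hgt=int(d_hgt.size), n_resident=int(d_res.size))
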
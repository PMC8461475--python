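"""Directional post-transfer evolution of codon usage (gene amelioration).

For clusters with enough extant sequences tracing to a single HGT event,
the ancestral CDS is reconstructed at the root of the guide tree (the
strain tree restricted to the carriers) by per-column marginal ASR under a
symmetric 4-state nucleotide model; gap columns are removed first.  The
per-sequence change in COUSIN relative to the ancestor (positive = towards
the core genome's usage) is tested against zero with a two-sided one-sample
t-test.  A synonymous-only variant converts every non-synonymous codon back
to its ancestral state before scoring, isolating the contribution of
synonymous variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from . import asr as _asr
from .codon import CODON_TO_AA, STOP_CODONS, CodonUsageTable, cousin
from .hgt import HGTEvent
from .tree import Tree

_NUC = "ACGT"
_NUC_INDEX = {n: i for i, n in enumerate(_NUC)}

ALPHA = 0.05


class AmeliorationError(ValueError):
    pass


@dataclass
class AmeliorationResult:
    cluster_id: str
    n_extant: int
    cousin_anc: float
    delta_all: float
    delta_syn: float
    t_p_all: float
    t_p_syn: float
    S: int
    N: int
    direction: str  # towards | away | none
    degenerate_variance: bool = False


def select_clusters(events: Sequence[HGTEvent],
                    carriers: Mapping[str, Sequence[str]],
                    min_extant: int = 20) -> list[str]:
    """Clusters whose extant members tracing to a single HGT event number
    at least ``min_extant``.  A cluster appearing in several events must
    reach the threshold within one of them."""
    best: dict[str, int] = {}
    for event in events:
        for cid in event.clusters:
            n = len(carriers.get(cid, ()))
            best[cid] = max(best.get(cid, 0), n)
    return sorted(cid for cid, n in best.items() if n >= min_extant)


def strip_gap_columns(rows: Mapping[str, str]) -> dict[str, str]:
    """Remove every codon column containing a gap in any row."""
    names = sorted(rows)
    arr = np.array([list(rows[n]) for n in names])
    if arr.ndim != 2:
        raise AmeliorationError("rows of unequal length")
    keep_nt = ~(arr == "-").any(axis=0)
    # drop whole codons: a codon survives only if all 3 positions survive
    L = arr.shape[1]
    if L % 3:
        raise AmeliorationError("alignment length not divisible by 3")
    keep_codon = keep_nt.reshape(-1, 3).all(axis=1)
    keep = np.repeat(keep_codon, 3)
    return {n: "".join(arr[i, keep]) for i, n in enumerate(names)}


def reconstruct_ancestral_sequence(rows: Mapping[str, str],
                                   guide_tree: Tree,
                                   rate: float | None = None) -> str:
    """Maximum-posterior nucleotide at the guide-tree root, per column.

    Columns containing any gap are removed first.  A single symmetric
    substitution rate is fitted over all columns jointly.  If every guide
    branch has zero length the reconstruction falls back to column
    majority (ties broken alphabetically) with a warning.
    """
    if len(rows) < 3:
        raise AmeliorationError("need >= 3 extant sequences")
    rows = strip_gap_columns(rows)
    lengths = {len(s) for s in rows.values()}
    if len(lengths) != 1:
        raise AmeliorationError("rows of unequal length after stripping")

    tips = set(guide_tree.tip_names())
    if tips != set(rows):
        raise AmeliorationError(
            "guide tree tips must match the extant sequences")

    if all(n.length <= 0 for n in guide_tree.branches()):
        warnings.warn("zero-length guide tree; falling back to column "
                      "majority", stacklevel=2)
        names = sorted(rows)
        arr = np.array([[_NUC_INDEX[c] for c in rows[n]] for n in names])
        out = []
        for col in arr.T:
            counts = np.bincount(col, minlength=4)
            out.append(_NUC[int(np.argmax(counts))])
        return "".join(out)

    tip_states = {name: np.array([_NUC_INDEX[c] for c in seq])
                  for name, seq in rows.items()}
    asr = _asr.marginal_posteriors(guide_tree, tip_states, k=4, rate=rate)
    root_post = asr.posteriors[guide_tree.root.name]  # (n_cols, 4)
    return "".join(_NUC[i] for i in np.argmax(root_post, axis=1))


def synonymous_only_projection(extant: str, ancestral: str) -> str:
    """Convert every non-synonymous codon of ``extant`` back to the
    ancestral codon; synonymous differences are kept.  The projection
    translates identically to the ancestor."""
    if len(extant) != len(ancestral) or len(extant) % 3:
        raise AmeliorationError(
            "sequences must have equal lengths divisible by 3")
    out = []
    for i in range(0, len(extant), 3):
        ce, ca = extant[i:i + 3], ancestral[i:i + 3]
        if ce in STOP_CODONS or ca in STOP_CODONS:
            raise AmeliorationError(f"internal stop codon at position {i}")
        out.append(ce if CODON_TO_AA[ce] == CODON_TO_AA[ca] else ca)
    return "".join(out)


def count_syn_nonsyn(extants: Mapping[str, str],
                     ancestral: str) -> tuple[int, int]:
    """Codon columns with synonymous-only (S) vs any non-synonymous (N)
    variation relative to the ancestor.  A column counts toward N when any
    extant codon is non-synonymous; otherwise toward S when any extant
    codon differs synonymously."""
    S = N = 0
    for i in range(0, len(ancestral), 3):
        ca = ancestral[i:i + 3]
        any_non = any_syn = False
        for seq in extants.values():
            ce = seq[i:i + 3]
            if ce == ca:
                continue
            if CODON_TO_AA[ce] != CODON_TO_AA[ca]:
                any_non = True
            else:
                any_syn = True
        if any_non:
            N += 1
        elif any_syn:
            S += 1
    return S, N


def _one_sample_t(deltas: np.ndarray) -> tuple[float, bool]:
    """Two-sided one-sample t-test p-value; degenerate (zero-variance,
    nonzero-mean) samples get p reported below 1e-15."""
    if np.allclose(deltas, deltas[0]):
        if deltas[0] == 0:
            return 1.0, False
        return 1e-16, True
    res = stats.ttest_1samp(deltas, 0.0)
    return float(res.pvalue), False


def delta_cousin_test(cluster_id: str, extants: Mapping[str, str],
                      ancestral: str, reference: CodonUsageTable,
                      alpha: float = ALPHA) -> AmeliorationResult:
    """Per-extant ΔCOUSIN = COUSIN(extant) − COUSIN(ancestor); two-sided
    one-sample t-test of mean zero, repeated on the synonymous-only
    projections.  Direction is the sign of a significant delta_all."""
    if len(extants) < 3:
        raise AmeliorationError("need >= 3 extant sequences")
    c_anc = cousin(ancestral, reference)
    deltas, deltas_syn = [], []
    for seq in (extants[k] for k in sorted(extants)):
        deltas.append(cousin(seq, reference) - c_anc)
        proj = synonymous_only_projection(seq, ancestral)
        deltas_syn.append(cousin(proj, reference) - c_anc)
    deltas = np.array(deltas)
    deltas_syn = np.array(deltas_syn)

    p_all, degen_all = _one_sample_t(deltas)
    p_syn, degen_syn = _one_sample_t(deltas_syn)
    S, N = count_syn_nonsyn(extants, ancestral)

    if p_all < alpha:
        direction = "towards" if deltas.mean() > 0 else "away"
    else:
        direction = "none"
    return AmeliorationResult(
        cluster_id=cluster_id, n_extant=len(extants),
        cousin_anc=float(c_anc),
        delta_all=float(deltas.mean()), delta_syn=float(deltas_syn.mean()),
        t_p_all=p_all, t_p_syn=p_syn, S=S, N=N, direction=direction,
        degenerate_variance=degen_all or degen_syn)


def analyse_cluster(cluster_id: str, extants: Mapping[str, str],
                    strain_tree: Tree, reference: CodonUsageTable,
                    alpha: float = ALPHA) -> AmeliorationResult:
    """Guide-tree restriction, ancestral reconstruction and ΔCOUSIN test
    for one cluster's extant sequences (keyed by strain)."""
    guide = strain_tree.restrict(sorted(extants))
    stripped = strip_gap_columns(extants)
    ancestral = reconstruct_ancestral_sequence(stripped, guide)
    return delta_cousin_test(cluster_id, stripped, ancestral, reference,
                             alpha=alpha)
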
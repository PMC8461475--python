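"""Codon usage tables and per-gene codon-usage metrics.

The central metric is the COUSIN score (Codon Usage Similarity Index): a
normalised comparison of a query gene's synonymous codon usage against a
reference codon usage table (here, the pooled core genome).  It is scaled so
that a query with uniform usage within every synonymous family scores 0 (no
bias), a query whose per-family codon frequencies equal the reference's
scores 1 (bias identical in strength and direction to the reference), values
above 1 indicate a stronger same-direction bias, and negative values a bias
in the opposite direction.

Also provided: CAI (geometric mean of relative adaptiveness weights),
Wright's effective number of codons (ENC, from per-family homozygosities;
range 20 to 61), GC content, the >=100-codon length filter, and the
residence-time trend analysis (Kendall correlation plus per-interval
min/max/median linear fits).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable
from scipy import stats

logger = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# Genetic code (standard table)
# ---------------------------------------------------------------------------

_standard = _BioCodonTable.unambiguous_dna_by_id[1]

CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_standard.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    FAMILIES.setdefault(_aa, ())
    FAMILIES[_aa] += (_codon,)

#: amino acids with >= 2 synonymous codons
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, cods in FAMILIES.items() if len(cods) >= 2))
#: single-codon amino acids (Met, Trp)
SINGLE_CODON_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, cods in FAMILIES.items() if len(cods) == 1))

_CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}


class CodonUsageError(ValueError):
    pass


def split_codons(sequence: str) -> list[str]:
    """Split a CDS into codons; the length must be divisible by 3."""
    seq = sequence.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise CodonUsageError(
            f"sequence length {len(seq)} not divisible by 3")
    return [seq[i:i + 3] for i in range(0, len(seq), 3)]


def count_codons(sequences: Iterable[str]) -> np.ndarray:
    """Pooled sense-codon counts (length 61, ordered as SENSE_CODONS).

    Stop codons are excluded from the counts.
    """
    counts = np.zeros(len(SENSE_CODONS), dtype=np.int64)
    for seq in sequences:
        for codon in split_codons(seq):
            idx = _CODON_INDEX.get(codon)
            if idx is not None:
                counts[idx] += 1
            elif codon not in STOP_CODONS:
                raise CodonUsageError(f"invalid codon {codon!r}")
    return counts


def sense_codon_length(sequence: str) -> int:
    """Number of sense codons in a CDS (stop codons excluded)."""
    return sum(1 for c in split_codons(sequence) if c not in STOP_CODONS)


# ---------------------------------------------------------------------------
# Codon usage table
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    """Counts and derived frequencies over the 61 sense codons."""

    counts: np.ndarray  # int counts, ordered as SENSE_CODONS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(SENSE_CODONS),):
            raise CodonUsageError("counts must cover the 61 sense codons")
        if np.any(self.counts < 0):
            raise CodonUsageError("negative codon counts")
        if self.counts.sum() == 0:
            raise CodonUsageError("empty codon usage table")

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "CodonUsageTable":
        sequences = list(sequences)
        if not sequences:
            raise CodonUsageError("no sequences given")
        return cls(count_codons(sequences))

    @classmethod
    def from_counts(cls, counts: Mapping[str, float]) -> "CodonUsageTable":
        vec = np.zeros(len(SENSE_CODONS))
        for codon, n in counts.items():
            if codon in STOP_CODONS:
                continue
            vec[_CODON_INDEX[codon]] = n
        return cls(vec)

    def count(self, codon: str) -> float:
        return float(self.counts[_CODON_INDEX[codon]])

    @property
    def frequencies(self) -> dict[str, float]:
        total = self.counts.sum()
        return {c: float(self.counts[i]) / total
                for c, i in _CODON_INDEX.items()}

    def family_counts(self, aa: str) -> dict[str, float]:
        return {c: float(self.counts[_CODON_INDEX[c]]) for c in FAMILIES[aa]}

    def family_relative(self, aa: str) -> dict[str, float] | None:
        """Relative frequencies within the synonymous family of ``aa``;
        None when the family is unobserved."""
        fam = self.family_counts(aa)
        total = sum(fam.values())
        if total == 0:
            return None
        return {c: n / total for c, n in fam.items()}

    def to_frame(self):
        """cusp-style table: codon, amino acid, per-family fraction,
        frequency per 1000 codons, count."""
        import pandas as pd

        rows = []
        total = self.counts.sum()
        for aa in sorted(FAMILIES):
            rel = self.family_relative(aa)
            for codon in FAMILIES[aa]:
                n = self.count(codon)
                rows.append({
                    "codon": codon,
                    "aa": aa,
                    "fraction": rel[codon] if rel else float("nan"),
                    "per_1000": 1000.0 * n / total,
                    "count": n,
                })
        return pd.DataFrame(rows)


def build_codon_table(sequences: Iterable[str]) -> CodonUsageTable:
    """Pooled codon usage table over a gene set (e.g. all core genes)."""
    return CodonUsageTable.from_sequences(sequences)


# ---------------------------------------------------------------------------
# Simple statistics
# ---------------------------------------------------------------------------

def gc_content(sequences: str | Iterable[str]) -> float:
    """(#G + #C) / total bases, pooled over the input sequences."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = total = 0
    for seq in sequences:
        s = seq.upper()
        gc += s.count("G") + s.count("C")
        total += len(s)
    if total == 0:
        raise CodonUsageError("gc_content of empty input")
    return gc / total


def gc3_content(sequences: str | Iterable[str]) -> float:
    """GC fraction at third codon positions, pooled."""
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = total = 0
    for seq in sequences:
        thirds = seq.upper()[2::3]
        gc += thirds.count("G") + thirds.count("C")
        total += len(thirds)
    if total == 0:
        raise CodonUsageError("gc3_content of empty input")
    return gc / total


def length_filter(genes: Mapping[str, str], min_codons: int = 100
                  ) -> dict[str, str]:
    """Drop genes shorter than ``min_codons`` sense codons (stop excluded)."""
    kept = {}
    dropped = 0
    for gene_id, seq in genes.items():
        if sense_codon_length(seq) >= min_codons:
            kept[gene_id] = seq
        else:
            dropped += 1
    if dropped:
        logger.info("length_filter: dropped %d gene(s) shorter than %d codons",
                    dropped, min_codons)
    return kept


# ---------------------------------------------------------------------------
# ENC — Wright's effective number of codons
# ---------------------------------------------------------------------------

_DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa in DEGENERATE_AAS:
    _k = len(FAMILIES[_aa])
    _DEGENERACY_CLASSES.setdefault(_k, ())
    _DEGENERACY_CLASSES[_k] += (_aa,)
# class sizes under the standard code: 9 twofold, 1 threefold (Ile),
# 5 fourfold, 3 sixfold; plus Met and Trp -> ENC in [20, 61]
_CLASS_SIZES = {k: len(v) for k, v in _DEGENERACY_CLASSES.items()}


def _as_counts(gene: str | CodonUsageTable | np.ndarray) -> np.ndarray:
    if isinstance(gene, CodonUsageTable):
        return gene.counts
    if isinstance(gene, np.ndarray):
        return np.asarray(gene, dtype=float)
    return count_codons([gene]).astype(float)


def enc(gene: str | CodonUsageTable | np.ndarray,
        estimator: str = "plugin") -> float:
    """Wright's effective number of codons.

    ``plugin`` computes per-family homozygosity F = sum p_i**2 from the raw
    codon frequencies (hits 20 and 61 exactly at the boundary usages);
    ``sample`` applies the finite-sample correction (n*F - 1)/(n - 1).
    Families absent from the gene are imputed by the mean homozygosity of
    their degeneracy class; an empty threefold class falls back to the mean
    of the two- and fourfold classes.  Result clamped to <= 61.
    """
    if estimator not in ("plugin", "sample"):
        raise ValueError(f"unknown estimator {estimator!r}")
    counts = _as_counts(gene)

    fam_F: dict[str, float] = {}
    for aa in DEGENERATE_AAS:
        idx = [_CODON_INDEX[c] for c in FAMILIES[aa]]
        n = counts[idx].sum()
        if n == 0:
            continue
        p = counts[idx] / n
        F = float(np.sum(p * p))
        if estimator == "sample":
            if n < 2:
                continue
            F = (n * F - 1.0) / (n - 1.0)
            if F <= 0:
                continue
        fam_F[aa] = F

    if not fam_F:
        raise CodonUsageError("no degenerate family observed; ENC undefined")

    class_means: dict[int, float] = {}
    for k, aas in _DEGENERACY_CLASSES.items():
        vals = [fam_F[aa] for aa in aas if aa in fam_F]
        if vals:
            class_means[k] = float(np.mean(vals))
    if 3 not in class_means and 2 in class_means and 4 in class_means:
        class_means[3] = 0.5 * (class_means[2] + class_means[4])
    overall = float(np.mean(list(fam_F.values())))

    total = 2.0  # Met + Trp
    for k, size in _CLASS_SIZES.items():
        Fk = class_means.get(k, overall)
        total += size / Fk
    return min(total, 61.0)


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------

def cai(gene: str | CodonUsageTable | np.ndarray,
        reference: CodonUsageTable) -> float:
    """Codon Adaptation Index of a gene against a reference table.

    w(c) = f_ref(c) / max synonymous f_ref(c); geometric mean over the
    gene's codons, excluding stops and the single-codon amino acids.
    A reference codon with zero count used by the gene gets a smoothed
    weight of 0.5 / (family total count).
    """
    counts = _as_counts(gene)
    log_sum = 0.0
    n_codons = 0.0
    for aa in DEGENERATE_AAS:
        fam = FAMILIES[aa]
        if not any(counts[_CODON_INDEX[c]] for c in fam):
            continue
        ref_counts = np.array([reference.count(c) for c in fam])
        fam_total = ref_counts.sum()
        if fam_total == 0:
            raise CodonUsageError(
                f"reference has zero mass on family {aa!r}")
        ref_max = ref_counts.max()
        for c, rc in zip(fam, ref_counts):
            n = counts[_CODON_INDEX[c]]
            if n == 0:
                continue
            if rc == 0:
                warnings.warn(
                    f"reference count 0 for codon {c}; smoothing weight",
                    stacklevel=2)
                w = 0.5 / fam_total
            else:
                w = rc / ref_max
            log_sum += n * math.log(w)
            n_codons += n
    if n_codons == 0:
        raise CodonUsageError("gene has no codons from degenerate families")
    return math.exp(log_sum / n_codons)


# ---------------------------------------------------------------------------
# COUSIN
# ---------------------------------------------------------------------------

def cousin(gene: str | CodonUsageTable | np.ndarray,
           reference: CodonUsageTable) -> float:
    """Normalised codon usage similarity of a query against a reference.

    Per degenerate amino-acid family, let q, w be the query's and the
    reference's within-family codon frequency vectors and k the family
    degeneracy.  The family score q.w is compared with its value under the
    uniform null (1/k) and under the reference itself (w.w); families are
    aggregated weighted by the query's amino-acid composition g:

        COUSIN = sum_a g_a (q_a.w_a - 1/k_a) / sum_a g_a (w_a.w_a - 1/k_a)

    yielding 0 for an unbiased (within-family uniform) query, 1 for a query
    matching the reference, >1 for stronger same-direction bias and <0 for
    opposite-direction bias.
    """
    counts = _as_counts(gene)
    num = 0.0
    den = 0.0
    total = 0.0
    for aa in DEGENERATE_AAS:
        fam = FAMILIES[aa]
        idx = [_CODON_INDEX[c] for c in fam]
        n_fam = counts[idx].sum()
        if n_fam == 0:
            continue
        rel = reference.family_relative(aa)
        if rel is None:
            raise CodonUsageError(
                f"reference has zero mass on family {aa!r}")
        w = np.array([rel[c] for c in fam])
        q = counts[idx] / n_fam
        k = len(fam)
        num += n_fam * (float(q @ w) - 1.0 / k)
        den += n_fam * (float(w @ w) - 1.0 / k)
        total += n_fam
    if total == 0:
        raise CodonUsageError("gene has no codons from degenerate families")
    if abs(den) <= 1e-12 * total:
        raise CodonUsageError(
            "reference is uniform within every family the query uses; "
            "COUSIN undefined")
    return num / den


# ---------------------------------------------------------------------------
# Per-gene metric bundle
# ---------------------------------------------------------------------------

@dataclass
class CodonMetrics:
    gene_id: str
    length_codons: int
    gc: float
    cousin: float
    cai: float
    enc: float


def compute_metrics(genes: Mapping[str, str], reference: CodonUsageTable,
                    min_codons: int = 100) -> dict[str, CodonMetrics]:
    """COUSIN/CAI/ENC/GC for every gene passing the length filter."""
    out = {}
    for gene_id, seq in length_filter(genes, min_codons).items():
        counts = count_codons([seq]).astype(float)
        out[gene_id] = CodonMetrics(
            gene_id=gene_id,
            length_codons=sense_codon_length(seq),
            gc=gc_content(seq),
            cousin=cousin(counts, reference),
            cai=cai(counts, reference),
            enc=enc(counts),
        )
    return out


# ---------------------------------------------------------------------------
# Residence-time trend
# ---------------------------------------------------------------------------

@dataclass
class IntervalFit:
    slope: float
    intercept: float
    r2: float
    p: float


@dataclass
class ResidenceTrend:
    kendall_tau: float
    kendall_p: float
    interval: float
    n_pairs: int
    n_intervals: int
    fits: dict[str, IntervalFit] | None = field(default=None)


def residence_trend(residence: Sequence[float], values: Sequence[float],
                    interval: float = 0.001) -> ResidenceTrend:
    """Kendall correlation of a codon-usage metric with residence time, plus
    linear fits of the per-interval minimum, maximum and median against the
    interval midpoints.

    When all observations fall into a single interval the fits are undefined
    (``fits is None``); the Kendall statistics are still reported.
    """
    residence = np.asarray(residence, dtype=float)
    values = np.asarray(values, dtype=float)
    if residence.shape != values.shape or residence.size < 2:
        raise ValueError("need >= 2 paired observations")
    tau, tau_p = stats.kendalltau(residence, values)

    bins = np.floor(residence / interval).astype(int)
    mids, mins, maxs, meds = [], [], [], []
    for b in sorted(set(bins)):
        sel = values[bins == b]
        mids.append((b + 0.5) * interval)
        mins.append(sel.min())
        maxs.append(sel.max())
        meds.append(float(np.median(sel)))

    trend = ResidenceTrend(
        kendall_tau=float(tau), kendall_p=float(tau_p),
        interval=interval, n_pairs=int(residence.size),
        n_intervals=len(mids))
    if len(mids) < 2:
        warnings.warn("all residence times in one interval; "
                      "interval fits undefined", stacklevel=2)
        return trend

    fits = {}
    x = np.asarray(mids)
    for name, y in (("min", mins), ("max", maxs), ("median", meds)):
        res = stats.linregress(x, np.asarray(y))
        fits[name] = IntervalFit(slope=float(res.slope),
                                 intercept=float(res.intercept),
                                 r2=float(res.rvalue ** 2),
                                 p=float(res.pvalue))
    trend.fits = fits
    return trend
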
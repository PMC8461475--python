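"""Codon usage tables, COUSIN/CAI/ENC/GC and the residence trend."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hgtcodon.codon import (CodonUsageError, FAMILIES,
                            SENSE_CODONS, build_codon_table, cai, cousin,
                            enc, gc_content, length_filter, residence_trend,
                            sense_codon_length)
from hgtcodon.simulate import gc_biased_profile, profile_table

ONE_PER_AA = "".join(FAMILIES[aa][0] for aa in sorted(FAMILIES))
UNIFORM = "".join(c for aa in sorted(FAMILIES) for c in FAMILIES[aa])


def test_codon_table_counts_and_frequencies():
    t = build_codon_table(["ATGATGATG"])
    assert t.count("ATG") == 3
    assert t.frequencies["ATG"] == 1.0
    # additivity over genes, and a hand-tallied toy
    t2 = build_codon_table(["ATGAAA", "AAAGGG"])
    assert t2.count("AAA") == 2 and t2.count("ATG") == 1 \
        and t2.count("GGG") == 1
    assert t2.frequencies["AAA"] == pytest.approx(0.5)


def test_codon_table_excludes_stops_and_rejects_empty():
    t = build_codon_table(["ATGTAA"])  # trailing stop dropped from counts
    assert t.counts.sum() == 1
    with pytest.raises(CodonUsageError):
        build_codon_table([])


@pytest.mark.parametrize("seq,expected", [
    ("GGCC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5)])
def test_gc_content(seq, expected):
    assert gc_content(seq) == expected


def test_enc_boundary_single_codon_per_aa():
    # one codon per amino acid, all 20 present -> 20 effective codons
    assert enc(ONE_PER_AA * 10) == pytest.approx(20.0)


def test_enc_boundary_uniform_families():
    # exactly uniform synonymous usage -> 61 under the plug-in estimator
    assert enc(UNIFORM * 5) == pytest.approx(61.0)


def test_enc_matches_direct_homozygosity_computation(core_reference):
    rng = np.random.default_rng(7)
    gene = "".join(rng.choice(SENSE_CODONS, 300))
    # oracle: Wright's formula from directly tallied per-family p_i
    from collections import Counter

    counts = Counter(gene[i:i + 3] for i in range(0, len(gene), 3))
    class_F = {}
    for aa, fam in FAMILIES.items():
        if len(fam) < 2:
            continue
        n = sum(counts.get(c, 0) for c in fam)
        if n == 0:
            continue
        F = sum((counts.get(c, 0) / n) ** 2 for c in fam)
        class_F.setdefault(len(fam), []).append(F)
    expected = 2.0
    for k, size in ((2, 9), (3, 1), (4, 5), (6, 3)):
        Fs = class_F.get(k)
        expected += size / float(np.mean(Fs))
    assert enc(gene) == pytest.approx(min(expected, 61.0), abs=1e-9)


def test_enc_monotone_under_family_concentration():
    # forcing one family from uniform usage to a single codon lowers ENC
    base = UNIFORM * 5
    concentrated = base.replace("GGA", "GGG").replace("GGC", "GGG") \
                       .replace("GGT", "GGG")
    assert enc(concentrated) < enc(base)


def test_cai_boundaries_and_hand_computation(core_reference):
    # gene of family-maximal codons -> CAI = 1
    best = []
    for aa, fam in FAMILIES.items():
        if len(fam) < 2:
            rel = None
            continue
        rel = core_reference.family_relative(aa)
        best.append(max(fam, key=lambda c: rel[c]))
    assert cai("".join(best) * 3, core_reference) == pytest.approx(1.0)
    # log-domain hand computation on a toy gene
    gene = "AAAAAGGGC"  # Lys Lys Gly
    w = {}
    for aa in ("K", "G"):
        rel = core_reference.family_relative(aa)
        mx = max(rel.values())
        for c in FAMILIES[aa]:
            w[c] = rel[c] / mx
    expected = math.exp((math.log(w["AAA"]) + math.log(w["AAG"])
                         + math.log(w["GGC"])) / 3)
    assert cai(gene, core_reference) == pytest.approx(expected)


def test_cousin_uniform_query_scores_zero(core_reference):
    assert cousin(UNIFORM * 5, core_reference) == pytest.approx(0.0, abs=1e-12)


def test_cousin_reference_identical_query_scores_one(core_reference):
    assert cousin(core_reference.counts, core_reference) == pytest.approx(1.0)


def test_cousin_opposite_bias_is_negative(core_reference):
    worst = []
    for aa, fam in FAMILIES.items():
        if len(fam) < 2:
            continue
        rel = core_reference.family_relative(aa)
        worst.append(min(fam, key=lambda c: rel[c]))
    assert cousin("".join(worst) * 3, core_reference) < 0


def test_cousin_degenerate_reference_raises():
    uniform_ref = profile_table(np.full(61, 1 / 61) * 0 + 1 / 61)
    with pytest.raises(CodonUsageError):
        cousin(UNIFORM, uniform_ref)


def test_cousin_converges_to_one_for_reference_resampled_gene(core_reference):
    rng = np.random.default_rng(0)
    p = core_reference.counts / core_reference.counts.sum()
    gene_counts = np.bincount(rng.choice(61, size=100_000, p=p),
                              minlength=61).astype(float)
    assert cousin(gene_counts, core_reference) == pytest.approx(1.0,
                                                                abs=0.02)


@given(st.integers(2, 5))
@settings(max_examples=10, deadline=None, derandomize=True)
def test_cousin_and_cai_invariant_to_gene_duplication(n):
    ref = profile_table(gc_biased_profile(1.2))
    gene = UNIFORM * 2
    assert cousin(gene * n, ref) == pytest.approx(cousin(gene, ref))
    assert cai(gene * n, ref) == pytest.approx(cai(gene, ref))
    assert cai(gene, ref) <= 1.0


def test_length_filter_boundaries():
    genes = {"short": "ATG" * 99, "exact": "ATG" * 100,
             "with_stop": "ATG" * 100 + "TAA"}
    kept = length_filter(genes)
    assert set(kept) == {"exact", "with_stop"}
    assert length_filter({}) == {}
    assert sense_codon_length("ATG" * 100 + "TAA") == 100


def test_residence_trend_boundaries():
    res = np.linspace(0, 0.01, 50)
    const = np.ones(50)
    t = residence_trend(res, const)
    assert t.kendall_tau == pytest.approx(0.0, abs=1e-12) or np.isnan(
        t.kendall_tau)
    assert all(f.slope == pytest.approx(0.0, abs=1e-12)
               for f in t.fits.values())
    increasing = np.arange(50, dtype=float)
    t2 = residence_trend(res, increasing)
    assert t2.kendall_tau == pytest.approx(1.0)


def test_residence_trend_converging_fan_matches_ols_oracle():
    rng = np.random.default_rng(3)
    interval = 0.001
    res, vals = [], []
    for b in range(10):
        lo = -1.0 + 0.1 * b          # minima rising
        hi = 1.5 - 0.1 * b           # maxima falling
        mid = (b + 0.5) * interval
        for _ in range(20):
            res.append(mid + rng.uniform(-4e-4, 4e-4))
            vals.append(rng.uniform(lo, hi))
        res.extend([mid, mid])
        vals.extend([lo, hi])
    t = residence_trend(res, vals, interval=interval)
    assert t.fits["min"].slope > 0
    assert t.fits["max"].slope < 0
    assert t.fits["median"].p > 0.05
    # oracle: closed-form OLS slope on the binned minima
    res = np.asarray(res)
    vals = np.asarray(vals)
    bins = np.floor(res / interval).astype(int)
    x, y = [], []
    for b in sorted(set(bins)):
        x.append((b + 0.5) * interval)
        y.append(vals[bins == b].min())
    x, y = np.asarray(x), np.asarray(y)
    slope = ((x - x.mean()) @ (y - y.mean())) / ((x - x.mean()) ** 2).sum()
    assert t.fits["min"].slope == pytest.approx(slope)


def test_residence_trend_single_interval_has_no_fits():
    with pytest.warns(UserWarning):
        t = residence_trend([1e-5, 2e-5, 3e-5], [0.1, 0.2, 0.3])
    assert t.fits is None
    assert not np.isnan(t.kendall_tau)
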
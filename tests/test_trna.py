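"""tRNA copy-number ASR, pairing rules, permutation test and tAI_abs."""

import math

import numpy as np
import pytest

from conftest import build_tree, exact_rank_p
from hgtcodon.codon import CODON_TO_AA, _CODON_INDEX
from hgtcodon.trna import (PairingRule, TRNAError,
                           WATSON_CRICK, WOBBLE, absolute_adaptiveness,
                           asr_trna_counts, branch_compensation_test,
                           default_pairing_rules, delta_codon_freq,
                           flagged_pairs, node_codon_frequencies,
                           rank_permutation_test, revcomp, tai_abs)

NEWICK = "(((A:0.1,B:0.1)N1:0.1,C:0.2)N2:0.1,(D:0.15,E:0.15)N3:0.15)R;"


def test_pairing_rules_structure():
    rules = default_pairing_rules()
    by_key = {(r.anticodon, r.codon): r for r in rules}
    # Watson-Crick is the exact reverse complement, s = 0
    for r in rules:
        if r.pairing_class == WATSON_CRICK:
            assert r.codon == revcomp(r.anticodon)
            assert r.s == 0.0
        # all pairings stay within the anticodon's amino-acid family
        assert CODON_TO_AA[r.codon] == CODON_TO_AA[revcomp(r.anticodon)]
        assert 0.0 <= r.s <= 1.0
    # canonical wobble: tRNA-Phe-GAA reads TTC (WC) and TTT (wobble)
    assert by_key[("GAA", "TTC")].pairing_class == WATSON_CRICK
    assert by_key[("GAA", "TTT")].pairing_class == WOBBLE
    # U34: tRNA-Lys-TTT reads AAA (WC) and AAG (wobble)
    assert by_key[("TTT", "AAA")].pairing_class == WATSON_CRICK
    assert by_key[("TTT", "AAG")].pairing_class == WOBBLE


def test_absolute_adaptiveness_formula():
    rules = [PairingRule("GAA", "TTC", WATSON_CRICK, 0.0),
             PairingRule("AAA", "TTC", WOBBLE, 0.5)]
    W = absolute_adaptiveness({"GAA": 2}, rules)
    assert W[_CODON_INDEX["TTC"]] == 2.0
    W2 = absolute_adaptiveness({"GAA": 1, "AAA": 3}, rules)
    assert W2[_CODON_INDEX["TTC"]] == pytest.approx(1 + 1.5)
    W3 = absolute_adaptiveness({}, rules)
    assert W3[_CODON_INDEX["TTC"]] == 0.0


def test_tai_abs_geometric_mean():
    counts = np.zeros(61)
    counts[_CODON_INDEX["TTC"]] = 10
    counts[_CODON_INDEX["AAA"]] = 10
    W = np.zeros(61)
    W[_CODON_INDEX["TTC"]] = 1.0
    W[_CODON_INDEX["AAA"]] = 4.0
    val, flagged = tai_abs(counts, W)
    assert val == pytest.approx(2.0)
    assert not flagged
    # uniform W -> that value
    W[:] = 2.0
    assert tai_abs(counts, W)[0] == pytest.approx(2.0)
    # log-domain hand computation on an uneven toy
    counts2 = np.zeros(61)
    counts2[_CODON_INDEX["TTC"]] = 3
    counts2[_CODON_INDEX["AAA"]] = 1
    W2 = np.zeros(61)
    W2[_CODON_INDEX["TTC"]] = 0.5
    W2[_CODON_INDEX["AAA"]] = 3.0
    expected = math.exp((3 * math.log(0.5) + math.log(3.0)) / 4)
    assert tai_abs(counts2, W2)[0] == pytest.approx(expected)


def test_tai_abs_zero_w_replacement_and_error():
    counts = np.zeros(61)
    counts[_CODON_INDEX["TTC"]] = 1
    counts[_CODON_INDEX["AAA"]] = 1
    W = np.zeros(61)
    W[_CODON_INDEX["TTC"]] = 4.0
    W[_CODON_INDEX["GGG"]] = 1.0
    val, flagged = tai_abs(counts, W)
    assert flagged
    geo_bg = math.exp((math.log(4) + math.log(1)) / 2)
    assert val == pytest.approx(math.sqrt(4.0 * geo_bg))
    with pytest.raises(TRNAError):
        tai_abs(counts, np.zeros(61))


def test_asr_trna_constant_counts_no_changes():
    tree = build_tree(NEWICK)
    pools = {t: {"GAA": 2, "TTT": 3} for t in "ABCDE"}
    hist = asr_trna_counts(tree, pools)
    assert hist.changes == []
    assert all(p == {"GAA": 2, "TTT": 3}
               for p in hist.node_pools.values())


def test_asr_trna_clade_gain_on_stem_branch():
    tree = build_tree(NEWICK)
    pools = {t: {"GAA": 2} for t in "ABCDE"}
    for t in ("A", "B"):
        pools[t] = {"GAA": 3}
    hist = asr_trna_counts(tree, pools)
    assert hist.changes == [("N1", "GAA", 1)]


def test_asr_trna_two_state_magnitude_across_path():
    tree = build_tree("((A:0.1,B:0.1)N1:0.1,C:0.3)R;")
    pools = {"A": {"GAA": 4}, "B": {"GAA": 4}, "C": {"GAA": 2}}
    hist = asr_trna_counts(tree, pools)
    total = sum(abs(d) for _, _, d in hist.changes)
    assert total == 2


def test_node_codon_frequencies_and_conservation():
    aaa = np.zeros(61)
    aaa[_CODON_INDEX["AAA"]] = 1000
    ggg = np.zeros(61)
    ggg[_CODON_INDEX["GGG"]] = 9000
    counts = {"core": ggg, "hgt": aaa}
    parent = node_codon_frequencies(counts, ["core"])
    child = node_codon_frequencies(counts, ["core", "hgt"])
    # frequencies sum to 1000/3 per 1000 bases
    assert parent.sum() == pytest.approx(1000 / 3)
    assert child.sum() == pytest.approx(1000 / 3)
    delta = delta_codon_freq(parent, child)
    # direct recount: AAA goes from 0 to 1000/30000 codons per base
    assert delta[_CODON_INDEX["AAA"]] == pytest.approx(
        1000 * 1000 / 30000 - 0.0)
    assert delta.sum() == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(TRNAError):
        node_codon_frequencies(counts, [])


def test_rank_permutation_exact_small_cases():
    keys = [("B", f"c{i}") for i in range(4)]
    deltas = dict(zip(keys, [4.0, 3.0, 2.0, 1.0]))
    top = {keys[0], keys[1]}
    res = rank_permutation_test(deltas, top, n_perm=200_000, seed=0)
    assert res.observed_rank_sum == 3.0
    assert res.p == pytest.approx(1 / 6, abs=0.01)
    bottom = {keys[2], keys[3]}
    res2 = rank_permutation_test(deltas, bottom, n_perm=50_000, seed=0)
    assert res2.p == pytest.approx(1.0, abs=1e-12)


def test_rank_permutation_matches_enumeration_with_ties():
    rng = np.random.default_rng(1)
    values = np.array([2.0, 2.0, 1.0, 0.5, -1.0, -1.0])
    keys = [("B", f"c{i}") for i in range(6)]
    deltas = dict(zip(keys, values))
    for flagged_idx in ([0, 2], [1, 3, 5], [4]):
        flagged = {keys[i] for i in flagged_idx}
        res = rank_permutation_test(deltas, flagged, n_perm=100_000,
                                    seed=rng)
        exact = exact_rank_p(values, flagged_idx)
        se = math.sqrt(exact * (1 - exact) / 100_000) + 1e-9
        assert abs(res.p - exact) <= max(3 * se, 0.005)


def test_rank_permutation_empty_flagged_raises():
    with pytest.raises(TRNAError):
        rank_permutation_test({("B", "AAA"): 1.0}, set())


def test_pairing_rules_roundtrip(tmp_path):
    from hgtcodon.trna import read_pairing_rules, write_pairing_rules

    rules = default_pairing_rules()
    write_pairing_rules(rules, tmp_path / "pairing_rules.tsv")
    back = read_pairing_rules(tmp_path / "pairing_rules.tsv")
    assert back == rules


def test_flagged_pairs_respects_class_and_valid_keys():
    rules = default_pairing_rules()
    gains = [("N1", "GAA")]
    wc = flagged_pairs(gains, rules, WATSON_CRICK)
    assert wc == {("N1", "TTC")}
    wob = flagged_pairs(gains, rules, WOBBLE)
    assert wob == {("N1", "TTT")}
    assert flagged_pairs(gains, rules, WOBBLE,
                         valid_keys={("N1", "TTC")}) == set()


def test_branch_compensation_detects_matched_gain():
    rules = default_pairing_rules()
    rng = np.random.default_rng(0)
    # parent already carries one tRNA-Lys-TTT so no codon sits at W = 0
    parent = {"GCC": 2, "GAA": 2, "TTT": 1}
    child = dict(parent, TTT=2)            # +1 copy of tRNA-Lys-TTT -> AAA
    hgt, res = {}, {}
    for i in range(20):
        c = np.zeros(61)
        c[_CODON_INDEX["AAA"]] = 50 + rng.integers(0, 10)   # Lys-rich
        c[_CODON_INDEX["GGC"]] = 10
        hgt[f"h{i}"] = c
        r = np.zeros(61)
        r[_CODON_INDEX["GGC"]] = 50 + rng.integers(0, 10)
        r[_CODON_INDEX["AAA"]] = 2
        res[f"r{i}"] = r
    out = branch_compensation_test("N1", parent, child, hgt, res, rules)
    assert out.tested
    assert out.classification == "hgt_higher"
    assert out.p < 0.05
    assert out.ratio > 1
    # oracle: the rank-sum statistic computed independently
    from scipy.stats import mannwhitneyu

    # identical pools -> all deltas zero -> not tested
    same = branch_compensation_test("N1", parent, parent, hgt, res, rules)
    assert not same.tested
    del mannwhitneyu


def test_branch_compensation_null_calibration():
    rules = default_pairing_rules()
    rng = np.random.default_rng(2)
    parent = {"GCC": 2, "GAA": 2, "TTT": 1}
    child = dict(parent, TTT=2)
    fp = 0
    n = 50
    for _ in range(n):
        groups = []
        for _g in range(2):
            d = {}
            for i in range(15):
                c = np.zeros(61)
                c[_CODON_INDEX["AAA"]] = rng.integers(20, 40)
                c[_CODON_INDEX["GGC"]] = rng.integers(20, 40)
                d[f"g{_g}_{i}"] = c
            groups.append(d)
        out = branch_compensation_test("N1", parent, child,
                                       groups[0], groups[1], rules)
        if out.tested and out.classification != "no_difference":
            fp += 1
    assert fp / n <= 0.10
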
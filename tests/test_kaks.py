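"""NG86 estimator tests against independent enumeration oracles."""

import math
from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famevol.kaks import (
    GENETIC_CODE,
    SENSE_CODONS,
    STOP_CODONS,
    CodonAlignment,
    SaturationError,
    codon_align,
    jukes_cantor,
    mean_ks,
    ng86_codon_differences,
    ng86_pair,
    ng86_site_counts,
    sliding_window_omega,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-derivations)
# ---------------------------------------------------------------------------

def oracle_site_counts(codon):
    s = 0.0
    for pos in range(3):
        muts = [codon[:pos] + b + codon[pos + 1 :] for b in BASES if b != codon[pos]]
        viable = [m for m in muts if m not in STOP_CODONS]
        if viable:
            s += sum(GENETIC_CODE[m] == GENETIC_CODE[codon] for m in viable) / len(viable)
    return s, 3.0 - s


def oracle_differences(c1, c2):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    tallies = []
    blocked = []
    for order in permutations(diff):
        cur, syn, nonsyn, ok = c1, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            if GENETIC_CODE.get(nxt) == GENETIC_CODE.get(cur) and nxt not in STOP_CODONS:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (tallies if ok else blocked).append((syn, nonsyn))
    use = tallies or blocked
    return (
        sum(t[0] for t in use) / len(use),
        sum(t[1] for t in use) / len(use),
    )


# ---------------------------------------------------------------------------
# site counts
# ---------------------------------------------------------------------------

def test_site_counts_examples():
    assert ng86_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
    assert ng86_site_counts("ATG") == (0.0, 3.0)
    assert ng86_site_counts("GGG") == (1.0, 2.0)


def test_site_counts_all_sense_codons_match_oracle():
    for codon in SENSE_CODONS:
        s, n = ng86_site_counts(codon)
        es, en = oracle_site_counts(codon)
        assert s == pytest.approx(es), codon
        assert n == pytest.approx(en), codon
        assert 0 <= s <= 3 and s + n == pytest.approx(3.0)


def test_site_counts_rejects_stop():
    with pytest.raises(ValueError):
        ng86_site_counts("TAA")


# ---------------------------------------------------------------------------
# pathway-averaged differences
# ---------------------------------------------------------------------------

def test_difference_examples():
    assert ng86_codon_differences("TTT", "TTC") == (1.0, 0.0)
    assert ng86_codon_differences("TTT", "GTA") == (0.5, 1.5)
    assert ng86_codon_differences("AAA", "AAA") == (0.0, 0.0)


def test_differences_match_oracle_on_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(300):
        c1, c2 = rng.choice(SENSE_CODONS, size=2)
        sd, nd = ng86_codon_differences(c1, c2)
        esd, end_ = oracle_differences(c1, c2)
        assert sd == pytest.approx(esd), (c1, c2)
        assert nd == pytest.approx(end_), (c1, c2)
        n_diff = sum(a != b for a, b in zip(c1, c2))
        assert sd + nd == pytest.approx(float(n_diff))


# ---------------------------------------------------------------------------
# jukes-cantor
# ---------------------------------------------------------------------------

def test_jukes_cantor_values():
    assert jukes_cantor(0.0) == 0.0
    assert jukes_cantor(0.3) == pytest.approx(0.383119, abs=1e-6)


def test_jukes_cantor_saturation():
    with pytest.raises(SaturationError):
        jukes_cantor(0.75)


@given(st.floats(min_value=0.0, max_value=0.74))
def test_jukes_cantor_monotone(p):
    assert jukes_cantor(p + 0.005) > jukes_cantor(p) if p + 0.005 < 0.75 else True


# ---------------------------------------------------------------------------
# pairwise estimation
# ---------------------------------------------------------------------------

def test_ng86_pair_identical_is_zero():
    r = ng86_pair(CodonAlignment("ATGAAATTT", "ATGAAATTT"))
    assert (r.Sd, r.Nd, r.Ka, r.Ks) == (0.0, 0.0, 0.0, 0.0)
    assert math.isnan(r.omega)


def test_ng86_pair_single_synonymous():
    r = ng86_pair(CodonAlignment("TTT", "TTC"))
    assert (r.Sd, r.Nd) == (1.0, 0.0)
    assert r.Ka == 0.0
    assert math.isnan(r.Ks)  # pS = 3 on a lone codon: saturated, undefined
    longer = ng86_pair(CodonAlignment("TTTAAAGGG", "TTCAAAGGG"))
    assert (longer.Sd, longer.Nd) == (1.0, 0.0)
    assert longer.Ka == 0.0 and longer.Ks > 0


def test_ng86_pair_symmetric():
    rng = np.random.default_rng(5)
    s1 = "".join(rng.choice(SENSE_CODONS, size=40))
    s2 = "".join(rng.choice(SENSE_CODONS, size=40))
    a = ng86_pair(CodonAlignment(s1, s2))
    b = ng86_pair(CodonAlignment(s2, s1))
    assert a == b


def test_omega_infinite_when_only_nonsynonymous():
    # ATG -> CTG is nonsynonymous (M -> L); no synonymous differences
    r = ng86_pair(CodonAlignment("ATGATG", "ATGCTG"))
    assert r.Ks == 0.0 and r.Ka > 0
    assert math.isinf(r.omega)


def test_codon_alignment_validation():
    with pytest.raises(ValueError):
        CodonAlignment("ATG", "ATGA")
    with pytest.raises(ValueError, match="position 2"):
        CodonAlignment("A-G", "ATG")


# ---------------------------------------------------------------------------
# codon_align back-translation
# ---------------------------------------------------------------------------

def test_codon_align_simple():
    ca = codon_align("MK", "MK", "ATGAAA", "ATGAAG")
    assert (ca.seq1, ca.seq2) == ("ATGAAA", "ATGAAG")


def test_codon_align_drops_gap_columns():
    ca = codon_align("M-K", "MLK", "ATGAAA", "ATGCTGAAG")
    assert (ca.seq1, ca.seq2) == ("ATGAAA", "ATGAAG")


def test_codon_align_translation_mismatch():
    with pytest.raises(ValueError, match="residue 2"):
        codon_align("MK", "MK", "ATGCCC", "ATGAAA")


def test_codon_align_tolerates_trailing_stop():
    ca = codon_align("MK", "MK", "ATGAAATAA", "ATGAAG")
    assert ca.n_codons == 2


def test_codon_align_matches_brute_force_on_random_gapped_pair():
    # build 110 alignment columns, 10 carrying a gap in one of the rows
    rng = np.random.default_rng(7)
    n_cols = 110
    gap_cols = sorted(rng.choice(n_cols, size=10, replace=False))
    gap_in_row1 = {c for k, c in enumerate(gap_cols) if k % 2 == 0}
    row1 = []
    row2 = []
    cds1 = []
    cds2 = []
    full_columns = []
    for col in range(n_cols):
        c1 = c2 = None
        if col not in gap_in_row1:
            c1 = rng.choice(SENSE_CODONS)
            cds1.append(c1)
        if col not in (set(gap_cols) - gap_in_row1):
            c2 = rng.choice(SENSE_CODONS)
            cds2.append(c2)
        row1.append(GENETIC_CODE[c1] if c1 else "-")
        row2.append(GENETIC_CODE[c2] if c2 else "-")
        if c1 and c2:
            full_columns.append((c1, c2))
    ca = codon_align("".join(row1), "".join(row2), "".join(cds1), "".join(cds2))
    assert ca.seq1 == "".join(c for c, _ in full_columns)
    assert ca.seq2 == "".join(c for _, c in full_columns)
    assert ca.n_codons == 100


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def _random_pair(rng, n_codons, n_mut=0):
    c1 = list(rng.choice(SENSE_CODONS, size=n_codons))
    return "".join(c1)


def test_window_count_1200_300_50():
    rng = np.random.default_rng(1)
    seq = _random_pair(rng, 400)
    profile = sliding_window_omega(CodonAlignment(seq, seq), 300, 50)
    assert len(profile.windows) == 19
    starts = [w[0] for w in profile.windows]
    assert starts == [1 + 50 * k for k in range(19)]


def test_whole_alignment_window_equals_global():
    rng = np.random.default_rng(2)
    s1 = "".join(rng.choice(SENSE_CODONS, size=150))
    s2 = "".join(rng.choice(SENSE_CODONS, size=150))
    ca = CodonAlignment(s1, s2)
    profile = sliding_window_omega(ca, window_nt=450, step_nt=50)
    assert len(profile.windows) == 1
    assert profile.windows[0][2] == ng86_pair(ca)


def test_constant_pair_windows_have_no_differences():
    rng = np.random.default_rng(3)
    seq = _random_pair(rng, 200)
    profile = sliding_window_omega(CodonAlignment(seq, seq), 300, 50)
    for _, _, r in profile.windows:
        assert r.Sd == 0.0 and r.Nd == 0.0


def test_elevated_nterminal_window():
    # plant nonsynonymous changes only in the first 300 nt
    rng = np.random.default_rng(4)
    codons = list(rng.choice(SENSE_CODONS, size=400))
    other = list(codons)
    changed = 0
    i = 0
    while changed < 12 and i < 100:
        c = other[i]
        for b in BASES:
            mut = b + c[1:]
            if mut not in STOP_CODONS and mut != c and GENETIC_CODE[mut] != GENETIC_CODE[c]:
                other[i] = mut
                changed += 1
                break
        i += 1
    ca = CodonAlignment("".join(codons), "".join(other))
    profile = sliding_window_omega(ca, 300, 50)
    nds = [r.Nd for _, _, r in profile.windows]
    assert nds[0] == max(nds) and nds[0] > 0
    assert nds[-1] == 0.0


def test_short_alignment_single_window_with_warning():
    rng = np.random.default_rng(6)
    seq = _random_pair(rng, 50)
    with pytest.warns(UserWarning):
        profile = sliding_window_omega(CodonAlignment(seq, seq), 300, 50)
    assert len(profile.windows) == 1


# ---------------------------------------------------------------------------
# mean Ks
# ---------------------------------------------------------------------------

def test_mean_ks_discards_saturated():
    assert mean_ks([0.21, 0.25, 2.5]) == pytest.approx(0.23)


def test_mean_ks_single_value():
    assert mean_ks([0.2120]) == pytest.approx(0.2120)


def test_mean_ks_empty_after_filter_is_nan():
    assert math.isnan(mean_ks([2.5, 3.0]))
    assert math.isnan(mean_ks([]))


def test_mean_ks_negative_raises():
    with pytest.raises(ValueError):
        mean_ks([-0.1])


def test_mean_ks_recovery_from_simulated_flanks():
    from famevol.simulate import evolve_cds_pair

    rng = np.random.default_rng(9)
    anc = "".join(rng.choice(SENSE_CODONS, size=300))
    values = []
    for s in range(20):
        c1, c2 = evolve_cds_pair(anc, 0.25, 0.2, seed=1000 + s)
        values.append(ng86_pair(CodonAlignment(c1, c2)).Ks)
    assert mean_ks(values) == pytest.approx(0.25, rel=0.10)
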
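"""Unit and oracle tests for the six protein description schemes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinopcm.descriptors import (
    aac_dc_descriptors,
    acc_transform,
    ctd_descriptors,
    describe_set,
    encode_alignment_zscales,
    filter_gap_columns,
    macc1_transform,
    paa_descriptors,
    qso_descriptors,
    so_coupling_numbers,
    so_paa_vector,
)
from kinopcm.sequences import AlignedSequenceSet, ProteinSequence
from kinopcm.tables import (
    AMINO_ACIDS,
    CTD_ATTRIBUTES,
    GRANTHAM_MATRIX,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    SIDE_CHAIN_MASS,
    Z_SCALES,
    standardized_scale,
    zscale_matrix,
)

from conftest import random_sequence

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=30)


# ---------------------------------------------------------------------------
# Embedded tables
# ---------------------------------------------------------------------------

def test_ctd_attribute_classes_partition_alphabet():
    for attr, classes in CTD_ATTRIBUTES.items():
        joined = "".join(classes)
        assert sorted(joined) == sorted(AMINO_ACIDS), attr


def test_grantham_matrix_matches_canonical_anchor_values():
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    # canonical published pair distances (formula reproduces them within
    # rounding of the original table)
    for a, b, want in [("S", "R", 110), ("L", "I", 5), ("R", "K", 26),
                       ("C", "W", 215), ("A", "C", 195)]:
        got = GRANTHAM_MATRIX[idx[a], idx[b]]
        assert abs(got - want) < 2.0, (a, b, got)
    assert np.allclose(np.diag(GRANTHAM_MATRIX), 0.0)
    assert np.allclose(GRANTHAM_MATRIX, GRANTHAM_MATRIX.T)


def test_zscale_table_covers_alphabet():
    assert sorted(Z_SCALES) == sorted(AMINO_ACIDS)
    assert all(len(v) == 5 for v in Z_SCALES.values())


# ---------------------------------------------------------------------------
# ACC / MACC vs brute-force oracles
# ---------------------------------------------------------------------------

def _centered(seq):
    zmat = zscale_matrix()
    v = np.array([zmat[AMINO_ACIDS.index(a)] for a in seq]).T
    return v - v.mean(axis=1, keepdims=True)


def acc_oracle(seq, max_lag):
    """Naive double loop over positions and lags."""
    v = _centered(seq)
    n = len(seq)
    out = []
    for lag in range(1, max_lag + 1):
        for a in range(5):
            for b in range(5):
                s = sum(v[a, i] * v[b, i + lag] for i in range(n - lag))
                out.append(s / (n - lag))
    return np.array(out)


def macc_oracle(seq, max_lag):
    """Exhaustive enumeration over every (i, lag) residue pair."""
    v = _centered(seq)
    n = len(seq)
    out = []
    for lag in range(1, max_lag + 1):
        for a in range(5):
            for b in range(5):
                pp = [v[a, i] * v[b, i + lag] for i in range(n - lag)
                      if v[a, i] > 0 and v[b, i + lag] > 0]
                nn = [v[a, i] * v[b, i + lag] for i in range(n - lag)
                      if v[a, i] < 0 and v[b, i + lag] < 0]
                pn = [v[a, i] * v[b, i + lag] for i in range(n - lag)
                      if v[a, i] > 0 and v[b, i + lag] < 0]
                np_ = [v[a, i] * v[b, i + lag] for i in range(n - lag)
                       if v[a, i] < 0 and v[b, i + lag] > 0]
                out += [max(pp) if pp else 0.0, max(nn) if nn else 0.0,
                        min(pn) if pn else 0.0, min(np_) if np_ else 0.0]
    return np.array(out)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seq=seq_strategy)
def test_acc_equals_bruteforce_oracle(seq):
    max_lag = min(5, len(seq) - 1)
    assert np.allclose(acc_transform(seq, max_lag), acc_oracle(seq, max_lag),
                       atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seq=seq_strategy)
def test_macc_equals_exhaustive_enumeration(seq):
    max_lag = min(4, len(seq) - 1)
    assert np.allclose(macc1_transform(seq, max_lag), macc_oracle(seq, max_lag),
                       atol=1e-12)


def test_acc_widths_and_homopolymer():
    seq = random_sequence(np.random.default_rng(0), 120)
    assert acc_transform(seq, 50).shape == (1250,)
    assert macc1_transform(seq, 50).shape == (5000,)
    # per-sequence centering annihilates a constant sequence
    assert np.allclose(acc_transform("A" * 60, 10), 0.0)


def test_acc_dipeptide_single_term():
    # lag-1 term of a dipeptide is one product of centered z-values
    v = _centered("AR")
    got = acc_transform("AR", 1)
    want = np.array([v[a, 0] * v[b, 1] for a in range(5) for b in range(5)])
    assert np.allclose(got, want)


def test_macc_terms_attained_or_zero():
    seq = random_sequence(np.random.default_rng(3), 40)
    vals, arg = macc1_transform(seq, 5, return_argmax=True)
    assert np.all((vals != 0) == (arg >= 0))


def test_macc_sign_pattern_absent_gives_zero():
    # z4 of "DE" is negative for both residues: (+,+) z4xz4 term must be 0
    vals = macc1_transform("DEDEDE", 1)
    # index: lag 1 -> base 0; pair (z4,z4) = (3,3) -> slot (3*5+3)*4 + pattern
    base = (3 * 5 + 3) * 4
    v = _centered("DEDEDE")
    if (v[3] > 0).sum() == 0:
        assert vals[base + 0] == 0.0  # (+,+) unattainable


def test_sequence_too_short_errors():
    with pytest.raises(ValueError, match="sequence_too_short"):
        acc_transform("ACDEF", 10)
    with pytest.raises(ValueError, match="sequence_too_short"):
        so_coupling_numbers("ACDEF", "grantham", 30)


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

def test_ctd_hand_computed_homopolymer():
    vec = ctd_descriptors("RRRR")
    # hydrophobicity (first attribute): R is class 1
    assert np.allclose(vec[0:3], [1.0, 0.0, 0.0])
    # all transitions zero
    assert np.allclose(vec[21:42], 0.0)
    # hydrophobicity distribution for class 1: quintuple over positions 1..4
    dist = vec[42:47]
    assert np.allclose(dist, [1 / 4, 1 / 4, 2 / 4, 3 / 4, 4 / 4])


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seq=seq_strategy)
def test_ctd_invariants(seq):
    vec = ctd_descriptors(seq)
    assert vec.shape == (147,)
    comp = vec[:21].reshape(7, 3)
    assert np.allclose(comp.sum(axis=1), 1.0)
    dist = vec[42:].reshape(7, 3, 5)
    assert np.all(dist >= 0.0) and np.all(dist <= 1.0)
    # each quintuple non-decreasing
    assert np.all(np.diff(dist, axis=2) >= -1e-12)


# ---------------------------------------------------------------------------
# SO-PAA
# ---------------------------------------------------------------------------

def test_coupling_numbers_hand_sum():
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    tau = so_coupling_numbers("ACD", "grantham", d_max=1)
    want = (GRANTHAM_MATRIX[idx["A"], idx["C"]] ** 2
            + GRANTHAM_MATRIX[idx["C"], idx["D"]] ** 2)
    assert np.isclose(tau[0], want)


def test_coupling_numbers_homopolymer_zero():
    assert np.allclose(so_coupling_numbers("A" * 40, "grantham"), 0.0)
    assert np.allclose(so_coupling_numbers("A" * 40, "schneider_wrede"), 0.0)


def test_qso_sums_to_one_and_homopolymer_limit(rng):
    seq = random_sequence(rng, 50)
    for mat in ("grantham", "schneider_wrede"):
        assert np.isclose(qso_descriptors(seq, mat).sum(), 1.0)
    qso = qso_descriptors("A" * 40, "grantham")
    f = np.zeros(20)
    f[AMINO_ACIDS.index("A")] = 1.0
    assert np.allclose(qso[:20], f)
    assert np.allclose(qso[20:], 0.0)


def paa_oracle(seq, lam=5, w=0.05):
    """Independent direct summation of the type-1 construction."""
    h1 = standardized_scale(HYDROPHOBICITY)
    h2 = standardized_scale(HYDROPHILICITY)
    m = standardized_scale(SIDE_CHAIN_MASS)
    n = len(seq)
    idx = [AMINO_ACIDS.index(a) for a in seq]
    theta = []
    for d in range(1, lam + 1):
        acc = 0.0
        for i in range(n - d):
            a, b = idx[i], idx[i + d]
            acc += ((h1[a] - h1[b]) ** 2 + (h2[a] - h2[b]) ** 2
                    + (m[a] - m[b]) ** 2) / 3.0
        theta.append(acc / (n - d))
    f = [idx.count(j) / n for j in range(20)]
    den = sum(f) + w * sum(theta)
    return np.array([v / den for v in f] + [w * t / den for t in theta])


def test_paa_matches_independent_oracle(rng):
    seq = random_sequence(rng, 40)
    assert np.allclose(paa_descriptors(seq, lam=5), paa_oracle(seq, lam=5),
                       atol=1e-12)


def test_paa_width_and_homopolymer():
    seq = random_sequence(np.random.default_rng(5), 45)
    assert paa_descriptors(seq).shape == (50,)
    vec = paa_descriptors("A" * 40)
    assert np.allclose(vec[20:], 0.0)


def test_so_paa_block_width():
    seq = random_sequence(np.random.default_rng(6), 60)
    assert so_paa_vector(seq).shape == (210,)


# ---------------------------------------------------------------------------
# AAC-DC
# ---------------------------------------------------------------------------

def test_aac_dc_examples():
    vec = aac_dc_descriptors("AAAA")
    assert vec[AMINO_ACIDS.index("A")] == 1.0
    assert vec[20 + 0] == 1.0  # dipeptide AA (A is first alphabetically)
    assert vec.shape == (420,)
    vec = aac_dc_descriptors("ARA")
    ia, ir = AMINO_ACIDS.index("A"), AMINO_ACIDS.index("R")
    assert vec[20 + ia * 20 + ir] == 0.5  # AR
    assert vec[20 + ir * 20 + ia] == 0.5  # RA


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seq=seq_strategy)
def test_aac_invariant_under_shuffle_dc_generally_not(seq):
    rng = np.random.default_rng(0)
    shuffled = "".join(rng.permutation(list(seq)))
    v1, v2 = aac_dc_descriptors(seq), aac_dc_descriptors(shuffled)
    assert np.allclose(v1[:20], v2[:20])
    assert np.isclose(v1[:20].sum(), 1.0) and np.isclose(v1[20:].sum(), 1.0)


# ---------------------------------------------------------------------------
# Alignment-based encoding
# ---------------------------------------------------------------------------

def _msa(rows):
    return AlignedSequenceSet(
        sequences=[ProteinSequence(f"s{i}", r) for i, r in enumerate(rows)]
    )


def test_gap_filter_strictly_more_than_threshold():
    msa = _msa(["A-CD", "A-CD", "AAC-", "A-CD"])
    out = filter_gap_columns(msa, 0.5)
    # column 2 has 3/4 gaps -> removed; column 4 has 1/4 -> kept
    assert out.n_positions == 3
    assert out.column_origin == [0, 2, 3]
    # exactly 50% gaps is retained
    msa2 = _msa(["A-", "AC", "A-", "AC"])
    assert filter_gap_columns(msa2, 0.5).n_positions == 2
    # gap-free is identity
    msa3 = _msa(["ACD", "CDE"])
    assert filter_gap_columns(msa3).n_positions == 3


def test_ragged_alignment_rejected():
    with pytest.raises(ValueError, match="ragged"):
        _msa(["ACD", "AC"])


def test_aligned_z_encoding_values_and_width():
    block = encode_alignment_zscales(_msa(["AAA"]))
    assert block.n_descriptors == 15
    row = block.values()[0].reshape(3, 5)
    for pos in range(3):
        assert np.allclose(row[pos], Z_SCALES["A"])
    block = encode_alignment_zscales(_msa(["A-C", "ACC"]))
    assert np.allclose(block.values()[0].reshape(3, 5)[1], 0.0)  # gap -> zeros


def test_aligned_z_unknown_residue_named():
    with pytest.raises(ValueError, match="unknown_residue"):
        encode_alignment_zscales(_msa(["AXC"]))


def test_describe_set_widths_and_permutation_covariance(small_panel):
    seqs = small_panel.sequences[:6]
    block = describe_set(seqs, "ctd")
    perm = [3, 1, 5, 0, 2, 4]
    block_perm = describe_set([seqs[i] for i in perm], "ctd")
    assert np.allclose(block.values()[perm], block_perm.values())
    assert block_perm.entity_ids == [seqs[i].id for i in perm]
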
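"""Protein-sequence description schemes for proteochemometric modelling.

Six schemes, all returning rows of a uniform :class:`~kinopcm.blocks.DescriptorBlock`:

``aligned_z``
    z-scale encoding of the columns of a gap-filtered multiple sequence
    alignment (alignment-based; 5 descriptors per retained position).
``acc``
    auto- and cross-covariances of the five z-scales over lags 1..L
    (alignment-free; L x 25 terms).
``macc``
    sign-resolved maxima of the lagged z-scale products (MACC1 variant;
    4 x L x 25 terms, each traceable to one residue pair).
``ctd``
    composition / transition / distribution of seven physico-chemical
    attributes, three classes each (147 terms).
``so_paa``
    sequence-order coupling numbers for two residue-distance matrices (60),
    quasi-sequence-order descriptors (100) and type-1 pseudo-amino-acid
    descriptors (50): 210 terms.
``aac_dc``
    amino-acid and dipeptide composition (20 + 400 terms).

Sequence-level functions return 1-D vectors with frozen, documented ordering;
``*_block`` builders stack them for a sequence set, and :func:`describe_set`
dispatches on the method name.
"""

from __future__ import annotations

import itertools
from typing import Sequence

import numpy as np
import pandas as pd

from .blocks import DescriptorBlock
from .sequences import AlignedSequenceSet, ProteinSequence
from .tables import (
    AMINO_ACIDS,
    CTD_ATTRIBUTES,
    GAP_CHARACTER,
    HYDROPHILICITY,
    HYDROPHOBICITY,
    N_Z_SCALES,
    RESIDUE_DISTANCE_MATRICES,
    SIDE_CHAIN_MASS,
    ctd_class_of,
    residue_index,
    standardized_scale,
    zscale_matrix,
)

KINASE_METHODS = ("aligned_z", "acc", "macc", "ctd", "so_paa", "aac_dc")

_ZMAT = zscale_matrix()  # (20, 5)


# ---------------------------------------------------------------------------
# Alignment-based z-scale description
# ---------------------------------------------------------------------------

def filter_gap_columns(
    msa: AlignedSequenceSet, max_gap_fraction: float = 0.5
) -> AlignedSequenceSet:
    """Drop alignment columns whose gap fraction exceeds ``max_gap_fraction``.

    The threshold is strict (a column with exactly the threshold fraction of
    gaps is retained).  Column provenance is composed into ``column_origin``.
    """
    if not msa.sequences:
        return msa
    rows = np.array([list(s.sequence) for s in msa.sequences])
    gap_frac = (rows == GAP_CHARACTER).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    new_seqs = [
        ProteinSequence(s.id, "".join(rows[i, keep]), s.group)
        for i, s in enumerate(msa.sequences)
    ]
    origin = [msa.column_origin[j] for j in keep]
    return AlignedSequenceSet(sequences=new_seqs, column_origin=origin)


def encode_alignment_zscales(msa: AlignedSequenceSet) -> DescriptorBlock:
    """Encode every alignment column by the five z-scales.

    Gap positions encode as the zero vector: z-scales are mean-centered over
    the amino-acid alphabet, so zero reads as "average residue".  Width is
    n_positions x 5; names are ``p<position>_z<scale>`` with 1-based position
    in the filtered alignment.
    """
    n_pos = msa.n_positions
    names = [f"p{p + 1}_z{z + 1}" for p in range(n_pos) for z in range(N_Z_SCALES)]
    mat = np.zeros((len(msa), n_pos * N_Z_SCALES))
    for i, s in enumerate(msa.sequences):
        s.validate(allow_gaps=True)
        for p, aa in enumerate(s.sequence):
            if aa != GAP_CHARACTER:
                mat[i, p * N_Z_SCALES:(p + 1) * N_Z_SCALES] = _ZMAT[
                    AMINO_ACIDS.index(aa)
                ]
    df = pd.DataFrame(mat, index=[s.id for s in msa.sequences], columns=names)
    return DescriptorBlock(data=df, tag="aligned_z",
                           meta={"column_origin": list(msa.column_origin)})


# ---------------------------------------------------------------------------
# ACC / MACC transforms
# ---------------------------------------------------------------------------

def _centered_zvalues(seq: str) -> np.ndarray:
    """Per-sequence mean-centered z-scale values, shape (5, N)."""
    idx = residue_index(seq)
    v = _ZMAT[idx].T  # (5, N)
    return v - v.mean(axis=1, keepdims=True)


def acc_names(max_lag: int) -> list[str]:
    return [
        f"acc_lag{lag}_z{a + 1}z{b + 1}"
        for lag in range(1, max_lag + 1)
        for a in range(N_Z_SCALES)
        for b in range(N_Z_SCALES)
    ]


def acc_transform(seq: str, max_lag: int = 50) -> np.ndarray:
    """Auto/cross-covariances of z-scales over lags 1..max_lag.

    Term (lag, z_a, z_b) = sum_i V[a,i] V[b,i+lag] / (N - lag) on per-sequence
    centered z-values.  Ordering is lag-major, (z_a, z_b) row-major minor;
    length is max_lag x 25.
    """
    n = len(seq)
    if n <= max_lag:
        raise ValueError(f"sequence_too_short: length {n} <= max_lag {max_lag}")
    v = _centered_zvalues(seq)
    out = np.empty(max_lag * N_Z_SCALES * N_Z_SCALES)
    for lag in range(1, max_lag + 1):
        x, y = v[:, : n - lag], v[:, lag:]
        out[(lag - 1) * 25: lag * 25] = (x @ y.T).ravel() / (n - lag)
    return out


_MACC_PATTERNS = ("pp", "nn", "pn", "np")


def macc_names(max_lag: int) -> list[str]:
    return [
        f"macc_lag{lag}_z{a + 1}z{b + 1}_{pat}"
        for lag in range(1, max_lag + 1)
        for a in range(N_Z_SCALES)
        for b in range(N_Z_SCALES)
        for pat in _MACC_PATTERNS
    ]


def macc1_transform(
    seq: str, max_lag: int = 50, return_argmax: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """MACC1: sign-resolved extreme lagged products of z-scale values.

    For each (lag, z_a, z_b) four terms are kept, one per sign pattern of the
    centered values at the two positions: (+,+) and (-,-) take the largest
    positive product, (+,-) and (-,+) the most negative product (maximum
    magnitude with its natural sign).  A term with no qualifying residue pair
    is 0.  With ``return_argmax`` the attaining position i of each term is
    returned as well (-1 where the term is 0).
    """
    n = len(seq)
    if n <= max_lag:
        raise ValueError(f"sequence_too_short: length {n} <= max_lag {max_lag}")
    v = _centered_zvalues(seq)
    n_terms = max_lag * 25 * 4
    out = np.zeros(n_terms)
    arg = np.full(n_terms, -1, dtype=int)
    for lag in range(1, max_lag + 1):
        x, y = v[:, : n - lag], v[:, lag:]
        prod = x[:, None, :] * y[None, :, :]          # (5, 5, N-lag)
        px, nx = x > 0, x < 0
        py, ny = y > 0, y < 0
        masks = (
            px[:, None, :] & py[None, :, :],
            nx[:, None, :] & ny[None, :, :],
            px[:, None, :] & ny[None, :, :],
            nx[:, None, :] & py[None, :, :],
        )
        base = (lag - 1) * 100
        for q, mask in enumerate(masks):
            if q < 2:  # products positive inside the quadrant: take max
                masked = np.where(mask, prod, -np.inf)
                best = masked.max(axis=2)
                ibest = masked.argmax(axis=2)
            else:      # products negative: most negative = max magnitude
                masked = np.where(mask, prod, np.inf)
                best = masked.min(axis=2)
                ibest = masked.argmin(axis=2)
            have = mask.any(axis=2)
            vals = np.where(have, best, 0.0)
            slot = base + np.arange(25).reshape(5, 5) * 4 + q
            out[slot.ravel()] = vals.ravel()
            arg[slot.ravel()] = np.where(have, ibest, -1).ravel()
    if return_argmax:
        return out, arg
    return out


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

_CTD_PAIRS = ((1, 2), (1, 3), (2, 3))
_CTD_QUANTILES = ("p0", "p25", "p50", "p75", "p100")


def ctd_names() -> list[str]:
    names = []
    for attr in CTD_ATTRIBUTES:
        names += [f"{attr}_comp_c{c}" for c in (1, 2, 3)]
    for attr in CTD_ATTRIBUTES:
        names += [f"{attr}_trans_{a}{b}" for a, b in _CTD_PAIRS]
    for attr in CTD_ATTRIBUTES:
        for c in (1, 2, 3):
            names += [f"{attr}_dist_c{c}_{q}" for q in _CTD_QUANTILES]
    return names


def ctd_descriptors(seq: str) -> np.ndarray:
    """Composition (21), transition (21) and distribution (105) descriptors.

    Composition: class fraction per attribute.  Transition: adjacent pairs
    crossing each unordered class pair, divided by N-1.  Distribution: 1-based
    positions of the first, ceil(25%)-th, ceil(50%)-th, ceil(75%)-th and last
    residue of each class, each divided by N (all five 0 for an absent class).
    """
    n = len(seq)
    if n < 2:
        raise ValueError("sequence too short for CTD (need N >= 2)")
    residue_index(seq)  # validates alphabet
    comp, trans, dist = [], [], []
    for attr in CTD_ATTRIBUTES:
        cls_map = ctd_class_of(attr)
        classes = np.array([cls_map[aa] for aa in seq])
        for c in (1, 2, 3):
            comp.append(float((classes == c).mean()))
    for attr in CTD_ATTRIBUTES:
        cls_map = ctd_class_of(attr)
        classes = np.array([cls_map[aa] for aa in seq])
        a, b = classes[:-1], classes[1:]
        for c1, c2 in _CTD_PAIRS:
            count = np.sum(((a == c1) & (b == c2)) | ((a == c2) & (b == c1)))
            trans.append(float(count) / (n - 1))
    for attr in CTD_ATTRIBUTES:
        cls_map = ctd_class_of(attr)
        classes = np.array([cls_map[aa] for aa in seq])
        for c in (1, 2, 3):
            pos = np.flatnonzero(classes == c) + 1  # 1-based
            if pos.size == 0:
                dist += [0.0] * 5
                continue
            m = pos.size
            picks = [1,
                     int(np.ceil(0.25 * m)),
                     int(np.ceil(0.50 * m)),
                     int(np.ceil(0.75 * m)),
                     m]
            dist += [float(pos[max(p, 1) - 1]) / n for p in picks]
    return np.array(comp + trans + dist)


# ---------------------------------------------------------------------------
# Sequence-order / quasi-sequence-order / pseudo-amino-acid (SO-PAA)
# ---------------------------------------------------------------------------

def so_coupling_numbers(
    seq: str, matrix: str = "schneider_wrede", d_max: int = 30
) -> np.ndarray:
    """Sequence-order coupling numbers tau_d, d = 1..d_max.

    tau_d = sum over i of dist(s_i, s_{i+d})^2 for the named residue-distance
    matrix ("schneider_wrede" or "grantham").
    """
    n = len(seq)
    if n <= d_max:
        raise ValueError(f"sequence_too_short: length {n} <= d_max {d_max}")
    dm = RESIDUE_DISTANCE_MATRICES[matrix]
    idx = residue_index(seq)
    out = np.empty(d_max)
    for d in range(1, d_max + 1):
        out[d - 1] = float(np.sum(dm[idx[: n - d], idx[d:]] ** 2))
    return out


def qso_descriptors(
    seq: str, matrix: str = "schneider_wrede", d_max: int = 30, w: float = 0.1
) -> np.ndarray:
    """Quasi-sequence-order descriptors (Chou construction), 20 + d_max values.

    First 20: X_a = f_a / (1 + w sum_d tau_d) with f_a the normalized residue
    frequency; remaining d_max: X_{20+d} = w tau_d / (same denominator).  All
    values for one matrix sum to 1.
    """
    idx = residue_index(seq)
    tau = so_coupling_numbers(seq, matrix=matrix, d_max=d_max)
    f = np.bincount(idx, minlength=20).astype(float) / len(seq)
    den = f.sum() + w * tau.sum()
    return np.concatenate([f / den, w * tau / den])


def _paa_theta(seq: str, lam: int) -> np.ndarray:
    h1 = standardized_scale(HYDROPHOBICITY)
    h2 = standardized_scale(HYDROPHILICITY)
    m = standardized_scale(SIDE_CHAIN_MASS)
    idx = residue_index(seq)
    n = len(seq)
    theta = np.empty(lam)
    for d in range(1, lam + 1):
        a, b = idx[: n - d], idx[d:]
        corr = (
            (h1[a] - h1[b]) ** 2 + (h2[a] - h2[b]) ** 2 + (m[a] - m[b]) ** 2
        ) / 3.0
        theta[d - 1] = corr.mean()
    return theta


def paa_descriptors(seq: str, lam: int = 30, w_paa: float = 0.05) -> np.ndarray:
    """Type-1 pseudo-amino-acid descriptors: 20 composition + lam correlation.

    Correlation factor theta_d averages the squared differences of
    standardized hydrophobicity, hydrophilicity and side-chain mass between
    residues d apart; all 20 + lam values share one normalizing denominator.
    """
    n = len(seq)
    if n <= lam:
        raise ValueError(f"sequence_too_short: length {n} <= lambda {lam}")
    idx = residue_index(seq)
    theta = _paa_theta(seq, lam)
    f = np.bincount(idx, minlength=20).astype(float) / n
    den = f.sum() + w_paa * theta.sum()
    return np.concatenate([f / den, w_paa * theta / den])


def so_paa_names(d_max: int = 30, lam: int = 30) -> list[str]:
    names = []
    for mat in ("schneider_wrede", "grantham"):
        names += [f"tau_{mat}_d{d}" for d in range(1, d_max + 1)]
    for mat in ("schneider_wrede", "grantham"):
        names += [f"qso_{mat}_{aa}" for aa in AMINO_ACIDS]
        names += [f"qso_{mat}_d{d}" for d in range(1, d_max + 1)]
    names += [f"paa_{aa}" for aa in AMINO_ACIDS]
    names += [f"paa_d{d}" for d in range(1, lam + 1)]
    return names


def so_paa_vector(seq: str, d_max: int = 30, lam: int = 30,
                  w: float = 0.1, w_paa: float = 0.05) -> np.ndarray:
    """Full SO-PAA description: 2 x d_max coupling numbers, 2 x (20 + d_max)
    quasi-sequence-order values, 20 + lam pseudo-amino-acid values (210 for
    the defaults)."""
    parts = [so_coupling_numbers(seq, m, d_max) for m in ("schneider_wrede", "grantham")]
    parts += [qso_descriptors(seq, m, d_max, w) for m in ("schneider_wrede", "grantham")]
    parts.append(paa_descriptors(seq, lam, w_paa))
    return np.concatenate(parts)


# ---------------------------------------------------------------------------
# AAC-DC
# ---------------------------------------------------------------------------

def aac_dc_names() -> list[str]:
    return [f"aac_{aa}" for aa in AMINO_ACIDS] + [
        f"dc_{a}{b}" for a, b in itertools.product(AMINO_ACIDS, repeat=2)
    ]


def aac_dc_descriptors(seq: str) -> np.ndarray:
    """20 amino-acid fractions followed by 400 dipeptide fractions
    (alphabetical ordering; each group sums to 1)."""
    n = len(seq)
    if n < 2:
        raise ValueError("sequence too short for dipeptide composition (N >= 2)")
    idx = residue_index(seq)
    aac = np.bincount(idx, minlength=20).astype(float) / n
    pair_idx = idx[:-1] * 20 + idx[1:]
    dc = np.bincount(pair_idx, minlength=400).astype(float) / (n - 1)
    return np.concatenate([aac, dc])


# ---------------------------------------------------------------------------
# Block builders
# ---------------------------------------------------------------------------

def _stack(seqs: Sequence[ProteinSequence], fn, names: list[str], tag: str,
           **meta) -> DescriptorBlock:
    mat = np.vstack([fn(s.sequence) for s in seqs])
    df = pd.DataFrame(mat, index=[s.id for s in seqs], columns=names)
    return DescriptorBlock(data=df, tag=tag, meta=dict(meta))


def describe_set(
    sequences: Sequence[ProteinSequence] | AlignedSequenceSet,
    method: str,
    max_lag: int = 50,
    max_gap_fraction: float = 0.5,
) -> DescriptorBlock:
    """Compute one description scheme for a sequence set.

    ``aligned_z`` expects an :class:`AlignedSequenceSet` (gap filtering is
    applied here); the alignment-free methods accept either container and use
    ungapped sequences.
    """
    if method not in KINASE_METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {KINASE_METHODS}")
    if method == "aligned_z":
        if not isinstance(sequences, AlignedSequenceSet):
            raise ValueError("aligned_z needs an AlignedSequenceSet")
        return encode_alignment_zscales(
            filter_gap_columns(sequences, max_gap_fraction)
        )
    if isinstance(sequences, AlignedSequenceSet):
        seqs = [
            ProteinSequence(s.id, s.sequence.replace(GAP_CHARACTER, ""), s.group)
            for s in sequences.sequences
        ]
    else:
        seqs = list(sequences)
    if method == "acc":
        return _stack(seqs, lambda s: acc_transform(s, max_lag),
                      acc_names(max_lag), "acc", max_lag=max_lag)
    if method == "macc":
        return _stack(seqs, lambda s: macc1_transform(s, max_lag),
                      macc_names(max_lag), "macc", max_lag=max_lag)
    if method == "ctd":
        return _stack(seqs, ctd_descriptors, ctd_names(), "ctd")
    if method == "so_paa":
        return _stack(seqs, so_paa_vector, so_paa_names(), "so_paa")
    return _stack(seqs, aac_dc_descriptors, aac_dc_names(), "aac_dc")
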
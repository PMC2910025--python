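"""Embedded amino-acid property tables.

Every numeric description scheme in :mod:`kinopcm.descriptors` draws on one of
the tables below:

* the five z-scales of Sandberg et al. (principal-property scores of amino-acid
  physico-chemistry: z1 ~ hydrophobicity, z2 ~ steric bulk, z3 ~ polarity,
  z4/z5 ~ electronic properties),
* the seven three-class attribute partitions behind composition / transition /
  distribution (CTD) features,
* Grantham's chemical-distance matrix, computed here from his published
  composition / polarity / volume values and weighting constants,
* a physico-chemical residue distance in the role of the Schneider-Wrede
  matrix (see :data:`SCHNEIDER_WREDE_SYNTHETIC`),
* the hydrophobicity / hydrophilicity / side-chain-mass scales used by the
  type-1 pseudo-amino-acid construction.

All tables are keyed by one-letter codes over the 20 standard residues.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""The 20 standard residues, alphabetical by one-letter code."""

GAP_CHARACTER = "-"

# ---------------------------------------------------------------------------
# Sandberg z-scales (z1..z5), one row per residue.
# ---------------------------------------------------------------------------
Z_SCALES: dict[str, tuple[float, float, float, float, float]] = {
    "A": (0.24, -2.32, 0.60, -0.14, 1.30),
    "R": (3.52, 2.50, -3.50, 1.99, -0.17),
    "N": (3.05, 1.62, 1.04, -1.15, 1.61),
    "D": (3.98, 0.93, 1.93, -2.46, 0.75),
    "C": (0.84, -1.67, 3.71, 0.18, -2.65),
    "Q": (1.75, 0.50, -1.44, -1.34, 0.66),
    "E": (3.11, 0.26, -0.11, -3.04, -0.25),
    "G": (2.05, -4.06, 0.36, -0.82, -0.38),
    "H": (2.47, 1.95, 0.26, 3.90, 0.09),
    "I": (-3.89, -1.73, -1.71, -0.84, 0.26),
    "L": (-4.28, -1.30, -1.49, -0.72, 0.84),
    "K": (2.29, 0.89, -2.49, 1.49, 0.31),
    "M": (-2.85, -0.22, 0.47, 1.94, -0.98),
    "F": (-4.22, 1.94, 1.06, 0.54, -0.62),
    "P": (-1.66, 0.27, 1.84, 0.70, 2.00),
    "S": (2.39, -1.07, 1.15, -1.39, 0.67),
    "T": (0.75, -2.18, -1.12, -1.46, -0.40),
    "W": (-4.36, 3.94, 0.59, 3.44, -1.59),
    "Y": (-2.54, 2.44, 0.43, 0.04, -1.47),
    "V": (-2.59, -2.64, -1.54, -0.85, -0.02),
}

N_Z_SCALES = 5


def zscale_matrix() -> np.ndarray:
    """Return the z-scale table as a (20, 5) array in ``AMINO_ACIDS`` order."""
    return np.array([Z_SCALES[a] for a in AMINO_ACIDS], dtype=float)


# ---------------------------------------------------------------------------
# CTD attribute partitions (Dubchak-style / PROFEAT groupings).
# Each attribute splits the alphabet into exactly three disjoint classes.
# ---------------------------------------------------------------------------
CTD_ATTRIBUTES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASCTPD", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}


def ctd_class_of(attribute: str) -> dict[str, int]:
    """Map residue letter -> class index (1, 2 or 3) for one attribute."""
    out: dict[str, int] = {}
    for cls, members in enumerate(CTD_ATTRIBUTES[attribute], start=1):
        for aa in members:
            out[aa] = cls
    return out


# ---------------------------------------------------------------------------
# Grantham (1974) residue properties: composition c, polarity p, volume v.
# Distance d(a,b) = 50.723 * sqrt(1.833 dc^2 + 0.1018 dp^2 + 0.000399 dv^2),
# the scale constant putting the mean pairwise distance near 100.
# ---------------------------------------------------------------------------
GRANTHAM_PROPERTIES: dict[str, tuple[float, float, float]] = {
    "A": (0.00, 8.1, 31.0),
    "R": (0.65, 10.5, 124.0),
    "N": (1.33, 11.6, 56.0),
    "D": (1.38, 13.0, 54.0),
    "C": (2.75, 5.5, 55.0),
    "Q": (0.89, 10.5, 85.0),
    "E": (0.92, 12.3, 83.0),
    "G": (0.74, 9.0, 3.0),
    "H": (0.58, 10.4, 96.0),
    "I": (0.00, 5.2, 111.0),
    "L": (0.00, 4.9, 111.0),
    "K": (0.33, 11.3, 119.0),
    "M": (0.00, 5.7, 105.0),
    "F": (0.00, 5.2, 132.0),
    "P": (0.39, 8.0, 32.5),
    "S": (1.42, 9.2, 32.0),
    "T": (0.71, 8.6, 61.0),
    "W": (0.13, 5.4, 170.0),
    "Y": (0.20, 6.2, 136.0),
    "V": (0.00, 5.9, 84.0),
}

_GRANTHAM_ALPHA = 1.833
_GRANTHAM_BETA = 0.1018
_GRANTHAM_GAMMA = 0.000399
_GRANTHAM_SCALE = 50.723


def _grantham_matrix() -> np.ndarray:
    props = np.array([GRANTHAM_PROPERTIES[a] for a in AMINO_ACIDS])
    c, p, v = props[:, 0], props[:, 1], props[:, 2]
    d2 = (
        _GRANTHAM_ALPHA * (c[:, None] - c[None, :]) ** 2
        + _GRANTHAM_BETA * (p[:, None] - p[None, :]) ** 2
        + _GRANTHAM_GAMMA * (v[:, None] - v[None, :]) ** 2
    )
    return _GRANTHAM_SCALE * np.sqrt(d2)


GRANTHAM_MATRIX: np.ndarray = _grantham_matrix()
"""(20, 20) Grantham chemical distances in ``AMINO_ACIDS`` order."""


# ---------------------------------------------------------------------------
# Property scales for the type-1 pseudo-amino-acid construction:
# hydrophobicity (Tanford-style), hydrophilicity (Hopp-Woods) and
# side-chain mass.  Standardized before use.
# ---------------------------------------------------------------------------
HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}

SIDE_CHAIN_MASS: dict[str, float] = {
    "A": 15.0, "R": 101.0, "N": 58.0, "D": 59.0, "C": 47.0,
    "Q": 72.0, "E": 73.0, "G": 1.0, "H": 82.0, "I": 57.0,
    "L": 57.0, "K": 73.0, "M": 75.0, "F": 91.0, "P": 42.0,
    "S": 31.0, "T": 45.0, "W": 130.0, "Y": 107.0, "V": 43.0,
}


def standardized_scale(scale: dict[str, float]) -> np.ndarray:
    """Standardize a 20-residue property scale (mean 0, population sd 1)."""
    x = np.array([scale[a] for a in AMINO_ACIDS], dtype=float)
    return (x - x.mean()) / x.std()


def _schneider_wrede_synthetic() -> np.ndarray:
    # Synthetic stand-in: the original Schneider-Wrede physico-chemical
    # distance table is not bundled; this matrix is constructed from the
    # standardized hydrophobicity, hydrophilicity and side-chain-mass scales
    # (Euclidean distance, max-normalized to 1), which follows the same
    # physico-chemical-distance recipe and is symmetric with zero diagonal.
    h1 = standardized_scale(HYDROPHOBICITY)
    h2 = standardized_scale(HYDROPHILICITY)
    m = standardized_scale(SIDE_CHAIN_MASS)
    d2 = (
        (h1[:, None] - h1[None, :]) ** 2
        + (h2[:, None] - h2[None, :]) ** 2
        + (m[:, None] - m[None, :]) ** 2
    )
    d = np.sqrt(d2)
    return d / d.max()


SCHNEIDER_WREDE_SYNTHETIC: np.ndarray = _schneider_wrede_synthetic()
"""(20, 20) synthetic physico-chemical distance matrix.

Plays the role of the Schneider-Wrede matrix in the sequence-order coupling
numbers; synthetic reconstruction, see :func:`_schneider_wrede_synthetic`.
"""

RESIDUE_DISTANCE_MATRICES: dict[str, np.ndarray] = {
    "schneider_wrede": SCHNEIDER_WREDE_SYNTHETIC,
    "grantham": GRANTHAM_MATRIX,
}


def residue_index(seq: str) -> np.ndarray:
    """Encode a residue string as indices into ``AMINO_ACIDS``.

    Raises ``ValueError('unknown_residue: ...')`` on the first letter outside
    the 20-letter alphabet.
    """
    idx = np.empty(len(seq), dtype=np.intp)
    for i, aa in enumerate(seq):
        pos = AMINO_ACIDS.find(aa)
        if pos < 0:
            raise ValueError(f"unknown_residue: {aa!r} at position {i}")
        idx[i] = pos
    return idx
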
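"""Scaling, block weighting, PCA compression and cross-term construction.

The modelling design matrix has one row per kinase-inhibitor pair and is the
concatenation of (i) the inhibitor descriptor block, (ii) the kinase
descriptor block and optionally (iii) a cross-term block of element-wise
products of ligand and kinase principal-component scores, which lets a linear
model express the bilinear selectivity part of the interaction.

Scaling conventions: every descriptor is mean-centered and scaled to unit
variance ("autoscaling"); each block is then weighted by 1/sqrt(width) so the
blocks contribute equal total variance; cross-term columns are Pareto-scaled
(divided by the square root of their standard deviation).  All states are
fitted on training entities only and applied unchanged to held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .activity import ActivityMatrix
from .blocks import DescriptorBlock

# ---------------------------------------------------------------------------
# Autoscaling and block scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingState:
    """Per-descriptor mean/sd learned from training data."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray


def autoscale(
    block: DescriptorBlock, state: ScalingState | None = None
) -> tuple[DescriptorBlock, ScalingState]:
    """Mean-center and scale each descriptor to unit variance.

    In training mode (no ``state``) zero-variance columns are dropped with a
    warning and the fitted state is returned; in apply mode the stored state
    is used unchanged (descriptor names must match).
    """
    df = block.data
    if state is None:
        x = df.to_numpy(dtype=float)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1) if x.shape[0] > 1 else np.zeros(x.shape[1])
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance descriptor(s) "
                f"from block {block.tag!r}"
            )
        names = [c for c, k in zip(df.columns, keep) if k]
        state = ScalingState(names=names, mean=mean[keep], sd=sd[keep])
    else:
        missing = [c for c in state.names if c not in df.columns]
        if missing:
            raise ValueError(f"descriptor names missing in apply mode: {missing[:5]}")
    x = df[state.names].to_numpy(dtype=float)
    scaled = (x - state.mean) / state.sd
    out = replace(
        block,
        data=pd.DataFrame(scaled, index=df.index, columns=state.names),
        scaled=True,
        block_weight=1.0,
    )
    return out, state


def block_scale(blocks: list[DescriptorBlock]) -> list[DescriptorBlock]:
    """Weight each autoscaled block by 1/sqrt(width) so its descriptor
    variances sum to 1."""
    out = []
    for b in blocks:
        if not b.scaled:
            raise ValueError(f"block {b.tag!r} must be autoscaled before block scaling")
        w = 1.0 / np.sqrt(b.n_descriptors) if b.n_descriptors else 1.0
        out.append(replace(b, data=b.data * w, block_weight=w))
    return out


# ---------------------------------------------------------------------------
# PCA (NIPALS and exact-SVD solvers, identical output convention)
# ---------------------------------------------------------------------------


@dataclass
class PCAModel:
    """Principal components: orthonormal loadings, explained-variance
    fractions (non-increasing) and the training column means."""

    loadings: np.ndarray            # (p, A)
    explained_variance: np.ndarray  # (A,) fractions of total variance
    mean: np.ndarray                # (p,)
    names: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def transform(self, x: np.ndarray | DescriptorBlock) -> np.ndarray:
        if isinstance(x, DescriptorBlock):
            x = x.values()
        return (np.asarray(x, dtype=float) - self.mean) @ self.loadings

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.loadings.T + self.mean


def _fix_sign(loadings: np.ndarray, scores: np.ndarray) -> None:
    for a in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, a]))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1


def pca_nipals(
    block: DescriptorBlock | np.ndarray,
    n_components: int | None = None,
    variance_target: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 500,
    solver: str = "nipals",
) -> tuple[PCAModel, np.ndarray]:
    """Extract principal components by NIPALS (or an exact SVD equivalent).

    Stops at ``n_components`` or when the cumulative explained variance
    reaches ``variance_target``.  Sign convention: the largest-magnitude
    loading of each component is positive.  ``solver='svd'`` computes the
    same quantities from a singular value decomposition, which the NIPALS
    iteration converges to; it is preferred for wide blocks.
    """
    names = None
    if isinstance(block, DescriptorBlock):
        names = list(block.data.columns)
        x = block.values()
    else:
        x = np.asarray(block, dtype=float)
    n, p = x.shape
    a_max = min(n - 1, p)
    if n_components is not None and n_components > a_max:
        raise ValueError(f"n_components {n_components} exceeds min(n-1, p) = {a_max}")
    if variance_target is not None and not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    limit = n_components if n_components is not None else a_max
    mean = x.mean(axis=0)
    xc = x - mean
    total_ss = float(np.sum(xc ** 2))
    if total_ss == 0.0:
        model = PCAModel(np.zeros((p, 0)), np.zeros(0), mean, names)
        return model, np.zeros((n, 0))

    if solver == "svd":
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        ev = s ** 2 / total_ss
        if variance_target is not None:
            k = int(np.searchsorted(np.cumsum(ev), variance_target - 1e-12) + 1)
            limit = min(limit, k)
        limit = min(limit, a_max)
        loadings = vt[:limit].T.copy()
        scores = (u[:, :limit] * s[:limit]).copy()
        _fix_sign(loadings, scores)
        model = PCAModel(loadings, ev[:limit], mean, names)
        return model, scores
    if solver != "nipals":
        raise ValueError(f"unknown solver {solver!r}")

    loadings = np.zeros((p, 0))
    scores = np.zeros((n, 0))
    evs: list[float] = []
    resid = xc.copy()
    cum = 0.0
    for _ in range(limit):
        t = resid[:, int(np.argmax(resid.var(axis=0)))].copy()
        if not np.any(t):
            break
        for _ in range(max_iter):
            pvec = resid.T @ t / (t @ t)
            pvec /= np.linalg.norm(pvec)
            t_new = resid @ pvec
            if np.linalg.norm(t_new - t) <= tol * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
        resid -= np.outer(t, pvec)
        loadings = np.column_stack([loadings, pvec])
        scores = np.column_stack([scores, t])
        ev = float(t @ t) / total_ss
        evs.append(ev)
        cum += ev
        if variance_target is not None and cum >= variance_target - 1e-12:
            break
    _fix_sign(loadings, scores)
    model = PCAModel(loadings, np.array(evs), mean, names)
    return model, scores


# ---------------------------------------------------------------------------
# Cross-terms
# ---------------------------------------------------------------------------


@dataclass
class CrossTermState:
    """Pareto scaling state of the cross-term block (training sds)."""

    pareto_sd: np.ndarray  # per-column standard deviation before scaling
    names: list[str]


def make_cross_terms(
    ligand_scores: np.ndarray,
    kinase_scores: np.ndarray,
    block_weight: float = 1.0,
    state: CrossTermState | None = None,
) -> tuple[np.ndarray, CrossTermState]:
    """Element-wise products of every ligand PC with every kinase PC per pair.

    Inputs are row-aligned per pair (one row per kinase-inhibitor pair).
    Each product column is Pareto-scaled (divided by the square root of its
    training sd) and multiplied by ``block_weight``; weight 0 zeroes the
    block, the starting point of the block-weight sweep.
    """
    lig = np.asarray(ligand_scores, dtype=float)
    kin = np.asarray(kinase_scores, dtype=float)
    if lig.shape[0] != kin.shape[0]:
        raise ValueError("score matrices must be row-aligned per pair")
    cross = (lig[:, :, None] * kin[:, None, :]).reshape(lig.shape[0], -1)
    if state is None:
        sd = cross.std(axis=0, ddof=1) if cross.shape[0] > 1 else np.ones(cross.shape[1])
        sd = np.where(sd > 0, sd, 1.0)
        names = [
            f"x_l{a + 1}_k{b + 1}"
            for a in range(lig.shape[1])
            for b in range(kin.shape[1])
        ]
        state = CrossTermState(pareto_sd=sd, names=names)
    scaled = block_weight * cross / np.sqrt(state.pareto_sd)
    return scaled, state


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------


@dataclass
class DesignMatrix:
    """Model-ready design: one row per kinase-inhibitor pair."""

    x: np.ndarray
    y: np.ndarray              # centered response
    y_mean: float
    kinase_ids: list[str]
    inhibitor_ids: list[str]
    inactive: np.ndarray
    block_slices: dict[str, slice] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.x.shape[0]

    def decenter(self, predictions: np.ndarray) -> np.ndarray:
        return np.asarray(predictions) + self.y_mean


def assemble_design(
    pairs: list[tuple[str, str]],
    ligand_block: DescriptorBlock,
    kinase_block: DescriptorBlock,
    response: np.ndarray,
    cross_block: np.ndarray | None = None,
    cross_names: list[str] | None = None,
    inactive: np.ndarray | None = None,
) -> DesignMatrix:
    """Concatenate blocks row-per-pair and center the response."""
    kin_ids = [k for k, _ in pairs]
    inh_ids = [l for _, l in pairs]
    for k in set(kin_ids):
        if k not in kinase_block.data.index:
            raise ValueError(f"missing kinase entity {k!r}")
    for l in set(inh_ids):
        if l not in ligand_block.data.index:
            raise ValueError(f"missing inhibitor entity {l!r}")
    lig = ligand_block.data.loc[inh_ids].to_numpy(dtype=float)
    kin = kinase_block.data.loc[kin_ids].to_numpy(dtype=float)
    parts = [lig, kin]
    slices = {
        "ligand": slice(0, lig.shape[1]),
        "kinase": slice(lig.shape[1], lig.shape[1] + kin.shape[1]),
    }
    if cross_block is not None:
        start = lig.shape[1] + kin.shape[1]
        slices["cross"] = slice(start, start + cross_block.shape[1])
        parts.append(cross_block)
    x = np.hstack(parts)
    y = np.asarray(response, dtype=float)
    if y.shape[0] != x.shape[0]:
        raise ValueError("response length must match number of pairs")
    y_mean = float(y.mean())
    if inactive is None:
        inactive = np.zeros(len(pairs), dtype=bool)
    return DesignMatrix(
        x=x, y=y - y_mean, y_mean=y_mean,
        kinase_ids=kin_ids, inhibitor_ids=inh_ids,
        inactive=np.asarray(inactive, dtype=bool), block_slices=slices,
    )


# ---------------------------------------------------------------------------
# Fold-wise pipeline
# ---------------------------------------------------------------------------


class DesignBuilder:
    """Turns raw blocks + activity into per-fold, leakage-safe designs.

    All preprocessing state (autoscaling, block weights, PCAs, Pareto sds,
    response mean) is fitted on the training rows of a fold and applied
    unchanged to held-out rows, so held-out kinases never influence the
    transforms.
    """

    def __init__(
        self,
        ligand_block: DescriptorBlock,
        kinase_block: DescriptorBlock,
        activity: ActivityMatrix,
    ):
        self.ligand_block = ligand_block
        self.kinase_block = kinase_block
        self.activity = activity
        long = activity.to_long()
        self.kinase_ids = activity.kinase_ids
        self.inhibitor_ids = activity.inhibitor_ids
        kin_pos = {k: i for i, k in enumerate(self.kinase_ids)}
        inh_pos = {l: i for i, l in enumerate(self.inhibitor_ids)}
        self.k_idx = long["kinase"].map(kin_pos).to_numpy()
        self.l_idx = long["inhibitor"].map(inh_pos).to_numpy()
        self.y = long["pkd"].to_numpy(dtype=float)
        self.inactive = long["inactive"].to_numpy(dtype=bool)
        self.n_rows = len(self.y)

    def fit_fold(
        self,
        train_rows: np.ndarray,
        cross: bool = False,
        variance_target: float = 0.95,
    ) -> "FoldDesign":
        train_rows = np.asarray(train_rows)
        train_inh = np.unique(self.l_idx[train_rows])
        train_kin = np.unique(self.k_idx[train_rows])
        lig_fit = self.ligand_block.subset(
            [self.inhibitor_ids[i] for i in train_inh]
        )
        kin_fit = self.kinase_block.subset(
            [self.kinase_ids[i] for i in train_kin]
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lig_state = autoscale(lig_fit)
            _, kin_state = autoscale(kin_fit)
            lig_all, _ = autoscale(self.ligand_block, lig_state)
            kin_all, _ = autoscale(self.kinase_block, kin_state)
        lig_all, kin_all = block_scale([lig_all, kin_all])
        lig_mat = lig_all.values()
        kin_mat = kin_all.values()

        lig_scores = kin_scores = None
        cross_state = None
        if cross:
            lig_pca, _ = pca_nipals(
                lig_mat[train_inh], n_components=min(len(train_inh) - 1,
                                                     lig_mat.shape[1]),
                solver="svd",
            )
            kin_pca, _ = pca_nipals(
                kin_mat[train_kin], variance_target=variance_target,
                solver="svd",
            )
            lig_scores = lig_pca.transform(lig_mat)
            kin_scores = kin_pca.transform(kin_mat)
            unit, cross_state = make_cross_terms(
                lig_scores[self.l_idx[train_rows]],
                kin_scores[self.k_idx[train_rows]],
                block_weight=1.0,
            )
        y_mean = float(self.y[train_rows].mean())
        return FoldDesign(
            builder=self, lig_mat=lig_mat, kin_mat=kin_mat,
            lig_scores=lig_scores, kin_scores=kin_scores,
            cross_state=cross_state, y_mean=y_mean,
        )


@dataclass
class FoldDesign:
    """Fold-fitted transforms; produces X / y for any set of pair rows."""

    builder: DesignBuilder
    lig_mat: np.ndarray
    kin_mat: np.ndarray
    lig_scores: np.ndarray | None
    kin_scores: np.ndarray | None
    cross_state: CrossTermState | None
    y_mean: float

    def ligand_rows(self, rows: np.ndarray) -> np.ndarray:
        return self.lig_mat[self.builder.l_idx[rows]]

    def kinase_rows(self, rows: np.ndarray) -> np.ndarray:
        return self.kin_mat[self.builder.k_idx[rows]]

    def cross_rows(self, rows: np.ndarray, weight: float) -> np.ndarray:
        if self.cross_state is None:
            raise ValueError("fold was fitted without cross-terms")
        cross, _ = make_cross_terms(
            self.lig_scores[self.builder.l_idx[rows]],
            self.kin_scores[self.builder.k_idx[rows]],
            block_weight=weight, state=self.cross_state,
        )
        return cross

    def matrix(
        self,
        rows: np.ndarray,
        cross_weight: float | None = None,
        kinase_weight: float = 1.0,
    ) -> np.ndarray:
        rows = np.asarray(rows)
        parts = [self.ligand_rows(rows), kinase_weight * self.kinase_rows(rows)]
        if cross_weight is not None:
            parts.append(self.cross_rows(rows, cross_weight))
        return np.hstack(parts)

    def y_centered(self, rows: np.ndarray) -> np.ndarray:
        return self.builder.y[np.asarray(rows)] - self.y_mean

    def y_raw(self, rows: np.ndarray) -> np.ndarray:
        return self.builder.y[np.asarray(rows)]
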
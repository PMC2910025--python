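"""Correlation methods for kinase-inhibitor interaction modelling.

Five families, all consuming the same design-matrix contract:

* NIPALS partial least squares (PLS1/PLS2), with or without ligand x kinase
  cross-terms; the fitted model exposes a single regression coefficient
  vector, which is the method's interpretability advantage.
* PLS discriminant analysis (0/1 class indicators as responses).
* epsilon-SVR with an RBF kernel (quadratic-programming core delegated to
  scikit-learn / libsvm; grids, CV protocol and scaling are in scope here).
* distance-weighted k-nearest-neighbour regression over kinase-inhibitor
  pairs, with a systematic sweep of the kinase-block weight.
* an M5-style model tree: SD-reduction splits, linear models in the leaves,
  bottom-up pruning and smoothing along the path to the root.

Hyperparameters are selected by five-fold inner cross-validation; ties go to
the simplest model (grids are ordered simple to complex and the first
maximum wins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVR

from .preprocessing import DesignMatrix, FoldDesign, pca_nipals

# ---------------------------------------------------------------------------
# NIPALS PLS
# ---------------------------------------------------------------------------


@dataclass
class PLSModel:
    """A fitted NIPALS PLS model (single or multi response).

    Stores the weight (W), X-loading (P) and Y-loading (Q) structures, the
    training means, and exposes predictions both through the regression
    coefficient form B = W (P'W)^-1 Q' and through the score path; the two
    agree to numerical precision.  ``r_weights`` are the weights expressed
    against the undeflated X (R = W (P'W)^-1), which make per-component
    predictions a single matrix product.
    """

    x_mean: np.ndarray
    y_mean: np.ndarray
    weights: np.ndarray     # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (m, A)
    r_weights: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    def _r(self) -> np.ndarray:
        if self.r_weights is None:
            w, p = self.weights, self.x_loadings
            self.r_weights = w @ np.linalg.inv(p.T @ w)
        return self.r_weights

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        a = self.n_components if n_components is None else n_components
        w, p, q = self.weights[:, :a], self.x_loadings[:, :a], self.y_loadings[:, :a]
        return w @ np.linalg.solve(p.T @ w, q.T)

    def predict(self, x: np.ndarray, n_components: int | None = None) -> np.ndarray:
        xc = np.asarray(x, dtype=float) - self.x_mean
        out = xc @ self.coefficients(n_components) + self.y_mean
        return out[:, 0] if out.shape[1] == 1 else out

    def predict_via_scores(self, x: np.ndarray) -> np.ndarray:
        """Prediction through the sequential score path (deflation replay)."""
        xc = np.asarray(x, dtype=float) - self.x_mean
        yhat = np.tile(self.y_mean, (xc.shape[0], 1))
        for a in range(self.n_components):
            t = xc @ self.weights[:, a]
            yhat += np.outer(t, self.y_loadings[:, a])
            xc = xc - np.outer(t, self.x_loadings[:, a])
        return yhat[:, 0] if yhat.shape[1] == 1 else yhat

    def predict_per_component(self, x: np.ndarray) -> np.ndarray:
        """Predictions for every component count 1..A, shape (n, A[, m])."""
        xc = np.asarray(x, dtype=float) - self.x_mean
        t = xc @ self._r()                          # (n, A)
        m = self.y_mean.shape[0]
        if m == 1:
            return np.cumsum(t * self.y_loadings[0], axis=1) + self.y_mean[0]
        contrib = t[:, :, None] * self.y_loadings.T[None, :, :]
        return np.cumsum(contrib, axis=1) + self.y_mean


def _pls1(xc: np.ndarray, yc: np.ndarray, n_components: int) -> tuple:
    """Single-response PLS via the covariance-deflating form of the NIPALS
    recursion (Dayal-MacGregor): only the p-vector X'y is deflated, which
    yields exactly the NIPALS weights/loadings/scores without rewriting X."""
    p_dim = xc.shape[1]
    s = xc.T @ yc
    ws, ps, qs, rs = [], [], [], []
    for a in range(n_components):
        norm = np.linalg.norm(s)
        if norm <= 1e-300:
            break
        w = s / norm
        r = w.copy()
        for j in range(a):
            r -= (ps[j] @ w) * rs[j]
        t = xc @ r
        tt = float(t @ t)
        if tt <= 1e-300:
            break
        pvec = xc.T @ t / tt
        q = float(yc @ t / tt)
        s = s - (tt * q) * pvec
        ws.append(w)
        ps.append(pvec)
        qs.append(q)
        rs.append(r)
    return ws, ps, [np.array([q]) for q in qs], rs


def nipals_pls(
    x: np.ndarray,
    y: np.ndarray,
    n_components: int,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> PLSModel:
    """Fit PLS by the NIPALS recursion.

    The single-response path uses the covariance-deflation form (identical
    results, no repeated rewriting of X); the multi-response path runs the
    classic iterative NIPALS with X and Y deflation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n, p = x.shape
    m = y.shape[1]
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(f"n_components must lie in [1, {min(n - 1, p)}]")
    if np.allclose(y.std(axis=0), 0.0):
        raise ValueError("degenerate response: zero variance")
    x_mean, y_mean = x.mean(axis=0), y.mean(axis=0)
    if m == 1:
        ws, ps, qs, rs = _pls1(x - x_mean, (y - y_mean)[:, 0], n_components)
        return PLSModel(
            x_mean=x_mean, y_mean=y_mean,
            weights=np.column_stack(ws), x_loadings=np.column_stack(ps),
            y_loadings=np.column_stack(qs), r_weights=np.column_stack(rs),
        )
    xr, yr = x - x_mean, y - y_mean
    ws, ps, qs = [], [], []
    for _ in range(n_components):
        u = yr[:, int(np.argmax(yr.var(axis=0)))].copy()
        w_old = None
        for _ in range(max_iter):
            w = xr.T @ u
            norm = np.linalg.norm(w)
            if norm == 0.0:
                break
            w /= norm
            t = xr @ w
            q = yr.T @ t / (t @ t)
            u = yr @ q / (q @ q)
            if w_old is not None and np.linalg.norm(w - w_old) <= tol:
                break
            w_old = w
        t = xr @ w
        tt = float(t @ t)
        if tt == 0.0:
            break
        pvec = xr.T @ t / tt
        q = yr.T @ t / tt
        xr = xr - np.outer(t, pvec)
        yr = yr - np.outer(t, q)
        ws.append(w)
        ps.append(pvec)
        qs.append(q)
    return PLSModel(
        x_mean=x_mean, y_mean=y_mean,
        weights=np.column_stack(ws), x_loadings=np.column_stack(ps),
        y_loadings=np.column_stack(qs),
    )


def pls_fit(design: DesignMatrix, n_components: int) -> PLSModel:
    """Fit PLS1 on a design matrix (response already centered)."""
    return nipals_pls(design.x, design.y, n_components)


def plsda_fit(
    x: np.ndarray,
    labels: Sequence[str],
    n_components: int = 5,
    cv: int = 5,
    seed: int = 0,
) -> tuple[PLSModel, dict]:
    """PLS discriminant analysis with cross-validated Q² per class.

    Class membership is coded 1/0 per indicator column; the report carries
    the pooled overall Q² and the per-class Q² from ``cv``-fold CV.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray([str(l) for l in labels])
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((labels == c).sum()) for c in classes}
    singles = [c for c, n in counts.items() if n < 2]
    if singles:
        raise ValueError(f"singleton class(es): {singles}")
    y = np.column_stack([(labels == c).astype(float) for c in classes])
    n = x.shape[0]
    a = min(n_components, n - 1 - (n // cv), x.shape[1])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, cv)
    pred = np.empty_like(y)
    for va in folds:
        tr = np.setdiff1d(order, va)
        model = nipals_pls(x[tr], y[tr], a)
        p = model.predict(x[va])
        pred[va] = p if p.ndim == 2 else p[:, None]
    ss_res = ((y - pred) ** 2).sum(axis=0)
    ss_tot = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
    per_class = dict(zip(classes, 1.0 - ss_res / ss_tot))
    overall = float(1.0 - ss_res.sum() / ss_tot.sum())
    model = nipals_pls(x, y, a)
    report = {
        "classes": classes,
        "q2_per_class": {c: float(v) for c, v in per_class.items()},
        "q2_overall": overall,
        "n_components": a,
        "cv_predictions": pred,
    }
    return model, report


# ---------------------------------------------------------------------------
# Fitted-model container and inner-CV search record
# ---------------------------------------------------------------------------


@dataclass
class HyperparameterSearchResult:
    grid: list[dict]
    inner_q2: list[float]
    selected: dict

    def __post_init__(self) -> None:
        if self.grid:
            best = max(self.inner_q2)
            sel_idx = self.grid.index(self.selected)
            if self.inner_q2[sel_idx] < best - 1e-12:
                raise ValueError("selected point must maximize inner-CV Q²")


@dataclass
class FittedModel:
    """A fitted predictor: method tag, chosen hyperparameters, prediction
    function over feature rows."""

    method: str
    hyperparameters: dict
    predict_fn: Callable[[np.ndarray], np.ndarray]
    search: HyperparameterSearchResult | None = None
    extra: dict = field(default_factory=dict)

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.predict_fn(np.asarray(x, dtype=float))


def _inner_q2(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    ss_tot = float(((y_obs - y_obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return -np.inf
    return 1.0 - float(((y_obs - y_pred) ** 2).sum()) / ss_tot


def _argbest(q2: Sequence[float]) -> int:
    """First maximum = simplest model on a simple-to-complex grid."""
    arr = np.asarray(q2, dtype=float)
    return int(np.flatnonzero(arr >= arr.max() - 1e-12)[0])


# ---------------------------------------------------------------------------
# epsilon-SVR (RBF)
# ---------------------------------------------------------------------------

DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in (-6, -4, -2, 0))
DEFAULT_C_GRID = tuple(2.0 ** e for e in (-1, 1, 3, 5, 7, 9))


def _rbf_kernel_from_d2(d2: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * d2)


def squared_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = (
        (a ** 2).sum(axis=1)[:, None]
        + (b ** 2).sum(axis=1)[None, :]
        - 2.0 * a @ b.T
    )
    return np.maximum(d2, 0.0)


def svr_fit(
    design: DesignMatrix,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    epsilon: float | None = None,
    cv: int = 5,
    seed: int = 0,
) -> FittedModel:
    """epsilon-SVR with RBF kernel; (gamma, C) chosen by inner-CV Q².

    ``epsilon`` defaults to 0.1 x sd of the response.  The kernel matrix is
    precomputed once from pairwise squared distances and shared across the
    grid.
    """
    gamma_grid = sorted(float(g) for g in gamma_grid)
    c_grid = sorted(float(c) for c in c_grid)
    if not gamma_grid or not c_grid:
        raise ValueError("grids must be non-empty")
    if not all(np.isfinite(gamma_grid)) or not all(np.isfinite(c_grid)):
        raise ValueError("non-finite grid values")
    x, y = design.x, design.y
    if epsilon is None:
        epsilon = 0.1 * float(y.std())
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, cv)
    d2 = squared_distances(x, x)
    grid = [{"gamma": g, "C": c} for c in c_grid for g in gamma_grid]
    q2s = []
    for hp in grid:
        k = _rbf_kernel_from_d2(d2, hp["gamma"])
        pred = np.empty_like(y)
        for va in folds:
            tr = np.setdiff1d(order, va)
            svr = SVR(kernel="precomputed", C=hp["C"], epsilon=epsilon)
            svr.fit(k[np.ix_(tr, tr)], y[tr])
            pred[va] = svr.predict(k[np.ix_(va, tr)])
        q2s.append(_inner_q2(y, pred))
    best = grid[_argbest(q2s)]
    k = _rbf_kernel_from_d2(d2, best["gamma"])
    svr = SVR(kernel="precomputed", C=best["C"], epsilon=epsilon)
    svr.fit(k, y)

    def predict(x_new: np.ndarray) -> np.ndarray:
        k_new = _rbf_kernel_from_d2(squared_distances(x_new, x), best["gamma"])
        return svr.predict(k_new) + design.y_mean

    return FittedModel(
        method="svm",
        hyperparameters={**best, "epsilon": epsilon},
        predict_fn=predict,
        search=HyperparameterSearchResult(grid, q2s, best),
    )


# ---------------------------------------------------------------------------
# Distance-weighted k-NN over pairs
# ---------------------------------------------------------------------------

DEFAULT_K_GRID = (1, 3, 5, 7, 9)
DEFAULT_KINASE_WEIGHT_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


def knn_weighted(d2: np.ndarray, y_train: np.ndarray, k: int) -> np.ndarray:
    """1/distance-weighted mean of the k nearest training responses.

    ``d2`` holds squared distances (n_test x n_train).  An exact match
    (distance 0) returns the mean response of all zero-distance neighbours.
    """
    n_test, n_train = d2.shape
    if k > n_train:
        raise ValueError(f"k = {k} exceeds training size {n_train}")
    idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
    rows = np.arange(n_test)[:, None]
    nd2 = d2[rows, idx]
    ny = y_train[idx]
    out = np.empty(n_test)
    zero = nd2 <= 0.0
    has_zero = zero.any(axis=1)
    # exact matches: average the tied zero-distance neighbours
    for i in np.flatnonzero(has_zero):
        out[i] = ny[i, zero[i]].mean()
    rest = ~has_zero
    w = 1.0 / np.sqrt(nd2[rest])
    out[rest] = (w * ny[rest]).sum(axis=1) / w.sum(axis=1)
    return out


def knn_predict(
    train_design: DesignMatrix,
    test_x: np.ndarray,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    kinase_weight_grid: Sequence[float] = DEFAULT_KINASE_WEIGHT_GRID,
    cv: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """k-NN predictions for test rows with (k, kinase weight) from inner CV.

    The kinase-block weight rescales the kinase part of the squared distance
    (weight^2 on that block), steering neighbour ranking between ligand
    similarity (weight -> 0) and kinase similarity (weight -> infinity).
    """
    sl = train_design.block_slices
    if "kinase" not in sl:
        raise ValueError("design must carry kinase block boundaries")
    x, y = train_design.x, train_design.y
    test_x = np.asarray(test_x, dtype=float)
    kin, lig = sl["kinase"], sl["ligand"]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, cv)
    grid = [
        {"k": int(k), "kinase_weight": float(w)}
        for w in kinase_weight_grid for k in k_grid
    ]
    d2_parts = {}
    for va in folds:
        tr = np.setdiff1d(order, va)
        d2_parts[va.tobytes()] = (
            tr,
            squared_distances(x[va][:, lig], x[tr][:, lig]),
            squared_distances(x[va][:, kin], x[tr][:, kin]),
        )
    q2s = []
    for hp in grid:
        pred = np.empty_like(y)
        for va in folds:
            tr, d2_lig, d2_kin = d2_parts[va.tobytes()]
            d2 = d2_lig + hp["kinase_weight"] ** 2 * d2_kin
            pred[va] = knn_weighted(d2, y[tr], min(hp["k"], len(tr)))
        q2s.append(_inner_q2(y, pred))
    best = grid[_argbest(q2s)]
    d2 = (
        squared_distances(test_x[:, lig], x[:, lig])
        + best["kinase_weight"] ** 2 * squared_distances(test_x[:, kin], x[:, kin])
    )
    preds = knn_weighted(d2, y, best["k"]) + train_design.y_mean
    return preds, {
        "selected": best,
        "search": HyperparameterSearchResult(grid, q2s, best),
    }


# ---------------------------------------------------------------------------
# M5-style model tree
# ---------------------------------------------------------------------------


class _TreeNode:
    __slots__ = ("feature", "threshold", "left", "right", "model", "n",
                 "attrs", "is_leaf")

    def __init__(self) -> None:
        self.feature = -1
        self.threshold = 0.0
        self.left = self.right = None
        self.model = None  # (intercept, coefs over attrs)
        self.n = 0
        self.attrs: tuple[int, ...] = ()
        self.is_leaf = True


def _fit_linear(x: np.ndarray, y: np.ndarray, attrs: tuple[int, ...],
                ridge: float = 1e-6):
    if not attrs:
        return float(y.mean()), np.zeros(0)
    a = x[:, attrs]
    a1 = np.column_stack([np.ones(len(y)), a])
    gram = a1.T @ a1 + ridge * np.eye(a1.shape[1])
    beta = np.linalg.solve(gram, a1.T @ y)
    return float(beta[0]), beta[1:]


def _node_predict(node: _TreeNode, x: np.ndarray) -> np.ndarray:
    b0, b = node.model
    if len(b) == 0:
        return np.full(x.shape[0], b0)
    return b0 + x[:, list(node.attrs)] @ b


class M5ModelTree:
    """M5-style regression model tree.

    Splits maximize standard-deviation reduction; each node carries a linear
    model over the attributes tested in its subtree; pruning compares the
    node model's complexity-penalized error against its subtree; prediction
    is smoothed along the path to the root with smoothing constant ``k``.
    A constant response yields a single-leaf tree.
    """

    def __init__(self, min_leaf: int = 4, smoothing: float = 15.0,
                 sd_stop: float = 0.05):
        if min_leaf < 2:
            raise ValueError("min_leaf must be >= 2")
        self.min_leaf = min_leaf
        self.smoothing = smoothing
        self.sd_stop = sd_stop
        self.root: _TreeNode | None = None

    # -- building ----------------------------------------------------------
    def _best_split(self, x: np.ndarray, y: np.ndarray):
        n = len(y)
        sd_all = y.std()
        best = (0.0, -1, 0.0)
        for j in range(x.shape[1]):
            order = np.argsort(x[:, j], kind="mergesort")
            xs, ys = x[order, j], y[order]
            csum = np.cumsum(ys)
            csum2 = np.cumsum(ys ** 2)
            nl = np.arange(1, n)
            nr = n - nl
            sl = csum[:-1]
            sl2 = csum2[:-1]
            var_l = np.maximum(sl2 / nl - (sl / nl) ** 2, 0.0)
            var_r = np.maximum(
                (csum2[-1] - sl2) / nr - ((csum[-1] - sl) / nr) ** 2, 0.0
            )
            sdr = sd_all - (nl * np.sqrt(var_l) + nr * np.sqrt(var_r)) / n
            valid = (
                (nl >= self.min_leaf)
                & (nr >= self.min_leaf)
                & (np.diff(xs) > 0)
            )
            if not valid.any():
                continue
            sdr = np.where(valid, sdr, -np.inf)
            i = int(np.argmax(sdr))
            if sdr[i] > best[0]:
                best = (float(sdr[i]), j, float((xs[i] + xs[i + 1]) / 2.0))
        return best

    def _build(self, x: np.ndarray, y: np.ndarray, root_sd: float) -> _TreeNode:
        node = _TreeNode()
        node.n = len(y)
        if len(y) < 2 * self.min_leaf or y.std() <= self.sd_stop * root_sd:
            return node
        sdr, j, thr = self._best_split(x, y)
        if j < 0 or sdr <= 0.0:
            return node
        mask = x[:, j] <= thr
        node.feature, node.threshold = j, thr
        node.is_leaf = False
        node.left = self._build(x[mask], y[mask], root_sd)
        node.right = self._build(x[~mask], y[~mask], root_sd)
        return node

    def _collect_attrs(self, node: _TreeNode) -> tuple[int, ...]:
        if node.is_leaf:
            return node.attrs
        attrs = {node.feature}
        attrs.update(self._collect_attrs(node.left))
        attrs.update(self._collect_attrs(node.right))
        node.attrs = tuple(sorted(attrs))
        return node.attrs

    def _fit_models_and_prune(self, node: _TreeNode, x: np.ndarray,
                              y: np.ndarray) -> float:
        """Returns the subtree's training MAE after pruning."""
        node.model = _fit_linear(x, y, node.attrs)
        node_err = float(np.abs(y - _node_predict(node, x)).mean())
        nu = len(node.attrs) + 1
        penalty = (node.n + nu) / max(node.n - nu, 1)
        if node.is_leaf:
            return node_err
        mask = x[:, node.feature] <= node.threshold
        err_l = self._fit_models_and_prune(node.left, x[mask], y[mask])
        err_r = self._fit_models_and_prune(node.right, x[~mask], y[~mask])
        sub_err = (mask.sum() * err_l + (~mask).sum() * err_r) / node.n
        if node_err * penalty <= sub_err:
            node.is_leaf = True
            node.left = node.right = None
            return node_err
        return sub_err

    def fit(self, x: np.ndarray, y: np.ndarray) -> "M5ModelTree":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        root_sd = float(y.std())
        if root_sd == 0.0:
            self.root = _TreeNode()
            self.root.n = len(y)
            self.root.model = (float(y.mean()), np.zeros(0))
            return self
        self.root = self._build(x, y, root_sd)
        self._collect_attrs(self.root)
        self._fit_models_and_prune(self.root, x, y)
        return self

    # -- prediction --------------------------------------------------------
    def _predict_one(self, x: np.ndarray) -> float:
        path = []
        node = self.root
        while not node.is_leaf:
            path.append(node)
            node = node.left if x[node.feature] <= node.threshold else node.right
        pred = float(_node_predict(node, x[None, :])[0])
        n = node.n
        for parent in reversed(path):
            pp = float(_node_predict(parent, x[None, :])[0])
            pred = (n * pred + self.smoothing * pp) / (n + self.smoothing)
        return pred

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.array([self._predict_one(row) for row in x])

    @property
    def n_leaves(self) -> int:
        def count(node: _TreeNode) -> int:
            if node.is_leaf:
                return 1
            return count(node.left) + count(node.right)
        return count(self.root)


def model_tree_fit(
    design: DesignMatrix,
    min_leaf_grid: Sequence[int] = (4, 8, 16),
    cv: int = 5,
    seed: int = 0,
) -> FittedModel:
    """M5-style model tree with min-objects-per-leaf chosen by inner CV."""
    x, y = design.x, design.y
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(y))
    folds = np.array_split(order, cv)
    grid = [{"min_leaf": int(m)} for m in sorted(min_leaf_grid, reverse=True)]
    q2s = []
    for hp in grid:
        pred = np.empty_like(y)
        for va in folds:
            tr = np.setdiff1d(order, va)
            tree = M5ModelTree(min_leaf=hp["min_leaf"]).fit(x[tr], y[tr])
            pred[va] = tree.predict(x[va])
        q2s.append(_inner_q2(y, pred))
    best = grid[_argbest(q2s)]
    tree = M5ModelTree(min_leaf=best["min_leaf"]).fit(x, y)
    return FittedModel(
        method="tree",
        hyperparameters=best,
        predict_fn=lambda x_new: tree.predict(x_new) + design.y_mean,
        search=HyperparameterSearchResult(grid, q2s, best),
        extra={"n_leaves": tree.n_leaves},
    )


# ---------------------------------------------------------------------------
# Uniform method interface for the double-CV driver
# ---------------------------------------------------------------------------


class Method:
    """Interface consumed by :func:`kinopcm.validation.double_cv`.

    ``inner_scores`` returns, per grid point, pooled inner-CV validation
    predictions on the raw pK_d scale; ``fit_predict`` refits on the full
    training rows with the chosen hyperparameters and predicts held-out rows.
    """

    name: str = "base"
    needs_cross: bool = False

    def grid(self) -> list[dict]:  # simple -> complex
        raise NotImplementedError

    def fit_predict(self, fold: FoldDesign, train_rows: np.ndarray,
                    eval_rows: np.ndarray, hp: dict) -> np.ndarray:
        raise NotImplementedError

    def inner_scores(self, fold: FoldDesign, tr: np.ndarray,
                     va: np.ndarray) -> dict[int, np.ndarray]:
        return {
            i: self.fit_predict(fold, tr, va, hp)
            for i, hp in enumerate(self.grid())
        }


class PLSMethod(Method):
    """Linear PLS on the two descriptor blocks (no cross-terms)."""

    name = "pls"

    def __init__(self, max_components: int = 15):
        self.max_components = max_components

    def grid(self) -> list[dict]:
        return [{"n_components": a} for a in range(1, self.max_components + 1)]

    def _a_max(self, n_rows: int) -> int:
        return min(self.max_components, n_rows - 1)

    def fit_predict(self, fold, train_rows, eval_rows, hp):
        a = min(hp["n_components"], self._a_max(len(train_rows)))
        model = nipals_pls(fold.matrix(train_rows),
                           fold.y_centered(train_rows), a)
        return model.predict(fold.matrix(eval_rows)) + fold.y_mean

    def inner_scores(self, fold, tr, va):
        a_max = self._a_max(len(tr))
        model = nipals_pls(fold.matrix(tr), fold.y_centered(tr), a_max)
        per_comp = model.predict_per_component(fold.matrix(va)) + fold.y_mean
        out = {}
        for i, hp in enumerate(self.grid()):
            a = min(hp["n_components"], a_max)
            out[i] = per_comp[:, a - 1]
        return out


class PLSCrossMethod(PLSMethod):
    """PLS with Pareto-scaled ligand x kinase cross-terms; the cross-block
    weight is swept from 0 upward and chosen jointly with the component
    count by inner CV."""

    name = "pls_x"
    needs_cross = True

    def __init__(self, max_components: int = 15,
                 weight_grid: Sequence[float] | None = None):
        super().__init__(max_components)
        if weight_grid is None:
            weight_grid = np.round(np.arange(0.0, 2.01, 0.1), 2)
        self.weight_grid = [float(w) for w in weight_grid]

    def grid(self) -> list[dict]:
        return [
            {"cross_weight": w, "n_components": a}
            for w in self.weight_grid
            for a in range(1, self.max_components + 1)
        ]

    def fit_predict(self, fold, train_rows, eval_rows, hp):
        a = min(hp["n_components"], self._a_max(len(train_rows)))
        w = hp["cross_weight"]
        model = nipals_pls(fold.matrix(train_rows, cross_weight=w),
                           fold.y_centered(train_rows), a)
        return model.predict(fold.matrix(eval_rows, cross_weight=w)) + fold.y_mean

    def inner_scores(self, fold, tr, va):
        a_max = self._a_max(len(tr))
        base_tr, base_va = fold.matrix(tr), fold.matrix(va)
        unit_tr, unit_va = fold.cross_rows(tr, 1.0), fold.cross_rows(va, 1.0)
        y_tr = fold.y_centered(tr)
        pb = base_tr.shape[1]
        x_tr = np.empty((base_tr.shape[0], pb + unit_tr.shape[1]))
        x_va = np.empty((base_va.shape[0], pb + unit_va.shape[1]))
        x_tr[:, :pb], x_va[:, :pb] = base_tr, base_va
        out = {}
        i = 0
        for w in self.weight_grid:
            x_tr[:, pb:] = w * unit_tr
            x_va[:, pb:] = w * unit_va
            model = nipals_pls(x_tr, y_tr, a_max)
            per_comp = model.predict_per_component(x_va) + fold.y_mean
            for a in range(1, self.max_components + 1):
                out[i] = per_comp[:, min(a, a_max) - 1]
                i += 1
        return out


class SVRMethod(Method):
    name = "svm"

    def __init__(self, gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
                 c_grid: Sequence[float] = DEFAULT_C_GRID,
                 epsilon_factor: float = 0.1):
        self.gamma_grid = sorted(float(g) for g in gamma_grid)
        self.c_grid = sorted(float(c) for c in c_grid)
        self.epsilon_factor = epsilon_factor

    def grid(self) -> list[dict]:
        return [
            {"gamma": g, "C": c} for c in self.c_grid for g in self.gamma_grid
        ]

    def fit_predict(self, fold, train_rows, eval_rows, hp):
        x_tr = fold.matrix(train_rows)
        y_tr = fold.y_centered(train_rows)
        eps = self.epsilon_factor * float(y_tr.std())
        d2 = squared_distances(x_tr, x_tr)
        svr = SVR(kernel="precomputed", C=hp["C"], epsilon=eps)
        svr.fit(_rbf_kernel_from_d2(d2, hp["gamma"]), y_tr)
        d2_new = squared_distances(fold.matrix(eval_rows), x_tr)
        return (
            svr.predict(_rbf_kernel_from_d2(d2_new, hp["gamma"])) + fold.y_mean
        )

    def inner_scores(self, fold, tr, va):
        x_tr = fold.matrix(tr)
        y_tr = fold.y_centered(tr)
        eps = self.epsilon_factor * float(y_tr.std())
        d2_tr = squared_distances(x_tr, x_tr)
        d2_va = squared_distances(fold.matrix(va), x_tr)
        out = {}
        for i, hp in enumerate(self.grid()):
            svr = SVR(kernel="precomputed", C=hp["C"], epsilon=eps)
            svr.fit(_rbf_kernel_from_d2(d2_tr, hp["gamma"]), y_tr)
            out[i] = (
                svr.predict(_rbf_kernel_from_d2(d2_va, hp["gamma"]))
                + fold.y_mean
            )
        return out


class KNNMethod(Method):
    name = "knn"

    def __init__(self, k_grid: Sequence[int] = DEFAULT_K_GRID,
                 kinase_weight_grid: Sequence[float] = DEFAULT_KINASE_WEIGHT_GRID):
        self.k_grid = [int(k) for k in k_grid]
        self.kinase_weight_grid = [float(w) for w in kinase_weight_grid]

    def grid(self) -> list[dict]:
        return [
            {"k": k, "kinase_weight": w}
            for w in self.kinase_weight_grid for k in self.k_grid
        ]

    def _distance_parts(self, fold, tr, va):
        return (
            squared_distances(fold.ligand_rows(va), fold.ligand_rows(tr)),
            squared_distances(fold.kinase_rows(va), fold.kinase_rows(tr)),
        )

    def fit_predict(self, fold, train_rows, eval_rows, hp):
        d2_lig, d2_kin = self._distance_parts(fold, train_rows, eval_rows)
        d2 = d2_lig + hp["kinase_weight"] ** 2 * d2_kin
        k = min(hp["k"], len(train_rows))
        return knn_weighted(d2, fold.y_raw(train_rows), k)

    def inner_scores(self, fold, tr, va):
        d2_lig, d2_kin = self._distance_parts(fold, tr, va)
        y_tr = fold.y_raw(tr)
        out = {}
        for i, hp in enumerate(self.grid()):
            d2 = d2_lig + hp["kinase_weight"] ** 2 * d2_kin
            out[i] = knn_weighted(d2, y_tr, min(hp["k"], len(tr)))
        return out


class OneNNMethod(KNNMethod):
    name = "1nn"

    def __init__(self, kinase_weight_grid=DEFAULT_KINASE_WEIGHT_GRID):
        super().__init__(k_grid=(1,), kinase_weight_grid=kinase_weight_grid)


class TreeMethod(Method):
    """M5-style model tree on a PCA-compressed design (the compression keeps
    split search tractable on wide descriptor blocks)."""

    name = "tree"

    def __init__(self, min_leaf_grid: Sequence[int] = (4, 8, 16),
                 variance_target: float = 0.95):
        self.min_leaf_grid = sorted(int(m) for m in min_leaf_grid)
        self.variance_target = variance_target

    def grid(self) -> list[dict]:
        return [{"min_leaf": m} for m in sorted(self.min_leaf_grid, reverse=True)]

    def _compress(self, fold, tr):
        x_tr = fold.matrix(tr)
        pca, _ = pca_nipals(x_tr, variance_target=self.variance_target,
                            solver="svd")
        return pca

    def fit_predict(self, fold, train_rows, eval_rows, hp):
        pca = self._compress(fold, train_rows)
        x_tr = pca.transform(fold.matrix(train_rows))
        tree = M5ModelTree(min_leaf=hp["min_leaf"]).fit(
            x_tr, fold.y_centered(train_rows)
        )
        return tree.predict(pca.transform(fold.matrix(eval_rows))) + fold.y_mean

    def inner_scores(self, fold, tr, va):
        pca = self._compress(fold, tr)
        x_tr = pca.transform(fold.matrix(tr))
        x_va = pca.transform(fold.matrix(va))
        y_tr = fold.y_centered(tr)
        out = {}
        for i, hp in enumerate(self.grid()):
            tree = M5ModelTree(min_leaf=hp["min_leaf"]).fit(x_tr, y_tr)
            out[i] = tree.predict(x_va) + fold.y_mean
        return out


METHODS: dict[str, Callable[[], Method]] = {
    "pls": PLSMethod,
    "pls_x": PLSCrossMethod,
    "svm": SVRMethod,
    "knn": KNNMethod,
    "1nn": OneNNMethod,
    "tree": TreeMethod,
}


def make_method(name: str, **kwargs) -> Method:
    if name not in METHODS:
        raise ValueError(f"unknown method {name!r}; choose from {sorted(METHODS)}")
    return METHODS[name](**kwargs)
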
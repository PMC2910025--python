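"""Model validation: Q²/P² metrics, double cross-validation, ROC analysis.

Double (nested) cross-validation splits the panel into 25 parts.  Five parts
at a time are put aside as the outer verification set; the remaining 20 parts
feed a five-fold inner loop (models built on 16/25, validated on 4/25) that
selects hyperparameters; the selected model is refit on the 20/25 and scored
on the untouched 5/25.  Pooled outer predictions give P² when parts are drawn
over kinase-inhibitor pairs and P²_kin when whole kinases are held out — the
latter measures generalization to proteins with no measured data at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve

from .models import Method, _argbest
from .preprocessing import DesignBuilder

DETECTION_LIMIT = 5.0


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def q_squared(y_obs: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross-validated squared correlation Q² = 1 - PRESS / SS_tot.

    The reference mean is the mean of the observed values of the evaluated
    set; a model predicting that mean scores 0 and worse models go negative.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_obs.shape != y_pred.shape or y_obs.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    ss_tot = float(((y_obs - y_obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("undefined_q2: constant observed values")
    return 1.0 - float(((y_obs - y_pred) ** 2).sum()) / ss_tot


def roc_analysis(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    active_threshold: float = DETECTION_LIMIT,
    sensitivities: tuple[float, ...] = (0.80, 0.90, 0.95),
) -> dict:
    """ROC curve for separating interacting from non-interacting pairs.

    True class: observed pK_d >= threshold; score: predicted pK_d.  AUC by
    the trapezoidal rule (identical to the Mann-Whitney rank statistic); the
    table reports, for each requested sensitivity, the best specificity
    attainable at at least that sensitivity.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    labels = (y_obs >= active_threshold).astype(int)
    if labels.min() == labels.max():
        raise ValueError("single-class input: need both active and inactive pairs")
    fpr, tpr, thresholds = roc_curve(labels, y_pred)
    auc = float(np.trapezoid(tpr, fpr))
    table = {}
    for s in sensitivities:
        ok = tpr >= s - 1e-12
        table[s] = float(1.0 - fpr[ok].min()) if ok.any() else 0.0
    return {
        "fpr": fpr,
        "tpr": tpr,
        "thresholds": thresholds,
        "auc": auc,
        "specificity_at_sensitivity": table,
    }


def auc_rank(y_obs: np.ndarray, y_pred: np.ndarray,
             active_threshold: float = DETECTION_LIMIT) -> float:
    """AUC via the Mann-Whitney rank formulation (cross-check for the
    trapezoid value)."""
    labels = np.asarray(y_obs, dtype=float) >= active_threshold
    pos = np.asarray(y_pred, dtype=float)[labels]
    neg = np.asarray(y_pred, dtype=float)[~labels]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("single-class input")
    greater = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return float((greater + 0.5 * ties) / (len(pos) * len(neg)))


def error_histogram(
    y_obs: np.ndarray,
    y_pred: np.ndarray,
    bin_edges: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0),
) -> dict:
    """Cumulative fractions of |prediction error| within each edge, plus
    plot-ready bin counts."""
    err = np.abs(np.asarray(y_obs, dtype=float) - np.asarray(y_pred, dtype=float))
    if err.size == 0:
        raise ValueError("empty input")
    cumulative = {float(e): float((err <= e).mean()) for e in bin_edges}
    hist_edges = (0.0,) + tuple(bin_edges) + (float(max(err.max(), bin_edges[-1])) + 1e-9,)
    counts, _ = np.histogram(err, bins=np.asarray(hist_edges))
    return {
        "cumulative": cumulative,
        "bin_edges": hist_edges,
        "bin_counts": counts,
    }


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Assignment of rows (pairwise) or kinases (kinasewise) to parts.

    Parts are disjoint and exhaustive; in kinasewise mode all pairs of one
    kinase share a part, so a held-out kinase never leaks into training.
    """

    mode: str
    n_parts: int
    part_of_row: np.ndarray
    seed: int

    def rows_of_parts(self, parts: np.ndarray) -> np.ndarray:
        return np.flatnonzero(np.isin(self.part_of_row, parts))


def make_split_plan(
    builder: DesignBuilder, mode: str, n_parts: int = 25, seed: int = 0
) -> SplitPlan:
    rng = np.random.default_rng(seed)
    if mode == "pairwise":
        part = np.empty(builder.n_rows, dtype=int)
        order = rng.permutation(builder.n_rows)
        for p, chunk in enumerate(np.array_split(order, n_parts)):
            part[chunk] = p
    elif mode == "kinasewise":
        n_kin = len(builder.kinase_ids)
        if n_kin < n_parts / 5:
            raise ValueError(
                f"kinasewise mode needs at least {n_parts / 5:.0f} kinases"
            )
        kin_part = np.empty(n_kin, dtype=int)
        order = rng.permutation(n_kin)
        for p, chunk in enumerate(np.array_split(order, n_parts)):
            kin_part[chunk] = p
        part = kin_part[builder.k_idx]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SplitPlan(mode=mode, n_parts=n_parts, part_of_row=part, seed=seed)


# ---------------------------------------------------------------------------
# Double cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    """Pooled outer-loop predictions and derived summaries."""

    method: str
    mode: str
    metric_name: str
    metric: float
    predictions: pd.DataFrame     # kinase, inhibitor, y_obs, y_pred, outer_fold
    fold_hyperparameters: list[dict]
    roc: dict = field(default_factory=dict)
    auc: float = float("nan")
    error_fractions: dict = field(default_factory=dict)


def _audit_outer_purity(builder, plan, train_rows, test_rows) -> None:
    train_set, test_set = set(train_rows.tolist()), set(test_rows.tolist())
    if train_set & test_set:
        raise AssertionError("outer-loop purity violated: shared rows")
    if plan.mode == "kinasewise":
        shared = set(builder.k_idx[train_rows]) & set(builder.k_idx[test_rows])
        if shared:
            raise AssertionError(
                f"outer-loop purity violated: kinases {sorted(shared)[:5]} "
                "appear on both sides"
            )


def double_cv(
    builder: DesignBuilder,
    method: Method,
    mode: str = "pairwise",
    n_parts: int = 25,
    seed: int = 0,
    variance_target: float = 0.95,
    compute_roc: bool = True,
) -> CVResult:
    """Nested cross-validation with per-outer-fold hyperparameter selection.

    All preprocessing is refit inside every (inner and outer) training set.
    Pooled outer predictions yield P² (pairwise) or P²_kin (kinasewise).
    """
    plan = make_split_plan(builder, mode, n_parts, seed)
    n_outer = 5
    outer_groups = np.array_split(np.arange(n_parts), n_outer)
    grid = method.grid()
    y_pred = np.full(builder.n_rows, np.nan)
    outer_fold_of_row = np.full(builder.n_rows, -1, dtype=int)
    fold_hps: list[dict] = []
    for g, test_parts in enumerate(outer_groups):
        test_rows = plan.rows_of_parts(test_parts)
        train_parts = np.setdiff1d(np.arange(n_parts), test_parts)
        train_rows = plan.rows_of_parts(train_parts)
        if len(test_rows) == 0 or len(train_rows) == 0:
            raise ValueError("empty outer part; dataset too small for n_parts")
        _audit_outer_purity(builder, plan, train_rows, test_rows)

        # inner loop: 5 folds over the 20 training parts (train 16, val 4)
        inner_groups = np.array_split(train_parts, 5)
        pooled: dict[int, list[np.ndarray]] = {i: [] for i in range(len(grid))}
        pooled_obs: list[np.ndarray] = []
        for va_parts in inner_groups:
            va_rows = plan.rows_of_parts(va_parts)
            tr_parts = np.setdiff1d(train_parts, va_parts)
            tr_rows = plan.rows_of_parts(tr_parts)
            if set(tr_rows.tolist()) & set(test_rows.tolist()):
                raise AssertionError("inner training touched outer test rows")
            fold = builder.fit_fold(tr_rows, cross=method.needs_cross,
                                    variance_target=variance_target)
            scores = method.inner_scores(fold, tr_rows, va_rows)
            for i in range(len(grid)):
                pooled[i].append(scores[i])
            pooled_obs.append(builder.y[va_rows])
        obs = np.concatenate(pooled_obs)
        ss_tot = float(((obs - obs.mean()) ** 2).sum())
        q2s = [
            1.0 - float(((obs - np.concatenate(pooled[i])) ** 2).sum()) / ss_tot
            for i in range(len(grid))
        ]
        hp = grid[_argbest(q2s)]
        fold_hps.append({**hp, "inner_q2": float(max(q2s)), "outer_fold": g})

        fold = builder.fit_fold(train_rows, cross=method.needs_cross,
                                variance_target=variance_target)
        y_pred[test_rows] = method.fit_predict(fold, train_rows, test_rows, hp)
        outer_fold_of_row[test_rows] = g

    if np.isnan(y_pred).any():
        raise AssertionError("some rows were never predicted in the outer loop")
    metric_name = "P2" if mode == "pairwise" else "P2_kin"
    metric = q_squared(builder.y, y_pred)
    predictions = pd.DataFrame({
        "kinase": [builder.kinase_ids[i] for i in builder.k_idx],
        "inhibitor": [builder.inhibitor_ids[i] for i in builder.l_idx],
        "y_obs": builder.y,
        "y_pred": y_pred,
        "outer_fold": outer_fold_of_row,
    })
    roc: dict = {}
    auc = float("nan")
    if compute_roc:
        try:
            roc = roc_analysis(builder.y, y_pred)
            auc = roc["auc"]
        except ValueError:
            pass
    return CVResult(
        method=method.name, mode=mode, metric_name=metric_name, metric=metric,
        predictions=predictions, fold_hyperparameters=fold_hps,
        roc=roc, auc=auc,
        error_fractions=error_histogram(builder.y, y_pred)["cumulative"],
    )


# ---------------------------------------------------------------------------
# Dataset-size sweep
# ---------------------------------------------------------------------------


def _inner_folds_of_rows(rows: np.ndarray, rng: np.random.Generator,
                         cv: int = 5) -> list[tuple[np.ndarray, np.ndarray]]:
    order = rng.permutation(rows)
    folds = np.array_split(order, cv)
    return [
        (np.setdiff1d(order, va), va) for va in folds
    ]


def dataset_size_sweep(
    builder: DesignBuilder,
    method: Method,
    fractions: tuple[float, ...] = (0.8, 0.6, 0.4, 0.2, 0.1),
    n_repeats: int = 10,
    mode: str = "pairwise",
    seed: int = 0,
    variance_target: float = 0.95,
) -> pd.DataFrame:
    """Train on a fraction of the panel, evaluate on the remainder.

    Pairwise mode samples pairs; kinasewise mode samples whole kinases.
    Each fraction is repeated ``n_repeats`` times with fresh random splits;
    the table reports mean and sd of the outer metric and of AUC.
    """
    rng = np.random.default_rng(seed)
    grid = method.grid()
    records = []
    for frac in fractions:
        for rep in range(n_repeats):
            if mode == "pairwise":
                n_train = max(int(round(frac * builder.n_rows)), 10)
                train_rows = rng.choice(builder.n_rows, size=n_train,
                                        replace=False)
            elif mode == "kinasewise":
                n_kin = len(builder.kinase_ids)
                n_train = max(int(round(frac * n_kin)), 2)
                train_kin = rng.choice(n_kin, size=n_train, replace=False)
                train_rows = np.flatnonzero(np.isin(builder.k_idx, train_kin))
            else:
                raise ValueError(f"unknown mode {mode!r}")
            test_rows = np.setdiff1d(np.arange(builder.n_rows), train_rows)
            if frac >= 1.0 or len(test_rows) == 0:
                result = double_cv(builder, method, mode=mode, seed=seed,
                                   variance_target=variance_target)
                records.append({"fraction": frac, "repeat": rep,
                                "metric": result.metric, "auc": result.auc})
                continue
            # hyperparameters by 5-fold inner CV on the training subset
            pooled: dict[int, list[np.ndarray]] = {i: [] for i in range(len(grid))}
            pooled_obs = []
            for tr, va in _inner_folds_of_rows(train_rows, rng):
                fold = builder.fit_fold(tr, cross=method.needs_cross,
                                        variance_target=variance_target)
                scores = method.inner_scores(fold, tr, va)
                for i in range(len(grid)):
                    pooled[i].append(scores[i])
                pooled_obs.append(builder.y[va])
            obs = np.concatenate(pooled_obs)
            ss_tot = float(((obs - obs.mean()) ** 2).sum())
            q2s = [
                1.0 - float(((obs - np.concatenate(pooled[i])) ** 2).sum()) / ss_tot
                for i in range(len(grid))
            ]
            hp = grid[_argbest(q2s)]
            fold = builder.fit_fold(train_rows, cross=method.needs_cross,
                                    variance_target=variance_target)
            pred = method.fit_predict(fold, train_rows, test_rows, hp)
            metric = q_squared(builder.y[test_rows], pred)
            try:
                auc = roc_analysis(builder.y[test_rows], pred)["auc"]
            except ValueError:
                auc = float("nan")
            records.append({"fraction": frac, "repeat": rep,
                            "metric": metric, "auc": auc})
    df = pd.DataFrame(records)
    summary = df.groupby("fraction", sort=False).agg(
        metric_mean=("metric", "mean"), metric_sd=("metric", "std"),
        auc_mean=("auc", "mean"), auc_sd=("auc", "std"),
        n=("repeat", "count"),
    ).reset_index()
    return summary
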
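"""Q² metrics, ROC analysis, split plans, double CV and the size sweep."""

import numpy as np
import pytest

from kinopcm.models import Method, PLSMethod
from kinopcm.validation import (
    auc_rank,
    dataset_size_sweep,
    double_cv,
    error_histogram,
    make_split_plan,
    q_squared,
    roc_analysis,
)


# ---------------------------------------------------------------------------
# Q²
# ---------------------------------------------------------------------------

def test_q_squared_reference_points(rng):
    y = rng.standard_normal(50)
    assert q_squared(y, y) == 1.0
    assert abs(q_squared(y, np.full(50, y.mean()))) < 1e-12
    # hand arithmetic: PRESS = 4, SS_tot = 2
    assert q_squared([0, 1, 2], [0, 1, 4]) == -1.0


def test_q_squared_undefined_for_constant_observations():
    with pytest.raises(ValueError, match="undefined_q2"):
        q_squared([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_perfect_and_random(rng):
    y_obs = np.concatenate([np.full(50, 4.0), np.full(50, 7.0)])
    assert roc_analysis(y_obs, y_obs)["auc"] == 1.0
    y_obs = np.where(rng.random(4000) < 0.25, 7.0, 4.0)
    scores = rng.standard_normal(4000)
    assert abs(roc_analysis(y_obs, scores)["auc"] - 0.5) < 0.05


def test_roc_four_point_hand_value():
    # classes (1,1,0,0), scores (0.9, 0.4, 0.6, 0.2): 3 of 4 pos-neg pairs won
    y_obs = np.array([6.0, 6.0, 4.0, 4.0])
    scores = np.array([0.9, 0.4, 0.6, 0.2])
    assert np.isclose(roc_analysis(y_obs, scores)["auc"], 0.75)


def test_roc_trapezoid_equals_rank_statistic(rng):
    y_obs = np.where(rng.random(500) < 0.3, 6.5, 4.0)
    scores = y_obs + 2.0 * rng.standard_normal(500)
    assert abs(roc_analysis(y_obs, scores)["auc"]
               - auc_rank(y_obs, scores)) < 1e-10


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="single-class"):
        roc_analysis([6.0, 7.0], [0.1, 0.2])


def test_roc_specificity_table(rng):
    y_obs = np.where(rng.random(600) < 0.25, 7.0, 4.0)
    scores = y_obs + 0.8 * rng.standard_normal(600)
    table = roc_analysis(y_obs, scores)["specificity_at_sensitivity"]
    assert set(table) == {0.80, 0.90, 0.95}
    assert table[0.80] >= table[0.95]


# ---------------------------------------------------------------------------
# Error histogram
# ---------------------------------------------------------------------------

def test_error_histogram_hand_fractions():
    # absolute errors 0.1, 0.3, 1.5: one within 0.25, two within 0.5 and
    # within 1.0, all within 2.0
    out = error_histogram([0.0, 0.0, 0.0], [0.1, 0.3, 1.5])
    assert [out["cumulative"][e] for e in (0.25, 0.5, 1.0, 2.0)] == \
        [1 / 3, 2 / 3, 2 / 3, 1.0]
    perfect = error_histogram([1.0, 2.0], [1.0, 2.0])
    assert all(v == 1.0 for v in perfect["cumulative"].values())
    fr = list(out["cumulative"].values())
    assert all(a <= b for a, b in zip(fr, fr[1:]))


# ---------------------------------------------------------------------------
# Split plans
# ---------------------------------------------------------------------------

def test_split_plans_disjoint_exhaustive(small_builder):
    for mode in ("pairwise", "kinasewise"):
        plan = make_split_plan(small_builder, mode, n_parts=25, seed=1)
        assert plan.part_of_row.shape == (small_builder.n_rows,)
        assert set(plan.part_of_row) == set(range(25))
    plan = make_split_plan(small_builder, "kinasewise", 25, seed=1)
    # all pairs of a kinase share one part
    for k in range(len(small_builder.kinase_ids)):
        parts = plan.part_of_row[small_builder.k_idx == k]
        assert len(set(parts)) == 1


def test_kinasewise_plan_needs_enough_kinases(small_builder):
    with pytest.raises(ValueError, match="kinases"):
        make_split_plan(small_builder, "kinasewise", n_parts=1000, seed=0)


# ---------------------------------------------------------------------------
# Double CV
# ---------------------------------------------------------------------------

class MeanOnlyMethod(Method):
    """Predicts the training mean; a null model scoring P² near 0."""

    name = "mean_only"

    def grid(self):
        return [{}]

    def fit_predict(self, fold, train_rows, eval_rows, hp):
        return np.full(len(eval_rows), fold.y_raw(train_rows).mean())


@pytest.fixture(scope="module")
def pls_cv_results(small_builder):
    method = PLSMethod(max_components=6)
    return {
        mode: double_cv(small_builder, method, mode=mode, seed=7)
        for mode in ("pairwise", "kinasewise")
    }


def test_double_cv_every_row_predicted_once(small_builder, pls_cv_results):
    for mode, result in pls_cv_results.items():
        df = result.predictions
        assert len(df) == small_builder.n_rows
        assert df["y_pred"].notna().all()
        assert set(df["outer_fold"]) == set(range(5))


def test_double_cv_kinasewise_outer_purity(pls_cv_results):
    df = pls_cv_results["kinasewise"].predictions
    folds_per_kinase = df.groupby("kinase")["outer_fold"].nunique()
    assert (folds_per_kinase == 1).all()


def test_double_cv_metric_matches_manual_recomputation(pls_cv_results):
    for result in pls_cv_results.values():
        df = result.predictions
        manual = q_squared(df["y_obs"].to_numpy(), df["y_pred"].to_numpy())
        assert np.isclose(result.metric, manual)


def test_double_cv_reports_roc_and_errors(pls_cv_results):
    r = pls_cv_results["pairwise"]
    assert 0.5 < r.auc <= 1.0
    fr = [r.error_fractions[e] for e in (0.25, 0.5, 1.0, 2.0)]
    assert all(a <= b for a, b in zip(fr, fr[1:]))
    assert len(r.fold_hyperparameters) == 5


def test_double_cv_mean_only_model_scores_near_zero(small_builder):
    result = double_cv(small_builder, MeanOnlyMethod(), mode="pairwise",
                       seed=2, compute_roc=False)
    assert abs(result.metric) < 0.1


def test_double_cv_part_sizes(small_builder, pls_cv_results):
    df = pls_cv_results["pairwise"].predictions
    sizes = df.groupby("outer_fold").size()
    expect = small_builder.n_rows / 5
    assert np.all(np.abs(sizes - expect) <= 25)


# ---------------------------------------------------------------------------
# Dataset-size sweep
# ---------------------------------------------------------------------------

def test_size_sweep_deterministic_and_ordered(small_builder):
    method = PLSMethod(max_components=4)
    kw = dict(fractions=(0.8, 0.2), n_repeats=2, mode="pairwise", seed=5)
    a = dataset_size_sweep(small_builder, method, **kw)
    b = dataset_size_sweep(small_builder, method, **kw)
    assert a.equals(b)
    assert list(a["fraction"]) == [0.8, 0.2]
    big, small = a["metric_mean"].to_numpy()
    assert big >= small - 0.1  # larger training fraction at least as good
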
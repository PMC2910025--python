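"""Correlation methods: PLS (with independent oracle), PLS-DA, SVR, k-NN,
and the M5-style model tree."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from kinopcm.models import (
    M5ModelTree,
    knn_weighted,
    model_tree_fit,
    nipals_pls,
    pls_fit,
    plsda_fit,
    svr_fit,
)
from kinopcm.preprocessing import DesignMatrix


def _design(x, y, n_lig=None):
    n_lig = n_lig if n_lig is not None else x.shape[1] // 2
    return DesignMatrix(
        x=x, y=y - y.mean(), y_mean=float(y.mean()),
        kinase_ids=[f"k{i}" for i in range(len(y))],
        inhibitor_ids=[f"l{i}" for i in range(len(y))],
        inactive=np.zeros(len(y), bool),
        block_slices={"ligand": slice(0, n_lig),
                      "kinase": slice(n_lig, x.shape[1])},
    )


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

def test_pls_matches_sklearn_oracle(rng):
    x = rng.standard_normal((50, 20))
    y = x @ rng.standard_normal(20) + 0.3 * rng.standard_normal(50)
    for a in (1, 3, 7):
        ours = nipals_pls(x, y, a)
        oracle = PLSRegression(n_components=a, scale=False).fit(x, y)
        assert np.allclose(ours.predict(x), oracle.predict(x).ravel(),
                           atol=1e-6)


def test_pls_exact_fit_limit(rng):
    x = rng.standard_normal((30, 5))
    beta = rng.standard_normal(5)
    y = x @ beta
    model = nipals_pls(x, y, 5)
    assert np.max(np.abs(model.predict(x) - y)) < 1e-8


def test_pls_first_weight_tracks_informative_column(rng):
    x = rng.standard_normal((60, 6))
    y = 3.0 * x[:, 2] + 0.01 * rng.standard_normal(60)
    model = nipals_pls(x, y, 1)
    w = np.abs(model.weights[:, 0])
    assert np.argmax(w) == 2 and w[2] > 0.9


def test_pls_coefficient_path_equals_score_path(rng):
    x = rng.standard_normal((40, 12))
    y = x @ rng.standard_normal(12) + rng.standard_normal(40)
    model = nipals_pls(x, y, 6)
    x_new = rng.standard_normal((15, 12))
    assert np.allclose(model.predict(x_new),
                       model.predict_via_scores(x_new), atol=1e-8)
    per = model.predict_per_component(x_new)
    assert np.allclose(per[:, -1], model.predict(x_new), atol=1e-8)


def test_pls_degenerate_response_rejected(rng):
    x = rng.standard_normal((10, 4))
    with pytest.raises(ValueError, match="degenerate"):
        nipals_pls(x, np.full(10, 2.0), 2)


def test_pls_fit_on_design(rng):
    x = rng.standard_normal((25, 8))
    y = x @ rng.standard_normal(8) + 7.0
    design = _design(x, y)
    model = pls_fit(design, 4)
    assert np.corrcoef(design.decenter(model.predict(x)), y)[0, 1] > 0.9


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def test_plsda_shuffled_labels_score_near_zero(rng):
    x = rng.standard_normal((60, 20))
    labels = [f"g{i % 3}" for i in range(60)]
    _, rep = plsda_fit(x, labels, n_components=3, seed=0)
    assert rep["q2_overall"] < 0.15


def test_plsda_identical_classes_inseparable(rng):
    base = rng.standard_normal(10)
    x = np.tile(base, (20, 1)) + 0.01 * rng.standard_normal((20, 10))
    labels = ["a"] * 10 + ["b"] * 10
    _, rep = plsda_fit(x, labels, n_components=2, seed=0)
    assert rep["q2_overall"] < 0.1


def test_plsda_singleton_class_rejected(rng):
    with pytest.raises(ValueError, match="singleton"):
        plsda_fit(rng.standard_normal((5, 3)), ["a", "a", "a", "a", "b"])


def test_plsda_separates_synthetic_groups(small_panel):
    import warnings
    from kinopcm.descriptors import describe_set
    from kinopcm.preprocessing import autoscale
    blk = describe_set(small_panel.msa, "aligned_z")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        x, _ = autoscale(blk)
    labels = [s.group for s in small_panel.sequences]
    _, rep = plsda_fit(x.values(), labels, n_components=8, seed=0)
    assert rep["q2_overall"] >= 0.6


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

def test_svr_beats_linear_pls_on_smooth_nonlinearity(rng):
    x = rng.uniform(-2, 2, size=(150, 2))
    y = np.sin(x[:, 0]) * np.cos(x[:, 1]) + 0.05 * rng.standard_normal(150)
    design = _design(x, y, n_lig=1)
    fitted = svr_fit(design, gamma_grid=(0.25, 1.0), c_grid=(1.0, 10.0), seed=0)
    svr_q2 = max(fitted.search.inner_q2)
    # linear PLS inner CV on the same folds cannot express the interaction
    order = np.random.default_rng(0).permutation(150)
    folds = np.array_split(order, 5)
    pred = np.empty(150)
    for va in folds:
        tr = np.setdiff1d(order, va)
        model = nipals_pls(x[tr], design.y[tr], 2)
        pred[va] = model.predict(x[va])
    ss = ((design.y - pred) ** 2).sum() / ((design.y - design.y.mean()) ** 2).sum()
    assert svr_q2 > 1 - ss


def test_svr_small_c_collapses_to_mean(rng):
    x = rng.standard_normal((40, 3))
    y = x @ np.array([2.0, -1.0, 0.5]) + 5.0
    design = _design(x, y)
    fitted = svr_fit(design, gamma_grid=(0.5,), c_grid=(1e-6,), seed=0)
    pred = fitted.predict(x)
    assert np.std(pred) < 0.1 * np.std(y)


def test_svr_epsilon_tube_on_duplicates(rng):
    x = np.repeat(rng.standard_normal((8, 2)), 4, axis=0)
    y = np.repeat(rng.standard_normal(8), 4) * 3.0
    design = _design(x, y)
    fitted = svr_fit(design, gamma_grid=(1.0,), c_grid=(1000.0,),
                     epsilon=0.05, seed=0)
    assert np.max(np.abs(fitted.predict(x) - y)) < 0.2


def test_svr_rejects_bad_grids(rng):
    design = _design(rng.standard_normal((10, 2)), rng.standard_normal(10))
    with pytest.raises(ValueError):
        svr_fit(design, gamma_grid=(), c_grid=(1.0,))
    with pytest.raises(ValueError, match="non-finite"):
        svr_fit(design, gamma_grid=(np.nan,), c_grid=(1.0,))


# ---------------------------------------------------------------------------
# k-NN
# ---------------------------------------------------------------------------

def test_knn_hand_computed_weighted_mean():
    # distances 1 and 3, y = 4 and 8 -> (4/1 + 8/3)/(1 + 1/3) = 5.0
    d2 = np.array([[1.0, 9.0]])
    y = np.array([4.0, 8.0])
    assert np.isclose(knn_weighted(d2, y, 2)[0], 5.0)


def test_knn_exact_match_returns_neighbor_and_ties_average():
    d2 = np.array([[0.0, 4.0, 0.0]])
    y = np.array([2.0, 9.0, 4.0])
    assert np.isclose(knn_weighted(d2, y, 3)[0], 3.0)  # mean of the two ties
    d2 = np.array([[0.0, 4.0]])
    assert np.isclose(knn_weighted(d2, np.array([7.0, 1.0]), 1)[0], 7.0)


def test_knn_all_inactive_neighborhood_predicts_floor():
    d2 = np.array([[1.0, 2.0, 3.0]])
    y = np.array([4.0, 4.0, 4.0])  # all neighbours floored
    assert knn_weighted(d2, y, 3)[0] == 4.0


def test_knn_k_exceeding_train_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        knn_weighted(np.ones((1, 2)), np.ones(2), 5)


def test_knn_kinase_weight_steers_neighbor_ranking(small_builder):
    """Extreme kinase-block weights rank neighbours purely by one block."""
    from kinopcm.models import KNNMethod
    rows = np.arange(small_builder.n_rows)
    rng = np.random.default_rng(1)
    train = np.sort(rng.choice(rows, 200, replace=False))
    test = np.setdiff1d(rows, train)[:20]
    fold = small_builder.fit_fold(train)
    m = KNNMethod()
    d2_lig, d2_kin = m._distance_parts(fold, train, test)
    tiny = d2_lig + 1e-8 * d2_kin
    huge = d2_lig / 1e8 + d2_kin
    # nearest-neighbour distances coincide with the pure-block ones (indices
    # may differ under exact ties, e.g. pairs sharing an inhibitor)
    assert np.allclose(np.min(tiny, axis=1), np.min(d2_lig, axis=1), atol=1e-6)
    assert np.allclose(np.min(huge, axis=1), np.min(d2_kin, axis=1), atol=1e-6)


# ---------------------------------------------------------------------------
# Model tree
# ---------------------------------------------------------------------------

def test_tree_recovers_single_split(rng):
    x = rng.uniform(0, 1, size=(200, 3))
    y = np.where(x[:, 1] <= 0.5, 1.0, 5.0) + 0.01 * rng.standard_normal(200)
    tree = M5ModelTree(min_leaf=10).fit(x, y)
    assert tree.root.feature == 1
    assert abs(tree.root.threshold - 0.5) < 0.05
    pred = tree.predict(np.array([[0.5, 0.1, 0.5], [0.5, 0.9, 0.5]]))
    assert abs(pred[0] - 1.0) < 0.3 and abs(pred[1] - 5.0) < 0.3


def test_tree_collapses_on_pure_linear_response(rng):
    x = rng.standard_normal((150, 4))
    beta = np.array([1.0, -2.0, 0.5, 3.0])
    y = x @ beta
    tree = M5ModelTree(min_leaf=10).fit(x, y)
    assert tree.n_leaves <= 3
    # node models use subtree attributes only, so compare against the least
    # squares fit restricted to the same attributes
    attrs = tree.root.attrs if not tree.root.is_leaf or tree.root.attrs else \
        tuple(range(4))
    a1 = np.column_stack([np.ones(150), x[:, list(attrs)]])
    lsq = np.linalg.lstsq(a1, y, rcond=None)[0]
    b0, b = tree.root.model
    assert abs(b0 - lsq[0]) < 0.2
    assert np.allclose(b, lsq[1:], atol=0.2)
    resid = tree.predict(x) - y
    assert 1 - resid.var() / y.var() > 0.95


def test_tree_min_leaf_n_gives_single_leaf(rng):
    x = rng.standard_normal((30, 2))
    y = x[:, 0] + rng.standard_normal(30)
    tree = M5ModelTree(min_leaf=30).fit(x, y)
    assert tree.n_leaves == 1


def test_tree_constant_response_single_leaf(rng):
    x = rng.standard_normal((20, 2))
    tree = M5ModelTree(min_leaf=4).fit(x, np.full(20, 3.0))
    assert tree.n_leaves == 1
    assert np.allclose(tree.predict(x), 3.0)


def test_model_tree_fit_selects_by_inner_cv(rng):
    x = rng.uniform(0, 1, (120, 2))
    y = np.where(x[:, 0] <= 0.5, 0.0, 4.0) + 0.1 * rng.standard_normal(120)
    fitted = model_tree_fit(_design(x, y), min_leaf_grid=(4, 8), seed=0)
    assert fitted.search.selected == fitted.hyperparameters
    assert max(fitted.search.inner_q2) > 0.7
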
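"""PLS core: Z-scoring, NIPALS fits, orthogonalization, VIP, serialization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cytopls as cp
from cytopls.pls import (
    PlsError,
    load_model,
    loadings_table,
    save_model,
    scores_table,
)


# ---------------------------------------------------------------------------
# zscore
# ---------------------------------------------------------------------------

def test_zscore_symmetric_column_with_sample_sd():
    sc = cp.zscore(np.array([[1.0], [2.0], [3.0]]))
    np.testing.assert_allclose(sc.X[:, 0], [-1.0, 0.0, 1.0])


def test_zscore_columns_are_centered_and_unit_variance():
    rng = np.random.default_rng(0)
    sc = cp.zscore(rng.lognormal(size=(30, 6)))
    assert np.abs(sc.X.mean(axis=0)).max() < 1e-10
    assert np.abs(sc.X.std(axis=0, ddof=1) - 1).max() < 1e-10


def test_zscore_rejects_constant_and_missing_columns():
    with pytest.raises(PlsError, match="zero-variance"):
        cp.zscore(pd.DataFrame({"IL6": [5.0, 5.0, 5.0], "TNF": [1.0, 2.0, 3.0]}))
    with pytest.raises(PlsError, match="clean"):
        cp.zscore(pd.DataFrame({"IL6": [np.nan, 1.0, 2.0]}))


def test_heldout_rows_use_training_constants():
    rng = np.random.default_rng(1)
    train, held = rng.normal(10, 3, (20, 4)), rng.normal(10, 3, (5, 4))
    sc = cp.zscore(train)
    np.testing.assert_allclose(sc.transform(held), (held - sc.means) / sc.sds)


# ---------------------------------------------------------------------------
# fit_pls
# ---------------------------------------------------------------------------

def test_rank_one_noiseless_fit_explains_everything():
    rng = np.random.default_rng(2)
    col = rng.standard_normal(15)
    X = np.outer(col, [1.0, -2.0, 0.5])
    y = X[:, 0]
    model = cp.fit_pls(X - X.mean(0), y, 1, mode="regression")
    assert model.ss_y[0] == pytest.approx(model.total_ss_y)


def test_l_exceeding_rank_errors():
    X = np.outer(np.arange(5.0) - 2, [1.0, 2.0])  # rank 1
    with pytest.raises(PlsError, match="rank"):
        cp.fit_pls(X, np.arange(5.0) - 2, 2, mode="regression")


def test_single_class_errors():
    rng = np.random.default_rng(3)
    with pytest.raises(PlsError, match="two class"):
        cp.fit_pls(rng.standard_normal((6, 3)), ["a"] * 6, 1, mode="discriminant")


def test_weights_are_orthonormal_and_scores_orthogonal(cleaned_scaled):
    panel, _, sc = cleaned_scaled
    model = cp.fit_pls(sc, panel.samples["genotype"], 3, mode="discriminant")
    np.testing.assert_allclose(model.weights.T @ model.weights, np.eye(3), atol=1e-8)
    G = model.scores.T @ model.scores
    norms = np.sqrt(np.diag(G))
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * norms.max() ** 2


def test_ss_y_nonnegative_and_bounded(cleaned_scaled):
    panel, _, sc = cleaned_scaled
    model = cp.fit_pls(sc, panel.samples["genotype"], 4, mode="discriminant")
    assert (model.ss_y >= 0).all()
    assert model.ss_y.sum() <= model.total_ss_y + 1e-10


def test_independent_y_explains_little():
    rng = np.random.default_rng(4)
    X = rng.standard_normal((200, 5))
    y = rng.standard_normal(200)
    model = cp.fit_pls(X - X.mean(0), y, 1, mode="regression")
    assert model.ss_y[0] / model.total_ss_y < 0.1


def test_matches_reference_pls_implementation():
    """Predictions agree with scikit-learn's NIPALS PLS within 1e-8."""
    PLSRegression = pytest.importorskip("sklearn.cross_decomposition").PLSRegression
    rng = np.random.default_rng(5)
    for _ in range(10):
        X, y = rng.standard_normal((20, 8)), rng.standard_normal(20)
        sc = cp.zscore(X)
        model = cp.fit_pls(sc, y, 3, mode="regression")
        ref = PLSRegression(n_components=3, scale=False).fit(sc.X, y)
        Xnew = sc.transform(rng.normal(0, 1, (6, 8)) * sc.sds + sc.means)
        np.testing.assert_allclose(model.predict(Xnew), ref.predict(Xnew).ravel(), atol=1e-8)
        # scores and weights agree up to per-component sign
        for l in range(3):
            s = np.sign(model.weights[:, l] @ ref.x_weights_[:, l])
            np.testing.assert_allclose(model.weights[:, l], s * ref.x_weights_[:, l], atol=1e-8)


def test_sign_flip_of_a_component_leaves_predictions_and_vip_unchanged(cleaned_scaled):
    panel, _, sc = cleaned_scaled
    model = cp.fit_pls(sc, panel.samples["genotype"], 3, mode="discriminant")
    flipped = cp.fit_pls(sc, panel.samples["genotype"], 3, mode="discriminant")
    for arr in (flipped.weights, flipped.x_loadings):
        arr[:, 1] *= -1
    flipped.scores[:, 1] *= -1
    flipped.y_loadings[1] *= -1
    np.testing.assert_allclose(flipped.predict(sc.X), model.predict(sc.X), atol=1e-12)
    np.testing.assert_allclose(cp.vip_scores(flipped).vip, cp.vip_scores(model).vip)


def test_scale_equivariance_of_raw_predictors(cleaned_scaled):
    """Multiplying a raw predictor column by c>0 changes nothing after Z-scoring."""
    panel, matrix, sc = cleaned_scaled
    scaled_raw = matrix.values.copy()
    scaled_raw.iloc[:, 0] *= 37.5
    sc2 = cp.zscore(scaled_raw)
    m1 = cp.fit_pls(sc, panel.samples["genotype"], 2, mode="discriminant")
    m2 = cp.fit_pls(sc2, panel.samples["genotype"], 2, mode="discriminant")
    np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-10)
    np.testing.assert_allclose(m1.scores, m2.scores, atol=1e-10)


# ---------------------------------------------------------------------------
# orthogonalize_lv1
# ---------------------------------------------------------------------------

def test_single_lv_orthogonalization_is_identity(cleaned_scaled):
    panel, _, sc = cleaned_scaled
    model = cp.fit_pls(sc, panel.samples["genotype"], 1, mode="discriminant")
    om = cp.orthogonalize_lv1(model)
    np.testing.assert_array_equal(om.scores, model.scores)
    assert om.orthogonalized


def test_orthogonalization_preserves_fitted_values(cleaned_scaled):
    panel, _, sc = cleaned_scaled
    rng = np.random.default_rng(6)
    model = cp.fit_pls(sc, panel.samples["genotype"], 3, mode="discriminant")
    om = cp.orthogonalize_lv1(model)
    assert np.abs(om.predict(sc.X) - model.predict(sc.X)).max() < 1e-8
    held = sc.transform(rng.normal(50, 20, (7, sc.X.shape[1])))
    assert np.abs(om.predict(held) - model.predict(held)).max() < 1e-8


def test_orthogonalization_concentrates_y_covariance_on_lv1():
    """LV1 covariance beats a brute-force rotation grid; later LVs carry none."""
    rng = np.random.default_rng(7)
    for _ in range(5):
        n = 25
        t = rng.standard_normal((n, 2))
        y = t @ [1.0, 0.8] + 0.3 * rng.standard_normal(n)
        X = t @ rng.standard_normal((2, 9)) + 0.05 * rng.standard_normal((n, 9))
        model = cp.fit_pls(cp.zscore(X), y, 2, mode="regression")
        om = cp.orthogonalize_lv1(model)
        yc = model.y_centered
        theta = np.linspace(0, 2 * np.pi, 721)
        grid = np.cos(theta)[:, None] * model.scores[:, 0] + np.sin(theta)[:, None] * model.scores[:, 1]
        best = (grid @ yc).max() / (n - 1)
        ours = om.scores[:, 0] @ yc / (n - 1)
        assert ours >= best - 1e-12
        assert abs(np.corrcoef(om.scores[:, 0], yc)[0, 1]) >= abs(
            np.corrcoef(model.scores[:, 0], yc)[0, 1]
        ) - 1e-12
        assert abs(om.scores[:, 1] @ yc) < 1e-8 * np.linalg.norm(om.scores[:, 1]) * np.linalg.norm(yc)


# ---------------------------------------------------------------------------
# VIP
# ---------------------------------------------------------------------------

def _toy_model(weights, ss_y):
    """Minimal PlsModel shell for exercising the VIP formula directly."""
    m, L = weights.shape
    return cp.PlsModel(
        mode="regression", L=L, weights=weights, x_loadings=weights,
        scores=np.zeros((1, L)), y_loadings=np.zeros(L), ss_y=ss_y,
        total_ss_y=float(ss_y.sum()), y_center=0.0, y_centered=np.zeros(1),
        columns=[f"x{j}" for j in range(m)],
    )


def test_vip_matches_hand_evaluated_formula():
    """m=3, L=2 fixture with hand-set weights and per-LV explained Y.

    VIP_j = sqrt(3 * (w_1j^2*3 + w_2j^2*1) / 4):
    (1,0,0)/(0,.6,.8) weights give 1.5, sqrt(0.27), sqrt(0.48).
    """
    model = _toy_model(np.array([[1.0, 0.0], [0.0, 0.6], [0.0, 0.8]]),
                       np.array([3.0, 1.0]))
    vip = cp.vip_scores(model)
    np.testing.assert_allclose(
        vip.vip.to_numpy(), [1.5, np.sqrt(0.27), np.sqrt(0.48)], atol=1e-12
    )
    assert vip.ranking[0] == "x0"
    assert vip.above_average() == ["x0"]


def test_vip_errors_when_model_explains_nothing():
    with pytest.raises(PlsError, match="explains no"):
        cp.vip_scores(_toy_model(np.eye(2), np.zeros(2)))


def test_equal_weights_give_unit_vip():
    model = cp.fit_pls(np.outer([1.0, -1.0, 0.5, -0.5], np.ones(4)),
                       np.array([1.0, -1.0, 0.5, -0.5]), 1, mode="regression")
    np.testing.assert_allclose(cp.vip_scores(model).vip, 1.0, atol=1e-8)


@given(st.integers(3, 16), st.integers(1, 4), st.integers(0, 10_000))
def test_mean_squared_vip_is_one(m, L, seed):
    rng = np.random.default_rng(seed)
    n = 20
    X = rng.standard_normal((n, m))
    y = X @ rng.standard_normal(m) + 0.5 * rng.standard_normal(n)
    L = min(L, m)
    model = cp.fit_pls(cp.zscore(X), y, L, mode="regression")
    assert (cp.vip_scores(model).vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)
    om = cp.orthogonalize_lv1(model)
    assert (cp.vip_scores(om).vip ** 2).mean() == pytest.approx(1.0, abs=1e-8)


# ---------------------------------------------------------------------------
# serialization / tables
# ---------------------------------------------------------------------------

def test_model_round_trips_through_json(tmp_path, cleaned_scaled):
    panel, _, sc = cleaned_scaled
    model = cp.orthogonalize_lv1(cp.fit_pls(sc, panel.samples["genotype"], 2, mode="discriminant"))
    save_model(model, sc, tmp_path / "model.json")
    loaded, scaler = load_model(tmp_path / "model.json")
    np.testing.assert_array_equal(loaded.weights, model.weights)
    np.testing.assert_array_equal(scaler.means, sc.means)
    assert loaded.y_encoding == model.y_encoding
    assert loaded.orthogonalized
    np.testing.assert_array_equal(loaded.predict(sc.X), model.predict(sc.X))
    assert list(loaded.classify(sc.X)) == list(model.classify(sc.X))


def test_scores_and_loadings_tables(cleaned_scaled):
    panel, _, sc = cleaned_scaled
    model = cp.fit_pls(sc, panel.samples["genotype"], 2, mode="discriminant")
    st_ = scores_table(model, panel.sample_ids, groups=panel.samples["genotype"])
    lt = loadings_table(model)
    assert list(st_.columns) == ["group", "LV1", "LV2"]
    assert {"LV1_loading", "LV2_loading", "VIP", "VIP_gt_1"} <= set(lt.columns)
    assert ((lt["VIP"] > 1) == lt["VIP_gt_1"]).all()
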
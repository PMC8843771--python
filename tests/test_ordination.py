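import numpy as np
import pandas as pd
import pytest

from benthosom.data import ValidationError, hellinger_transform
from benthosom.ordination import (dca_gradient_length, forward_select, pca,
                                  pca_proportions, rda, vif)
from benthosom.ordination import test_axes as rda_axis_test


# ---------------------------------------------------------------- PCA

def test_pca_two_variable_closed_form():
    rng = np.random.default_rng(0)
    a = rng.normal(size=400)
    b = 0.6 * a + 0.8 * rng.normal(size=400)
    df = pd.DataFrame({"a": a, "b": b})
    r = np.corrcoef(a, b)[0, 1]
    res = pca(df)
    assert np.allclose(res.eigenvalues, [1 + r, 1 - r], atol=1e-10)


def test_pca_trace_identity_and_proportions():
    rng = np.random.default_rng(1)
    df = pd.DataFrame(rng.normal(size=(40, 6)) @ rng.normal(size=(6, 6)))
    res = pca(df)
    assert res.eigenvalues.sum() == pytest.approx(6.0, abs=1e-10)
    assert res.prop_explained.sum() == pytest.approx(1.0, abs=1e-10)
    v = res.variable_scores.to_numpy()
    assert np.allclose(v.T @ v, np.eye(6), atol=1e-10)


def test_pca_constant_variable_rejected():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
    with pytest.raises(ValidationError):
        pca(df)


def test_pca_proportion_convention():
    # eigenvalue / number of variables, on the percent scale used in reports
    props = pca_proportions([3.10, 2.74], 13) * 100
    assert round(props[0], 1) == 23.8
    assert round(props[1], 1) == 21.1


# ---------------------------------------------------------------- DCA

def test_short_gradient_recommends_linear(coenocline):
    res = dca_gradient_length(coenocline(2.0, seed=1))
    assert res.gradient_length_sd < 4
    assert res.recommendation == "linear"


def test_long_gradient_recommends_unimodal(coenocline):
    res = dca_gradient_length(coenocline(8.0, seed=1))
    assert res.gradient_length_sd > 4
    assert res.recommendation == "unimodal"


def test_gradient_length_tracks_true_turnover(coenocline):
    for true_len in (2.0, 6.0, 10.0):
        res = dca_gradient_length(coenocline(true_len, seed=2))
        assert res.gradient_length_sd == pytest.approx(true_len, rel=0.25)


def test_gradient_length_invariant_to_site_order(coenocline):
    df = coenocline(5.0, seed=3)
    shuffled = df.sample(frac=1.0, random_state=0)
    a = dca_gradient_length(df).gradient_length_sd
    b = dca_gradient_length(shuffled).gradient_length_sd
    assert a == pytest.approx(b, abs=1e-9)


def test_dca_degenerate_inputs_rejected():
    with pytest.raises(ValidationError):
        dca_gradient_length(pd.DataFrame([[1.0, 2.0]]))
    with pytest.raises(ValidationError, match="empty"):
        dca_gradient_length(pd.DataFrame([[1.0, 0.0], [0.0, 0.0]]))


# ---------------------------------------------------------------- VIF

def test_vif_orthogonal_predictors_are_one():
    x = pd.DataFrame({"a": [1.0, 1.0, -1.0, -1.0],
                      "b": [1.0, -1.0, 1.0, -1.0],
                      "c": [1.0, -1.0, -1.0, 1.0]})
    assert np.allclose(vif(x).to_numpy(), 1.0, atol=1e-10)


def test_vif_duplicate_column_infinite():
    rng = np.random.default_rng(2)
    a = rng.normal(size=10)
    x = pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=10)})
    with pytest.warns(UserWarning, match="collinear"):
        v = vif(x)
    assert np.isinf(v["a"]) and np.isinf(v["b"])


def test_vif_matches_normal_equation_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(9, 3))
    x[:, 2] = 0.7 * x[:, 0] + 0.3 * rng.normal(size=9)
    df = pd.DataFrame(x, columns=["a", "b", "c"])
    v = vif(df)
    for j, name in enumerate(df.columns):
        others = np.column_stack([np.ones(9), np.delete(x, j, axis=1)])
        beta = np.linalg.solve(others.T @ others, others.T @ x[:, j])
        resid = x[:, j] - others @ beta
        r2 = 1 - resid @ resid / np.sum((x[:, j] - x[:, j].mean()) ** 2)
        assert v[name] == pytest.approx(1.0 / (1.0 - r2), abs=1e-10)


# ---------------------------------------------------------------- RDA

def test_rda_with_identity_basis_reproduces_pca_of_y():
    rng = np.random.default_rng(4)
    y = pd.DataFrame(rng.normal(size=(12, 5)))
    x = pd.DataFrame(np.eye(12)[:, :11])       # full-rank site basis
    res = rda(y, x, standardize_x=False)
    yc = y - y.mean()
    pca_eig = np.linalg.svd(yc.to_numpy(), compute_uv=False) ** 2 / 11
    assert np.allclose(res.eigenvalues, pca_eig[:len(res.eigenvalues)],
                       atol=1e-8)
    assert res.constrained_total == pytest.approx(1.0, abs=1e-8)


def test_rda_perfect_linear_fit():
    rng = np.random.default_rng(5)
    x = pd.DataFrame({"grad": rng.normal(size=20)})
    y = pd.DataFrame(np.outer(x["grad"], [1.0, -2.0, 0.5]))
    res = rda(y, x)
    assert res.constrained_total == pytest.approx(1.0, abs=1e-10)
    assert res.prop_explained[0] == pytest.approx(1.0, abs=1e-10)


def test_rda_null_baseline_near_p_over_n_minus_1():
    rng = np.random.default_rng(6)
    reps = 30
    vals = []
    for r in range(reps):
        y = pd.DataFrame(rng.normal(size=(40, 6)))
        x = pd.DataFrame(rng.normal(size=(40, 3)))
        vals.append(rda(y, x).constrained_total)
    assert np.mean(vals) == pytest.approx(3 / 39, rel=0.2)


def test_rda_binary_predictor_orders_group_centroids():
    rng = np.random.default_rng(7)
    g = np.repeat([0.0, 1.0], 10)
    y = pd.DataFrame(np.outer(g, [2.0, 1.0]) + 0.05 * rng.normal(size=(20, 2)))
    res = rda(y, pd.DataFrame({"g": g}))
    s1 = res.site_scores["RDA1"].to_numpy()
    assert abs(np.mean(s1[g == 1]) - np.mean(s1[g == 0])) > 0
    # the binary predictor separates the two groups completely on axis 1
    assert (s1[g == 1].min() > s1[g == 0].max()) or \
           (s1[g == 1].max() < s1[g == 0].min())


def test_rda_monotone_in_added_predictors():
    rng = np.random.default_rng(8)
    y = pd.DataFrame(rng.normal(size=(30, 4)))
    x = pd.DataFrame(rng.normal(size=(30, 5)))
    totals = [rda(y, x.iloc[:, :k]).constrained_total for k in range(1, 6)]
    assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))
    assert all(0 <= t <= 1 for t in totals)


def test_rda_rank_deficient_names_dependent_columns():
    rng = np.random.default_rng(9)
    a = rng.normal(size=15)
    x = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.normal(size=15)})
    y = pd.DataFrame(rng.normal(size=(15, 3)))
    with pytest.raises(ValidationError, match="a"):
        rda(y, x)


# ------------------------------------------------- forward selection

def _signal_dataset(seed, n=40, noise_vars=8, effect=2.0):
    rng = np.random.default_rng(seed)
    grad = rng.normal(size=n)
    y = pd.DataFrame(np.outer(grad, rng.normal(size=5)) * effect
                     + rng.normal(size=(n, 5)))
    x = pd.DataFrame(rng.normal(size=(n, noise_vars)))
    x.insert(0, "signal", grad + 0.1 * rng.normal(size=n))
    return y, x


def test_forward_selection_finds_the_true_predictor():
    first_hits = 0
    for seed in range(10):
        y, x = _signal_dataset(seed)
        res = forward_select(y, x, n_perm=199, alpha=0.05, seed=seed)
        assert res.selected_vars, "nothing selected despite strong signal"
        first_hits += res.selected_vars[0] == "signal"
    assert first_hits >= 9


def test_forward_selection_deterministic_given_seed():
    y, x = _signal_dataset(3)
    a = forward_select(y, x, n_perm=99, seed=42)
    b = forward_select(y, x, n_perm=99, seed=42)
    assert a.selected_vars == b.selected_vars
    pd.testing.assert_frame_equal(a.selection_steps, b.selection_steps)


def test_forward_selection_reports_steps():
    y, x = _signal_dataset(1)
    res = forward_select(y, x, n_perm=99, seed=0)
    steps = res.selection_steps
    assert {"variable", "added_r2", "cum_r2", "p"} <= set(steps.columns)
    assert (steps["p"] < 0.05).all()
    assert steps["cum_r2"].is_monotonic_increasing


# ---------------------------------------------------------- axis tests

def test_axis_test_floor_on_perfect_fit():
    rng = np.random.default_rng(10)
    x = pd.DataFrame({"grad": np.linspace(-2, 2, 25)})
    y = pd.DataFrame(np.outer(x["grad"], [1.0, 0.5, -1.0]))
    res = rda(y, x)
    p = rda_axis_test(res, n_perm=99, seed=0)
    assert p[0] == pytest.approx(1 / 100, abs=1e-12)


def test_axis_test_reproducible():
    rng = np.random.default_rng(11)
    y = pd.DataFrame(rng.normal(size=(20, 4)))
    x = pd.DataFrame(rng.normal(size=(20, 2)))
    res = rda(y, x)
    a = rda_axis_test(res, n_perm=49, seed=5)
    b = rda_axis_test(res, n_perm=49, seed=5)
    assert np.array_equal(a, b)
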
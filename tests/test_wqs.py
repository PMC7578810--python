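import numpy as np
import pandas as pd
import pytest

from conftest import planted_response
from wqslearn import (WeightVector, WQSModel, attribute_weights,
                      bootstrap_weights, fit_wqs_final, fit_wqs_single,
                      fit_wqs_stratified, sensitivity_quadratic,
                      submixture_scan, wqs_index)
from wqslearn.errors import ValidationError
from wqslearn.quantiles import decile_transform
from wqslearn.wqs import _submixture_columns

SIMPLEX_TOL = 1e-9


# -- WeightVector / index ----------------------------------------------------

def test_weight_vector_rejects_off_simplex():
    with pytest.raises(ValidationError):
        WeightVector(np.array([0.5, 0.6]), ("a", "b"))
    with pytest.raises(ValidationError):
        WeightVector(np.array([-0.2, 1.2]), ("a", "b"))


def test_index_bounded_and_uniform_equals_mean_decile(small_Q):
    w = np.full(20, 0.05)
    idx = wqs_index(small_Q, w)
    assert idx.min() >= 0.0 and idx.max() <= 9.0
    np.testing.assert_allclose(idx, small_Q.mean(axis=1), atol=1e-12)


# -- single constrained fit --------------------------------------------------

def test_single_fit_recovers_single_driver_exactly(small_Q):
    y = 3.0 * small_Q["blood_Mn"].to_numpy().astype(float)
    fit = fit_wqs_single(small_Q, y, "pos")
    assert fit.converged
    w = pd.Series(fit.weights, index=small_Q.columns)
    assert w["blood_Mn"] > 0.999
    assert fit.beta1 == pytest.approx(3.0, abs=1e-3)


def test_single_fit_matches_grid_search_c2(rng):
    """c = 2 oracle: a 1e-3-resolution simplex grid search cannot beat the
    optimiser by more than 1e-6 in objective value."""
    n = 150
    Q = pd.DataFrame({"a": rng.integers(0, 10, n), "b": rng.integers(0, 10, n)})
    y = planted_response(Q, [0.3, 0.7], 1.5, 0.5, rng)
    ys = y / y.std()
    fit = fit_wqs_single(Q, y, "pos")

    def objective(a):
        s = Q.to_numpy() @ np.array([a, 1.0 - a])
        X = np.column_stack([np.ones(n), s])
        beta, *_ = np.linalg.lstsq(X, ys, rcond=None)
        beta[1] = max(beta[1], 0.0)  # honour the sign constraint
        r = ys - X @ beta
        return 0.5 * float(r @ r) / n

    grid_best = min(objective(a) for a in np.linspace(0.0, 1.0, 1001))
    assert abs(fit.objective - grid_best) <= 1e-6


def test_single_fit_direction_constraint(small_Q, rng):
    y = planted_response(small_Q, np.full(20, 0.05), -2.0, 0.5, rng)
    fit_neg = fit_wqs_single(small_Q, y, "neg")
    assert fit_neg.beta1 < 0
    fit_pos = fit_wqs_single(small_Q, y, "pos")
    assert fit_pos.beta1 >= 0  # clipped at the boundary


def test_single_fit_duplicated_column_is_equivalent(rng):
    n = 200
    Q = pd.DataFrame({"a": rng.integers(0, 10, n), "b": rng.integers(0, 10, n)})
    y = planted_response(Q, [0.6, 0.4], 2.0, 0.3, rng)
    base = fit_wqs_single(Q, y, "pos")
    Qdup = Q.assign(a2=Q["a"])
    dup = fit_wqs_single(Qdup, y, "pos")
    # the duplicated column splits the original weight; predictions agree
    w = pd.Series(dup.weights, index=Qdup.columns)
    assert w["a"] + w["a2"] == pytest.approx(base.weights[0], abs=1e-4)
    assert dup.objective == pytest.approx(base.objective, abs=1e-8)


def test_single_fit_input_validation(small_Q):
    with pytest.raises(ValidationError):
        fit_wqs_single(small_Q, np.zeros(len(small_Q) - 1), "pos")
    with pytest.raises(ValidationError):
        fit_wqs_single(small_Q, np.full(len(small_Q), np.nan), "pos")
    with pytest.raises(ValidationError):
        fit_wqs_single(small_Q, np.zeros(len(small_Q)), "sideways")


# -- bootstrap ensemble ------------------------------------------------------

def test_bootstrap_weights_simplex_and_deterministic(small_Q, rng):
    y = planted_response(small_Q, np.full(20, 0.05), 1.0, 1.0, rng)
    w1 = bootstrap_weights(small_Q, y, "pos", B=25, seed=4)
    w2 = bootstrap_weights(small_Q, y, "pos", B=25, seed=4)
    assert np.all(w1.w >= 0)
    assert abs(w1.w.sum() - 1.0) < SIMPLEX_TOL
    np.testing.assert_array_equal(w1.w, w2.w)
    assert w1.n_bootstrap_used <= 25
    w3 = bootstrap_weights(small_Q, y, "pos", B=25, seed=5)
    assert not np.array_equal(w1.w, w3.w)


def test_bootstrap_signif_aggregation_differs(small_Q, rng):
    y = planted_response(small_Q, np.full(20, 0.05), 1.0, 1.0, rng)
    wm = bootstrap_weights(small_Q, y, "pos", B=15, seed=4, aggregation="mean")
    ws = bootstrap_weights(small_Q, y, "pos", B=15, seed=4, aggregation="signif")
    assert abs(ws.w.sum() - 1.0) < SIMPLEX_TOL
    assert not np.array_equal(wm.w, ws.w)
    with pytest.raises(ValidationError):
        bootstrap_weights(small_Q, y, "pos", B=15, aggregation="median")


def test_bootstrap_replicates_do_not_depend_on_B(small_Q, rng):
    """Replicate b's resample is a function of (seed, b) only."""
    seen = {}

    def recorder(b, n):
        idx = np.random.default_rng(
            np.random.SeedSequence(9).spawn(b + 1)[-1]).integers(0, n, n)
        seen.setdefault(b, idx)
        return idx

    y = planted_response(small_Q, np.full(20, 0.05), 1.0, 1.0, rng)
    bootstrap_weights(small_Q, y, "pos", B=5, seed=9, sampler=recorder)
    first = {b: v.copy() for b, v in seen.items()}
    w_small = bootstrap_weights(small_Q, y, "pos", B=5, seed=9)
    w_large = bootstrap_weights(small_Q, y, "pos", B=10, seed=9)
    # the aggregate changes with B, but not because earlier draws changed
    assert first.keys() == set(range(5))
    assert w_small.n_bootstrap_used <= w_large.n_bootstrap_used


# -- final model and attribution ---------------------------------------------

def test_final_model_and_interaction(small_Q, small_sex, rng):
    y = planted_response(small_Q, np.full(20, 0.05), 0.5, 0.5, rng,
                         sex=small_sex, beta_girl=2.5)
    w = WeightVector(np.full(20, 0.05), tuple(small_Q.columns))
    fit = fit_wqs_final(small_Q, y, w, "pos", interaction=small_sex)
    assert fit.beta_interaction == pytest.approx(2.0, abs=0.3)
    assert fit.p_interaction < 1e-6
    assert fit.ci_index[0] < fit.beta_index < fit.ci_index[1]
    assert "sex x index" in fit.summary()
    plain = fit_wqs_final(small_Q, y, w, "pos")
    assert plain.beta_interaction is None


def test_attribution_uniform_and_point_mass(small_Q):
    comps = tuple(small_Q.columns)
    uniform = WeightVector(np.full(20, 0.05), comps)
    by_metal = attribute_weights(uniform, "by_metal")
    by_matrix = attribute_weights(uniform, "by_matrix")
    assert all(v == pytest.approx(25.0) for v in by_metal.shares.values())
    assert all(v == pytest.approx(20.0) for v in by_matrix.shares.values())
    point = np.zeros(20)
    point[comps.index("blood_Mn")] = 1.0
    pm = WeightVector(point, comps)
    assert attribute_weights(pm, "by_metal").shares["Mn"] == pytest.approx(100.0)
    assert attribute_weights(pm, "by_matrix").shares["blood"] == pytest.approx(100.0)
    with pytest.raises(ValidationError):
        attribute_weights(uniform, "by_isotope")


def test_attribution_matches_brute_force(small_Q, rng):
    comps = tuple(small_Q.columns)
    w = rng.dirichlet(np.ones(20))
    shares = attribute_weights(WeightVector(w, comps), "by_metal").shares
    for metal in ("Mn", "Pb", "Cr", "Cu"):
        manual = 100.0 * sum(w[i] for i, c in enumerate(comps)
                             if c.endswith("_" + metal))
        assert shares[metal] == pytest.approx(manual, abs=1e-12)
    assert sum(shares.values()) == pytest.approx(100.0)


def test_wqs_model_scale_invariance(small_cohort, rng):
    exposures = small_cohort["exposures"].drop(columns=["subject_id"])
    Q = decile_transform(exposures)
    y = planted_response(Q, np.full(20, 0.05), 1.0, 1.0, rng)
    fit_a = WQSModel(exposures, y, "pos").fit(n_boot=10, seed=3)
    rescaled = exposures.copy()
    rescaled["blood_Mn"] *= 1000.0  # unit change, rank preserving
    fit_b = WQSModel(rescaled, y, "pos").fit(n_boot=10, seed=3)
    np.testing.assert_array_equal(fit_a.weights.w, fit_b.weights.w)
    assert fit_a.beta_index == fit_b.beta_index


# -- stratified, sensitivity, submixtures ------------------------------------

def test_stratified_recovers_opposite_sex_effects(small_Q, small_sex, rng):
    y = planted_response(small_Q, np.full(20, 0.05), -1.5, 0.8, rng,
                         sex=small_sex, beta_girl=1.5)
    girls = fit_wqs_stratified(small_Q, y, small_sex, "pos", B=20, seed=2,
                               min_stratum=20)["girl"]
    boys = fit_wqs_stratified(small_Q, y, small_sex, "neg", B=20, seed=2,
                              min_stratum=20)["boy"]
    assert girls.beta_index > 0 > boys.beta_index
    assert girls.stratum == "girl" and boys.stratum == "boy"
    with pytest.raises(ValidationError):
        fit_wqs_stratified(small_Q, y, small_sex, "pos", min_stratum=1000)


def test_stratified_matches_manual_substratum_fit(small_Q, small_sex, rng):
    """The documented per-stratum seed policy (2*seed girls, 2*seed+1 boys)
    makes each stratum reproducible in isolation."""
    y = planted_response(small_Q, np.full(20, 0.05), 1.0, 1.0, rng)
    out = fit_wqs_stratified(small_Q, y, small_sex, "pos", B=15, seed=6,
                             min_stratum=20)
    mask = np.asarray(small_sex) == "girl"
    w = bootstrap_weights(small_Q[mask], y[mask], "pos", B=15, seed=12)
    manual = fit_wqs_final(small_Q[mask], y[mask], w, "pos", stratum="girl")
    np.testing.assert_array_equal(out["girl"].weights.w, manual.weights.w)
    assert out["girl"].beta_index == manual.beta_index


def test_sensitivity_linear_truth(small_Q, rng):
    y = planted_response(small_Q, np.full(20, 0.05), 1.0, 0.5, rng)
    w = WeightVector(np.full(20, 0.05), tuple(small_Q.columns))
    res = sensitivity_quadratic(small_Q, y, w, "pos")
    assert res.df == 1
    assert res.lrt >= 0.0
    assert res.linear.loglik <= res.quadratic.loglik + 1e-9


def test_sensitivity_detects_planted_quadratic(small_Q, small_sex, rng):
    idx = wqs_index(small_Q, np.full(20, 0.05))
    y = 0.5 * (idx - 4.5) ** 2 + rng.normal(0, 0.3, len(idx))
    w = WeightVector(np.full(20, 0.05), tuple(small_Q.columns))
    res = sensitivity_quadratic(small_Q, y, w, "pos", interaction=small_sex)
    assert res.df == 2
    assert res.p < 1e-6
    assert res.delta_aic < 0
    assert res.quadratic_preferred


def test_submixture_scan_shape_and_bonferroni(small_cohort, rng):
    exposures = small_cohort["exposures"]
    Q = decile_transform(exposures.drop(columns=["subject_id"]))
    y = planted_response(Q, np.full(20, 0.05), 0.0, 1.0, rng)
    sex = small_cohort["subjects"]["sex"].to_numpy()
    scan = submixture_scan(exposures, y, sex, B=5, seed=3)
    assert len(scan) == 36  # 9 subsets x 2 sexes x 2 directions
    np.testing.assert_allclose(scan["p_adjusted"],
                               np.minimum(scan["p"] * 9, 1.0))
    subsets = _submixture_columns(list(Q.columns))
    assert len(subsets) == 9
    assert all(len(cols) in (4, 5) for cols in subsets.values())


def test_bonferroni_arithmetic():
    # raw p = 0.001 among nine subsets -> adjusted 0.009
    assert min(0.001 * 9, 1.0) == pytest.approx(0.009)
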
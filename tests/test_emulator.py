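"""GP emulator machinery: design stratification, the GP equations against a
dense linear-algebra oracle, and the analytic Gaussian-measure integrals
against Monte-Carlo oracles."""

import numpy as np
import pytest

from cardiouq import emulator as E


# ---------------------------------------------------------------------------
# Latin hypercube and input spec
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n,d", [(1, 3), (50, 13), (25, 2)])
def test_lhs_one_point_per_stratum(n, d):
    X = E.latin_hypercube(n, d, seed=4)
    assert X.shape == (n, d)
    for k in range(d):
        strata = np.floor(X[:, k] * n).astype(int)
        assert sorted(strata) == list(range(n))


def test_lhs_deterministic_given_seed():
    assert np.array_equal(E.latin_hypercube(20, 5, seed=11), E.latin_hypercube(20, 5, seed=11))


def test_tp06_input_spec_matches_published_ranges():
    spec = E.tp06_input_spec()
    assert spec.dim == 13
    centre = spec.to_natural(np.full(13, 0.5))
    i_kr = spec.names.index("G_Kr")
    assert centre[i_kr] == pytest.approx(0.153)
    i_na = spec.names.index("G_Na")
    assert spec.mins[i_na] == pytest.approx(7.419)
    assert spec.maxs[i_na] == pytest.approx(22.257)
    # round trip
    u = np.linspace(0.1, 0.9, 13)
    assert np.allclose(spec.to_normalised(spec.to_natural(u)), u)


# ---------------------------------------------------------------------------
# GP fit and predictions
# ---------------------------------------------------------------------------


def _toy_design(n=16, d=2, seed=0, fn=None):
    """Small synthetic design wrapped in DesignData for gp_fit."""
    X = E.latin_hypercube(n, d, seed=seed)
    if fn is None:
        fn = lambda x: np.sin(3 * x[:, 0]) + 0.5 * x[:, 1] ** 2
    y = fn(X)
    return E.DesignData(
        spec=E.InputSpec(tuple(f"x{i}" for i in range(d)), np.ones(d)),
        inputs=X,
        outputs={"y": y},
        apd90_beat19=np.zeros(n),
    )


def test_gp_interpolates_design_points_with_tiny_nugget():
    design = _toy_design()
    em = E.gp_fit(design, "y", nugget=1e-10)
    mu, var = em.predict(design.inputs)
    assert np.allclose(mu, design.outputs["y"], atol=1e-4)
    assert np.all(var < 1e-4 * em.sigma2)


def test_gp_symmetric_1d_fixture():
    """3 points (0 -> 0, 0.5 -> 1, 1 -> 0): symmetric predictions."""
    design = E.DesignData(
        spec=E.InputSpec(("x",), np.ones(1)),
        inputs=np.array([[0.0], [0.5], [1.0]]),
        outputs={"y": np.array([0.0, 1.0, 0.0])},
        apd90_beat19=np.zeros(3),
    )
    em = E.GPEmulator(
        X=design.inputs,
        y=design.outputs["y"],
        ell=np.array([0.4]),
        sigma2=1.0,
        beta=np.zeros(2),
        nugget=1e-10,
    )._finalise()
    m1, _ = em.predict([[0.25]])
    m2, _ = em.predict([[0.75]])
    assert m1[0] == pytest.approx(m2[0], abs=1e-10)


def test_gp_prediction_matches_dense_oracle():
    """Mean and variance against a direct dense evaluation of the universal
    kriging equations (independent implementation with plain inverses)."""
    design = _toy_design(n=20, d=3, seed=2, fn=lambda x: x[:, 0] * np.exp(-x[:, 1]) + x[:, 2])
    em = E.gp_fit(design, "y")
    X, y = em.X, em.y
    n = X.shape[0]

    def kern(A, B):
        out = np.ones((A.shape[0], B.shape[0]))
        for k in range(A.shape[1]):
            out *= np.exp(-0.5 * ((A[:, k, None] - B[None, :, k]) / em.ell[k]) ** 2)
        return out

    R = kern(X, X) + em.nugget * np.eye(n)
    H = np.column_stack([np.ones(n), X])
    Rinv = np.linalg.inv(R)
    G = H.T @ Rinv @ H
    beta = np.linalg.solve(G, H.T @ Rinv @ y)
    assert np.allclose(beta, em.beta, atol=1e-8)

    rng = np.random.default_rng(5)
    Xs = rng.uniform(0, 1, size=(7, 3))
    r = kern(Xs, X)
    hs = np.column_stack([np.ones(7), Xs])
    mean_o = hs @ beta + r @ Rinv @ (y - H @ beta)
    u = hs.T - H.T @ Rinv @ r.T
    var_o = em.sigma2 * (
        1.0 - np.einsum("ij,jk,ik->i", r, Rinv, r) + np.einsum("ji,jk,ki->i", u, np.linalg.inv(G), u)
    )
    mean, var = em.predict(Xs)
    assert np.allclose(mean, mean_o, atol=1e-8)
    assert np.allclose(var, np.maximum(var_o, 0), atol=1e-8)


def test_gp_needs_enough_points():
    design = _toy_design(n=10, d=13, seed=1, fn=lambda x: x[:, 0])
    with pytest.raises(ValueError, match="design points"):
        E.gp_fit(design, "y")


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def test_validation_near_zero_on_own_design():
    design = _toy_design()
    em = E.gp_fit(design, "y", nugget=1e-10)
    # predicting the design points themselves: residuals are ~0; guard only
    # that the statistic is far below the test-data regime
    mean, _ = em.predict(design.inputs)
    assert np.allclose(mean, design.outputs["y"], atol=1e-4)


def test_validation_calibrated_on_gp_draws():
    """Data drawn from the emulator's own predictive distribution gives a
    Mahalanobis distance ~ chi2(m): expectation m, inside a wide band."""
    design = _toy_design(n=25, d=2, seed=3)
    em = E.gp_fit(design, "y")
    rng = np.random.default_rng(17)
    Xs = rng.uniform(0, 1, size=(8, 2))
    mean, cov = em.predict(Xs, full_cov=True, include_noise=True)
    dists = []
    for _ in range(40):
        y_draw = rng.multivariate_normal(mean, cov)
        dists.append(E.validate(em, Xs, y_draw).distance)
    avg = np.mean(dists)
    # mean of chi2(8) is 8; 40 averages have sd ~ sqrt(2*8/40) = 0.63
    assert abs(avg - 8.0) < 2.0


def test_validation_flags_corrupted_output():
    design = _toy_design(n=25, d=2, seed=3)
    em = E.gp_fit(design, "y")
    rng = np.random.default_rng(21)
    Xs = rng.uniform(0, 1, size=(6, 2))
    mean, _ = em.predict(Xs)
    y_bad = mean.copy()
    y_bad[2] += 50.0
    rep = E.validate(em, Xs, y_bad)
    assert rep.distance > rep.upper_95
    assert not rep.passed


# ---------------------------------------------------------------------------
# analytic integrals vs Monte-Carlo oracles
# ---------------------------------------------------------------------------


def _linear_design(a, n=30, seed=6):
    d = a.size
    X = E.latin_hypercube(n, d, seed=seed)
    return _toy_design(n=n, d=d, seed=seed, fn=lambda x: x @ a)


def test_mean_effect_flat_for_ignored_input():
    a = np.array([1.5, 0.0, -0.7])
    em = E.gp_fit(_linear_design(a), "y")
    grid, curve = E.mean_effect(em, 1)
    assert np.ptp(curve) < 1e-3 * np.ptp(E.mean_effect(em, 0)[1])


def test_mean_effect_linear_closed_form():
    a = np.array([2.0, -1.0])
    em = E.gp_fit(_linear_design(a), "y")
    dist = E.InputDistribution.uniform_spec(2)
    grid, curve = E.mean_effect(em, 0, dist)
    expected = a[0] * grid + a[1] * 0.5
    assert np.allclose(curve, expected, atol=5e-3)


def test_mean_effect_matches_mc_oracle():
    design = _toy_design(n=24, d=3, seed=8, fn=lambda x: np.sin(2 * x[:, 0]) * x[:, 1] + x[:, 2])
    em = E.gp_fit(design, "y")
    dist = E.InputDistribution.uniform_spec(3)
    grid = np.array([0.1, 0.5, 0.9])
    _, curve = E.mean_effect(em, 0, dist, grid=grid)
    rng = np.random.default_rng(123)
    n_mc = 100_000
    for g, analytic in zip(grid, curve):
        Xs = rng.normal(dist.mean, np.sqrt(dist.var), size=(n_mc, 3))
        Xs[:, 0] = g
        mc_vals, _ = em.predict(Xs)
        se = mc_vals.std() / np.sqrt(n_mc)
        assert abs(analytic - mc_vals.mean()) < 3 * se + 1e-8


def test_main_effect_index_zero_for_ignored_input():
    a = np.array([1.0, 0.0, 0.5])
    em = E.gp_fit(_linear_design(a), "y")
    assert E.main_effect_index(em, 1) < 0.01


def test_main_effect_index_linear_closed_form():
    """Additive linear function, equal input variances: S_i = a_i^2/sum a^2."""
    a = np.array([3.0, 2.0, 1.0])
    em = E.gp_fit(_linear_design(a), "y")
    S = E.main_effect_indices(em)
    assert np.allclose(S, a ** 2 / np.sum(a ** 2), atol=0.02)
    assert np.all(S >= 0) and np.all(S <= 1.0 + 1e-9)


def test_main_effect_index_matches_mc_double_loop():
    design = _toy_design(n=24, d=3, seed=9, fn=lambda x: x[:, 0] ** 2 + 0.5 * x[:, 1])
    em = E.gp_fit(design, "y")
    dist = E.InputDistribution.uniform_spec(3)
    S0 = E.main_effect_index(em, 0, dist)
    rng = np.random.default_rng(77)
    outer, inner = 300, 3000
    cond_means = np.empty(outer)
    for k, g in enumerate(rng.normal(0.5, 0.2, size=outer)):
        Xs = rng.normal(dist.mean, np.sqrt(dist.var), size=(inner, 3))
        Xs[:, 0] = g
        cond_means[k] = em.predict(Xs)[0].mean()
    total = E.propagate(em, dist).variance_input
    S_mc = cond_means.var(ddof=1) / total
    # outer-loop sampling error on a variance estimate
    se = S_mc * np.sqrt(2.0 / (outer - 1))
    assert abs(S0 - S_mc) < 3 * se + 0.02


def test_propagate_degenerate_measure_reduces_to_prediction():
    design = _toy_design(n=20, d=2, seed=10)
    em = E.gp_fit(design, "y")
    dist = E.InputDistribution(np.array([0.4, 0.6]), np.zeros(2))
    res = E.propagate(em, dist)
    mu, var = em.predict([[0.4, 0.6]])
    assert res.mean == pytest.approx(mu[0], abs=1e-8)
    assert res.variance_input == pytest.approx(0.0, abs=1e-10)
    # both are ~0; agreement limited by roundoff in tr(R^-1 Q) with Q ~ R
    assert res.variance_code == pytest.approx(var[0], abs=1e-6 * em.sigma2)


def test_propagate_linear_surface_closed_form():
    a = np.array([2.0, -1.5])
    em = E.gp_fit(_linear_design(a), "y")
    v = np.array([0.02, 0.01])
    res = E.propagate(em, E.InputDistribution(np.full(2, 0.5), v))
    assert res.variance_input == pytest.approx(np.sum(a ** 2 * v), rel=0.05)
    assert res.mean == pytest.approx(a @ np.full(2, 0.5), abs=0.01)


def test_propagate_matches_mc_oracle():
    design = _toy_design(n=24, d=3, seed=12, fn=lambda x: np.exp(-x[:, 0]) + x[:, 1] * x[:, 2])
    em = E.gp_fit(design, "y")
    dist = E.InputDistribution.uniform_spec(3)
    res = E.propagate(em, dist)
    rng = np.random.default_rng(55)
    n_mc = 100_000
    Xs = rng.normal(dist.mean, np.sqrt(dist.var), size=(n_mc, 3))
    mc, _ = em.predict(Xs)
    se_mean = mc.std() / np.sqrt(n_mc)
    assert res.mean == pytest.approx(mc.mean(), abs=3 * se_mean + 1e-9)
    se_sd = mc.std() / np.sqrt(2 * n_mc)
    assert res.sd == pytest.approx(mc.std(), abs=3 * se_sd + 1e-9)


def test_propagated_variance_monotone_in_input_variance():
    design = _toy_design(n=24, d=3, seed=13)
    em = E.gp_fit(design, "y")
    base = E.InputDistribution.uniform_spec(3, var=0.04)
    v_base = E.propagate(em, base).variance_input
    for i in range(3):
        smaller = E.propagate(em, base.with_var(i, 0.01)).variance_input
        # tolerance: an inert input's spurious GP wiggle can add ~1e-6
        assert smaller <= v_base * (1.0 + 1e-4) + 1e-8
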
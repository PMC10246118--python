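"""The filter itself: predict, correction, updates, learning, bounds."""

import numpy as np
import pytest
from scipy.optimize import minimize

from evkf import expfam
from evkf.baselines import GaussianBelief, kalman_step
from evkf.core import (
    AlgorithmConfig,
    apply_averaged_theta,
    Likelihood,
    NotConjugateError,
    VariationalPosterior,
    bound_gap,
    bound_gap_exact_lingauss,
    conjugate_update,
    cvi_update,
    elbo,
    expected_loglik,
    filter_step,
    free_energy,
    free_energy_exact_lingauss,
    init_state,
    learn_dynamics_step,
    predict_correction,
    run_filter,
    single_step_bound,
    two_step_bound,
    variational_predict,
)
from evkf.dynamics import (
    MLP,
    ConstantDynamics,
    LinearGaussianDynamics,
    NNCBDynamics,
    NNGammaDynamics,
)
from evkf.expfam import (
    ContinuousBernoulliFamily,
    FamilyMismatchError,
    GammaFamily,
    GaussianFamily,
    kl_divergence,
)


def _gauss_post(fam, m, P):
    return VariationalPosterior(fam.from_moments(m, P))


# ----------------------------------------------------------------------
# variational predict
# ----------------------------------------------------------------------

def test_predict_linear_gaussian_exact_mode():
    # q_prev = N(1, 0.5), A=0.9, Q=0.2 -> q_bar = N(0.9, 0.2)
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.9]]), np.array([[0.2]]))
    q_bar = variational_predict(_gauss_post(fam, [1.0], [[0.5]]), dyn)
    m, P = fam.to_moments(q_bar.lam.values)
    assert m[0] == pytest.approx(0.9, abs=1e-12)
    assert P[0, 0] == pytest.approx(0.2, abs=1e-12)


def test_predict_constant_dynamics_any_posterior(rng):
    fam = GaussianFamily(2)
    lam0 = fam.from_moments([0.1, -0.4], 0.7 * np.eye(2)).values
    dyn = ConstantDynamics(fam, lam0)
    for _ in range(3):
        q = _gauss_post(fam, rng.normal(size=2), np.eye(2))
        q_bar = variational_predict(q, dyn, n_mc=8, rng=rng, mode="mc")
        np.testing.assert_allclose(q_bar.lam.values, lam0, atol=1e-12)


def test_predict_mc_converges_to_exact(rng):
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.8]]), np.array([[0.3]]))
    q = _gauss_post(fam, [0.5], [[0.4]])
    exact = variational_predict(q, dyn, mode="exact").lam.values
    # the only stochastic coordinate is the first natural parameter
    Z = expfam.sample(q.lam, 100_000, rng)
    per_sample = dyn.eval_lambda_batch(Z)
    se = per_sample[:, 0].std(ddof=1) / np.sqrt(Z.shape[0])
    mc = variational_predict(q, dyn, n_mc=100_000,
                             rng=np.random.default_rng(0), mode="mc").lam.values
    assert mc[0] == pytest.approx(exact[0], abs=3.5 * se)
    assert mc[1] == pytest.approx(exact[1], abs=1e-12)


def test_predict_family_mismatch():
    fam = ContinuousBernoulliFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.9]]), np.array([[0.2]]))
    with pytest.raises(FamilyMismatchError):
        variational_predict(VariationalPosterior(fam.natural([0.0])), dyn)


# ----------------------------------------------------------------------
# variance correction
# ----------------------------------------------------------------------

def test_correction_scalar_reference():
    # corrected variance 0.2 + 0.81 * 0.5 = 0.605
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.9]]), np.array([[0.2]]))
    q_prev = _gauss_post(fam, [1.0], [[0.5]])
    q_bar = variational_predict(q_prev, dyn)
    corr = predict_correction(q_bar, q_prev, dyn)
    _, P = fam.to_moments(corr.lam.values)
    assert P[0, 0] == pytest.approx(0.605, abs=1e-12)


def test_correction_vanishes_for_delta_prev():
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.9]]), np.array([[0.2]]))
    q_prev = _gauss_post(fam, [1.0], [[1e-12]])
    q_bar = variational_predict(q_prev, dyn)
    corr = predict_correction(q_bar, q_prev, dyn)
    _, P = fam.to_moments(corr.lam.values)
    assert P[0, 0] == pytest.approx(0.2, abs=1e-10)


def test_correction_matches_kalman_predict(rng):
    # random 3-d system: corrected q_bar equals the Kalman prediction moments
    L = 3
    A = rng.normal(size=(L, L)) * 0.4
    W = rng.normal(size=(L, L))
    Q = W @ W.T + 0.4 * np.eye(L)
    dyn = LinearGaussianDynamics(A, Q)
    fam = dyn.family
    m = rng.normal(size=L)
    Wp = rng.normal(size=(L, L))
    P = Wp @ Wp.T + 0.3 * np.eye(L)
    q_prev = _gauss_post(fam, m, P)
    corr = predict_correction(variational_predict(q_prev, dyn), q_prev, dyn)
    mc, Pc = fam.to_moments(corr.lam.values)
    np.testing.assert_allclose(mc, A @ m, atol=1e-10)
    np.testing.assert_allclose(Pc, Q + A @ P @ A.T, atol=1e-10)


def test_underestimation_identity(rng):
    # uncorrected covariance + A P A^T == corrected covariance, exactly
    A = np.array([[0.9, 0.2], [-0.1, 0.7]])
    Q = 0.3 * np.eye(2)
    dyn = LinearGaussianDynamics(A, Q)
    fam = dyn.family
    P = np.array([[0.5, 0.1], [0.1, 0.4]])
    q_prev = _gauss_post(fam, [1.0, -1.0], P)
    q_bar = variational_predict(q_prev, dyn)
    _, P_raw = fam.to_moments(q_bar.lam.values)
    corr = predict_correction(q_bar, q_prev, dyn)
    _, P_corr = fam.to_moments(corr.lam.values)
    np.testing.assert_allclose(P_raw + A @ P @ A.T, P_corr, atol=1e-12)
    np.testing.assert_allclose(P_raw, Q, atol=1e-12)


def test_gamma_correction_widens_variance(rng):
    # law-of-total-variance widening for Gamma dynamics
    gm = GammaFamily(1)
    mlp = MLP([1, 8, 2], rng)
    dyn = NNGammaDynamics(mlp)
    q_prev = VariationalPosterior(gm.from_shape_rate([3.0], [2.0]))
    q_bar = variational_predict(q_prev, dyn, n_mc=2000, rng=rng)
    corr = predict_correction(q_bar, q_prev, dyn, n_mc=4000, rng=rng)
    _, v_raw = q_bar.moments()
    m_raw, _ = q_bar.moments()
    m_corr, v_corr = corr.moments()
    assert v_corr[0] >= v_raw[0] - 1e-10          # never narrower
    np.testing.assert_allclose(m_corr, m_raw, rtol=1e-8)  # mean preserved


def test_cb_correction_widens(rng):
    cb = ContinuousBernoulliFamily(2)
    mlp = MLP([2, 8, 2], rng, weight_scale=3.0)
    dyn = NNCBDynamics(mlp)
    q_prev = VariationalPosterior(cb.natural([1.0, -2.0]))
    q_bar = variational_predict(q_prev, dyn, n_mc=2000, rng=rng)
    corr = predict_correction(q_bar, q_prev, dyn, n_mc=4000, rng=rng)
    _, v_raw = q_bar.moments()
    _, v_corr = corr.moments()
    assert np.all(v_corr >= v_raw - 1e-10)


# ----------------------------------------------------------------------
# updates
# ----------------------------------------------------------------------

def test_conjugate_update_scalar_bayes():
    # q_bar=N(0,1), C=1, b=0, R=1, y=2 -> posterior N(1, 0.5)
    fam = GaussianFamily(1)
    lik = Likelihood("gaussian", [[1.0]], [0.0], R=[[1.0]])
    post = conjugate_update(_gauss_post(fam, [0.0], [[1.0]]), [2.0], lik)
    m, P = fam.to_moments(post.lam.values)
    assert m[0] == pytest.approx(1.0, abs=1e-12)
    assert P[0, 0] == pytest.approx(0.5, abs=1e-12)


def test_conjugate_update_uninformative_limit():
    fam = GaussianFamily(1)
    lik = Likelihood("gaussian", [[1.0]], [0.0], R=[[1e12]])
    q_bar = _gauss_post(fam, [0.3], [[0.7]])
    post = conjugate_update(q_bar, [100.0], lik)
    np.testing.assert_allclose(post.lam.values, q_bar.lam.values, rtol=1e-9)


def test_conjugate_update_rejects_nonconjugate():
    fam = GaussianFamily(1)
    lik = Likelihood("poisson", [[1.0]], [0.0], dt=0.1)
    with pytest.raises(NotConjugateError):
        conjugate_update(_gauss_post(fam, [0.0], [[1.0]]), [1.0], lik)


def test_cvi_equals_conjugate_for_gaussian(rng):
    fam = GaussianFamily(2)
    C = rng.normal(size=(3, 2))
    lik = Likelihood("gaussian", C, np.zeros(3), R=0.5 * np.eye(3))
    q_bar = _gauss_post(fam, [0.2, -0.5], np.array([[0.8, 0.1], [0.1, 0.6]]))
    y = rng.normal(size=3)
    exact = conjugate_update(q_bar, y, lik)
    one_step = cvi_update(q_bar, y, lik, iters=1, step_size=1.0)
    np.testing.assert_allclose(one_step.lam.values, exact.lam.values, atol=1e-12)


def test_cvi_poisson_uninformative_limit():
    fam = GaussianFamily(1)
    lik = Likelihood("poisson", [[1.0]], [-20.0], dt=0.1)
    q_bar = _gauss_post(fam, [0.4], [[0.9]])
    post = cvi_update(q_bar, [0.0], lik, iters=20, step_size=0.5)
    np.testing.assert_allclose(post.lam.values, q_bar.lam.values, atol=1e-6)


def test_cvi_poisson_matches_numerical_elbo_optimum(rng):
    fam = GaussianFamily(1)
    for _ in range(5):
        q_bar = _gauss_post(fam, [rng.normal()], [[np.exp(0.5 * rng.normal())]])
        lik = Likelihood("poisson", [[rng.uniform(0.5, 1.5)]],
                         [rng.uniform(-1, 1)], dt=0.1)
        y = np.array([float(rng.poisson(2.0))])
        post = cvi_update(q_bar, y, lik, iters=100, step_size=0.5)
        m_cvi, P_cvi = fam.to_moments(post.lam.values)

        def neg_elbo(x):
            lam = fam.from_moments([x[0]], [[np.exp(x[1])]])
            return -(expected_loglik(lam, y, lik)
                     - kl_divergence(lam, q_bar.lam))

        res = minimize(neg_elbo, [m_cvi[0], np.log(P_cvi[0, 0])],
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14})
        assert m_cvi[0] == pytest.approx(res.x[0], abs=1e-3)
        assert P_cvi[0, 0] == pytest.approx(np.exp(res.x[1]), abs=1e-3)


def test_cvi_elbo_nondecreasing():
    fam = GaussianFamily(1)
    q_bar = _gauss_post(fam, [0.3], [[0.8]])
    lik = Likelihood("poisson", [[1.0]], [0.5], dt=0.1)
    y = np.array([3.0])
    vals = [elbo(cvi_update(q_bar, y, lik, iters=k, step_size=0.5), q_bar, y, lik)
            for k in range(1, 12)]
    assert np.min(np.diff(vals)) > -1e-9


def test_cvi_cb_gaussian_improves_elbo(rng):
    # CB latent with Gaussian readout: CVI should beat the prior's ELBO
    cb = ContinuousBernoulliFamily(2)
    C = rng.normal(size=(4, 2))
    lik = Likelihood("gaussian", C, np.zeros(4), R=0.05 * np.eye(4))
    z_true = np.array([0.9, 0.2])
    y = C @ z_true + 0.05 * rng.normal(size=4)
    q_bar = VariationalPosterior(cb.natural([0.5, -0.5]))
    post = cvi_update(q_bar, y, lik, iters=50, step_size=0.5)
    assert elbo(post, q_bar, y, lik) > elbo(q_bar, q_bar, y, lik)
    mu, _ = post.moments()
    assert np.all(np.abs(mu - z_true) < 0.2)


# ----------------------------------------------------------------------
# learning
# ----------------------------------------------------------------------

def test_learning_stationary_at_optimum(rng):
    fam = GaussianFamily(1)
    lam_star = fam.from_moments([0.4], [[0.6]])
    dyn = ConstantDynamics(fam, lam_star.values)
    q_prev = _gauss_post(fam, [0.0], [[1.0]])
    theta0 = dyn.get_theta()
    dyn, _, loss = learn_dynamics_step(lam_star, q_prev, dyn, None, n_mc=16,
                                       steps=1, rate=0.5, rng=rng,
                                       optimizer="sgd", loss_mode="natural")
    assert loss == pytest.approx(0.0, abs=1e-20)
    np.testing.assert_allclose(dyn.get_theta(), theta0, atol=1e-12)


def test_lookup_dynamics_drives_loss_and_kl_to_zero(rng):
    # squared natural-parameter loss -> 0 implies KL -> 0
    fam = GaussianFamily(2)
    lam_star = fam.from_moments([0.5, -0.2], np.array([[0.7, 0.1], [0.1, 0.5]]))
    dyn = ConstantDynamics(fam, fam.from_moments([0.0, 0.0], np.eye(2)).values)
    q_prev = _gauss_post(fam, [0.0, 0.0], np.eye(2))
    opt = None
    for _ in range(60):
        dyn, opt, loss = learn_dynamics_step(
            lam_star, q_prev, dyn, opt, n_mc=4, steps=1, rate=0.9, rng=rng,
            optimizer="sgd", loss_mode="natural")
    assert loss < 1e-8
    lam_bar = fam.natural(dyn.lam0)
    assert kl_divergence(lam_star, lam_bar) < 1e-6


def test_online_scalar_parameter_recovery():
    # A_true = 0.9, Q = 0.1, T = 2000, conjugate updates
    from evkf.synth import LDSConfig, simulate_lds

    cfg = LDSConfig(L=1, N=3, T=2000, seed=0, A=np.array([[0.9]]),
                    Q_scale=0.1, R_scale=0.1)
    sim = simulate_lds(cfg)
    dyn = LinearGaussianDynamics(np.zeros((1, 1)), 0.1 * np.eye(1))
    ac = AlgorithmConfig(seed=0, learn_rate=0.05, learn_rate_decay="sqrt",
                         optimizer="sgd")
    state = init_state(dyn, ac)
    state, _ = run_filter(sim.ys, state, sim.likelihood)
    state = apply_averaged_theta(state)
    assert abs(state.dynamics.A[0, 0] - 0.9) < 0.05


# ----------------------------------------------------------------------
# filter_step / run_filter
# ----------------------------------------------------------------------

def _random_lingauss(rng, L=2, N=3):
    A = rng.normal(size=(L, L))
    A *= 0.85 / max(abs(np.linalg.eigvals(A)))
    Q = 0.2 * np.eye(L)
    C = rng.normal(size=(N, L))
    R = 0.4 * np.eye(N)
    return LinearGaussianDynamics(A, Q), Likelihood("gaussian", C, np.zeros(N), R=R)


def test_filter_step_matches_kalman(rng):
    dyn, lik = _random_lingauss(rng)
    ys = rng.normal(size=(100, 3))
    state = init_state(dyn, AlgorithmConfig(learn_steps_per_t=0))
    belief = GaussianBelief(np.zeros(2), np.eye(2))
    fam = dyn.family
    for y in ys:
        state, _ = filter_step(state, y, lik)
        belief = kalman_step(belief, y, dyn.A, dyn.Q, lik.C, lik.b, lik.R)
        m, P = fam.to_moments(state.posterior.lam.values)
        np.testing.assert_allclose(m, belief.m, atol=1e-8)
        np.testing.assert_allclose(P, belief.P, atol=1e-8)


def test_filter_zero_information_keeps_prediction(rng):
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.9]]), np.array([[0.2]]))
    lik = Likelihood("gaussian", [[1.0]], [0.0], R=[[1e12]])
    state = init_state(dyn, AlgorithmConfig(learn_steps_per_t=0))
    for y in rng.normal(size=(20, 1)):
        state, rec = filter_step(state, y, lik)
        np.testing.assert_allclose(rec.lam_star, rec.lam_bar,
                                   rtol=1e-9, atol=1e-9)


def test_filter_determinism(rng):
    dyn1, lik = _random_lingauss(rng)
    import copy
    dyn2 = copy.deepcopy(dyn1)
    ys = rng.normal(size=(30, 3))
    recs1, recs2 = [], []
    for dyn, out in ((dyn1, recs1), (dyn2, recs2)):
        state = init_state(dyn, AlgorithmConfig(seed=99, learn_rate=0.01,
                                                optimizer="sgd"))
        for y in ys:
            state, rec = filter_step(state, y, lik)
            out.append(rec)
    for r1, r2 in zip(recs1, recs2):
        assert np.array_equal(r1.lam_star, r2.lam_star)
        assert r1.elbo == r2.elbo and r1.learn_loss == r2.learn_loss


def test_run_filter_dataframe_schema(rng):
    dyn, lik = _random_lingauss(rng)
    ys = rng.normal(size=(10, 3))
    state = init_state(dyn, AlgorithmConfig(learn_steps_per_t=0))
    state, df = run_filter(ys, state, lik)
    assert list(df.columns) == ["t", "m_0", "m_1", "v_0", "v_1",
                                "elbo", "learn_loss"]
    assert len(df) == 10 and state.t == 10


# ----------------------------------------------------------------------
# free energy and bound gap
# ----------------------------------------------------------------------

def test_free_energy_minimised_by_closed_form(rng):
    # numerical minimisation of F lands on the closed-form lam_bar
    fam = GaussianFamily(2)
    A = np.array([[0.8, 0.2], [-0.1, 0.7]])
    dyn = LinearGaussianDynamics(A, 0.3 * np.eye(2))
    q_prev = _gauss_post(fam, [0.5, -0.3], np.array([[0.6, 0.1], [0.1, 0.4]]))
    closed = dyn.expected_lambda(q_prev.lam)

    def F(x):
        Lc = np.array([[np.exp(x[2]), 0.0], [x[4], np.exp(x[3])]])
        lam = fam.from_moments(x[:2], Lc @ Lc.T)
        return free_energy_exact_lingauss(lam, q_prev, dyn)

    res = minimize(F, np.zeros(5), method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14,
                            "maxiter": 20000, "maxfev": 20000})
    Lc = np.array([[np.exp(res.x[2]), 0.0], [res.x[4], np.exp(res.x[3])]])
    lam_num = fam.from_moments(res.x[:2], Lc @ Lc.T).values
    np.testing.assert_allclose(lam_num, closed, atol=1e-4)


def test_free_energy_closed_form_matches_mc(rng):
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.8]]), np.array([[0.3]]))
    q_prev = _gauss_post(fam, [0.5], [[0.4]])
    lam_bar = fam.from_moments([0.3], [[0.5]])
    exact = free_energy_exact_lingauss(lam_bar, q_prev, dyn)
    mc = free_energy(lam_bar, q_prev, dyn, n_mc=200_000, rng=rng)
    assert mc == pytest.approx(exact, abs=0.02)


def test_free_energy_above_at_perturbations(rng):
    # F at the closed-form lam_bar is below F at random perturbations
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.8]]), np.array([[0.3]]))
    q_prev = _gauss_post(fam, [0.5], [[0.4]])
    lam_opt = VariationalPosterior(fam.natural(dyn.expected_lambda(q_prev.lam)))
    f_opt = free_energy_exact_lingauss(lam_opt.lam, q_prev, dyn)
    for _ in range(50):
        pert = lam_opt.lam.values + rng.normal(scale=0.1, size=2)
        if not fam.is_valid_natural(pert):
            continue
        assert free_energy_exact_lingauss(fam.natural(pert), q_prev, dyn) >= f_opt - 1e-12


def test_bound_gap_nonnegative_all_families(rng):
    # Jensen gap >= 0 by convexity of A, for every family and random config
    from conftest import random_natural
    fams_dyns = [
        (GaussianFamily(2), lambda r: LinearGaussianDynamics(
            r.normal(size=(2, 2)) * 0.4, 0.3 * np.eye(2))),
        (ContinuousBernoulliFamily(2), lambda r: NNCBDynamics(MLP([2, 8, 2], r))),
        (GammaFamily(2), lambda r: NNGammaDynamics(MLP([2, 8, 4], r))),
    ]
    for fam, make in fams_dyns:
        for _ in range(30):
            dyn = make(rng)
            q_prev = VariationalPosterior(random_natural(fam, rng))
            gap, se = bound_gap(q_prev, dyn, n_mc=500, rng=rng)
            assert gap >= -3 * se


def test_bound_gap_vanishes_for_tight_posterior(rng):
    dyn = LinearGaussianDynamics(np.array([[0.9]]), np.array([[0.2]]))
    fam = dyn.family
    q_prev = _gauss_post(fam, [1.0], [[1e-10]])
    gap, _ = bound_gap(q_prev, dyn, n_mc=2000, rng=rng)
    assert gap == pytest.approx(0.0, abs=1e-8)


def test_bound_gap_zero_for_constant_dynamics(rng):
    fam = GaussianFamily(1)
    dyn = ConstantDynamics(fam, fam.from_moments([0.0], [[1.0]]).values)
    q_prev = _gauss_post(fam, [0.5], [[0.7]])
    gap, _ = bound_gap(q_prev, dyn, n_mc=1000, rng=rng)
    assert gap == pytest.approx(0.0, abs=1e-14)


def test_bound_gap_linear_gaussian_closed_form(rng):
    dyn = LinearGaussianDynamics(np.array([[0.9, 0.3], [0.0, 0.7]]),
                                 0.25 * np.eye(2))
    q_prev = _gauss_post(dyn.family, [0.4, -0.6],
                         np.array([[0.5, 0.1], [0.1, 0.3]]))
    exact = bound_gap_exact_lingauss(q_prev, dyn)
    gap, se = bound_gap(q_prev, dyn, n_mc=200_000, rng=rng)
    assert gap == pytest.approx(exact, abs=3.5 * se)


def test_two_step_bound_exceeds_single_step_by_gap(rng):
    # L_t - M_t equals the Jensen gap, evaluated at a common q
    fam = GaussianFamily(1)
    dyn = LinearGaussianDynamics(np.array([[0.8]]), np.array([[0.3]]))
    lik = Likelihood("gaussian", [[1.0]], [0.0], R=[[0.5]])
    q_prev = _gauss_post(fam, [0.5], [[0.4]])
    q_bar = predict_correction(variational_predict(q_prev, dyn), q_prev, dyn)
    y = np.array([0.7])
    q = conjugate_update(q_bar, y, lik)
    q_bar_raw = variational_predict(q_prev, dyn)  # uncorrected prediction
    L_t = two_step_bound(q, q_bar_raw, y, lik)
    M_t = single_step_bound(q, q_prev, dyn, y, lik,
                            n_mc=200_000, rng=rng)
    gap_exact = bound_gap_exact_lingauss(q_prev, dyn)
    assert L_t - M_t == pytest.approx(gap_exact, abs=0.02)
    assert L_t >= M_t - 1e-9
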
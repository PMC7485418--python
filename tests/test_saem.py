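"""SAEM estimation: reproducibility, identifiability, and a quadrature
oracle on a reduced one-parameter problem."""
import numpy as np
import pytest

from pigletpk.datatypes import DoseEvent, Observation, PKDataset, StructuralParams, SubjectCovariates
from pigletpk.model import published_model
from pigletpk.saem import SAEMSettings, fit_saem, sample_conditional
from pigletpk.structural import solve_profile
from pigletpk.synth import GeneratorConfig, StudyDesign, generate_study

SHORT = dict(n_explore=120, n_smooth=60)


@pytest.fixture(scope="module")
def small_noise_study():
    truth = published_model()
    truth.omega = truth.omega * 0.04  # one fifth of the study IIV
    truth.b = 0.05
    return truth, generate_study(StudyDesign(), GeneratorConfig(seed=7, truth=truth))


@pytest.fixture(scope="module")
def small_noise_fit(small_noise_study):
    truth, ds = small_noise_study
    return fit_saem(ds, init=truth.copy(),
                    settings=SAEMSettings(**SHORT, met_covariate=True, seed=1))


def test_seed_reproducibility(small_noise_study):
    """Identical settings and seed give a bit-for-bit identical fit."""
    truth, ds = small_noise_study
    st = SAEMSettings(n_explore=40, n_smooth=20, met_covariate=True, seed=3)
    a = fit_saem(ds, init=truth.copy(), settings=st)
    b = fit_saem(ds, init=truth.copy(), settings=st)
    assert a.estimates.theta == b.estimates.theta
    assert a.estimates.b == b.estimates.b
    assert np.array_equal(a.estimates.omega, b.estimates.omega)
    assert a.loglik == b.loglik


def test_bic_identity(small_noise_fit):
    f = small_noise_fit
    assert f.bic == pytest.approx(-2.0 * f.loglik + f.n_params * np.log(39), rel=1e-12)


def test_low_noise_identifiability(small_noise_fit):
    """With modest variability the fit lands on the generating values."""
    th = small_noise_fit.estimates.theta
    truth = dict(Cl=0.012, Vc=1.35, Q=0.003, Vp=1.18, F_top=0.0784,
                 k_top=3e-4, Lag=26.4, k_po=0.06)
    for name, v in truth.items():
        assert th[name] == pytest.approx(v, rel=0.25), name
    assert small_noise_fit.estimates.beta_cl_met == pytest.approx(-0.892, abs=0.15)
    assert small_noise_fit.estimates.b == pytest.approx(0.05, rel=0.5)


def test_rse_definition(small_noise_fit):
    f = small_noise_fit
    for name in ("Cl", "Vc"):
        se, rse = f.standard_errors.get(name), f.rse_pct.get(name)
        if np.isfinite(se):
            assert rse == pytest.approx(100.0 * se / abs(f.estimates.theta[name]))


def test_convergence_trace_recorded(small_noise_fit):
    tr = small_noise_fit.trace
    assert len(tr) == SHORT["n_explore"] + SHORT["n_smooth"]
    assert {"Cl", "Vc", "b", "omega2_Cl"} <= set(tr.columns)


# ---- one-parameter toy vs adaptive-quadrature MLE -------------------

VC_TOY, B_TOY, OMEGA_TOY, CL_TOY = 2.0, 0.15, 0.3, 0.01
TOY_TIMES = np.array([15.0, 45.0, 90.0, 180.0, 360.0, 720.0, 1080.0, 1440.0])
TOY_FIXED = {"Vc": VC_TOY, "Q": 1e-4, "Vp": 0.5, "F_top": 0.1, "k_top": 3e-4,
             "Lag": 10.0, "k_po": 0.06}


def _toy_dataset(n=20, seed=5):
    rng = np.random.default_rng(seed)
    doses, obs, covs = [], [], []
    for i in range(n):
        sid = f"t{i}"
        cl = CL_TOY * np.exp(OMEGA_TOY * rng.standard_normal())
        phi = StructuralParams(Cl=cl, Vc=VC_TOY, Q=1e-4, Vp=0.5, F_top=0.1,
                               k_top=3e-4, Lag=10.0, F_po=1.0, k_po=0.06)
        doses.append(DoseEvent(sid, 0.0, 10.0, "IV"))
        f = solve_profile(phi, [doses[-1]], TOY_TIMES)
        y = f * (1.0 + B_TOY * rng.standard_normal(TOY_TIMES.size))
        covs.append(SubjectCovariates(sid, "F", 4.0))
        obs.extend(Observation(sid, t, max(yy, 1e-6)) for t, yy in zip(TOY_TIMES, y))
    return PKDataset(doses=doses, observations=obs, covariates=covs, lloq=1e-7)


def _marginal_ll(mu_log_cl, dataset, omega, b):
    """Gauss-Hermite marginal likelihood of the toy model, maximised over
    nothing — the brute-force oracle for the population clearance."""
    z, w = np.polynomial.hermite_e.hermegauss(60)
    w = w / w.sum()
    total = 0.0
    for sid in dataset.subject_ids:
        obs = dataset.observations_for(sid)
        t = np.array([o.time for o in obs])
        y = np.array([o.concentration for o in obs])
        lls = np.empty(z.size)
        for k, zk in enumerate(z):
            cl = np.exp(mu_log_cl + omega * zk)
            phi = StructuralParams(Cl=cl, Vc=VC_TOY, Q=1e-4, Vp=0.5, F_top=0.1,
                                   k_top=3e-4, Lag=10.0, F_po=1.0, k_po=0.06)
            f = solve_profile(phi, dataset.doses_for(sid), t)
            sd = b * np.maximum(f, 1e-12)
            lls[k] = np.sum(-0.5 * ((y - f) / sd) ** 2 - np.log(sd)
                            - 0.5 * np.log(2 * np.pi))
        m = lls.max()
        total += m + np.log(np.sum(w * np.exp(lls - m)))
    return total


@pytest.fixture(scope="module")
def toy_fit():
    ds = _toy_dataset()
    init = published_model()
    init.theta = dict(init.theta, Cl=0.02, **TOY_FIXED)
    init.beta_cl_met = 0.0
    return ds, fit_saem(ds, init=init,
                        settings=SAEMSettings(n_explore=200, n_smooth=120,
                                              met_covariate=False, correlated=(),
                                              fixed=TOY_FIXED, seed=11))


def test_toy_matches_quadrature_mle(toy_fit):
    """The SAEM population clearance agrees with a grid-search MLE under
    adaptive Gauss-Hermite integration to two significant figures."""
    ds, fit = toy_fit
    cl_hat = fit.estimates.theta["Cl"]
    om_hat = float(np.sqrt(fit.estimates.omega[0, 0]))
    b_hat = fit.estimates.b
    grid = np.log(CL_TOY) + np.linspace(-0.5, 0.5, 81)
    lls = [_marginal_ll(m, ds, om_hat, b_hat) for m in grid]
    cl_oracle = float(np.exp(grid[int(np.argmax(lls))]))
    assert cl_hat == pytest.approx(cl_oracle, rel=0.05)


def test_toy_conditional_mean_vs_quadrature(toy_fit):
    """Posterior-mean random effects from MCMC match deterministic
    quadrature posterior means within Monte-Carlo error."""
    ds, fit = toy_fit
    draws = sample_conditional(fit, n_draws=300, seed=2)
    mu = np.log(fit.estimates.theta["Cl"])
    om = float(np.sqrt(fit.estimates.omega[0, 0]))
    b = fit.estimates.b
    z, w = np.polynomial.hermite_e.hermegauss(60)
    w = w / w.sum()
    for sid in list(ds.subject_ids)[:4]:
        obs = ds.observations_for(sid)
        t = np.array([o.time for o in obs])
        y = np.array([o.concentration for o in obs])
        lls = np.empty(z.size)
        for k, zk in enumerate(z):
            phi = StructuralParams(Cl=float(np.exp(mu + om * zk)), Vc=VC_TOY,
                                   Q=1e-4, Vp=0.5, F_top=0.1, k_top=3e-4,
                                   Lag=10.0, F_po=1.0, k_po=0.06)
            f = solve_profile(phi, ds.doses_for(sid), t)
            sd = b * np.maximum(f, 1e-12)
            lls[k] = np.sum(-0.5 * ((y - f) / sd) ** 2 - np.log(sd))
        post = w * np.exp(lls - lls.max())
        post /= post.sum()
        eta_quad = float(np.sum(post * om * z))
        eta_mcmc = float(draws[sid]["eta"][:, 0].mean())
        assert eta_mcmc == pytest.approx(eta_quad, abs=0.12)


def test_prior_dominated_subject():
    """A subject whose every sample is below the quantification limit
    carries almost no information: its conditional distribution reverts
    to the population prior."""
    rng = np.random.default_rng(9)
    doses, obs, covs = [], [], []
    for i in range(6):
        sid = f"s{i}"
        covs.append(SubjectCovariates(sid, "F", 4.0))
        if i < 5:
            cl = CL_TOY * np.exp(OMEGA_TOY * rng.standard_normal())
            phi = StructuralParams(Cl=cl, Vc=VC_TOY, Q=1e-4, Vp=0.5, F_top=0.1,
                                   k_top=3e-4, Lag=10.0, F_po=1.0, k_po=0.06)
            doses.append(DoseEvent(sid, 0.0, 10.0, "IV"))
            f = solve_profile(phi, [doses[-1]], TOY_TIMES)
            y = f * (1.0 + B_TOY * rng.standard_normal(TOY_TIMES.size))
            obs.extend(Observation(sid, t, max(yy, 1e-6))
                       for t, yy in zip(TOY_TIMES, y))
        else:  # microscopic dose: everything censored far below the LLOQ
            doses.append(DoseEvent(sid, 0.0, 1e-6, "IV"))
            obs.extend(Observation(sid, t, 0.002, censored=True)
                       for t in TOY_TIMES)
    ds = PKDataset(doses=doses, observations=obs, covariates=covs, lloq=0.002)
    init = published_model()
    init.theta = dict(init.theta, Cl=0.015, **TOY_FIXED)
    fit = fit_saem(ds, init=init,
                   settings=SAEMSettings(n_explore=120, n_smooth=60,
                                         met_covariate=False, correlated=(),
                                         fixed=TOY_FIXED, seed=4))
    draws = sample_conditional(fit, n_draws=400, seed=5)
    eta_blq = draws["s5"]["eta"][:, 0]
    om_fit = float(np.sqrt(fit.estimates.omega[0, 0]))
    assert abs(eta_blq.mean()) < 0.5 * om_fit
    assert eta_blq.std() == pytest.approx(om_fit, rel=0.5)
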
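"""Stochastic-approximation EM estimation of the population model.

The latent variables are each subject's transformed individual parameters
psi_i ~ N(X_i theta, Omega).  Every iteration alternates

* a simulation step — a few Metropolis-Hastings transitions per subject
  (one independent proposal from the current population prior plus
  adaptive full-vector random walks) targeting p(psi_i | y_i; theta),
  with below-LLOQ observations entering through their censored
  probability mass; censored concentrations are then imputed from the
  corresponding truncated Gaussian so the residual-scale statistic has a
  complete-data form;
* a stochastic-approximation update of the sufficient statistics (step
  size 1 through the exploratory phase, then 1/(k - K1)^0.7 during
  smoothing); and
* an exact M-step: generalised-least-squares fixed effects, block-
  structured covariance (free correlations only inside the configured
  block), and the proportional error scale from the imputed residuals.
  During exploration the variances and the error scale are annealed
  (never shrunk by more than 5 % per iteration) to keep the sampler from
  collapsing into an early local mode.

Standard errors come from a stochastic approximation of the observed
Fisher information (Louis' identity, accumulated over the smoothing
phase); the observed-data log-likelihood is estimated afterwards by
importance sampling with a multivariate-t proposal (df = 5) built from
each subject's conditional draws.  Everything is driven by one seeded
generator, so a refit with the same seed reproduces the fit bit-for-bit.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri

from .model import (CORRELATED_BLOCK, LINKS, PARAM_NAMES, PopulationModel,
                    _loglik_from_pred)
from .structural import conc_profile_arrays

log = logging.getLogger(__name__)

__all__ = ["SAEMSettings", "FitResult", "fit_saem", "sample_conditional",
            "initial_estimates"]


@dataclass
class SAEMSettings:
    n_explore: int = 500
    n_smooth: int = 200
    smooth_power: float = 0.7
    n_rw: int = 2                  # random-walk transitions per iteration
    target_accept: float = 0.30
    anneal: float = 0.95
    met_covariate: bool = True     # MET class on clearance
    fpo_free: bool = False
    correlated: tuple = CORRELATED_BLOCK
    fixed: dict | None = None      # name -> value: no IIV, typical value pinned
    n_loglik_is: int = 500
    loglik_df: float = 5.0
    n_conditional: int = 200       # stored smoothing-phase draws per subject
    seed: int = 0


@dataclass
class FitResult:
    estimates: PopulationModel
    standard_errors: dict
    rse_pct: dict
    cv_pct: dict
    loglik: float
    n_params: int
    bic: float
    trace: pd.DataFrame
    met: dict
    settings: SAEMSettings
    lloq: float = 0.002
    # internal state enabling conditional sampling and diagnostics
    _subjects: list = field(repr=False, default_factory=list)
    _psi: np.ndarray = field(repr=False, default=None)
    _draws: dict = field(repr=False, default_factory=dict)

    @property
    def theta(self) -> dict:
        return self.estimates.theta


# ---------------------------------------------------------------------
# dataset preprocessing

_ROUTE_CODE = {"IV": 0, "IM": 0, "PO": 1, "TD": 2}


def _prepare_subjects(dataset, need_met: bool):
    subs = []
    for cov in dataset.covariates:
        sid = cov.subject_id
        doses = dataset.doses_for(sid)
        obs = dataset.observations_for(sid)
        if not obs:
            continue
        met = cov.MET
        if need_met and met is None:
            raise ValueError(f"subject {sid} lacks a MET label; classify metabolizers "
                             "before fitting with the MET covariate")
        subs.append({
            "sid": sid,
            "dose_t": np.array([d.time for d in doses]),
            "dose_a": np.array([d.amount for d in doses]),
            "dose_code": np.array([_ROUTE_CODE[d.route] for d in doses]),
            "obs_t": np.array([o.time for o in obs]),
            "y": np.array([o.concentration for o in obs]),
            "cens": np.array([o.censored for o in obs]),
            "met": int(met) if met is not None else 0,
        })
    if len(subs) < 2:
        raise ValueError("need at least 2 subjects with observations")
    return subs


# ---------------------------------------------------------------------
# psi -> structural phi fast path

def _phi_indices(param_names):
    """Map the random-effect order onto the structural phi layout
    (Cl, Vc, Q, Vp, F_top, k_top, Lag, F_po, k_po)."""
    layout = ("Cl", "Vc", "Q", "Vp", "F_top", "k_top", "Lag", "F_po", "k_po")
    src = []
    for i, n in enumerate(param_names):
        src.append((layout.index(n), i))
    return layout, src


def _make_phi_fn(param_names, fpo_free):
    layout, src = _phi_indices(param_names)
    logit_ix = [i for i, n in enumerate(param_names) if LINKS[n] == "logit"]
    dst = np.array([d for d, _ in src])
    ssrc = np.array([s for _, s in src])

    def phi_from_psi(psi: np.ndarray) -> np.ndarray:
        nat = np.exp(np.minimum(psi, 60.0))  # guard against logit overflow
        for j in logit_ix:
            nat[j] = expit(psi[j])
        phi = np.empty(9)
        phi[7] = 1.0  # F_po unless freed
        phi[dst] = nat[ssrc]
        return phi

    return phi_from_psi


# ---------------------------------------------------------------------
# initial estimates from NCA

def initial_estimates(dataset) -> PopulationModel:
    """Typical values seeded from a quick noncompartmental pass.

    IV profiles give clearance, the back-extrapolated initial
    concentration gives the central volume; the transdermal terminal
    slope is (by flip-flop) the transdermal absorption rate and the
    dose-normalised AUC ratio its bioavailability.  Missing routes fall
    back on generic piglet-scale values.  Spread parameters start wide
    (omega = 0.3, correlations 0, b = 0.3).
    """
    from .pipeline import nca_by_profile
    results = nca_by_profile(dataset)
    by_route = {}
    for r in results:
        by_route.setdefault(r.route, []).append(r)

    def med(route, attr):
        vals = [getattr(r, attr) for r in by_route.get(route, [])]
        vals = [v for v in vals if np.isfinite(v)]
        return float(np.median(vals)) if vals else np.nan

    cl = med("IV", "Cl") / 60.0  # L/h -> L/min
    if not np.isfinite(cl):
        cl = med("PO", "Cl") / 60.0
    if not np.isfinite(cl):
        cl = 0.01
    # with metabolizer labels available, seed the reference-class
    # clearance and the class effect from the labelled NCA clearances
    beta0 = 0.0
    met_map = {c.subject_id: c.MET for c in dataset.covariates}
    if all(v is not None for v in met_map.values()):
        by_class = {0: [], 1: []}
        for r in results:
            if r.route in ("IV", "IM", "PO") and np.isfinite(r.Cl) and r.Cl > 0:
                by_class[met_map[r.subject_id]].append(np.log(r.Cl / 60.0))
        if by_class[0] and by_class[1]:
            m0, m1 = np.mean(by_class[0]), np.mean(by_class[1])
            cl = float(np.exp(m0))
            beta0 = float(m1 - m0)
    c0 = med("IV", "C0") / 1000.0  # µg/L -> mg/L
    doses_iv = [r.dose for r in by_route.get("IV", [])]
    vc = float(np.median(doses_iv)) / c0 if doses_iv and np.isfinite(c0) and c0 > 0 else 1.0
    vss = med("IV", "Vss")
    vp = max(vss - vc, 0.3 * vc) if np.isfinite(vss) else vc
    q = 0.25 * cl
    tmax_po = med("PO", "tmax") * 60.0
    k_po = min(3.0 / tmax_po, 0.5) if np.isfinite(tmax_po) and tmax_po > 0 else 0.05
    lz_td = med("TD", "lambda_z") / 60.0
    k_top = lz_td if np.isfinite(lz_td) and lz_td > 0 else 5e-4
    aucd_td, aucd_iv = med("TD", "AUC_over_dose"), med("IV", "AUC_over_dose")
    if np.isfinite(aucd_td) and np.isfinite(aucd_iv) and aucd_iv > 0:
        f_top = float(np.clip(aucd_td / aucd_iv, 0.01, 0.5))
    else:
        f_top = 0.1
    theta = {"Cl": cl, "Vc": vc, "Q": q, "Vp": vp, "F_top": f_top,
             "k_top": k_top, "Lag": 30.0, "k_po": k_po}
    aucd_po = med("PO", "AUC_over_dose")
    if np.isfinite(aucd_po) and np.isfinite(aucd_iv) and aucd_iv > 0:
        theta["F_po"] = float(np.clip(aucd_po / aucd_iv, 0.5, 0.99))
    return PopulationModel(theta=theta, beta_cl_met=beta0,
                           omega=np.diag([0.09] * len(PARAM_NAMES)), b=0.3)


# ---------------------------------------------------------------------
# the SAEM loop

def fit_saem(dataset, init: PopulationModel | None = None,
             settings: SAEMSettings | None = None) -> FitResult:
    """Fit the population model to a :class:`PKDataset` by SAEM."""
    st = settings or SAEMSettings()
    rng = np.random.default_rng(st.seed)
    subs = _prepare_subjects(dataset, need_met=st.met_covariate)
    N = len(subs)
    lloq = dataset.lloq

    if init is None:
        init = initial_estimates(dataset)
    param_names = PARAM_NAMES + (("F_po",) if st.fpo_free else ())
    d = len(param_names)
    use_beta = st.met_covariate
    p = d + (1 if use_beta else 0)
    i_cl = param_names.index("Cl")
    phi_from_psi = _make_phi_fn(param_names, st.fpo_free)
    if st.fpo_free:
        def phi_full(psi):
            ph = phi_from_psi(psi)
            ph[7] = expit(psi[param_names.index("F_po")])
            return ph
    else:
        phi_full = phi_from_psi

    fixed = dict(st.fixed or {})
    for nm in fixed:
        if nm not in param_names:
            raise ValueError(f"cannot fix unknown parameter {nm!r}")
        if nm in st.correlated:
            raise ValueError(f"fixed parameter {nm!r} cannot carry a free correlation")
    fixed_ix = {param_names.index(nm): v for nm, v in fixed.items()}

    def _link(n, v):
        return np.log(v) if LINKS[n] == "log" else np.log(v / (1 - v))

    # initial theta on the transformed scale
    theta = np.zeros(p)
    init_theta = dict(init.theta)
    init_theta.setdefault("F_po", 0.9)
    init_theta.update(fixed)
    for j, n in enumerate(param_names):
        theta[j] = _link(n, init_theta[n])
    if use_beta:
        theta[d] = init.beta_cl_met
    omega = init.omega.copy() if init.omega.shape == (d, d) else np.diag([0.09] * d)
    for j in fixed_ix:
        omega[j, :] = omega[:, j] = 0.0
        omega[j, j] = 1e-8
    b = init.b

    # per-subject design matrices
    for s in subs:
        X = np.zeros((d, p))
        X[:, :d] = np.eye(d)
        if use_beta:
            X[i_cl, d] = s["met"]
        s["X"] = X

    block_ix = np.array([param_names.index(n) for n in st.correlated], dtype=int)
    diag_ix = np.array([j for j in range(d) if j not in set(block_ix.tolist())],
                       dtype=int)
    met_vec = np.array([s["met"] for s in subs], dtype=float)

    def obs_ll(s, psi):
        f = conc_profile_arrays(phi_full(psi), s["dose_t"], s["dose_a"],
                                s["dose_code"], s["obs_t"])
        return _loglik_from_pred(f, s["y"], s["cens"], b, lloq), f

    # coordinates whose random effect actually enters a subject's
    # predictions (transdermal parameters are inert without a TD dose,
    # the oral rate without a PO dose); inert coordinates are refreshed
    # by exact Gibbs draws from their conditional prior
    for s in subs:
        routes = set(s["dose_code"].tolist())
        active = np.ones(d, bool)
        if 2 not in routes:
            for nm in ("F_top", "k_top", "Lag"):
                active[param_names.index(nm)] = False
        if 1 not in routes:
            active[param_names.index("k_po")] = False
            if st.fpo_free:
                active[param_names.index("F_po")] = False
        for j in fixed_ix:  # pinned coordinates are never MH-updated
            active[j] = False
        s["active"] = active

    # state
    psi = np.stack([s["X"] @ theta for s in subs])
    ll_cur = np.empty(N)
    f_cur = []
    for i, s in enumerate(subs):
        ll_cur[i], f = obs_ll(s, psi[i])
        f_cur.append(f)
    step_scale = np.full(N, 0.4)
    step_comp = np.full((N, d), 0.6)

    # smoothed sufficient statistics
    psi_bar = psi.copy()
    m2_bar = np.einsum("ij,ik->jk", psi, psi)
    ss_b = sum(np.sum(((s["y"] - f) / np.maximum(f, 0.5 * lloq)) ** 2)
               for s, f in zip(subs, f_cur))
    n_obs_total = sum(s["y"].size for s in subs)

    # Fisher accumulation (Louis)
    zeta_slices = _zeta_layout(d, p, block_ix, diag_ix)
    nz = zeta_slices["n"]
    louis_A = np.zeros((nz, nz))
    louis_B = np.zeros((nz, nz))
    louis_g = np.zeros(nz)

    draws = {s["sid"]: [] for s in subs}
    trace_rows = []
    n_iter = st.n_explore + st.n_smooth

    for k in range(1, n_iter + 1):
        exploring = k <= st.n_explore
        gamma = 1.0 if exploring else 1.0 / (k - st.n_explore) ** st.smooth_power
        chol = np.linalg.cholesky(omega + 1e-10 * np.eye(d))
        prec = np.linalg.inv(omega + 1e-10 * np.eye(d))
        mu_i = np.stack([s["X"] @ theta for s in subs])
        # the error scale moved in the last M-step: refresh cached
        # likelihood values from the cached predictions
        for i, s in enumerate(subs):
            ll_cur[i] = _loglik_from_pred(f_cur[i], s["y"], s["cens"], b, lloq)

        # conditional-prior factorisations per activity pattern; inert
        # coordinates enter the sufficient statistics through their exact
        # conditional moments (Rao-Blackwellisation) — sampling them
        # would only inject noise that makes weakly-identified
        # population means random-walk
        cond_cache = {}
        psi_eff = psi.copy()
        extra_cov = np.zeros((d, d))
        adapt_gain = 1.0 / max(k, 10) ** 0.5
        omega_sd = np.sqrt(np.maximum(np.diag(omega), 1e-12))
        for i, s in enumerate(subs):
            active = s["active"]
            # exact Gibbs refresh of likelihood-inert coordinates
            if not active.all():
                key = active.tobytes()
                if key not in cond_cache:
                    ia = np.where(active)[0]
                    ii = np.where(~active)[0]
                    Saa = omega[np.ix_(ia, ia)]
                    Sia = omega[np.ix_(ii, ia)]
                    Sii = omega[np.ix_(ii, ii)]
                    G = Sia @ np.linalg.inv(Saa + 1e-12 * np.eye(ia.size))
                    Lc = np.linalg.cholesky(Sii - G @ Sia.T + 1e-10 * np.eye(ii.size))
                    cond_cache[key] = (ia, ii, G, Lc)
                ia, ii, G, Lc = cond_cache[key]
                cond_mean = mu_i[i][ii] + G @ (psi[i][ia] - mu_i[i][ia])
                psi[i][ii] = cond_mean + Lc @ rng.standard_normal(ii.size)
            # kernel 1: independent draw from the population prior
            prop = mu_i[i] + chol @ rng.standard_normal(d)
            llp, fp = obs_ll(s, prop)
            if np.log(rng.random()) < llp - ll_cur[i]:
                psi[i], ll_cur[i], f_cur[i] = prop, llp, fp
            # kernel 2: componentwise adaptive Metropolis over the
            # likelihood-active coordinates
            r = psi[i] - mu_i[i]
            Pr = prec @ r
            for j in np.where(active)[0]:
                dlt = step_comp[i, j] * omega_sd[j] * rng.standard_normal()
                prop = psi[i].copy()
                prop[j] += dlt
                llp, fp = obs_ll(s, prop)
                dpr = 2.0 * dlt * Pr[j] + dlt * dlt * prec[j, j]
                ok = np.log(rng.random()) < llp - ll_cur[i] - 0.5 * dpr
                if ok:
                    psi[i], ll_cur[i], f_cur[i] = prop, llp, fp
                    r = psi[i] - mu_i[i]
                    Pr = prec @ r
                step_comp[i, j] *= np.exp(((1.0 if ok else 0.0) - st.target_accept)
                                          * adapt_gain)
            # kernel 3: adaptive full-vector random walks
            acc = 0
            for _ in range(st.n_rw):
                prop = psi[i] + step_scale[i] * (chol @ rng.standard_normal(d))
                llp, fp = obs_ll(s, prop)
                dpr = _qform(prec, prop - mu_i[i]) - _qform(prec, psi[i] - mu_i[i])
                if np.log(rng.random()) < llp - ll_cur[i] - 0.5 * dpr:
                    psi[i], ll_cur[i], f_cur[i] = prop, llp, fp
                    acc += 1
            step_scale[i] *= np.exp((acc / st.n_rw - st.target_accept) * adapt_gain)
            # Rao-Blackwellised statistics contribution
            psi_eff[i] = psi[i]
            if not active.all():
                ia, ii, G, Lc = cond_cache[active.tobytes()]
                psi_eff[i, ii] = mu_i[i][ii] + G @ (psi[i][ia] - mu_i[i][ia])
                extra_cov[np.ix_(ii, ii)] += Lc @ Lc.T

        # impute censored observations for the residual statistic
        ss_now = 0.0
        for i, s in enumerate(subs):
            f = f_cur[i]
            g = np.maximum(f, 0.5 * lloq)
            resid = (s["y"] - f) / g
            if np.any(s["cens"]):
                c = s["cens"]
                zmax = (lloq - f[c]) / (b * g[c])
                u = rng.random(int(np.sum(c)))
                z = ndtri(np.clip(u * _ndtr_safe(zmax), 1e-300, 1 - 1e-16))
                resid[c] = b * np.clip(z, -8.0, None)
            ss_now += float(np.sum(resid ** 2))

        # stochastic approximation of the sufficient statistics
        psi_bar += gamma * (psi_eff - psi_bar)
        m2_bar += gamma * (np.einsum("ij,ik->jk", psi_eff, psi_eff) + extra_cov
                           - m2_bar)
        ss_b += gamma * (ss_now - ss_b)

        # M-step: GLS fixed effects, structured covariance, error scale
        A = np.zeros((p, p))
        rhs = np.zeros(p)
        for i, s in enumerate(subs):
            XtP = s["X"].T @ prec
            A += XtP @ s["X"]
            rhs += XtP @ psi_bar[i]
        theta = np.linalg.solve(A, rhs)
        for j, v in fixed_ix.items():
            theta[j] = _link(param_names[j], v)
        mu_new = np.stack([s["X"] @ theta for s in subs])
        S = (m2_bar - mu_new.T @ psi_bar - psi_bar.T @ mu_new
             + mu_new.T @ mu_new) / N
        S = 0.5 * (S + S.T)
        omega_hat = _structure_omega(S, block_ix, diag_ix)
        for j in fixed_ix:
            omega_hat[j, :] = omega_hat[:, j] = 0.0
            omega_hat[j, j] = 1e-8
        b_hat = float(np.sqrt(ss_b / n_obs_total))
        if exploring:  # annealing: no fast collapse of the spread terms
            omega = _anneal_omega(omega_hat, omega, st.anneal, block_ix, diag_ix)
            b = max(b_hat, st.anneal * b)
        else:
            omega, b = omega_hat, b_hat

        if not exploring:
            # Louis accumulation for the observed Fisher information
            zeta = _pack_zeta(theta, omega, b, zeta_slices, block_ix, diag_ix)
            g_vec, H = _complete_grad_hess(zeta, zeta_slices, psi, met_vec, i_cl,
                                           use_beta, ss_now, n_obs_total,
                                           block_ix, diag_ix)
            louis_g += gamma * (g_vec - louis_g)
            louis_A += gamma * (-H - louis_A)
            louis_B += gamma * (np.outer(g_vec, g_vec) - louis_B)
            # store conditional draws for diagnostics / importance sampling
            for i, s in enumerate(subs):
                dq = draws[s["sid"]]
                dq.append(psi[i].copy())
                if len(dq) > st.n_conditional:
                    dq.pop(0)

        if not np.all(np.isfinite(theta)) or not np.isfinite(b):
            raise RuntimeError(f"SAEM diverged at iteration {k}")
        trace_rows.append(_trace_row(k, theta, omega, b, param_names, use_beta, d))

    # ---- assemble results ------------------------------------------
    est_theta = {}
    for j, n in enumerate(param_names):
        est_theta[n] = float(np.exp(theta[j])) if LINKS[n] == "log" else float(expit(theta[j]))
    model = PopulationModel(theta={n: est_theta[n] for n in param_names if n != "F_po"}
                            if not st.fpo_free else est_theta,
                            beta_cl_met=float(theta[d]) if use_beta else 0.0,
                            omega=omega, b=b, fpo_free=st.fpo_free)

    draws_arr = {sid: np.array(v) for sid, v in draws.items()}
    ll = _loglik_importance(subs, draws_arr, theta, omega, b, lloq, phi_full,
                            st, rng)
    n_params = p + d + len(block_ix) * (len(block_ix) - 1) // 2 + 1
    bic = -2.0 * ll + n_params * np.log(N)

    ses, rses = _standard_errors(theta, omega, b, zeta_slices, louis_A, louis_B,
                                 louis_g, param_names, use_beta, d, block_ix, diag_ix)
    cvs = model.cv_pct()
    met = {s["sid"]: s["met"] for s in subs}
    return FitResult(estimates=model, standard_errors=ses, rse_pct=rses,
                     cv_pct=cvs, loglik=float(ll), n_params=n_params,
                     bic=float(bic), trace=pd.DataFrame(trace_rows), met=met,
                     settings=st, lloq=lloq, _subjects=subs, _psi=psi,
                     _draws=draws_arr)


def _qform(P, v):
    return float(v @ P @ v)


def _ndtr_safe(z):
    from scipy.special import ndtr
    return np.maximum(ndtr(z), 1e-300)


def _structure_omega(S, block_ix, diag_ix):
    d = S.shape[0]
    om = np.zeros((d, d))
    om[np.ix_(block_ix, block_ix)] = _nearest_psd(S[np.ix_(block_ix, block_ix)])
    om[diag_ix, diag_ix] = np.maximum(S[diag_ix, diag_ix], 1e-8)
    np.fill_diagonal(om, np.maximum(np.diag(om), 1e-8))
    return om


def _nearest_psd(M, floor=1e-8):
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    return (V * np.maximum(w, floor)) @ V.T


def _anneal_omega(om_hat, om_prev, anneal, block_ix, diag_ix):
    """Floor each variance at `anneal` times its previous value while
    keeping the estimated correlation structure."""
    d = om_hat.shape[0]
    v_hat = np.diag(om_hat)
    v = np.maximum(v_hat, anneal * np.diag(om_prev))
    scale = np.sqrt(v / np.maximum(v_hat, 1e-300))
    om = om_hat * np.outer(scale, scale)
    np.fill_diagonal(om, v)
    return om


def _trace_row(k, theta, omega, b, param_names, use_beta, d):
    row = {"iteration": k}
    for j, n in enumerate(param_names):
        row[n] = float(np.exp(theta[j])) if LINKS[n] == "log" else float(expit(theta[j]))
    if use_beta:
        row["beta_Cl_MET"] = float(theta[d])
    row["b"] = float(b)
    for j, n in enumerate(param_names):
        row[f"omega2_{n}"] = float(omega[j, j])
    return row


# ---------------------------------------------------------------------
# Louis / Fisher machinery on the packed parameter vector zeta

def _zeta_layout(d, p, block_ix, diag_ix):
    nb = len(block_ix)
    n_cov = nb * (nb + 1) // 2
    layout = {"theta": slice(0, p),
              "block": slice(p, p + n_cov),
              "diag": slice(p + n_cov, p + n_cov + len(diag_ix)),
              "b": p + n_cov + len(diag_ix)}
    layout["n"] = p + n_cov + len(diag_ix) + 1
    layout["tri"] = np.triu_indices(nb)
    return layout


def _pack_zeta(theta, omega, b, zl, block_ix, diag_ix):
    z = np.empty(zl["n"])
    z[zl["theta"]] = theta
    z[zl["block"]] = omega[np.ix_(block_ix, block_ix)][zl["tri"]]
    z[zl["diag"]] = omega[diag_ix, diag_ix]
    z[zl["b"]] = b
    return z


def _unpack_zeta(z, zl, d, block_ix, diag_ix):
    theta = z[zl["theta"]]
    om = np.zeros((d, d))
    nb = len(block_ix)
    blk = np.zeros((nb, nb))
    blk[zl["tri"]] = z[zl["block"]]
    blk = blk + blk.T - np.diag(np.diag(blk))
    om[np.ix_(block_ix, block_ix)] = blk
    om[diag_ix, diag_ix] = z[zl["diag"]]
    return theta, om, float(z[zl["b"]])


def _complete_ll(z, zl, psi_mat, met, i_cl, use_beta, ss_now, n_obs, d,
                 block_ix, diag_ix):
    """Complete-data log-likelihood at packed parameters ``z`` given the
    simulated individual parameters (vectorised over subjects; the
    structural predictions depend only on psi, so the residual part of
    the complete likelihood involves the parameters only through b)."""
    theta, om, b = _unpack_zeta(z, zl, d, block_ix, diag_ix)
    if b <= 0:
        return -np.inf
    # eigenvalue clipping keeps the evaluation finite when a finite-
    # difference step pushes a just-PSD covariance over the boundary
    w, V = np.linalg.eigh(om)
    w = np.maximum(w, 1e-10)
    logdet = float(np.sum(np.log(w)))
    prec = (V / w) @ V.T
    R = psi_mat - theta[:d][None, :]
    if use_beta:
        R[:, i_cl] -= theta[d] * met
    ll = -0.5 * (psi_mat.shape[0] * logdet + float(np.sum((R @ prec) * R)))
    ll += -n_obs * np.log(b) - ss_now / (2.0 * b * b)
    return ll


def _complete_grad_hess(zeta, zl, psi_mat, met, i_cl, use_beta, ss_now, n_obs,
                        block_ix, diag_ix):
    d = psi_mat.shape[1]
    n = zl["n"]
    h = 1e-5 * np.maximum(np.abs(zeta), 1e-2)
    args = (psi_mat, met, i_cl, use_beta, ss_now, n_obs, d, block_ix, diag_ix)
    f0 = _complete_ll(zeta, zl, *args)
    grad = np.zeros(n)
    H = np.zeros((n, n))
    fp = np.zeros(n)
    fm = np.zeros(n)
    for a in range(n):
        za, zb = zeta.copy(), zeta.copy()
        za[a] += h[a]
        zb[a] -= h[a]
        fp[a] = _complete_ll(za, zl, *args)
        fm[a] = _complete_ll(zb, zl, *args)
        grad[a] = (fp[a] - fm[a]) / (2 * h[a])
        H[a, a] = (fp[a] - 2 * f0 + fm[a]) / h[a] ** 2
    for a in range(n):
        for c in range(a + 1, n):
            zz = zeta.copy()
            zz[a] += h[a]
            zz[c] += h[c]
            fac = _complete_ll(zz, zl, *args)
            H[a, c] = H[c, a] = (fac - fp[a] - fp[c] + f0) / (h[a] * h[c])
    return grad, H


def _standard_errors(theta, omega, b, zl, A, B, g, param_names, use_beta, d,
                     block_ix, diag_ix):
    """Delta-method SEs on the reporting scale from the Louis information."""
    info = A - B + np.outer(g, g)
    info = 0.5 * (info + info.T)
    n_all = info.shape[0]
    # invert over the well-behaved sub-block; parameters whose
    # information row is non-finite or non-positive get NaN SEs
    keep = np.isfinite(info).all(axis=1) & (np.diag(info) > 0)
    cov = np.full((n_all, n_all), np.nan)
    if np.any(keep):
        sub = info[np.ix_(keep, keep)]
        try:
            cs = np.linalg.inv(sub)
        except np.linalg.LinAlgError:
            cs = np.linalg.pinv(sub)
        cov[np.ix_(keep, keep)] = cs
    dcov = np.diag(cov).copy()
    bad = ~np.isfinite(dcov) | (dcov <= 0)
    if np.any(bad):
        log.warning("standard errors unavailable for %d of %d parameters "
                    "(information not positive definite)", int(bad.sum()), n_all)
        dcov[bad] = np.nan
    se_zeta = np.sqrt(dcov)
    ses, rses = {}, {}
    p = d + (1 if use_beta else 0)
    for j, nme in enumerate(param_names):
        est = float(np.exp(theta[j])) if LINKS[nme] == "log" else float(expit(theta[j]))
        deriv = est if LINKS[nme] == "log" else est * (1 - est)
        ses[nme] = float(se_zeta[j] * deriv)
        rses[nme] = 100.0 * ses[nme] / abs(est) if est else np.nan
    if use_beta:
        ses["beta_Cl_MET"] = float(se_zeta[d])
        rses["beta_Cl_MET"] = 100.0 * ses["beta_Cl_MET"] / abs(theta[d]) if theta[d] else np.nan
    ses["b"] = float(se_zeta[zl["b"]])
    rses["b"] = 100.0 * ses["b"] / b
    # correlations by the delta method on the block covariances
    nb = len(block_ix)
    tri = zl["tri"]
    cov_blk = cov[zl["block"], :][:, zl["block"]]
    blk = omega[np.ix_(block_ix, block_ix)]
    pos = {(tri[0][t], tri[1][t]): t for t in range(len(tri[0]))}
    for a in range(nb):
        for c in range(a + 1, nb):
            va, vc, cac = blk[a, a], blk[c, c], blk[a, c]
            rho = cac / np.sqrt(va * vc)
            jac = np.zeros(len(tri[0]))
            jac[pos[(a, c)]] = 1.0 / np.sqrt(va * vc)
            jac[pos[(a, a)]] = -0.5 * cac / (va ** 1.5 * np.sqrt(vc))
            jac[pos[(c, c)]] = -0.5 * cac / (vc ** 1.5 * np.sqrt(va))
            var = float(jac @ cov_blk @ jac)
            key = f"corr({param_names[block_ix[c]]},{param_names[block_ix[a]]})"
            ses[key] = float(np.sqrt(var)) if var > 0 else np.nan
            rses[key] = 100.0 * ses[key] / abs(rho) if rho else np.nan
    return ses, rses


# ---------------------------------------------------------------------
# observed-data log-likelihood by importance sampling

def _loglik_importance(subs, draws, theta, omega, b, lloq, phi_full, st, rng):
    from scipy.special import gammaln
    d = omega.shape[0]
    df = st.loglik_df
    M = st.n_loglik_is
    prec = np.linalg.inv(omega + 1e-10 * np.eye(d))
    sign, logdet_om = np.linalg.slogdet(omega + 1e-10 * np.eye(d))
    total = 0.0
    for s in subs:
        mu = s["X"] @ theta
        dk = draws.get(s["sid"])
        if dk is None or len(dk) < 10:
            m, V = mu, omega
        else:
            m = dk.mean(axis=0)
            V = np.cov(dk.T) + 1e-8 * np.eye(d)
        L = np.linalg.cholesky(V)
        z = rng.standard_normal((M, d))
        w = rng.chisquare(df, M) / df
        x = m + (z @ L.T) / np.sqrt(w)[:, None]
        # multivariate-t log-density
        delta = x - m
        sol = np.linalg.solve(L, delta.T)
        quad = np.sum(sol ** 2, axis=0)
        logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
        logq = (gammaln((df + d) / 2) - gammaln(df / 2) - 0.5 * d * np.log(df * np.pi)
                - 0.5 * logdet_V - 0.5 * (df + d) * np.log1p(quad / df))
        lw = np.empty(M)
        for mdx in range(M):
            psi = x[mdx]
            f = conc_profile_arrays(phi_full(psi), s["dose_t"], s["dose_a"],
                                    s["dose_code"], s["obs_t"])
            llo = _loglik_from_pred(f, s["y"], s["cens"], b, lloq)
            r = psi - mu
            lpr = -0.5 * (d * np.log(2 * np.pi) + logdet_om + r @ prec @ r)
            lw[mdx] = llo + lpr - logq[mdx]
        mx = np.max(lw)
        total += mx + np.log(np.mean(np.exp(lw - mx)))
    return total


# ---------------------------------------------------------------------
# conditional distribution sampling at the final estimates

def sample_conditional(fit: FitResult, n_draws: int = 200, thin: int = 3,
                       seed: int = 1) -> dict:
    """Fresh MCMC draws of each subject's random effects given the data
    and the final estimates.

    Returns ``{subject_id: {"psi": (n_draws, d), "eta": (n_draws, d)}}``;
    eta is psi minus the subject's population prediction (covariates
    included), the quantity the covariate and correlation screens use.
    Posterior samples are preferred to point EBEs because shrinkage drags
    modes toward zero for sparse subjects.
    """
    st = fit.settings
    rng = np.random.default_rng(seed)
    model = fit.estimates
    d = model.n_random
    param_names = model.param_names
    phi_fn = _make_phi_fn(param_names, st.fpo_free)
    if st.fpo_free:
        ifpo = param_names.index("F_po")

        def phi_full(psi):
            ph = phi_fn(psi)
            ph[7] = expit(psi[ifpo])
            return ph
    else:
        phi_full = phi_fn
    theta = np.zeros(d + (1 if st.met_covariate else 0))
    for j, n in enumerate(param_names):
        v = model.theta[n]
        theta[j] = np.log(v) if LINKS[n] == "log" else np.log(v / (1 - v))
    if st.met_covariate:
        theta[d] = model.beta_cl_met
    omega, b, lloq = model.omega, model.b, fit.lloq
    chol = np.linalg.cholesky(omega + 1e-10 * np.eye(d))
    prec = np.linalg.inv(omega + 1e-10 * np.eye(d))
    out = {}
    for i, s in enumerate(fit._subjects):
        mu = s["X"] @ theta
        psi = fit._psi[i].copy()

        def ll(ps):
            f = conc_profile_arrays(phi_full(ps), s["dose_t"], s["dose_a"],
                                    s["dose_code"], s["obs_t"])
            return _loglik_from_pred(f, s["y"], s["cens"], b, lloq)

        cur = ll(psi)
        scale = 0.35
        keep = np.empty((n_draws, d))
        for t in range(n_draws * thin):
            prop = mu + chol @ rng.standard_normal(d) if t % 5 == 0 else \
                psi + scale * (chol @ rng.standard_normal(d))
            lp = ll(prop)
            if t % 5 == 0:
                ratio = lp - cur
            else:
                ratio = lp - cur - 0.5 * (_qform(prec, prop - mu) - _qform(prec, psi - mu))
            if np.log(rng.random()) < ratio:
                psi, cur = prop, lp
            if t % thin == thin - 1:
                keep[t // thin] = psi
        out[s["sid"]] = {"psi": keep, "eta": keep - mu}
    return out
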
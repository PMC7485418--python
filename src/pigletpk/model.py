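"""Hierarchical population model: links, individual parameters, and the
censoring-aware individual likelihood.

Each structural parameter has a typical value and, on a transformed scale
(log for positive parameters, logit for bioavailabilities), an additive
normal random effect: psi_i = psi_pop + covariate effect + eta_i with
eta_i ~ N(0, Omega).  The slow-metabolizer class acts additively on
log-clearance (equivalently multiplicatively on clearance), following the
software convention for categorical covariates on log-normal parameters.
Oral bioavailability is fixed at 1 in the final model (its IIV is
reported as the conventional placeholder variance 0.01, which has no
effect on predictions); it can be freed (logit link) for exploratory
fits.

Residual error is proportional: y = F(1 + b*eps).  Observations below the
LLOQ contribute the probability mass below the limit, log Phi((LLOQ - F)
/ (b*F)) — the censored-likelihood treatment known as M3.  The error SD
is floored at b*max(F, LLOQ/2) so the censored term stays finite when a
prediction approaches zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, log_ndtr, logit

from . import published as pub
from .datatypes import StructuralParams
from .structural import conc_profile_arrays

log = logging.getLogger(__name__)

__all__ = ["PopulationModel", "IndividualParams", "link_transform",
           "individual_loglik_m3", "published_model", "PARAM_NAMES", "LINKS"]

#: parameters carrying random effects, in canonical order ("F_po" appended
#: when oral bioavailability is estimated rather than fixed)
PARAM_NAMES = ("Cl", "Vc", "Q", "Vp", "F_top", "k_top", "Lag", "k_po")
LINKS = {"Cl": "log", "Vc": "log", "Q": "log", "Vp": "log", "F_top": "logit",
         "k_top": "log", "Lag": "log", "k_po": "log", "F_po": "logit"}

#: default free correlation structure (the final-model block)
CORRELATED_BLOCK = ("Cl", "Q", "Vp", "F_top")


def _fwd(link: str, x: float) -> float:
    return float(np.log(x)) if link == "log" else float(logit(x))


def _inv(link: str, psi: np.ndarray):
    return np.exp(psi) if link == "log" else expit(psi)


@dataclass
class PopulationModel:
    """Fixed effects, covariate effect, random-effect covariance and
    residual scale — the estimand of the mixed-effects fit.

    ``theta`` holds typical values on the natural scale; ``omega`` is the
    covariance of the transformed-scale random effects in ``param_names``
    order; ``b`` the proportional residual-error scale.
    """

    theta: dict = field(default_factory=dict)
    beta_cl_met: float = 0.0
    omega: np.ndarray = None
    b: float = 0.3
    fpo_free: bool = False
    fpo_iiv_placeholder: float = 0.01  # reported, inert when F_po is fixed at 1

    def __post_init__(self) -> None:
        names = self.param_names
        if self.omega is None:
            self.omega = np.diag([0.09] * len(names))
        self.omega = np.asarray(self.omega, float)
        if self.omega.shape != (len(names), len(names)):
            raise ValueError(f"omega must be {len(names)}x{len(names)}")
        if not np.allclose(self.omega, self.omega.T):
            raise ValueError("omega must be symmetric")
        if np.min(np.linalg.eigvalsh(self.omega)) < -1e-10:
            raise ValueError("omega must be positive semi-definite")
        if not self.b > 0:
            raise ValueError("b must be > 0")
        ft = self.theta.get("F_top")
        if ft is not None and not (0 < ft < 1):
            raise ValueError("typical F_top must lie in (0, 1)")

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES + ("F_po",) if self.fpo_free else PARAM_NAMES

    @property
    def n_random(self) -> int:
        return len(self.param_names)

    def psi_pop(self) -> np.ndarray:
        """Typical values on the transformed (log/logit) scale."""
        return np.array([_fwd(LINKS[n], self.theta[n]) for n in self.param_names])

    def copy(self) -> "PopulationModel":
        return PopulationModel(theta=dict(self.theta), beta_cl_met=self.beta_cl_met,
                               omega=self.omega.copy(), b=self.b, fpo_free=self.fpo_free,
                               fpo_iiv_placeholder=self.fpo_iiv_placeholder)

    def cv_pct(self) -> dict:
        """IIV magnitude per parameter as CV% (log-normal convention,
        applied uniformly — including the logit-linked bioavailability,
        matching the reporting convention of the reference analysis)."""
        out = {}
        for i, n in enumerate(self.param_names):
            out[n] = 100.0 * float(np.sqrt(np.expm1(min(self.omega[i, i], 50.0))))
        if not self.fpo_free:
            out["F_po"] = 100.0 * float(np.sqrt(np.expm1(self.fpo_iiv_placeholder))) * 0.0
        return out


@dataclass(frozen=True)
class IndividualParams:
    """One subject's random effects and the structural parameters they imply."""

    eta: np.ndarray
    phi: StructuralParams
    MET: int = 0


def link_transform(model: PopulationModel, eta: np.ndarray, MET: int = 0) -> StructuralParams:
    """Map population parameters + random effects + MET class to one
    individual's structural parameters.

    Log-normal parameters: phi = mu * exp(eta) (clearance additionally
    times exp(beta*MET)); logit-linked bioavailability:
    logit(F) = logit(xi) + eta.
    """
    eta = np.asarray(eta, float)
    if eta.shape != (model.n_random,):
        raise ValueError(f"eta must have length {model.n_random}")
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    psi = model.psi_pop() + eta
    icl = model.param_names.index("Cl")
    psi[icl] += model.beta_cl_met * MET
    vals = {n: float(_inv(LINKS[n], p)) for n, p in zip(model.param_names, psi)}
    if not model.fpo_free:
        vals["F_po"] = 1.0
    return StructuralParams(**vals)


def individual_loglik_m3(model: PopulationModel, phi: StructuralParams,
                         dose_t: np.ndarray, dose_a: np.ndarray, dose_code: np.ndarray,
                         obs_t: np.ndarray, y: np.ndarray, censored: np.ndarray,
                         lloq: float) -> float:
    """Censoring-aware log-likelihood of one subject's observations.

    Quantified samples contribute a Gaussian log-density with mean F and
    SD b*F; BLQ samples contribute log Phi((LLOQ - F) / (b*F)).  The SD is
    floored at b*LLOQ/2 (logged when active) to keep the censored term
    finite for near-zero predictions.
    """
    if obs_t.size == 0:
        raise ValueError("subject has no observations")
    from .structural import phi_array
    f = conc_profile_arrays(phi_array(phi), dose_t, dose_a, dose_code, obs_t)
    return _loglik_from_pred(f, y, censored, model.b, lloq)


def _loglik_from_pred(f: np.ndarray, y: np.ndarray, censored: np.ndarray,
                      b: float, lloq: float) -> float:
    scale = np.maximum(f, 0.5 * lloq)
    if np.any(f < 0.5 * lloq):
        log.debug("proportional-error SD floored at b*LLOQ/2 for %d predictions",
                  int(np.sum(f < 0.5 * lloq)))
    sd = b * scale
    ll = 0.0
    q = ~censored
    if np.any(q):
        r = (y[q] - f[q]) / sd[q]
        ll += float(np.sum(-0.5 * r * r - np.log(sd[q]) - 0.5 * np.log(2.0 * np.pi)))
    if np.any(censored):
        z = (lloq - f[censored]) / sd[censored]
        ll += float(np.sum(log_ndtr(z)))
    return ll


def published_model() -> PopulationModel:
    """The published population parameter set, assembled as a
    :class:`PopulationModel` (final-model structure: F_po fixed at 1,
    free correlations among Cl, Q, Vp and F_top)."""
    theta = {"Cl": pub.CL, "Vc": pub.VC, "Q": pub.Q, "Vp": pub.VP,
             "F_top": pub.F_TOP, "k_top": pub.K_TOP, "Lag": pub.LAG,
             "k_po": pub.K_PO}
    names = PARAM_NAMES
    sd = np.array([pub.OMEGA_SD[n] for n in names])
    corr = np.eye(len(names))
    idx = {n: i for i, n in enumerate(names)}
    for (a, b_), r in pub.CORRELATIONS.items():
        corr[idx[a], idx[b_]] = corr[idx[b_], idx[a]] = r
    omega = corr * np.outer(sd, sd)
    return PopulationModel(theta=theta, beta_cl_met=pub.BETA_CL_MET, omega=omega,
                           b=pub.B_PROP, fpo_free=False)
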
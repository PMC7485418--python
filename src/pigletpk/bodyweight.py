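"""Box-Cox bodyweight sub-model.

Doses in the trial are per-kilogram, so simulating a treatment requires a
bodyweight distribution.  The sub-model regresses a Box-Cox transform of
weight on a population intercept and a study-phase offset:

    (BW^lambda - 1) / lambda = BW_pop + IPV*[phase 2] + eps,  eps ~ N(0, sigma^2)

The exponent lambda is chosen on a grid from -2 to 2 in steps of 0.1.
Raw sums of squared errors are not comparable across lambda (the
transform rescales the response), so the grid search scores each lambda
with the geometric-mean-normalised transform — the standard Box-Cox
profile-likelihood criterion — and the minimiser is refined through a
cubic-spline interpolation of the score curve.  The returned sigma is the
residual SD on the unnormalised transform scale at the selected lambda.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from . import published as pub

log = logging.getLogger(__name__)

__all__ = ["BodyweightModel", "fit_bodyweight_boxcox", "sample_bodyweight",
           "typical_weight", "published_bodyweight_model"]


@dataclass(frozen=True)
class BodyweightModel:
    bw_pop: float = pub.BW_POP     # transformed-scale population weight
    ipv: float = pub.BW_IPV        # inter-phase offset (phase 2 adds this)
    sigma: float = pub.BW_SIGMA    # residual SD on the transform scale
    lam: float = pub.BW_LAMBDA     # Box-Cox exponent

    def __post_init__(self) -> None:
        if not (-2.0 <= self.lam <= 2.0):
            raise ValueError("lambda must lie in [-2, 2]")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


def _boxcox(bw: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.log(bw)
    return (bw ** lam - 1.0) / lam


def _inv_boxcox(z: np.ndarray, lam: float) -> np.ndarray:
    if abs(lam) < 1e-12:
        return np.exp(z)
    return (1.0 + lam * z) ** (1.0 / lam)


def typical_weight(model: BodyweightModel, phase: int = 1) -> float:
    """Deterministic inverse transform of the population parameters (kg)."""
    z = model.bw_pop + (model.ipv if phase == 2 else 0.0)
    return float(_inv_boxcox(np.array(z), model.lam))


def fit_bodyweight_boxcox(weights: np.ndarray, phases: np.ndarray,
                          grid_step: float = 0.1) -> BodyweightModel:
    """Grid-search Box-Cox fit of weights (kg) with phase labels {1, 2}."""
    weights = np.asarray(weights, float)
    phases = np.asarray(phases, int)
    if np.any(weights <= 0):
        raise ValueError("bodyweights must be positive")
    if weights.size < 3 or len(set(phases.tolist())) < 2:
        raise ValueError("need >= 3 weights spanning both phases")
    n = weights.size
    gm = float(np.exp(np.mean(np.log(weights))))
    X = np.column_stack([np.ones(n), (phases == 2).astype(float)])
    lams = np.round(np.arange(-2.0, 2.0 + grid_step / 2, grid_step), 10)
    sses = np.empty_like(lams)
    for j, lam in enumerate(lams):
        # geometric-mean normalisation makes SSE comparable across lambda
        y = gm * np.log(weights) if abs(lam) < 1e-12 else (weights ** lam - 1.0) / (lam * gm ** (lam - 1.0))
        coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        sses[j] = float(np.sum((y - X @ coef) ** 2))
    spline = CubicSpline(lams, sses)
    fine = np.arange(-2.0, 2.0 + 5e-4, 1e-3)
    lam_hat = float(fine[np.argmin(spline(fine))])
    # parameters and residual SD on the raw transform scale at the optimum
    y = _boxcox(weights, lam_hat)
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sigma = float(np.sqrt(np.sum(resid ** 2) / max(n - 2, 1)))
    return BodyweightModel(bw_pop=float(coef[0]), ipv=float(coef[1]),
                           sigma=sigma, lam=lam_hat)


def sample_bodyweight(model: BodyweightModel, n: int, phase: int = 1,
                      seed: int | np.random.Generator = 0) -> np.ndarray:
    """Draw ``n`` positive bodyweights (kg) for the given study phase.

    Residuals whose inverse transform would be non-positive are redrawn
    (and counted in the log); with the published parameters this is a
    ~1-in-10^5 event.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = model.bw_pop + (model.ipv if phase == 2 else 0.0)
    out = np.empty(n)
    todo = np.arange(n)
    redraws = 0
    while todo.size:
        z = base + rng.normal(0.0, model.sigma, todo.size)
        ok = (1.0 + model.lam * z > 0) if abs(model.lam) >= 1e-12 else np.ones(todo.size, bool)
        out[todo[ok]] = _inv_boxcox(z[ok], model.lam)
        redraws += int(np.sum(~ok))
        todo = todo[~ok]
    if redraws:
        log.debug("redrew %d bodyweight residuals outside the transform domain", redraws)
    return out


def published_bodyweight_model() -> BodyweightModel:
    return BodyweightModel()
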
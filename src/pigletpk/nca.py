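"""Noncompartmental analysis of individual concentration–time profiles.

Conventions follow the common "best-fit" NCA defaults: the terminal rate
constant lambda_z is a log-linear regression over the contiguous terminal
window that maximises adjusted R^2 (>= 3 points, Cmax excluded for
extravascular routes, windows within 1e-4 of the best adjusted R^2 broken
toward more points); AUC uses the linear-up/log-down trapezoid unless
configured otherwise; BLQ samples are excluded outright (the mixed-effects
stage handles censoring properly — NCA here serves initial estimates and
descriptive summaries).

Inputs are in internal units (min, mg, mg/L); results are reported on the
conventional NCA scale: hours, 1/h, L/h, and µg/L for concentrations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import MIN_PER_H, UGL_PER_MGL

__all__ = ["NCAConfig", "NCAResult", "estimate_lambda_z", "nca_single_profile",
           "nca_summarize"]

#: adjusted-R^2 tie window for the terminal-slope search
_ADJR2_TIE = 1e-4


@dataclass(frozen=True)
class NCAConfig:
    min_lambda_points: int = 3
    lambda_selection: str = "best-adjusted-R2"   # or "manual-window"
    manual_window: tuple[float, float] | None = None  # minutes, used by manual-window
    trapezoid: str = "lin-up-log-down"           # or "linear"
    blq_rule: str = "exclude"

    def __post_init__(self) -> None:
        if self.min_lambda_points < 3:
            raise ValueError("min_lambda_points must be >= 3")
        if self.trapezoid not in ("lin-up-log-down", "linear"):
            raise ValueError(f"unknown trapezoid rule {self.trapezoid!r}")
        if self.lambda_selection not in ("best-adjusted-R2", "manual-window"):
            raise ValueError(f"unknown lambda_selection {self.lambda_selection!r}")


@dataclass
class NCAResult:
    """Per-profile noncompartmental metrics (hour-based units).

    For intravascular profiles clearance and Vss are absolute (Cl, Vss);
    for extravascular routes they are apparent (Cl/F, Vss/F) and are
    stored in the same fields with ``apparent=True``.  Metrics that need
    lambda_z are NaN when the terminal slope is not estimable.
    """

    subject_id: str = ""
    route: str = ""
    dose: float = np.nan            # mg
    lambda_z: float = np.nan        # 1/h
    lambda_z_points: int = 0
    lambda_z_adj_r2: float = np.nan
    t_half: float = np.nan          # h
    Cmax: float = np.nan            # µg/L
    tmax: float = np.nan            # h
    C0: float = np.nan              # µg/L, IV back-extrapolation only
    AUC_last: float = np.nan        # mg·h/L
    AUC_inf: float = np.nan         # mg·h/L
    AUC_extrap_pct: float = np.nan  # %
    AUC_over_dose: float = np.nan   # h/L
    AUMC_inf: float = np.nan        # mg·h²/L
    MRT: float = np.nan             # h (includes absorption for extravascular)
    Cl: float = np.nan              # L/h (Cl/F when apparent)
    Vss: float = np.nan             # L  (Vss/F when apparent)
    apparent: bool = True
    estimable: bool = True

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("subject_id", "route", "dose", "lambda_z", "t_half", "Cmax", "tmax",
                 "C0", "AUC_last", "AUC_inf", "AUC_extrap_pct", "AUC_over_dose",
                 "MRT", "Cl", "Vss", "apparent", "estimable")}


def _adj_r2(logc: np.ndarray, t: np.ndarray) -> tuple[float, float]:
    """Slope and adjusted R^2 of the log-linear regression (slope < 0 expected)."""
    n = len(t)
    A = np.vstack([t, np.ones(n)]).T
    coef, res, *_ = np.linalg.lstsq(A, logc, rcond=None)
    ss_res = float(res[0]) if res.size else float(np.sum((logc - A @ coef) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return coef[0], adj


def estimate_lambda_z(times: np.ndarray, conc: np.ndarray, config: NCAConfig = NCAConfig(),
                      extravascular: bool = True) -> dict:
    """Terminal elimination rate constant from a single profile.

    ``times`` in minutes, ``conc`` in mg/L, BLQ already excluded (zeros and
    negatives are dropped here).  Returns lambda_z in 1/h with the window
    size and adjusted R^2, or ``estimable=False`` when fewer than
    ``min_lambda_points`` usable post-Cmax points exist.
    """
    times = np.asarray(times, float)
    conc = np.asarray(conc, float)
    pos = conc > 0
    t, c = times[pos], conc[pos]
    out = {"lambda_z": np.nan, "n_points": 0, "adjusted_r2": np.nan, "estimable": False}
    if t.size == 0:
        return out
    imax = int(np.argmax(c))
    start = imax + 1 if extravascular else imax  # Cmax excluded for extravascular
    t_term, c_term = t[start:], c[start:]
    if config.lambda_selection == "manual-window":
        lo, hi = config.manual_window
        sel = (t_term >= lo) & (t_term <= hi)
        t_term, c_term = t_term[sel], c_term[sel]
        if t_term.size < config.min_lambda_points:
            return out
        slope, adj = _adj_r2(np.log(c_term), t_term)
        if slope >= 0:
            return out
        return {"lambda_z": -slope * MIN_PER_H, "n_points": int(t_term.size),
                "adjusted_r2": adj, "estimable": True}
    n = t_term.size
    if n < config.min_lambda_points:
        return out
    best = None  # (adj, npts, slope)
    for i in range(0, n - config.min_lambda_points + 1):
        tw, cw = t_term[i:], c_term[i:]
        slope, adj = _adj_r2(np.log(cw), tw)
        if slope >= 0:
            continue
        if best is None or adj > best[0] + _ADJR2_TIE:
            best = (adj, tw.size, slope)
        # ties toward more points: the earlier (larger) window was seen first,
        # so an equal-or-tied later window never replaces it
    if best is None:
        return out
    adj, npts, slope = best
    return {"lambda_z": -slope * MIN_PER_H, "n_points": int(npts),
            "adjusted_r2": adj, "estimable": True}


def _auc_segment(t1, t2, c1, c2, rule: str) -> tuple[float, float]:
    """(AUC, AUMC) of one segment, times in minutes, conc mg/L -> mg·min/L."""
    dt = t2 - t1
    if rule == "lin-up-log-down" and c2 < c1 and c1 > 0 and c2 > 0:
        k = np.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k ** 2
    else:
        auc = 0.5 * (c1 + c2) * dt
        aumc = 0.5 * (t1 * c1 + t2 * c2) * dt
    return auc, aumc


def nca_single_profile(times: np.ndarray, conc: np.ndarray, dose: float, route: str,
                       config: NCAConfig = NCAConfig(), subject_id: str = "") -> NCAResult:
    """Full NCA of one profile (times min, conc mg/L, dose mg).

    BLQ-excluded input expected.  For IV the initial concentration C0 is
    back-extrapolated log-linearly from the first two positive samples and
    a t=0 point is prepended for the AUC; clearance is then absolute,
    otherwise apparent (Cl/F).
    """
    if not dose > 0:
        raise ValueError("dose must be > 0")
    # zeros are kept for the trapezoid (a true pre-absorption zero anchors
    # the AUC) but never enter the log-linear terminal fit
    t = np.asarray(times, float)
    c = np.asarray(conc, float)
    res = NCAResult(subject_id=subject_id, route=route, dose=dose,
                    apparent=route != "IV")
    if t.size == 0 or not np.any(c > 0):
        res.estimable = False
        return res
    imax = int(np.argmax(c))
    res.Cmax = c[imax] * UGL_PER_MGL
    res.tmax = t[imax] / MIN_PER_H
    if route == "IV":
        tp, cp = t[c > 0], c[c > 0]
        if tp.size >= 2 and cp[1] < cp[0] and tp[0] > 0:
            k0 = np.log(cp[0] / cp[1]) / (tp[1] - tp[0])
            c0 = cp[0] * np.exp(k0 * tp[0])
        else:
            c0 = cp[0]
        res.C0 = c0 * UGL_PER_MGL
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            c = np.concatenate([[c0], c])
    lz = estimate_lambda_z(t, c, config, extravascular=route != "IV")
    res.lambda_z = lz["lambda_z"]
    res.lambda_z_points = lz["n_points"]
    res.lambda_z_adj_r2 = lz["adjusted_r2"]
    auc = aumc = 0.0
    for i in range(t.size - 1):
        a, m = _auc_segment(t[i], t[i + 1], c[i], c[i + 1], config.trapezoid)
        auc += a
        aumc += m
    res.AUC_last = auc / MIN_PER_H            # mg·min/L -> mg·h/L
    if not lz["estimable"]:
        res.estimable = False
        return res
    lam_min = lz["lambda_z"] / MIN_PER_H      # back to 1/min for extrapolation
    res.t_half = np.log(2.0) / lz["lambda_z"]
    c_last, t_last = c[-1], t[-1]
    auc_inf = auc + c_last / lam_min
    aumc_inf = aumc + c_last * t_last / lam_min + c_last / lam_min ** 2
    res.AUC_inf = auc_inf / MIN_PER_H
    res.AUMC_inf = aumc_inf / MIN_PER_H ** 2
    res.AUC_extrap_pct = 100.0 * (1.0 - auc / auc_inf)
    res.AUC_over_dose = res.AUC_inf / dose
    res.MRT = (aumc_inf / auc_inf) / MIN_PER_H
    res.Cl = dose / res.AUC_inf               # L/h (apparent unless IV)
    res.Vss = res.Cl * res.MRT                # L  (apparent unless IV)
    return res


_METRICS = ("AUC_over_dose", "AUC_inf", "Cl", "Cmax", "t_half", "lambda_z",
            "MRT", "tmax", "Vss", "AUC_extrap_pct")


def nca_summarize(results: Sequence[NCAResult]) -> pd.DataFrame:
    """Group summary (mean / SD / median per metric, grouped by route).

    Missing (non-estimable) metrics are excluded pairwise, mirroring the
    NA handling of standard NCA summary tables.  MRT is reported raw
    (absorption-inclusive for extravascular routes); when IV results are
    present the extravascular Mean/Median rows additionally carry ``mat``,
    the mean absorption time — the excess of the route's MRT over the IV
    reference.
    """
    if not results:
        raise ValueError("no NCA results to summarize")
    rows = [r.as_dict() for r in results]
    df = pd.DataFrame(rows)
    out = []
    for route, grp in df.groupby("route", sort=False):
        if grp.empty:
            raise ValueError(f"empty NCA group {route!r}")
        for stat, fn in (("Mean", np.nanmean), ("SD", lambda x: np.nanstd(x, ddof=1) if np.sum(~np.isnan(x)) > 1 else 0.0),
                         ("Median", np.nanmedian)):
            row = {"route": route, "stat": stat, "n": len(grp)}
            for mcol in _METRICS:
                vals = grp[mcol].to_numpy(dtype=float)
                row[mcol] = float(fn(vals)) if np.any(~np.isnan(vals)) else np.nan
            out.append(row)
    tab = pd.DataFrame(out)
    iv = tab[(tab.route == "IV")]
    tab["mat"] = np.nan
    if not iv.empty:
        for stat in ("Mean", "Median"):
            ref = iv[iv.stat == stat]["MRT"]
            if ref.empty or np.isnan(ref.iloc[0]):
                continue
            sel = (tab.stat == stat) & (tab.route != "IV")
            tab.loc[sel, "mat"] = tab.loc[sel, "MRT"] - ref.iloc[0]
    return tab
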
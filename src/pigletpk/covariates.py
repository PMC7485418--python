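"""Metabolizer classification and covariate / correlation screens.

The study population splits into fast and slow flunixin metabolizers.
The classifier is a one-dimensional 2-means split of log-clearance
proxies (per-subject NCA clearances, or conditional-mean individual
clearances from a base fit without the covariate); the higher-clearance
cluster is labelled fast (MET = 0).  Covariate screens follow the
original analysis: one-way ANOVA of the random effects against
categorical covariates and Pearson correlation against bodyweight, both
at a raw p < 0.05 (no multiplicity correction — a documented
limitation).  Random effects enter the tests as conditional means of
posterior draws rather than EBE modes, which mitigates shrinkage.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = ["classify_metabolizers", "two_means_1d", "covariate_tests",
           "correlation_tests"]

#: minimum separation of the cluster means on the log scale below which
#: the population is treated as a single (slow) group
SEPARATION_THRESHOLD = 0.25


def two_means_1d(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Exact 2-means clustering of a 1-D sample (all split points tried).

    Returns (labels with 1 for the lower cluster, lower mean, upper mean).
    """
    x = np.asarray(x, float)
    order = np.argsort(x)
    xs = x[order]
    n = x.size
    best = (np.inf, 1)
    csum = np.cumsum(xs)
    total = csum[-1]
    for k in range(1, n):
        m1 = csum[k - 1] / k
        m2 = (total - csum[k - 1]) / (n - k)
        sse = np.sum((xs[:k] - m1) ** 2) + np.sum((xs[k:] - m2) ** 2)
        if sse < best[0]:
            best = (sse, k)
    k = best[1]
    labels = np.empty(n, int)
    labels[order[:k]] = 1   # lower cluster
    labels[order[k:]] = 0
    return labels, float(np.mean(xs[:k])), float(np.mean(xs[k:]))


def classify_metabolizers(clearances: dict[str, float],
                          threshold: float = SEPARATION_THRESHOLD) -> dict[str, int]:
    """Assign MET labels from per-subject clearance proxies (L/min or any
    common unit — only the log-scale split matters).

    When the two cluster means are closer than ``threshold`` on the log
    scale (a degenerate, effectively unimodal population) every subject
    is assigned MET = 1 with a warning.
    """
    sids = list(clearances)
    vals = np.array([clearances[s] for s in sids], float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("clearance proxies must be positive and finite")
    logv = np.log(vals)
    labels, m_lo, m_hi = two_means_1d(logv)
    if m_hi - m_lo < threshold:
        log.warning("cluster separation %.3f below threshold %.3f; "
                    "assigning all subjects MET=1", m_hi - m_lo, threshold)
        return {s: 1 for s in sids}
    return {s: int(l) for s, l in zip(sids, labels)}


def _eta_table(draws: dict, param_names) -> pd.DataFrame:
    rows = {}
    for sid, dd in draws.items():
        rows[sid] = dd["eta"].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(param_names))


def covariate_tests(fit, dataset, draws: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Screen sex, bodyweight and the MET class against every random effect.

    Categorical covariates use one-way ANOVA on the conditional-mean
    random effects; bodyweight uses the Pearson correlation test.
    Constant covariates are skipped with a note.
    """
    eta = _eta_table(draws, fit.estimates.param_names)
    cov = {c.subject_id: c for c in dataset.covariates}
    sids = [s for s in eta.index if s in cov]
    eta = eta.loc[sids]
    sex = np.array([cov[s].sex for s in sids])
    bw = np.array([cov[s].bodyweight for s in sids], float)
    met = np.array([cov[s].MET if cov[s].MET is not None else -1 for s in sids])
    rows = []
    for name in eta.columns:
        e = eta[name].to_numpy()
        for label, values, kind in (("sex", sex, "anova"), ("MET", met, "anova"),
                                    ("bodyweight", bw, "pearson")):
            if kind == "anova":
                groups = [e[values == g] for g in np.unique(values) if g != -1]
                if len(groups) < 2 or min(len(g) for g in groups) < 2:
                    rows.append({"effect": name, "covariate": label, "test": kind,
                                 "statistic": np.nan, "p": np.nan,
                                 "include": False, "note": "skipped: constant or tiny group"})
                    continue
                stat, p = stats.f_oneway(*groups)
            else:
                if np.std(values) == 0:
                    rows.append({"effect": name, "covariate": label, "test": kind,
                                 "statistic": np.nan, "p": np.nan,
                                 "include": False, "note": "skipped: constant covariate"})
                    continue
                stat, p = stats.pearsonr(values, e)
            rows.append({"effect": name, "covariate": label, "test": kind,
                         "statistic": float(stat), "p": float(p),
                         "include": bool(p < alpha), "note": ""})
    return pd.DataFrame(rows)


def correlation_tests(fit, draws: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Pairwise Pearson tests between random effects; significant pairs
    are candidates for free correlations in the covariance matrix."""
    eta = _eta_table(draws, fit.estimates.param_names)
    if len(eta) < 3:
        log.warning("fewer than 3 subjects; correlation screen skipped")
        return pd.DataFrame(columns=["pair", "r", "p", "include"])
    rows = []
    cols = list(eta.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            r, p = stats.pearsonr(eta[cols[i]], eta[cols[j]])
            rows.append({"pair": f"{cols[i]}~{cols[j]}", "r": float(r),
                         "p": float(p), "include": bool(p < alpha)})
    return pd.DataFrame(rows)
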
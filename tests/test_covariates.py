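"""Metabolizer classification and covariate / correlation screens."""
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from pigletpk.covariates import (classify_metabolizers, correlation_tests,
                                 covariate_tests, two_means_1d)
from pigletpk.datatypes import PKDataset, SubjectCovariates
from pigletpk.model import PARAM_NAMES

BETA = -0.892
OMEGA_CL = 0.311


def _mixture_proxies(rng, n_fast=9, n_slow=29, omega=OMEGA_CL):
    cls = {}
    truth = {}
    for i in range(n_fast + n_slow):
        met = 0 if i < n_fast else 1
        cls[f"s{i}"] = 0.012 * np.exp(BETA * met + omega * rng.standard_normal())
        truth[f"s{i}"] = met
    return cls, truth


def test_well_separated_clusters_recovered():
    """At the published clearance ratio (e^0.892 ~ 2.44) with small IIV
    the 2-means split is exact."""
    rng = np.random.default_rng(0)
    cls, truth = _mixture_proxies(rng, omega=0.05)
    met = classify_metabolizers(cls)
    assert met == truth


def test_study_level_mixture_confusion_bounded():
    """At the study's IIV the class distributions overlap, so a few
    subjects land on the wrong side of any boundary; the confusion stays
    near the Bayes floor (~3 of 38)."""
    confusions = []
    for seed in range(5):
        rng = np.random.default_rng(100 + seed)
        cls, truth = _mixture_proxies(rng)
        met = classify_metabolizers(cls)
        confusions.append(sum(met[s] != truth[s] for s in truth))
    # Bayes floor at this overlap is ~3 of 38; 2-means boundary noise
    # adds a little on unlucky draws
    assert max(confusions) <= 8
    assert np.mean(confusions) <= 5.0


def test_identical_clearances_degenerate():
    met = classify_metabolizers({f"s{i}": 0.01 for i in range(10)})
    assert all(v == 1 for v in met.values())


def test_two_means_exactness():
    x = np.array([1.0, 1.1, 0.9, 5.0, 5.2, 4.8])
    labels, lo, hi = two_means_1d(x)
    assert lo == pytest.approx(1.0)
    assert hi == pytest.approx(5.0)
    assert list(labels) == [1, 1, 1, 0, 0, 0]


# ---- screens on conditional-mean random effects ---------------------

def _fake_fit_and_draws(rng, n=60, beta_effect=0.0, rho=0.0):
    """Synthetic conditional draws with a known generative structure."""
    names = PARAM_NAMES
    fit = SimpleNamespace(estimates=SimpleNamespace(param_names=names))
    covs = []
    draws = {}
    for i in range(n):
        sid = f"s{i}"
        met = int(rng.random() < 0.3)
        sex = "M" if rng.random() < 0.5 else "F"
        bw = float(rng.uniform(2.5, 5.0))
        covs.append(SubjectCovariates(sid, sex, bw, MET=met))
        eta = rng.standard_normal(len(names)) * 0.3
        eta[0] += beta_effect * met
        if rho:
            shared = rng.standard_normal()
            eta[2] = 0.3 * (np.sqrt(1 - rho ** 2) * rng.standard_normal()
                            + rho * shared)
            eta[3] = 0.3 * (np.sqrt(1 - rho ** 2) * rng.standard_normal()
                            + rho * shared)
        draws[sid] = {"eta": eta[None, :] + 0.01 * rng.standard_normal((50, len(names))),
                      "psi": np.zeros((50, len(names)))}
    ds = PKDataset(doses=[], observations=[], covariates=covs)
    return fit, ds, draws


def test_met_effect_detected():
    """A clearance shift of the published size is flagged significant in
    essentially every replicate at study size."""
    hits = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        fit, ds, draws = _fake_fit_and_draws(rng, n=38, beta_effect=BETA)
        tab = covariate_tests(fit, ds, draws)
        row = tab[(tab.effect == "Cl") & (tab.covariate == "MET")].iloc[0]
        hits += int(row["include"])
    assert hits >= 9


def test_null_covariate_type_one_error():
    """With no generative effect, sex is flagged at roughly the nominal
    5% rate (binomial envelope over 200 screens)."""
    rng = np.random.default_rng(42)
    flags = []
    for _ in range(200):
        fit, ds, draws = _fake_fit_and_draws(rng, n=38)
        tab = covariate_tests(fit, ds, draws)
        row = tab[(tab.effect == "Vc") & (tab.covariate == "sex")].iloc[0]
        flags.append(bool(row["include"]))
    rate = np.mean(flags)
    assert 0.01 <= rate <= 0.11


def test_constant_covariate_skipped():
    rng = np.random.default_rng(1)
    fit, ds, draws = _fake_fit_and_draws(rng, n=20)
    ds = PKDataset(doses=[], observations=[],
                   covariates=[SubjectCovariates(c.subject_id, "F", c.bodyweight,
                                                 MET=c.MET) for c in ds.covariates])
    tab = covariate_tests(fit, ds, draws)
    sex_rows = tab[tab.covariate == "sex"]
    assert not sex_rows["include"].any()
    assert (sex_rows["note"].str.contains("skipped")).all()


def test_strong_eta_correlation_detected():
    """A Q~Vp random-effect correlation of 0.967 size is detected in
    every replicate."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        fit, _, draws = _fake_fit_and_draws(rng, n=38, rho=0.967)
        tab = correlation_tests(fit, draws)
        row = tab[tab.pair == "Q~Vp"].iloc[0]
        assert row["include"] and row["r"] > 0.7


def test_independent_etas_rarely_flagged():
    rng = np.random.default_rng(7)
    flags = []
    for _ in range(60):
        fit, _, draws = _fake_fit_and_draws(rng, n=38)
        tab = correlation_tests(fit, draws)
        flags.append(bool(tab[tab.pair == "Vc~k_top"].iloc[0]["include"]))
    assert np.mean(flags) <= 0.15


def test_two_subjects_skipped():
    rng = np.random.default_rng(2)
    fit, _, draws = _fake_fit_and_draws(rng, n=2)
    tab = correlation_tests(fit, draws)
    assert tab.empty
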
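"""Noncompartmental analysis against closed forms and hand oracles."""
import numpy as np
import pytest

from pigletpk.datatypes import DoseEvent
from pigletpk.nca import NCAConfig, estimate_lambda_z, nca_single_profile, nca_summarize
from pigletpk.structural import solve_profile

#: Phase II transdermal sampling times (hours)
TD_SCHEDULE_H = [0.25, 0.5, 0.75, 1, 1.5, 2, 3, 6, 12, 24, 36, 48, 60, 72, 84, 96,
                 108, 120, 132, 144, 156, 168, 180, 192, 204, 216]


def test_lambda_z_exact_monoexponential():
    """A noise-free single exponential is recovered to numerical precision."""
    t = np.array([10, 30, 60, 120, 240, 480, 720, 960.0])
    c = 10.0 * np.exp(-0.1 * t)
    out = estimate_lambda_z(t, c, extravascular=False)
    assert out["estimable"]
    assert out["lambda_z"] / 60.0 == pytest.approx(0.1, abs=1e-10)


def test_lambda_z_needs_three_points():
    t = np.array([0.0, 60.0, 120.0, 180.0])
    c = np.array([1.0, 5.0, 2.0, 1.0])  # only 2 usable post-Cmax points
    out = estimate_lambda_z(t, c, extravascular=True)
    assert not out["estimable"]
    res = nca_single_profile(t, c, 1.0, "PO")
    assert not res.estimable
    assert np.isnan(res.AUC_inf)
    assert res.Cmax == pytest.approx(5000.0)  # Cmax/tmax still reported


def test_transdermal_half_life_flipflop(typical_slow):
    """A noise-free transdermal profile sampled on the late-extended
    schedule shows the flip-flop terminal half-life near 39 h."""
    t = np.array(TD_SCHEDULE_H) * 60.0
    dose = 3.3 * 4.0
    c = solve_profile(typical_slow, [DoseEvent("s", 0.0, dose, "TD")], t)
    res = nca_single_profile(t, c, dose, "TD")
    assert res.t_half == pytest.approx(38.89, rel=0.05)
    assert res.AUC_extrap_pct < 20.0


def test_truncated_transdermal_extrapolation(typical_slow):
    """Stopping transdermal sampling at 72 h leaves a large extrapolated
    AUC fraction; extending to 216 h brings it below 20%."""
    dose = 3.3 * 4.0
    t_full = np.array(TD_SCHEDULE_H) * 60.0
    t_short = t_full[t_full <= 72 * 60.0]
    c_full = solve_profile(typical_slow, [DoseEvent("s", 0.0, dose, "TD")], t_full)
    c_short = c_full[: t_short.size]
    r_short = nca_single_profile(t_short, c_short, dose, "TD")
    r_full = nca_single_profile(t_full, c_full, dose, "TD")
    assert r_short.AUC_extrap_pct > 30.0
    assert r_full.AUC_extrap_pct < 20.0


def test_hand_trapezoid():
    """(0,0),(1,10),(2,5) with the plain linear rule integrates to 12.5."""
    res = nca_single_profile(np.array([0.0, 1.0, 2.0]), np.array([0.0, 10.0, 5.0]),
                             1.0, "PO", NCAConfig(trapezoid="linear"))
    assert res.AUC_last * 60.0 == pytest.approx(12.5)


def test_monoexponential_closed_forms():
    """Dense monoexponential sampling: AUCinf -> C0/k, MRT -> 1/k,
    Cl = D k / C0 and Vss = Cl * MRT."""
    k = 0.01  # 1/min
    c0 = 2.0  # mg/L
    d = 10.0  # mg
    t = np.linspace(0.5, 1200.0, 4000)
    c = c0 * np.exp(-k * t)
    res = nca_single_profile(t, c, d, "IV")
    assert res.AUC_inf * 60.0 == pytest.approx(c0 / k, rel=1e-3)
    assert res.MRT * 60.0 == pytest.approx(1.0 / k, rel=2e-3)
    assert res.Cl / 60.0 == pytest.approx(d * k / c0, rel=1e-3)
    assert res.Vss == pytest.approx(d / c0, rel=3e-3)
    assert res.C0 == pytest.approx(c0 * 1000.0, rel=1e-4)


def test_iv_auc_over_dose_published(typical_slow):
    """Noise-free slow-metabolizer IV profile over 7 terminal half-lives:
    AUCinf/Dose equals the reciprocal clearance, near the published 3.4 h/L."""
    dose = 2.2 * 4.0
    t = np.linspace(1.0, 7 * 7.06 * 60.0, 3000)
    c = solve_profile(typical_slow, [DoseEvent("s", 0.0, dose, "IV")], t)
    res = nca_single_profile(t, c, dose, "IV")
    assert res.AUC_over_dose == pytest.approx(1.0 / (typical_slow.Cl * 60.0), rel=0.01)
    assert res.AUC_over_dose == pytest.approx(3.4, rel=0.03)


def test_iv_clearance_recovery(typical_fast):
    """NCA clearance recovers the model clearance within 2% under dense
    sampling over >= 7 terminal half-lives."""
    dose = 8.8
    t = np.linspace(1.0, 5 * 24 * 60.0, 4000)
    c = solve_profile(typical_fast, [DoseEvent("s", 0.0, dose, "IV")], t)
    res = nca_single_profile(t, c, dose, "IV")
    assert res.Cl / 60.0 == pytest.approx(typical_fast.Cl, rel=0.02)
    assert res.Vss == pytest.approx(typical_fast.vss, rel=0.05)


def test_auc_monotone_in_added_samples(typical_fast):
    """Appending a later positive sample never decreases AUC_last."""
    dose = 13.2
    t = np.linspace(30.0, 4000.0, 25)
    c = solve_profile(typical_fast, [DoseEvent("s", 0.0, dose, "PO")], t)
    prev = 0.0
    for n in range(5, t.size + 1):
        res = nca_single_profile(t[:n], c[:n], dose, "PO")
        assert res.AUC_last >= prev - 1e-12
        prev = res.AUC_last


def test_dose_must_be_positive():
    with pytest.raises(ValueError):
        nca_single_profile(np.array([1.0, 2.0]), np.array([1.0, 0.5]), 0.0, "IV")


def test_summary_single_profile_group(typical_fast):
    t = np.linspace(1.0, 5000.0, 200)
    c = solve_profile(typical_fast, [DoseEvent("s", 0.0, 8.8, "IV")], t)
    res = nca_single_profile(t, c, 8.8, "IV", subject_id="a")
    tab = nca_summarize([res])
    mean = tab[(tab.stat == "Mean")].iloc[0]
    med = tab[(tab.stat == "Median")].iloc[0]
    sd = tab[(tab.stat == "SD")].iloc[0]
    assert mean["Cl"] == pytest.approx(med["Cl"])
    assert sd["Cl"] == 0.0


def test_summary_identical_profiles_zero_sd(typical_fast):
    t = np.linspace(1.0, 5000.0, 200)
    c = solve_profile(typical_fast, [DoseEvent("s", 0.0, 8.8, "IV")], t)
    results = [nca_single_profile(t, c, 8.8, "IV", subject_id=f"s{i}")
               for i in range(4)]
    tab = nca_summarize(results)
    sd = tab[tab.stat == "SD"].iloc[0]
    for col in ("Cl", "t_half", "Cmax", "MRT"):
        assert sd[col] == pytest.approx(0.0, abs=1e-12)


def test_summary_empty_errors():
    with pytest.raises(ValueError):
        nca_summarize([])


def test_transdermal_group_half_life_envelope():
    """An 8-subject transdermal group simulated with the study's
    inter-individual variability lands inside the published summary
    envelope (mean t1/2 38.89 +/- 10.69 h)."""
    from pigletpk.model import link_transform, published_model
    from pigletpk.nca import nca_summarize

    model = published_model()
    rng = np.random.default_rng(2209)
    chol = np.linalg.cholesky(model.omega + 1e-12 * np.eye(8))
    t = np.array(TD_SCHEDULE_H) * 60.0
    results = []
    for i in range(8):
        phi = link_transform(model, chol @ rng.standard_normal(8),
                             MET=int(rng.random() < 29 / 38))
        dose = 3.3 * 4.0
        c = solve_profile(phi, [DoseEvent("s", 0.0, dose, "TD")], t)
        c = c * (1.0 + model.b * rng.standard_normal(t.size))
        keep = c > 0.002  # LLOQ exclusion, as in the NCA convention
        results.append(nca_single_profile(t[keep], c[keep], dose, "TD",
                                          subject_id=f"td{i}"))
    tab = nca_summarize(results)
    mean_thalf = tab[(tab.route == "TD") & (tab.stat == "Mean")]["t_half"].iloc[0]
    assert abs(mean_thalf - 38.89) <= 10.69
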
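"""Closed-form structural model against analytic limits and an ODE oracle."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pigletpk.datatypes import DoseEvent, StructuralParams
from pigletpk.structural import mass_balance, solve_profile, solve_states

from conftest import ode_oracle


def _random_params(rng):
    return StructuralParams(
        Cl=float(rng.uniform(0.002, 0.05)), Vc=float(rng.uniform(0.5, 4.0)),
        Q=float(rng.uniform(0.0005, 0.02)), Vp=float(rng.uniform(0.3, 5.0)),
        F_top=float(rng.uniform(0.02, 0.6)), k_top=float(rng.uniform(1e-4, 5e-3)),
        Lag=float(rng.uniform(0.0, 60.0)), F_po=float(rng.uniform(0.5, 1.0)),
        k_po=float(rng.uniform(0.01, 0.3)))


def test_iv_bolus_initial_concentration(typical_fast):
    """An IV bolus of D into a central volume Vc starts at C = D/Vc."""
    c = solve_profile(typical_fast, [DoseEvent("s", 0.0, 1.35, "IV")],
                      np.array([0.0, 1.0]))
    assert c[0] == pytest.approx(1.0, abs=1e-12)


def test_no_doses_zero_profile(typical_fast):
    t = np.linspace(0, 1000, 20)
    assert np.all(solve_profile(typical_fast, [], t) == 0.0)


@pytest.mark.parametrize("route", ["TD", "PO", "IV"])
def test_matches_ode_oracle(route):
    """Closed-form profiles agree with adaptive-step numerical
    integration to 1e-8 relative on random parameter sets."""
    rng = np.random.default_rng(17)
    for _ in range(4):
        p = _random_params(rng)
        doses = [DoseEvent("s", 10.0, 13.2, route)]
        times = np.linspace(0.0, 6000.0, 50)
        ca = solve_profile(p, doses, times)
        cn = ode_oracle(p, doses, times)
        # compare where the oracle itself is accurate: below ~1e-6 of the
        # peak the integrator's absolute tolerance dominates
        mask = cn > 1e-6 * cn.max()
        assert np.max(np.abs(ca[mask] - cn[mask]) / cn[mask]) < 1e-8


def test_one_compartment_limit():
    """As Q -> 0 the IV profile collapses onto (D/Vc) exp(-Cl t / Vc)."""
    p = StructuralParams(Cl=0.01, Vc=2.0, Q=1e-12, Vp=1.0, F_top=0.1,
                        k_top=3e-4, Lag=0.0, F_po=1.0, k_po=0.06)
    t = np.linspace(0.0, 2000.0, 30)
    c = solve_profile(p, [DoseEvent("s", 0.0, 4.0, "IV")], t)
    ref = (4.0 / 2.0) * np.exp(-0.01 * t / 2.0)
    assert np.allclose(c, ref, rtol=1e-6)


def test_linearity_in_dose(typical_slow):
    """Doubling every dose amount doubles every concentration."""
    t = np.linspace(0.0, 20000.0, 60)
    doses1 = [DoseEvent("s", 0.0, 13.2, "TD"), DoseEvent("s", 500.0, 8.8, "IV")]
    doses2 = [DoseEvent("s", d.time, 2 * d.amount, d.route) for d in doses1]
    c1 = solve_profile(typical_slow, doses1, t)
    c2 = solve_profile(typical_slow, doses2, t)
    assert np.allclose(c2, 2 * c1, rtol=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(scale=st.floats(0.1, 10.0))
def test_linearity_property(scale):
    p = StructuralParams(Cl=0.012, Vc=1.35, Q=0.003, Vp=1.18, F_top=0.0784,
                        k_top=3e-4, Lag=26.4)
    t = np.linspace(0.0, 10000.0, 25)
    c1 = solve_profile(p, [DoseEvent("s", 0.0, 13.2, "TD")], t)
    c2 = solve_profile(p, [DoseEvent("s", 0.0, 13.2 * scale, "TD")], t)
    assert np.allclose(c2, scale * c1, rtol=1e-12, atol=0)


def test_flipflop_terminal_slope(typical_slow):
    """With transdermal absorption far slower than elimination the
    terminal log-slope is the absorption rate: t_half = ln2/k_top."""
    t = np.linspace(40000.0, 70000.0, 10)
    c = solve_profile(typical_slow, [DoseEvent("s", 0.0, 13.2, "TD")], t)
    slope = np.polyfit(t, np.log(c), 1)[0]
    assert -slope == pytest.approx(typical_slow.k_top, rel=1e-3)
    assert np.log(2) / typical_slow.k_top == pytest.approx(2310.5, rel=1e-3)


def test_iv_terminal_slope_is_disposition(typical_slow):
    """IV decay ends on the smaller disposition exponent, not k_top."""
    from pigletpk.structural import disposition_rates
    *_, beta = disposition_rates(typical_slow.Cl, typical_slow.Vc,
                                 typical_slow.Q, typical_slow.Vp)
    t = np.linspace(8000.0, 15000.0, 10)
    c = solve_profile(typical_slow, [DoseEvent("s", 0.0, 8.8, "IV")], t)
    slope = np.polyfit(t, np.log(c), 1)[0]
    assert -slope == pytest.approx(beta, rel=1e-6)


def test_unsorted_times_rejected(typical_fast):
    with pytest.raises(ValueError):
        solve_profile(typical_fast, [DoseEvent("s", 0.0, 1.0, "IV")],
                      np.array([10.0, 5.0]))


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        StructuralParams(Cl=-0.01, Vc=1.0, Q=0.003, Vp=1.0, F_top=0.1,
                         k_top=3e-4, Lag=0.0)
    with pytest.raises(ValueError):
        StructuralParams(Cl=0.01, Vc=1.0, Q=0.003, Vp=1.0, F_top=1.2,
                         k_top=3e-4, Lag=0.0)


# ---- mass balance ----------------------------------------------------

def test_iv_conservation(typical_fast):
    """remaining + eliminated equals the dose at every horizon."""
    doses = [DoseEvent("s", 0.0, 8.8, "IV")]
    for t_end in (10.0, 500.0, 5000.0, 50000.0):
        mb = mass_balance(typical_fast, doses, t_end)
        assert mb["eliminated"] + mb["remaining"] == pytest.approx(8.8, rel=1e-9)


def test_lag_semantics(typical_fast):
    """Before the transdermal lag has elapsed everything is pending."""
    mb = mass_balance(typical_fast, [DoseEvent("s", 0.0, 13.2, "TD")], 10.0)
    assert mb["remaining"] == 0.0
    assert mb["eliminated"] == 0.0
    assert mb["pending"] == pytest.approx(0.0784 * 13.2)
    assert mb["unabsorbed"] == pytest.approx((1 - 0.0784) * 13.2)


def test_asymptotic_completeness():
    """At ten times the slowest half-life, essentially the whole
    bioavailable dose has been eliminated."""
    rng = np.random.default_rng(3)
    for _ in range(3):
        p = _random_params(rng)
        from pigletpk.structural import disposition_rates
        *_, beta = disposition_rates(p.Cl, p.Vc, p.Q, p.Vp)
        slowest = np.log(2) / min(beta, p.k_top, p.k_po)
        doses = [DoseEvent("s", 0.0, 10.0, "TD"), DoseEvent("s", 0.0, 10.0, "PO")]
        mb = mass_balance(p, doses, 10.0 * slowest)
        bioavailable = p.F_top * 10.0 + p.F_po * 10.0
        assert mb["eliminated"] / bioavailable > 0.999


def test_full_accounting(typical_fast):
    mb = mass_balance(typical_fast, [DoseEvent("s", 0.0, 13.2, "TD"),
                                     DoseEvent("s", 100.0, 8.8, "IV")], 4000.0)
    total = (mb["absorbed"] + mb["depot_residue"] + mb["pending"]
             + mb["unabsorbed"])
    assert total == pytest.approx(mb["total_dosed"], rel=1e-9)


def test_crossover_carryover_below_lloq(typical_slow):
    """Nine days after a 3.3 mg/kg transdermal dose the predicted
    concentration is below the 2 ng/mL LLOQ, so superposed crossover
    periods start effectively clean."""
    c = solve_profile(typical_slow, [DoseEvent("s", 0.0, 13.2, "TD")],
                      np.array([9 * 24 * 60.0]))
    assert c[0] < 0.002


def test_states_match_profile(typical_fast):
    t = np.linspace(0.0, 8000.0, 15)
    doses = [DoseEvent("s", 0.0, 13.2, "TD"), DoseEvent("s", 0.0, 10.0, "PO")]
    states = solve_states(typical_fast, doses, t)
    c = solve_profile(typical_fast, doses, t)
    ac = np.array([s.A_c for s in states])
    assert np.allclose(ac / typical_fast.Vc, c, rtol=1e-9, atol=1e-15)
    assert all(min(s.A_po, s.A_td, s.A_c, s.A_p) >= -1e-12 for s in states)
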
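import numpy as np
import pytest

from pigletpk.datatypes import DoseEvent, StructuralParams
from pigletpk.model import published_model
from pigletpk.synth import GeneratorConfig, StudyDesign, generate_study


@pytest.fixture(scope="session")
def typical_fast() -> StructuralParams:
    """Typical-individual parameters, fast-metabolizer reference class."""
    return StructuralParams(Cl=0.012, Vc=1.35, Q=0.003, Vp=1.18, F_top=0.0784,
                            k_top=3e-4, Lag=26.4, F_po=1.0, k_po=0.06)


@pytest.fixture(scope="session")
def typical_slow() -> StructuralParams:
    return StructuralParams(Cl=0.012 * np.exp(-0.892), Vc=1.35, Q=0.003, Vp=1.18,
                            F_top=0.0784, k_top=3e-4, Lag=26.4, F_po=1.0, k_po=0.06)


@pytest.fixture(scope="session")
def study_dataset():
    """One seeded default synthetic study, shared across tests."""
    return generate_study(StudyDesign(), GeneratorConfig(seed=20260928))


def ode_oracle(params: StructuralParams, doses: list[DoseEvent], times: np.ndarray,
               rtol: float = 1e-11) -> np.ndarray:
    """Adaptive-step numerical integration of the full linear system —
    the independent reference for the closed-form solver."""
    from scipy.integrate import solve_ivp

    k10, k12, k21 = params.Cl / params.Vc, params.Q / params.Vc, params.Q / params.Vp
    events = []
    for d in doses:
        if d.route == "TD":
            events.append((d.time + params.Lag, 1, params.F_top * d.amount))
        elif d.route == "PO":
            events.append((d.time, 0, params.F_po * d.amount))
        else:
            events.append((d.time, 2, d.amount))
    events.sort()

    def rhs(t, y):
        apo, atd, ac, ap = y
        return [-params.k_po * apo, -params.k_top * atd,
                params.k_po * apo + params.k_top * atd - (k10 + k12) * ac + k21 * ap,
                k12 * ac - k21 * ap]

    y = np.zeros(4)
    out = np.zeros_like(times, dtype=float)
    tprev = 0.0
    for tev, comp, amt in events + [(float(times[-1]) + 1.0, -1, 0.0)]:
        seg = (times >= tprev) & (times < tev)
        if np.any(seg):
            sol = solve_ivp(rhs, (tprev, tev), y, t_eval=times[seg], rtol=rtol,
                            atol=1e-16, method="LSODA")
            out[seg] = sol.y[2]
        if tev > tprev:
            sol = solve_ivp(rhs, (tprev, tev), y, rtol=rtol, atol=1e-16,
                            method="LSODA")
            y = sol.y[:, -1]
        if comp >= 0:
            y[comp] += amt
        tprev = tev
    return out / params.Vc
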
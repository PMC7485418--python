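"""Published population-PK estimates for flunixin meglumine in pre-wean
piglets, used as the generative truth of the synthetic study and as the
reference point of worked examples.

Typical values use the internal unit scheme (L/min, L, 1/min, min;
bioavailabilities as fractions).  Inter-individual variability is
log-normal for all structural parameters except the transdermal
bioavailability, which is logit-normal; the reported CV% column maps to a
transformed-scale SD via omega = sqrt(ln(1 + CV^2)).  That same formula is
applied to the logit-linked bioavailability: a logit-normal on a 7.84 %
typical value cannot exceed ~127 % CV, so the reported 192 % is only
consistent with the log-normal CV convention applied to the logit-scale
SD, and the package adopts that convention throughout.
"""
from __future__ import annotations

import numpy as np

# ---- fixed effects (reference category MET = 0, i.e. fast metabolizer) ----
CL = 0.012          # L/min
BETA_CL_MET = -0.892  # additive on log-Cl for slow metabolizers (MET = 1)
VC = 1.35           # L
Q = 0.003           # L/min
VP = 1.18           # L
F_TOP = 0.0784      # fraction
K_TOP = 3.0e-4      # 1/min
LAG = 26.4          # min
F_PO = 1.0          # fixed in the final model
K_PO = 0.060        # 1/min
B_PROP = 0.294      # proportional residual-error scale

#: reported standard errors on the natural scale (None where fixed)
SE = {"Cl": 0.0008, "beta_Cl_MET": 0.07, "Vc": 0.164, "Q": 0.0007, "Vp": 0.169,
      "F_top": 0.0168, "k_top": 1.97e-5, "Lag": 3.2, "F_po": None,
      "k_po": 0.0101, "b": 0.0085}

#: reported inter-individual CV%
CV_PCT = {"Cl": 31.9, "Vc": 83.8, "Q": 227.0, "Vp": 106.0, "F_top": 192.0,
          "k_top": 29.9, "Lag": 148.0, "k_po": 30.5}


def omega_from_cv(cv_pct: float) -> float:
    """Transformed-scale SD implied by a reported CV% (log-normal convention)."""
    cv = cv_pct / 100.0
    return float(np.sqrt(np.log1p(cv * cv)))


#: transformed-scale (log / logit) IIV SDs implied by the CV% column
OMEGA_SD = {name: omega_from_cv(cv) for name, cv in CV_PCT.items()}

#: random-effect correlations retained in the final model
CORRELATIONS = {("Cl", "Q"): 0.612, ("Cl", "Vp"): 0.694, ("Cl", "F_top"): 0.853,
                ("Q", "Vp"): 0.967, ("Q", "F_top"): 0.766, ("Vp", "F_top"): 0.817}

# ---- study design constants -------------------------------------------
LLOQ_MGL = 0.002      # 2 ng/mL
DOSE_IV_IM = 2.2      # mg/kg
DOSE_PO_TD = 3.3      # mg/kg
N_FAST = 9
N_SLOW = 29
FAST_FRACTION = N_FAST / (N_FAST + N_SLOW)

# ---- COX inhibition targets (µg/L) ------------------------------------
COX1_IC50 = 21.46
COX2_IC50 = 63.34
COX1_IC80 = 390.52
COX2_IC80 = 894.63

# ---- bodyweight sub-model (Box-Cox scale) -----------------------------
BW_POP = 1.31
BW_IPV = 0.89
BW_SIGMA = 0.29
BW_LAMBDA = 0.14
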
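# pigletpk

Population pharmacokinetics of flunixin meglumine (FM) in pre-wean
piglets: a reusable Python pipeline covering the full analysis of a
four-route (IV / IM / PO / transdermal) PK study — synthetic study
generation, noncompartmental analysis (NCA), nonlinear mixed-effects
estimation by SAEM with below-LLOQ censoring, covariate and correlation
selection, goodness-of-fit diagnostics, and Monte-Carlo dose–exposure
simulation against COX inhibition targets.

It is written for PK modellers and veterinary pharmacologists who want
the complete analysis as inspectable, testable code rather than a chain
of GUI operations. No subject-level data from the original trial are
included: a first-class generator recreates the study design (39
piglets, two phases, a 9-day crossover washout, 2 ng/mL LLOQ) from the
published population parameters, and every stage of the pipeline is
exercised against that synthetic study.

## The model

Disposition is a two-compartment mammillary system with first-order
elimination from the central compartment; oral and transdermal doses
enter through parallel first-order depots, the transdermal one after an
absorption lag:

    dA_po/dt = −k_po·A_po
    dA_td/dt = −k_top·A_td
    dA_c/dt  = k_po·A_po + k_top·A_td − (Cl/Vc + Q/Vc)·A_c + (Q/Vp)·A_p
    dA_p/dt  = (Q/Vc)·A_c − (Q/Vp)·A_p,        C(t) = A_c(t)/Vc

Because k_top (≈3×10⁻⁴ min⁻¹) is far slower than elimination, the
transdermal route shows flip-flop kinetics: its terminal half-life
(ln 2 / k_top ≈ 38.5 h) reflects absorption, not elimination.

The population layer is a standard nonlinear mixed-effects hierarchy:
y_ij = F(φ_i, t_ij)·(1 + b·ε_ij), with log-normal individual parameters
φ_i = μ·exp(η_i) (logit-normal for the bioavailabilities), a binary
fast/slow metabolizer class acting multiplicatively on clearance
(Cl_i = Cl·e^{β·MET_i}), and free correlations among the random effects
of Cl, Q, Vp and F_top. Samples below the 2 ng/mL LLOQ contribute their
censored probability mass Φ((LLOQ − F)/(b·F)) to the likelihood (the
"M3" treatment). Estimation is stochastic-approximation EM (SAEM) with
MCMC conditional sampling, exact M-steps, and importance-sampled
log-likelihood for BIC.

## Worked example

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_nca.py
python analysis/03_fit_population_model.py --seed 1
python analysis/04_dose_panel.py --seed 1 --n 200
python analysis/05_bodyweight_submodel.py --seed 1
```

The first two steps print (seed 1):

```
39 piglets; subjects per route: {'IV': 16, 'IM': 7, 'PO': 8, 'TD': 24}
970 modeled observations, 151 below LLOQ (15.6%)
route-level means:
  IV  t1/2 =   9.13 h   AUCinf/Dose =   3.71 h/L   Cmax =  15003.4 ug/L
  IM  t1/2 =  10.64 h   AUCinf/Dose =   3.32 h/L   Cmax =   5371.8 ug/L
  PO  t1/2 =   9.72 h   AUCinf/Dose =   3.28 h/L   Cmax =  11537.3 ug/L
  TD  t1/2 =  41.79 h   AUCinf/Dose =   0.24 h/L   Cmax =     67.1 ug/L
```

— the transdermal half-life (~42 h here) towers over the intravascular
one: flip-flop absorption, and the transdermal dose-normalised exposure
is more than tenfold lower, reflecting its poor bioavailability. The
population fit then reports (same seed):

```
classified 10 fast / 29 slow metabolizers
final estimates:
  Cl      0.01086 L/min   Vc  1.30 L   Q  0.0021 L/min   Vp  0.96 L
  F_top   5.63 %          k_top 3.4e-4 /min   Lag 22.8 min
  beta_Cl_MET  -0.913     b 0.311
IWRES mean -0.007, var 0.863; 5-95% band coverage 94.0%
```

close to the generating values (Cl 0.012, Vc 1.35, Vp 1.18, F_top
7.84 %, β −0.892, b 0.294). The dose panel finally shows why a
transdermal analgesic dose is impractical: even 20 mg/kg keeps plasma FM
above the COX-2 IC80 (894.63 µg/L, the therapeutic benchmark) for only
~0.2 h on average, while exceeding the COX-1 IC80 (390.52 µg/L, the
gastrointestinal-toxicity marker) for ~7 h.

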
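# Methods

This note documents the models, algorithms and numerical choices behind
`pigletpk`, and what the synthetic-study results do and do not show.

## Structural model

One individual's kinetics follow a linear two-compartment mammillary
system (clearance Cl, central volume Vc, intercompartmental clearance Q,
peripheral volume Vp) with two parallel first-order input depots: oral
(bioavailability F_po, rate k_po) and transdermal (F_top, k_top, with a
lag that shifts the depot deposit time). IV and IM doses are central
boluses; IM carries no absorption parameters because intramuscular
bioavailability is complete and absorption is fast relative to the
sampling grid, so the two routes are kinetically indistinguishable here
(an optional first-order IM depot exists for sensitivity runs).

Profiles are evaluated in closed form: the disposition exponents α ≥ β
solve α+β = k10+k12+k21, αβ = k10·k21, a central bolus contributes a
bi-exponential, and a depot contributes the standard three-exponential
convolution. Superposition handles arbitrary dosing histories, including
the 9-day crossover washout (carry-over at 216 h is below the LLOQ at the
default parameters, which the tests assert). A ka–exponent coincidence
is a measure-zero degeneracy of the three-exponential form and is
handled by a 1e-7 relative nudge; the analytic solution agrees with an
adaptive ODE integration to better than 1e-8 relative wherever the
integrator itself is accurate. The closed form exists because a SAEM fit
needs ~10⁵ profile evaluations; the ODE integrator survives only as a
test oracle.

Internal units are minutes, mg, L and mg/L; the I/O layer alone converts
to the external convention (hours, µg/L). Default population values
(units above): Cl 0.012 (fast-metabolizer reference), β_Cl_MET −0.892,
Vc 1.35, Q 0.003, Vp 1.18, F_top 0.0784, k_top 3e-4, Lag 26.4, F_po 1,
k_po 0.060, proportional error b 0.294.

## Noncompartmental analysis

The terminal slope λz is a log-linear regression over the contiguous
terminal window maximising adjusted R², with at least three points,
Cmax excluded for extravascular profiles, and windows within 1e-4 of the
best adjusted R² resolved toward more points — the common "best fit"
default of NCA software. AUC/AUMC use linear-up/log-down trapezoids
(plain linear available); AUC∞ = AUC_last + C_last/λz. For IV profiles
C0 is back-extrapolated log-linearly from the first two quantifiable
samples and anchors the AUC at t=0. Clearance and Vss are absolute for
IV and apparent (Cl/F, Vss/F) otherwise; MRT is reported raw
(absorption-inclusive for extravascular routes — the convention that
makes Vss/F = (Cl/F)·MRT match the published summary table), and the
route-level summary additionally derives mean absorption times against
the IV MRT when IV data are present. BLQ samples are excluded from NCA
entirely: the mixed-effects stage treats censoring properly, NCA serves
initial estimates and descriptive summaries.

## Population model and SAEM

Transformed individual parameters ψ_i (log scale; logit for
bioavailabilities) are Gaussian: ψ_i = X_iθ + η_i, η_i ~ N(0, Ω), where
X_i carries the MET class effect on log-clearance. Residual error is
proportional with SD b·max(F, LLOQ/2); the floor keeps the censored term
finite when predictions approach zero and is logged when active.
Below-LLOQ observations contribute log Φ((LLOQ − F)/(b·F)).

Each SAEM iteration runs, per subject: one independent
Metropolis-Hastings proposal from the current population prior, one
componentwise adaptive Metropolis sweep over the likelihood-active
coordinates, and two adaptive full-vector random walks scaled by the
Cholesky factor of Ω (acceptance targeted at 0.3, diminishing
adaptation). Censored observations are then imputed from the truncated
Gaussian so the residual-scale statistic has a complete-data form.
Sufficient statistics are updated with step size 1 for the exploratory
phase (default 500 iterations) and 1/(k−K1)^0.7 while smoothing (default
200); the M-step is exact: GLS fixed effects, a block-structured
covariance (free correlations only among Cl, Q, Vp, F_top — the
covariance is block-diagonal under permutation, so blockwise sample
covariances are the exact M-step), and b from the imputed residuals.
During exploration the variances and b are annealed (never shrunk by
more than 5% per iteration) to avoid premature collapse.

Two design points deserve emphasis:

* **Rao-Blackwellised statistics.** Coordinates with no likelihood
  dependence for a subject (transdermal parameters of pigs never dosed
  transdermally, the oral rate of pigs never dosed orally) enter the
  sufficient statistics through their exact conditional prior moments
  rather than sampled values. Sampling them is valid but injects pure
  noise into population means identified by few subjects, which then
  random-walk under the unit exploratory step size and can diverge;
  the conditional-moment form removes that noise entirely while leaving
  the EM fixed points unchanged. The MCMC state still samples those
  coordinates so conditional draws remain complete for the correlation
  screens.
* **Boundary-aware multi-start for F_po.** Oral data identify Cl/F and
  the shape-anchored Cl/Vc, so a bioavailability truly at 1 sits at a
  logit boundary that a stochastic optimiser approaches only slowly.
  The exploratory stage therefore multi-starts (once from the NCA AUC
  ratio, once just below the boundary) and keeps the fit with the higher
  importance-sampled log-likelihood. Note the estimand itself is
  realization-dependent: with F_po ≡ 1 in truth, the estimate
  approximates min(1, exp(−mean η_Cl of the oral pigs)), so roughly half
  of synthetic replicates legitimately estimate F_po between ~0.8 and
  0.99 rather than >0.99. The final model fixes F_po at 1 (its IIV
  reported as the conventional 0.01 placeholder) regardless, mirroring
  the reference analysis.

Standard errors come from a stochastic (Louis-identity) approximation of
the observed Fisher information accumulated over the smoothing phase,
delta-method-mapped to the reporting scale. Because successive MCMC
states are autocorrelated, the missing-information term is
underestimated for parameters whose information is dominated by the
latent layer: SEs for the covariance block, and occasionally for β, can
be optimistic or unavailable (NaN) when the block sits on the PSD
boundary. For simulation studies, replicate-based spread is the more
trustworthy uncertainty measure; the reported SEs are adequate for the
RSE% bookkeeping of the parameter table. The observed-data
log-likelihood (for BIC = −2·logL + k·ln N_subjects) is estimated by
importance sampling with a multivariate-t proposal (df 5) built from
each subject's conditional draws.

Initial estimates come from NCA (IV clearance and back-extrapolated C0;
the transdermal terminal slope is k_top by flip-flop; the transdermal/IV
AUC-ratio seeds F_top; cluster means of labelled NCA clearances seed Cl
and β when MET labels exist); ω starts at 0.3, correlations at 0, b at
0.3.

## Metabolizer classification and screens

The fast/slow class is a one-dimensional exact 2-means split of
log-clearance proxies (per-subject NCA clearances, or conditional-mean
clearances from a base fit for subjects with only transdermal data);
the higher cluster is fast (MET = 0). When the cluster means are closer
than 0.25 on the log scale the population is treated as one (slow)
group. Under the default mixture (separation 0.892, ω_Cl 0.311) the
class distributions overlap, so ~3 of 38 subjects sit on the wrong side
of any boundary — a Bayes floor, not an implementation artefact.

Covariate screens are one-way ANOVA (sex, MET) and Pearson correlation
(bodyweight) on conditional-mean random effects; correlation screens
are pairwise Pearson tests; both use raw p < 0.05 without multiplicity
correction (a deliberate fidelity-to-reference limitation). Conditional
means of posterior draws, not EBE modes, feed the screens to limit
shrinkage distortion.

## Bodyweight sub-model

(BW^λ − 1)/λ = BW_pop + IPV·[phase 2] + ε, ε ~ N(0, σ²), with defaults
BW_pop 1.31, IPV 0.89, σ 0.29, λ 0.14 — a phase-1 typical weight of
3.33 kg and phase-2 of 6.81 kg. The λ grid (−2 to 2, step 0.1) is scored
with the geometric-mean-normalised transform: raw SSE is not comparable
across λ (it degenerates toward λ = −2), and the normalised criterion is
the standard Box-Cox profile likelihood. A cubic spline interpolates the
score curve and the minimiser is read off a 0.001 grid. Inversion during
sampling redraws the ~1-in-10⁵ residuals that leave the transform's
domain.

## Dose–exposure simulation

For each dose the simulator draws individuals (correlated random
effects, fast fraction 9/38, phase-1 bodyweights), simulates noise-free
single-dose transdermal profiles on a 5-minute grid out to 10 days (the
flip-flop half-life of ~39 h needs the long horizon), and integrates the
time each course spends above the four COX thresholds (COX-1/2 IC50
21.46 / 63.34 µg/L, IC80 390.52 / 894.63 µg/L) with linear interpolation
at crossings. Two summaries are reported and clearly labelled: the
distribution of per-individual times (mean, median, interquartile band —
the published dose-finding figure's quantities) and the time above
target of the population-mean course. The latter is tail-insensitive:
at 20 mg/kg the mean course never reaches the COX-1 IC80, while the
per-individual mean time above it is several hours, carried by the
minority of high-bioavailability individuals.

## Synthetic-study generator

The generator reproduces the trial design exactly: Phase I parallel
groups (IM n=7 at 2.2 mg/kg, PO and TD n=8 at 3.3 mg/kg; sampling 0–90
min and 2–72 h), Phase II IV/TD crossover (n=16, half IV-first; IV
sampling to 60 h, TD to 216 h; the period-2 dose sits half a minute
after the washout so the final period-1 draw is a genuine pre-dose
sample), per-kg doses from phase-appropriate bodyweights, correlated
IIV at the default truth, proportional noise truncated at zero
(negative draws resampled and counted), and strict-inequality LLOQ
censoring with the LLOQ stored in place of the value. Pre-dose (t=0)
samples are generated as true zeros, flagged BLQ and excluded from
fitting. Optional flags emulate the real study's exclusions (one oral
subject; a configurable number of IV samples).

Two conventions resolve ambiguities in the reported parameterisation:
the IIV CV% of the logit-linked F_top uses the log-normal formula
100·sqrt(exp(ω²)−1) applied to the logit-scale SD (a logit-normal with a
7.84% typical value cannot exceed ~127% CV, so the reported 192% is only
consistent with that convention; the generator inverts it, ω = 1.243);
and correlations are drawn only within the {Cl, Q, Vp, F_top} block.

What the generator does not emulate: assay batch effects, dropout or
sparse missingness, dose-timing deviations, within-subject parameter
variability between crossover periods, and any real-data artefacts
(e.g. the regurgitated oral dose beyond a wholesale exclusion flag).
Passing tests therefore demonstrate the pipeline's internal correctness
and its behaviour under the published statistical structure — not that
the published estimates are recoverable from the original raw data.

## Problem sizes and determinism

Default analysis sizes: 39-subject studies, SAEM 500 exploratory + 200
smoothing iterations, 500 conditional draws for the log-likelihood, 500
Monte-Carlo individuals per dose, 500 study replicates for the
prediction distribution. The test-suite uses shortened SAEM schedules
(120–300 exploratory iterations) and smaller replicate counts chosen as
honest convergence points for their assertions. All stochastic stages
are driven by explicit seeds; a refit with the same seed is bit-for-bit
identical.

## Known limitations

* Louis-approximation SEs can be optimistic/NaN near covariance
  boundaries (above); BIC depends on an importance-sampling estimate
  with Monte-Carlo error of order ±1–2 log-units.
* The fast/slow class of subjects with only transdermal data is weakly
  identified; classification there leans on the random-effect
  correlation structure.
* The exploratory F_po estimate is realization-dependent by design of
  the estimand (above).
* No between-occasion variability, saturable elimination, transit-chain
  absorption or infusion records.
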
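"""Synthetic study generator.

Recreates the two-phase piglet trial — Phase I parallel groups (IM n=7 at
2.2 mg/kg, PO n=8 and TD n=8 at 3.3 mg/kg) and a Phase II IV/TD crossover
(n=16, 9-day washout) — with the published sampling schedules, LLOQ
censoring at 2 ng/mL, a fast/slow metabolizer mixture on clearance,
correlated log-normal / logit-normal inter-individual variability and
proportional residual error.  The generator's defaults are the study
conditions; every downstream module is exercised against its output.

Conventions: pre-dose (time-0) samples are generated as true zeros,
flagged BLQ and excluded from fitting.  Phase II period-2 concentrations
arise by superposition from period 1 (with the published parameters the
carry-over at 216 h is below the LLOQ).  Negative noise draws are
resampled rather than truncated to zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import published as pub
from .bodyweight import BodyweightModel, sample_bodyweight
from .datatypes import DoseEvent, Observation, PKDataset, SubjectCovariates
from .model import PopulationModel, link_transform, published_model
from .structural import solve_profile

log = logging.getLogger(__name__)

__all__ = ["StudyDesign", "GeneratorConfig", "generate_study", "censor_lloq",
           "default_design"]

_H = 60.0

#: Phase I sampling schedule (minutes): 0–90 min then 2–72 h
SCHEDULE_PHASE1 = tuple([0.0, 15, 30, 45, 60, 90]
                        + [h * _H for h in (2, 3, 6, 12, 24, 36, 48, 60, 72)])
#: Phase II IV schedule: 0–90 min then 2–60 h
SCHEDULE_IV = tuple([0.0, 5, 15, 30, 45, 60, 90]
                    + [h * _H for h in (2, 3, 6, 12, 24, 36, 48, 60)])
#: Phase II TD schedule: 0–90 min then 2–216 h
SCHEDULE_TD = tuple([0.0, 15, 30, 45, 60, 90]
                    + [h * _H for h in (2, 3, 6, 12, 24, 36, 48, 60, 72, 84, 96, 108,
                                        120, 132, 144, 156, 168, 180, 192, 204, 216)])
#: 9-day washout between crossover periods (minutes)
WASHOUT = 9 * 24 * _H


@dataclass(frozen=True)
class StudyDesign:
    n_im: int = 7
    n_po: int = 8
    n_td: int = 8
    n_crossover: int = 16
    dose_iv: float = pub.DOSE_IV_IM   # mg/kg
    dose_im: float = pub.DOSE_IV_IM
    dose_po: float = pub.DOSE_PO_TD
    dose_td: float = pub.DOSE_PO_TD
    schedule_phase1: tuple = SCHEDULE_PHASE1
    schedule_iv: tuple = SCHEDULE_IV
    schedule_td: tuple = SCHEDULE_TD
    washout: float = WASHOUT
    lloq: float = pub.LLOQ_MGL        # mg/L

    def __post_init__(self) -> None:
        for sched in (self.schedule_phase1, self.schedule_iv, self.schedule_td):
            if np.any(np.diff(sched) <= 0):
                raise ValueError("schedules must be strictly increasing")
        if min(self.n_im, self.n_po, self.n_td, self.n_crossover) < 1:
            raise ValueError("group sizes must be positive")


def default_design() -> StudyDesign:
    return StudyDesign()


@dataclass
class GeneratorConfig:
    truth: PopulationModel = None
    bodyweight: BodyweightModel = field(default_factory=BodyweightModel)
    fast_fraction: float = pub.FAST_FRACTION
    seed: int = 0
    drop_po_pig: bool = False      # emulate the regurgitated oral dose
    drop_iv_points: int = 0        # emulate unverifiable IV samples

    def __post_init__(self) -> None:
        if self.truth is None:
            self.truth = published_model()
        if not (0.0 <= self.fast_fraction <= 1.0):
            raise ValueError("fast_fraction must lie in [0, 1]")
        if np.min(np.linalg.eigvalsh(self.truth.omega)) < -1e-10:
            raise ValueError("truth omega must be positive semi-definite")


def censor_lloq(observations: list[Observation], lloq: float) -> tuple[list[Observation], int]:
    """Flag concentrations strictly below the LLOQ as censored (value set
    to the LLOQ itself); returns the new list and the number of flips."""
    if not lloq > 0:
        raise ValueError("lloq must be > 0")
    out, flips = [], 0
    for ob in observations:
        if not ob.censored and ob.concentration < lloq:
            out.append(Observation(ob.subject_id, ob.time, lloq, censored=True,
                                   excluded=ob.excluded))
            flips += 1
        else:
            out.append(ob)
    return out, flips


def _draw_eta(rng: np.random.Generator, omega: np.ndarray) -> np.ndarray:
    chol = np.linalg.cholesky(omega + 1e-12 * np.eye(omega.shape[0]))
    return chol @ rng.standard_normal(omega.shape[0])


def _noisy(rng: np.random.Generator, f: np.ndarray, b: float) -> np.ndarray:
    """Proportional noise y = F*(1 + b*eps); negative draws are resampled."""
    y = np.empty_like(f)
    todo = np.arange(f.size)
    resampled = 0
    while todo.size:
        cand = f[todo] * (1.0 + b * rng.standard_normal(todo.size))
        ok = cand >= 0
        y[todo[ok]] = cand[ok]
        resampled += int(np.sum(~ok))
        todo = todo[~ok]
    if resampled:
        log.debug("resampled %d negative concentration draws", resampled)
    return y


def _subject_records(rng, cfg, lloq, sid, doses_spec, obs_times):
    """Simulate one subject: returns (covariates, dose events, observations)."""
    sex = "M" if rng.random() < 0.5 else "F"
    met = 0 if rng.random() < cfg.fast_fraction else 1
    phase = doses_spec[0][3]
    bw = float(sample_bodyweight(cfg.bodyweight, 1, phase=phase, seed=rng)[0])
    eta = _draw_eta(rng, cfg.truth.omega)
    phi = link_transform(cfg.truth, eta, MET=met)
    doses = [DoseEvent(sid, t, rate * bw, route, phase=ph, period=per)
             for (t, rate, route, ph, per) in doses_spec]
    times = np.asarray(obs_times, float)
    f = solve_profile(phi, doses, times)
    y = _noisy(rng, f, cfg.truth.b)
    obs = []
    for t, yy in zip(times, y):
        if t == 0.0:  # pre-dose draw: a true zero, recorded as BLQ and
            # excluded from fitting (stored at the LLOQ per the censoring
            # convention — a censored field never holds a bare zero)
            obs.append(Observation(sid, t, lloq, censored=True, excluded=True))
        else:
            obs.append(Observation(sid, float(t), float(yy)))
    cov = SubjectCovariates(sid, sex, bw, MET=met)
    return cov, doses, obs


def generate_study(design: StudyDesign = None, config: GeneratorConfig = None) -> PKDataset:
    """Generate a complete synthetic study as a :class:`PKDataset`.

    The true MET class used in generation is attached to the covariates
    (a re-analysis classifies metabolizers itself and may overwrite it).
    """
    design = design or StudyDesign()
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    covs, doses, obs = [], [], []

    def add(sid, doses_spec, obs_times):
        c, d, o = _subject_records(rng, config, design.lloq, sid, doses_spec, obs_times)
        covs.append(c)
        doses.extend(d)
        obs.extend(o)

    # ---- Phase I parallel groups ----------------------------------
    for i in range(design.n_im):
        add(f"P1IM{i+1:02d}", [(0.0, design.dose_im, "IM", 1, 1)], design.schedule_phase1)
    for i in range(design.n_po):
        add(f"P1PO{i+1:02d}", [(0.0, design.dose_po, "PO", 1, 1)], design.schedule_phase1)
    for i in range(design.n_td):
        add(f"P1TD{i+1:02d}", [(0.0, design.dose_td, "TD", 1, 1)], design.schedule_phase1)

    # ---- Phase II IV/TD crossover ---------------------------------
    # period-2 doses sit half a minute after the washout so the final
    # period-1 sample (drawn first) is a genuine pre-dose sample
    t2 = design.washout + 0.5
    half = design.n_crossover // 2
    for i in range(design.n_crossover):
        sid = f"P2X{i+1:02d}"
        iv_first = i < half
        if iv_first:
            spec = [(0.0, design.dose_iv, "IV", 2, 1), (t2, design.dose_td, "TD", 2, 2)]
            times = sorted(set(list(design.schedule_iv)
                               + [design.washout + t for t in design.schedule_td]))
        else:
            spec = [(0.0, design.dose_td, "TD", 2, 1), (t2, design.dose_iv, "IV", 2, 2)]
            times = sorted(set(list(design.schedule_td)
                               + [design.washout + t for t in design.schedule_iv]))
        add(sid, spec, np.array(times))

    obs, _ = censor_lloq(obs, design.lloq)

    # ---- optional exclusion emulation -----------------------------
    if config.drop_po_pig:
        po_ids = [c.subject_id for c in covs if c.subject_id.startswith("P1PO")]
        victim = po_ids[int(rng.integers(len(po_ids)))]
        obs = [Observation(o.subject_id, o.time, o.concentration, o.censored, True)
               if o.subject_id == victim else o for o in obs]
    if config.drop_iv_points > 0:
        # samples drawn during each crossover pig's IV period
        iv_window = {}
        for d in doses:
            if d.route == "IV" and d.phase == 2:
                lo = d.time
                hi = design.washout if d.period == 1 else np.inf
                iv_window[d.subject_id] = (lo, hi)
        cand = [k for k, o in enumerate(obs)
                if o.subject_id in iv_window and not o.excluded
                and iv_window[o.subject_id][0] < o.time <= iv_window[o.subject_id][1]]
        take = rng.choice(len(cand), size=min(config.drop_iv_points, len(cand)),
                          replace=False)
        drop = {cand[j] for j in take}
        obs = [Observation(o.subject_id, o.time, o.concentration, o.censored, True)
               if k in drop else o for k, o in enumerate(obs)]

    return PKDataset(doses=doses, observations=obs, covariates=covs, lloq=design.lloq)
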
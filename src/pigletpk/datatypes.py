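"""Core exchange types for the piglet flunixin PK pipeline.

All internal quantities use one unit scheme: time in minutes, amounts in
mg, volumes in L, concentrations in mg/L.  The I/O layer converts to and
from the external convention (hours in some reports, µg/L == ng/mL for
plasma concentrations); nothing else in the package touches units.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

ROUTES = ("IV", "IM", "PO", "TD")

#: µg/L per mg/L
UGL_PER_MGL = 1000.0
#: minutes per hour
MIN_PER_H = 60.0


@dataclass(frozen=True)
class DoseEvent:
    """A single administration of flunixin meglumine.

    time is minutes since the subject's first event; amount is the full
    administered amount in mg (bioavailability is applied by the
    structural model, not here).
    """

    subject_id: str
    time: float
    amount: float
    route: str
    phase: int = 1
    period: int = 1

    def __post_init__(self) -> None:
        if self.route not in ROUTES:
            raise ValueError(f"unknown route {self.route!r}; expected one of {ROUTES}")
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")


@dataclass(frozen=True)
class Observation:
    """A plasma concentration sample (mg/L internally).

    ``censored`` marks a below-LLOQ sample; the concentration field then
    holds the LLOQ itself, never zero, so a true zero and a BLQ value
    cannot be confused.  ``excluded`` rows are retained in the dataset but
    skipped by every downstream stage.
    """

    subject_id: str
    time: float
    concentration: float
    censored: bool = False
    excluded: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration}")


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-piglet covariates; MET is the fast(0)/slow(1) metabolizer label
    and may be None before classification."""

    subject_id: str
    sex: str
    bodyweight: float
    MET: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if not self.bodyweight > 0:
            raise ValueError(f"bodyweight must be > 0, got {self.bodyweight}")
        if self.MET is not None and self.MET not in (0, 1):
            raise ValueError(f"MET must be 0, 1 or None, got {self.MET}")


@dataclass
class PKDataset:
    """Ordered dose events and (possibly censored) observations with
    covariates — the single exchange format between all pipeline stages.

    ``lloq`` is in mg/L internally (the study assay's 2 ng/mL == 0.002 mg/L).
    """

    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)
    covariates: list[SubjectCovariates] = field(default_factory=list)
    lloq: float = 0.002

    def __post_init__(self) -> None:
        if not self.lloq > 0:
            raise ValueError("lloq must be > 0")
        known = {c.subject_id for c in self.covariates}
        for ob in self.observations:
            if ob.subject_id not in known:
                raise ValueError(f"observation subject {ob.subject_id!r} has no covariates")
        for d in self.doses:
            if d.subject_id not in known:
                raise ValueError(f"dose subject {d.subject_id!r} has no covariates")

    # ---- queries ---------------------------------------------------

    @property
    def subject_ids(self) -> list[str]:
        return [c.subject_id for c in self.covariates]

    @property
    def n_subjects(self) -> int:
        return len(self.covariates)

    def covariates_for(self, subject_id: str) -> SubjectCovariates:
        for c in self.covariates:
            if c.subject_id == subject_id:
                return c
        raise KeyError(subject_id)

    def doses_for(self, subject_id: str) -> list[DoseEvent]:
        return [d for d in self.doses if d.subject_id == subject_id]

    def observations_for(self, subject_id: str, include_excluded: bool = False) -> list[Observation]:
        obs = [o for o in self.observations if o.subject_id == subject_id]
        if not include_excluded:
            obs = [o for o in obs if not o.excluded]
        return obs

    def routes_for(self, subject_id: str) -> set[str]:
        return {d.route for d in self.doses_for(subject_id)}

    def subjects_per_route(self) -> dict[str, int]:
        """Number of distinct subjects that received each route."""
        counts = {r: 0 for r in ROUTES}
        for sid in self.subject_ids:
            for r in self.routes_for(sid):
                counts[r] += 1
        return counts

    def n_observations(self, include_excluded: bool = False) -> int:
        if include_excluded:
            return len(self.observations)
        return sum(1 for o in self.observations if not o.excluded)

    def n_censored(self, include_excluded: bool = False) -> int:
        obs = self.observations if include_excluded else [o for o in self.observations if not o.excluded]
        return sum(1 for o in obs if o.censored)

    def with_met(self, met: dict[str, int]) -> "PKDataset":
        """Return a copy with MET labels attached from a subject_id -> {0,1} map."""
        covs = [replace(c, MET=met.get(c.subject_id, c.MET)) for c in self.covariates]
        return PKDataset(doses=list(self.doses), observations=list(self.observations),
                         covariates=covs, lloq=self.lloq)


@dataclass(frozen=True)
class StructuralParams:
    """The nine structural constants of one individual.

    Two-compartment mammillary disposition (Cl, Vc, Q, Vp) with two
    parallel first-order depots: oral (F_po, k_po) and transdermal
    (F_top, k_top) — the latter with an absorption lag.  Units: L/min,
    L, 1/min, min; bioavailabilities are fractions.
    """

    Cl: float
    Vc: float
    Q: float
    Vp: float
    F_top: float
    k_top: float
    Lag: float
    F_po: float = 1.0
    k_po: float = 0.06

    def __post_init__(self) -> None:
        for name in ("Cl", "Vc", "Q", "Vp", "k_top", "k_po"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("F_top", "F_po"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.Lag < 0:
            raise ValueError("Lag must be >= 0")

    @property
    def vss(self) -> float:
        """Steady-state volume of distribution, Vc + Vp (L)."""
        return self.Vc + self.Vp


@dataclass(frozen=True)
class CompartmentState:
    """Amounts (mg) in the four compartments at one instant."""

    A_po: float
    A_td: float
    A_c: float
    A_p: float


def as_route_array(doses: Iterable[DoseEvent]) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Times, amounts and routes of a dose list as parallel arrays."""
    ds = list(doses)
    return (np.array([d.time for d in ds], dtype=float),
            np.array([d.amount for d in ds], dtype=float),
            [d.route for d in ds])
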
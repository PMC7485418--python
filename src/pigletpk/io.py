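"""Reading and writing study tables.

The on-disk format is a long, one-row-per-event CSV in the style of
standard PK datasets: ``ID, TIME, EVID, AMT, ROUTE, DV, BLQ, EXCL, SEX,
BW, MET, PHASE, PERIOD``.  ``EVID`` discriminates dose rows (1) from
observation rows (0); ``DV`` holds the measured concentration in µg/L
(equal to ng/mL) or the string ``BLQ`` for a censored sample; external
time is in hours and amounts in mg.  Internally everything is converted
once, at this layer, to minutes / mg / mg/L.

A small key=value config file can override the delimiter, the LLOQ and
the external time/concentration units.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (MIN_PER_H, UGL_PER_MGL, DoseEvent, Observation, PKDataset,
                        SubjectCovariates)

__all__ = ["IOConfig", "read_dataset", "write_dataset", "write_results",
           "read_config", "fit_result_table"]

_COLUMNS = ["ID", "TIME", "EVID", "AMT", "ROUTE", "DV", "BLQ", "EXCL",
            "SEX", "BW", "MET", "PHASE", "PERIOD"]
_REQUIRED = ["ID", "TIME", "EVID", "AMT", "ROUTE", "DV", "BLQ"]


@dataclass(frozen=True)
class IOConfig:
    delimiter: str = ","
    lloq_ugl: float = 2.0            # µg/L
    time_unit: str = "h"             # "h" or "min"
    conc_unit: str = "ug/L"          # "ug/L" or "mg/L"

    @property
    def time_to_min(self) -> float:
        return MIN_PER_H if self.time_unit == "h" else 1.0

    @property
    def conc_to_mgl(self) -> float:
        return 1.0 / UGL_PER_MGL if self.conc_unit == "ug/L" else 1.0


def read_config(path: str | Path) -> IOConfig:
    """Parse a plain key=value config file (unknown keys rejected)."""
    kw = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key == "delimiter":
            kw["delimiter"] = {"comma": ",", "tab": "\t"}.get(val, val)
        elif key == "lloq_ugl":
            kw["lloq_ugl"] = float(val)
        elif key in ("time_unit", "conc_unit"):
            kw[key] = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    return IOConfig(**kw)


class FormatError(ValueError):
    pass


def read_dataset(path: str | Path, config: IOConfig = IOConfig()) -> PKDataset:
    """Read a long-format study CSV into a validated :class:`PKDataset`."""
    df = pd.read_csv(path, sep=config.delimiter, dtype={"ID": str})
    for col in _REQUIRED:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    doses, obs, covs = [], [], {}
    lloq = config.lloq_ugl * config.conc_to_mgl
    for k, row in df.iterrows():
        sid = str(row["ID"])
        t = float(row["TIME"]) * config.time_to_min
        if t < 0:
            raise ValueError(f"row {k}: negative time {row['TIME']}")
        if sid not in covs:
            covs[sid] = SubjectCovariates(
                sid, str(row.get("SEX", "F")), float(row.get("BW", np.nan)),
                MET=None if pd.isna(row.get("MET")) else int(row["MET"]))
        if int(row["EVID"]) == 1:
            amt = float(row["AMT"])
            if amt <= 0:
                raise ValueError(f"row {k}: non-positive dose amount {amt}")
            doses.append(DoseEvent(sid, t, amt, str(row["ROUTE"]),
                                   phase=int(row.get("PHASE", 1) or 1),
                                   period=int(row.get("PERIOD", 1) or 1)))
        else:
            blq = bool(int(row["BLQ"])) if not pd.isna(row["BLQ"]) else False
            excl = bool(int(row.get("EXCL", 0) or 0))
            dv = row["DV"]
            if isinstance(dv, str) and dv.strip().upper() == "BLQ":
                blq = True
                conc = lloq
            elif blq:
                conc = lloq
            else:
                conc = float(dv) * config.conc_to_mgl
                if conc < 0:
                    raise ValueError(f"row {k}: negative concentration {dv}")
            obs.append(Observation(sid, t, conc, censored=blq, excluded=excl))
    return PKDataset(doses=doses, observations=obs, covariates=list(covs.values()),
                     lloq=lloq)


def write_dataset(dataset: PKDataset, path: str | Path,
                  config: IOConfig = IOConfig()) -> Path:
    """Write a :class:`PKDataset` back to the long CSV format (the exact
    inverse of :func:`read_dataset`)."""
    path = Path(path)
    cov = {c.subject_id: c for c in dataset.covariates}
    rows = []
    events = ([("dose", d.time, d) for d in dataset.doses]
              + [("obs", o.time, o) for o in dataset.observations])
    order = {sid: i for i, sid in enumerate(dataset.subject_ids)}
    events.sort(key=lambda e: (order[e[2].subject_id], e[1], e[0] == "obs"))
    for kind, t, ev in events:
        c = cov[ev.subject_id]
        base = {"ID": ev.subject_id, "TIME": t / config.time_to_min,
                "SEX": c.sex, "BW": c.bodyweight,
                "MET": "" if c.MET is None else c.MET}
        if kind == "dose":
            rows.append({**base, "EVID": 1, "AMT": ev.amount, "ROUTE": ev.route,
                         "DV": "", "BLQ": "", "EXCL": 0,
                         "PHASE": ev.phase, "PERIOD": ev.period})
        else:
            rows.append({**base, "EVID": 0, "AMT": "", "ROUTE": "",
                         "DV": "BLQ" if ev.censored else ev.concentration / config.conc_to_mgl,
                         "BLQ": int(ev.censored), "EXCL": int(ev.excluded),
                         "PHASE": "", "PERIOD": ""})
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep=config.delimiter,
                                                index=False)
    return path


def write_results(tables: dict[str, pd.DataFrame], path: str | Path) -> list[Path]:
    """Write named result tables as CSVs with stable column order."""
    if not tables:
        raise ValueError("no tables to write")
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        if not isinstance(df, pd.DataFrame) or df.empty:
            raise ValueError(f"table {name!r} is empty")
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    return written


def fit_result_table(fit) -> pd.DataFrame:
    """Parameter table in the conventional layout: estimate, SE, RSE%, CV%."""
    est = fit.estimates
    rows = []
    for n in est.param_names:
        unit = {"Cl": "L/min", "Vc": "L", "Q": "L/min", "Vp": "L", "F_top": "%",
                "k_top": "1/min", "Lag": "min", "k_po": "1/min", "F_po": "%"}[n]
        v = est.theta[n] * (100.0 if unit == "%" else 1.0)
        se = fit.standard_errors.get(n, np.nan)
        rows.append({"parameter": n, "unit": unit, "estimate": v,
                     "se": se * (100.0 if unit == "%" else 1.0),
                     "rse_pct": fit.rse_pct.get(n, np.nan),
                     "cv_pct": fit.cv_pct.get(n, np.nan)})
    rows.append({"parameter": "beta_Cl_MET", "unit": "-",
                 "estimate": est.beta_cl_met,
                 "se": fit.standard_errors.get("beta_Cl_MET", np.nan),
                 "rse_pct": fit.rse_pct.get("beta_Cl_MET", np.nan),
                 "cv_pct": np.nan})
    if not est.fpo_free:
        rows.append({"parameter": "F_po", "unit": "%", "estimate": 100.0,
                     "se": np.nan, "rse_pct": np.nan, "cv_pct": 0.0})
    rows.append({"parameter": "b", "unit": "-", "estimate": est.b,
                 "se": fit.standard_errors.get("b", np.nan),
                 "rse_pct": fit.rse_pct.get("b", np.nan), "cv_pct": np.nan})
    names = est.param_names
    sd = np.sqrt(np.diag(est.omega))
    for key, se in fit.standard_errors.items():
        if key.startswith("corr("):
            a, c = key[5:-1].split(",")
            ia, ic = names.index(a), names.index(c)
            rho = est.omega[ia, ic] / (sd[ia] * sd[ic])
            rows.append({"parameter": key, "unit": "-", "estimate": rho,
                         "se": se, "rse_pct": fit.rse_pct.get(key, np.nan),
                         "cv_pct": np.nan})
    return pd.DataFrame(rows)
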
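"""Data model and tidy-CSV I/O.

The exchange format is a tidy CSV with one measurement per row and the
columns ``subject, period, dose_mg_kg, matrix, time_h, conc_ug_ml, blq``.
Times are decimal hours post-dose, concentrations µg/mL.  Observations
below the lower limit of quantification (LLOQ) are stored as a boolean
flag with the concentration withheld — never substituted by 0 or LLOQ/2;
each analysis stage applies its own censoring policy.  Pre-dose time-0
rows (the study control sample) are accepted on input but flagged as
control and excluded from every computation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

__all__ = [
    "ConcProfile",
    "StudyDataset",
    "RunConfig",
    "read_profiles",
    "write_dataset",
    "write_results",
    "provenance",
    "LLOQ_DEFAULT",
    "MRL_DEFAULT",
    "PAPER_SCHEDULE",
]

log = logging.getLogger("milkpk")

#: Default lower limit of quantification for both matrices, µg/mL.
LLOQ_DEFAULT = 0.04

#: Default maximum residue limit for milk, µg/kg.
MRL_DEFAULT = 50.0

#: Post-dose nominal sampling schedule of the study design, hours.
#: The pre-dose 0 h control sample is not part of the analyzed series.
PAPER_SCHEDULE = (
    0.08, 0.17, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0,
    4.0, 5.0, 6.0, 8.0, 10.0, 12.0, 18.0, 24.0, 48.0,
)

REQUIRED_COLUMNS = (
    "subject", "period", "dose_mg_kg", "matrix", "time_h", "conc_ug_ml", "blq",
)

MATRICES = ("plasma", "milk")


@dataclass(frozen=True)
class ConcProfile:
    """One subject × matrix × dose concentration–time series.

    ``concs`` holds NaN at BLQ positions; ``blq`` marks them.  Invariants:
    strictly increasing times, aligned arrays, every quantifiable
    concentration at or above the LLOQ.
    """

    subject_id: str
    period: int
    dose: float            # mg/kg
    matrix: str            # "plasma" | "milk"
    times: np.ndarray      # h, strictly increasing
    concs: np.ndarray      # µg/mL, NaN where BLQ
    blq: np.ndarray        # bool, aligned
    lloq: float            # µg/mL

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "concs", np.asarray(self.concs, dtype=float))
        object.__setattr__(self, "blq", np.asarray(self.blq, dtype=bool))
        ctx = f"subject {self.subject_id!r}, matrix {self.matrix!r}, dose {self.dose}"
        if self.matrix not in MATRICES:
            raise ValidationError(f"unknown matrix {self.matrix!r} ({ctx})")
        if not (self.lloq > 0):
            raise ValidationError(f"lloq must be > 0 ({ctx})")
        if not (self.dose > 0):
            raise ValidationError(f"dose must be > 0 ({ctx})")
        if not (len(self.times) == len(self.concs) == len(self.blq)):
            raise ValidationError(f"times/concs/blq lengths differ ({ctx})")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValidationError(f"times not strictly increasing ({ctx})")
        if len(self.times) and np.any(self.times < 0):
            raise ValidationError(f"negative time ({ctx})")
        q = ~self.blq
        if np.any(self.concs[q] < 0):
            raise ValidationError(f"negative concentration ({ctx})")
        if np.any(self.concs[q] < self.lloq):
            raise ValidationError(
                f"quantifiable concentration below LLOQ without BLQ flag ({ctx})"
            )

    @property
    def n(self) -> int:
        return len(self.times)

    def quantifiable(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (times, concs) with BLQ observations dropped."""
        q = ~self.blq
        return self.times[q], self.concs[q]

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.subject_id, self.matrix, self.dose)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": self.subject_id,
                "period": self.period,
                "dose_mg_kg": self.dose,
                "matrix": self.matrix,
                "time_h": self.times,
                "conc_ug_ml": self.concs,
                "blq": self.blq,
            }
        )


@dataclass(frozen=True)
class StudyDataset:
    """A collection of profiles with the study design attached."""

    profiles: tuple[ConcProfile, ...]
    design: str = "crossover"       # "crossover" | "parallel"
    washout_days: float = 15.0
    n_control_rows: int = 0         # pre-dose rows dropped on read

    def __post_init__(self):
        object.__setattr__(self, "profiles", tuple(self.profiles))
        seen = set()
        for p in self.profiles:
            k = (p.subject_id, p.matrix, p.dose, p.period)
            if k in seen:
                raise ValidationError(f"duplicate profile for {k}")
            seen.add(k)
        if self.design == "crossover":
            by_subject: dict[str, set[float]] = {}
            for p in self.profiles:
                by_subject.setdefault(p.subject_id, set()).add(p.dose)
            for s, doses in by_subject.items():
                if len(doses) < 2:
                    raise ValidationError(
                        f"crossover design but subject {s!r} has a single dose"
                    )

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(sorted({p.subject_id for p in self.profiles}))

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(sorted({p.dose for p in self.profiles}))

    def select(self, matrix: str | None = None, dose: float | None = None,
               subject: str | None = None) -> list[ConcProfile]:
        out = []
        for p in self.profiles:
            if matrix is not None and p.matrix != matrix:
                continue
            if dose is not None and p.dose != dose:
                continue
            if subject is not None and p.subject_id != subject:
                continue
            out.append(p)
        return out

    def get(self, subject: str, matrix: str, dose: float) -> ConcProfile:
        hits = self.select(matrix=matrix, dose=dose, subject=subject)
        if not hits:
            raise KeyError((subject, matrix, dose))
        return hits[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([p.to_frame() for p in self.profiles], ignore_index=True)


@dataclass(frozen=True)
class RunConfig:
    """Analysis configuration shared by all stages.

    ``mrl`` is in µg/kg and is converted to a concentration cutoff via
    ``milk_density`` (kg/L): 50 µg/kg × 1.0 kg/L = 50 µg/L = 0.05 µg/mL.
    """

    auc_method: str = "linear"              # "linear" | "linear_up_log_down"
    lambda_z_rule: str = "best_adj_r2"      # "best_adj_r2" | "manual"
    lambda_z_min_points: int = 3
    c0_policy: str = "first_observed"       # "first_observed" | "back_extrapolate"
    mrl: float = MRL_DEFAULT                # µg/kg
    milk_density: float = 1.0               # kg/L
    tolerance_p: float = 0.95
    tolerance_conf: float = 0.95
    max_wt_time_points: int = 7
    excluded_times: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "excluded_times", tuple(self.excluded_times))
        if not (0 < self.tolerance_p < 1):
            raise ValidationError("tolerance_p must be in (0, 1)")
        if not (0 < self.tolerance_conf < 1):
            raise ValidationError("tolerance_conf must be in (0, 1)")
        if self.lambda_z_min_points < 3:
            raise ValidationError("lambda_z_min_points must be >= 3")
        if not (self.mrl > 0):
            raise ValidationError("mrl must be > 0")

    @property
    def mrl_conc(self) -> float:
        """MRL expressed as µg/mL."""
        return self.mrl * self.milk_density / 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["excluded_times"] = list(self.excluded_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))


def _parse_blq(values: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }

    def one(v):
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        if isinstance(v, (int, float, np.integer, np.floating)) and not pd.isna(v):
            return bool(v)
        s = str(v).strip().lower()
        if s in mapping:
            return mapping[s]
        raise SchemaError(f"cannot interpret blq value {v!r}")

    return values.map(one)


def read_profiles(path: str | Path, lloq: float = LLOQ_DEFAULT) -> StudyDataset:
    """Read a tidy concentration CSV into a validated :class:`StudyDataset`.

    Rows at time 0 (pre-dose control) are dropped from the profiles but
    counted in ``n_control_rows``.  BLQ rows may carry an empty
    concentration field.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"empty file: {path}") from None
    if df.empty:
        raise SchemaError(f"no data rows in {path}")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df = df.copy()
    df["blq"] = _parse_blq(df["blq"])
    df["time_h"] = df["time_h"].astype(float)
    df["conc_ug_ml"] = pd.to_numeric(df["conc_ug_ml"], errors="coerce")
    df["subject"] = df["subject"].astype(str)

    dup_key = ["subject", "matrix", "dose_mg_kg", "period", "time_h"]
    if df.duplicated(subset=dup_key).any():
        bad = df[df.duplicated(subset=dup_key, keep=False)].iloc[0]
        raise ValidationError(
            "duplicated (subject, matrix, dose, period, time) row: "
            f"subject {bad['subject']!r} matrix {bad['matrix']!r} "
            f"time {bad['time_h']}"
        )
    neg = (~df["blq"]) & (df["conc_ug_ml"] < 0)
    if neg.any():
        bad = df[neg].iloc[0]
        raise ValidationError(
            f"negative concentration for subject {bad['subject']!r} "
            f"matrix {bad['matrix']!r} at t={bad['time_h']} h"
        )

    control = df["time_h"] == 0.0
    n_control = int(control.sum())
    df = df[~control]
    if df.empty:
        raise SchemaError("file contains only pre-dose control rows")

    profiles = []
    for (subject, matrix, dose, period), g in df.groupby(
        ["subject", "matrix", "dose_mg_kg", "period"], sort=True
    ):
        g = g.sort_values("time_h")
        times = g["time_h"].to_numpy()
        if np.any(np.diff(times) <= 0):
            raise ValidationError(
                f"non-increasing times for subject {subject!r}, matrix {matrix!r}"
            )
        concs = g["conc_ug_ml"].to_numpy(dtype=float)
        blq = g["blq"].to_numpy()
        concs = np.where(blq, np.nan, concs)
        profiles.append(
            ConcProfile(
                subject_id=str(subject), period=int(period), dose=float(dose),
                matrix=str(matrix), times=times, concs=concs, blq=blq, lloq=lloq,
            )
        )

    doses_per_subject = df.groupby("subject")["dose_mg_kg"].nunique()
    design = "crossover" if (doses_per_subject >= 2).all() else "parallel"
    ds = StudyDataset(profiles=tuple(profiles), design=design,
                      n_control_rows=n_control)
    log.info(
        "read_profiles: %d profiles, %d subjects, design=%s, %d control rows dropped",
        len(ds.profiles), len(ds.subjects), design, n_control,
    )
    return ds


def provenance(config: RunConfig | dict | None = None, seed: int | None = None) -> dict:
    """Provenance block written alongside every output."""
    from . import __version__

    cfg = config.to_dict() if isinstance(config, RunConfig) else (config or {})
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return {
        "software": "milkpk",
        "version": __version__,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
    }


def write_dataset(dataset: StudyDataset, path: str | Path,
                  config: RunConfig | None = None, seed: int | None = None) -> None:
    """Write a StudyDataset as tidy CSV with a '#'-comment provenance header."""
    path = Path(path)
    df = dataset.to_frame()
    prov = provenance(config, seed)
    with open(path, "w") as f:
        f.write(f"# provenance: {json.dumps(prov)}\n")
        f.write(f"# design: {dataset.design}\n")
        df.to_csv(f, index=False, float_format="%.10g")


def _coerce_records(results) -> list[dict]:
    if isinstance(results, pd.DataFrame):
        return results.to_dict(orient="records")
    if isinstance(results, dict):
        return [results]
    out = []
    for r in results:
        if dataclasses.is_dataclass(r):
            out.append(dataclasses.asdict(r))
        elif isinstance(r, dict):
            out.append(r)
        elif hasattr(r, "to_dict"):
            out.append(r.to_dict())
        else:
            raise TypeError(f"cannot serialize {type(r)}")
    return out


def write_results(results, path: str | Path, format: str = "csv",
                  config: RunConfig | None = None, seed: int | None = None) -> None:
    """Serialize stage output (records or a DataFrame) with provenance.

    CSV output carries provenance as '#' comment lines; JSON wraps the
    records in ``{"provenance": ..., "results": ...}``.  Floats keep at
    least 10 significant digits so a write/read cycle is lossless at the
    printed precision.
    """
    records = _coerce_records(results)
    if not records:
        raise ValidationError("refusing to write empty results")
    path = Path(path)
    prov = provenance(config, seed)
    try:
        if format == "json":
            with open(path, "w") as f:
                json.dump({"provenance": prov, "results": records}, f,
                          indent=2, default=_json_default)
        elif format == "csv":
            df = pd.DataFrame.from_records(records)
            with open(path, "w") as f:
                f.write(f"# provenance: {json.dumps(prov)}\n")
                df.to_csv(f, index=False, float_format="%.10g")
        else:
            raise ValidationError(f"unknown format {format!r}")
    except OSError as e:
        raise OSError(f"cannot write {path}: {e}") from e


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)
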
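"""Non-compartmental analysis (NCA) of an IV-bolus concentration–time profile.

The model-free parameter set follows standard slope/area definitions:

* terminal rate constant λz from the best adjusted-R² log-linear terminal
  window (window ends at the last quantifiable point, starts strictly after
  Tmax, holds at least ``min_points`` points); t½λz = ln 2 / λz;
* AUC and AUMC by trapezoidal integration (linear or linear-up/log-down)
  with the tail extrapolated as C_last/λz and C_last·t_last/λz + C_last/λz²;
* MRT = AUMC_∞ / AUC_∞, Cl_T = dose / AUC_∞, Vdss = Cl_T · MRT;
* C0 is by default the first observed post-dose concentration (the study
  design samples at 0.08 h), optionally a log-linear back-extrapolation
  to t = 0 through the first two quantifiable points.

BLQ observations are dropped entirely; the analyzed series is the
quantifiable span of the profile.

The statsmodels-style surface is :class:`NCA` (model) and
:class:`NCAResults`; :func:`compute_nca` is the functional wrapper.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ConcProfile, RunConfig
from .exceptions import InsufficientDataError, NotEstimableError, ValidationError

__all__ = [
    "LambdaZFit", "NCA", "NCAResults", "SummaryStats",
    "fit_lambda_z", "auc_aumc", "extrapolate_to_inf", "compute_nca",
    "summarize", "summarize_all", "results_to_frame",
]

log = logging.getLogger("milkpk")

NCA_PARAMETERS = (
    "c0", "cmax", "tmax", "auc_last", "auc_inf", "auc_extrap_pct",
    "aumc_last", "aumc_inf", "mrt_inf", "t_half_lambda_z", "cl_t", "v_dss",
)


@dataclass(frozen=True)
class LambdaZFit:
    """Accepted terminal-phase log-linear regression."""

    lambda_z: float        # 1/h, -slope of ln C vs t
    intercept_ln: float    # ln(µg/mL)
    n_points: int
    adj_r2: float
    t_first_used: float    # h
    t_last_used: float     # h

    @property
    def t_half(self) -> float:
        return math.log(2) / self.lambda_z


def _window_stats(t: np.ndarray, lnc: np.ndarray):
    """Vectorized OLS over all suffix windows of (t, lnc).

    Returns per-start-index arrays (slope, intercept, adj_r2) for windows
    [i:], computed from suffix sums in O(n).
    """
    n = len(t)
    # suffix sums: s_*[i] = sum over j >= i
    rev = slice(None, None, -1)
    s_n = np.arange(n, 0, -1, dtype=float)
    s_t = np.cumsum(t[rev])[rev]
    s_tt = np.cumsum((t * t)[rev])[rev]
    s_y = np.cumsum(lnc[rev])[rev]
    s_yy = np.cumsum((lnc * lnc)[rev])[rev]
    s_ty = np.cumsum((t * lnc)[rev])[rev]
    sxx = s_tt - s_t * s_t / s_n
    sxy = s_ty - s_t * s_y / s_n
    syy = s_yy - s_y * s_y / s_n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
        intercept = (s_y - slope * s_t) / s_n
        r2 = np.where(syy > 0, (sxy * sxy) / (sxx * syy), np.nan)
        adj = 1.0 - (1.0 - r2) * (s_n - 1) / (s_n - 2)
    return slope, intercept, adj


def fit_lambda_z(
    profile: ConcProfile,
    rule: str = "best_adj_r2",
    min_points: int = 3,
    manual_window: tuple[float, float] | None = None,
) -> LambdaZFit:
    """Fit the terminal elimination rate constant λz.

    Under ``best_adj_r2`` every candidate window ending at the last
    quantifiable point, containing at least ``min_points`` points and
    starting strictly after Tmax is evaluated; the window maximizing the
    adjusted R² of the ln-concentration regression wins.  Under ``manual``
    the window is the closed time interval ``manual_window``.

    Raises :class:`NotEstimableError` when fewer than ``min_points`` usable
    points exist or the best window has a non-negative slope.
    """
    t, c = profile.quantifiable()
    if len(t) < min_points:
        raise NotEstimableError(
            f"need >= {min_points} quantifiable points, have {len(t)}"
        )
    if np.any(c <= 0):
        raise NotEstimableError("non-positive quantifiable concentration")
    lnc = np.log(c)

    if rule == "manual":
        if manual_window is None:
            raise ValidationError("manual lambda-z rule requires manual_window")
        lo, hi = manual_window
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < min_points:
            raise NotEstimableError("manual window holds fewer than min_points points")
        tw, yw = t[mask], lnc[mask]
        slope, intercept = np.polyfit(tw, yw, 1)
        resid = yw - (intercept + slope * tw)
        syy = np.sum((yw - yw.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / syy if syy > 0 else np.nan
        adj = 1.0 - (1.0 - r2) * (len(tw) - 1) / (len(tw) - 2)
        if not (slope < 0):
            raise NotEstimableError("non-negative terminal slope in manual window")
        return LambdaZFit(-float(slope), float(intercept), int(mask.sum()),
                          float(adj), float(tw[0]), float(tw[-1]))

    if rule != "best_adj_r2":
        raise ValidationError(f"unknown lambda-z rule {rule!r}")

    i_tmax = int(np.argmax(c))  # earliest max by argmax convention
    first_start = i_tmax + 1    # strictly after Tmax
    last_start = len(t) - min_points
    if last_start < first_start:
        raise NotEstimableError(
            "too few points after Tmax for a terminal window "
            f"(need {min_points}, Tmax at index {i_tmax})"
        )
    slope, intercept, adj = _window_stats(t, lnc)
    cand = np.arange(first_start, last_start + 1)
    adj_c = adj[cand]
    if np.all(np.isnan(adj_c)):
        raise NotEstimableError("all candidate windows degenerate (flat data)")
    best = cand[int(np.nanargmax(adj_c))]
    if not (slope[best] < 0):
        raise NotEstimableError("non-negative terminal slope in best window")
    return LambdaZFit(
        lambda_z=-float(slope[best]),
        intercept_ln=float(intercept[best]),
        n_points=int(len(t) - best),
        adj_r2=float(adj[best]),
        t_first_used=float(t[best]),
        t_last_used=float(t[-1]),
    )


def _back_extrapolated_c0(t: np.ndarray, c: np.ndarray) -> float:
    """ln-linear extrapolation to t=0 through the first two points."""
    if len(t) < 2:
        return float(c[0])
    lnc0, lnc1 = math.log(c[0]), math.log(c[1])
    slope = (lnc1 - lnc0) / (t[1] - t[0])
    return float(math.exp(lnc0 - slope * t[0]))


def _trapezoid_segments(t, c, method: str):
    """Per-interval (auc, aumc) contributions."""
    dt = np.diff(t)
    c1, c2 = c[:-1], c[1:]
    t1, t2 = t[:-1], t[1:]
    auc_lin = dt * (c1 + c2) / 2.0
    aumc_lin = dt * (t1 * c1 + t2 * c2) / 2.0
    if method == "linear":
        return auc_lin, aumc_lin
    if method != "linear_up_log_down":
        raise ValidationError(f"unknown AUC method {method!r}")
    down = (c2 < c1) & (c1 > 0) & (c2 > 0)
    if np.any((c1 <= 0) | (c2 <= 0)):
        log.info("auc_aumc: zero/negative concentration inside interval; "
                 "falling back to linear rule there")
    auc = auc_lin.copy()
    aumc = aumc_lin.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(down, c1 / np.where(c2 > 0, c2, 1.0), np.e)
        k = np.log(ratio) / dt
        auc[down] = (dt * (c1 - c2) / np.log(ratio))[down]
        # exponential-segment moment: (t1 C1 - t2 C2)/k + (C1 - C2)/k^2
        aumc[down] = ((t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2)[down]
    return auc, aumc


def auc_aumc(
    profile: ConcProfile,
    method: str = "linear",
    c0_policy: str = "first_observed",
) -> tuple[float, float]:
    """AUC_0–last and AUMC_0–last by trapezoidal integration.

    Under ``back_extrapolate`` a synthetic t=0 point from the log-linear
    extrapolation through the first two quantifiable points is prepended;
    under ``first_observed`` integration starts at the first quantifiable
    sample.
    """
    t, c = profile.quantifiable()
    if len(t) < 2:
        raise InsufficientDataError("need >= 2 quantifiable points for AUC")
    if c0_policy == "back_extrapolate" and t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[_back_extrapolated_c0(t[1:], c)], c])
    elif c0_policy not in ("first_observed", "back_extrapolate"):
        raise ValidationError(f"unknown c0 policy {c0_policy!r}")
    auc_seg, aumc_seg = _trapezoid_segments(t, c, method)
    return float(np.sum(auc_seg)), float(np.sum(aumc_seg))


def extrapolate_to_inf(
    auc_last: float, aumc_last: float, c_last: float, t_last: float,
    lz: LambdaZFit,
) -> tuple[float, float]:
    """Extrapolate AUC/AUMC from the last quantifiable point to infinity."""
    auc_inf = auc_last + c_last / lz.lambda_z
    aumc_inf = (
        aumc_last + c_last * t_last / lz.lambda_z + c_last / lz.lambda_z**2
    )
    return float(auc_inf), float(aumc_inf)


class NCA:
    """Non-compartmental model for one profile.

    Parameters
    ----------
    profile : ConcProfile
        The concentration–time series (dose is taken from the profile).
    config : RunConfig, optional
        Integration method, λz rule, C0 policy.
    manual_window : (float, float), optional
        Explicit λz window when ``config.lambda_z_rule == "manual"``.
    """

    def __init__(self, profile: ConcProfile, config: RunConfig | None = None,
                 manual_window: tuple[float, float] | None = None):
        self.profile = profile
        self.config = config or RunConfig()
        self.manual_window = manual_window

    def fit(self) -> "NCAResults":
        prof = self.profile
        cfg = self.config
        t, c = prof.quantifiable()
        if len(t) < 2:
            raise InsufficientDataError(
                f"profile {prof.key} has {len(t)} quantifiable points"
            )
        i_max = int(np.argmax(c))
        cmax, tmax = float(c[i_max]), float(t[i_max])
        if cfg.c0_policy == "back_extrapolate":
            c0 = _back_extrapolated_c0(t, c)
        else:
            c0 = float(c[0])
        auc_last, aumc_last = auc_aumc(prof, cfg.auc_method, cfg.c0_policy)

        lz = None
        vals = dict.fromkeys(
            ("auc_inf", "auc_extrap_pct", "aumc_inf", "mrt_inf",
             "t_half_lambda_z", "cl_t", "v_dss"), math.nan,
        )
        try:
            lz = fit_lambda_z(prof, cfg.lambda_z_rule, cfg.lambda_z_min_points,
                              self.manual_window)
            auc_inf, aumc_inf = extrapolate_to_inf(
                auc_last, aumc_last, float(c[-1]), float(t[-1]), lz
            )
            mrt = aumc_inf / auc_inf
            cl = prof.dose / auc_inf
            vals.update(
                auc_inf=auc_inf,
                auc_extrap_pct=100.0 * (auc_inf - auc_last) / auc_inf,
                aumc_inf=aumc_inf,
                mrt_inf=mrt,
                t_half_lambda_z=lz.t_half,
                cl_t=cl,
                v_dss=cl * mrt,
            )
        except NotEstimableError as e:
            log.info("NCA %s: lambda_z not estimable (%s); "
                     "extrapolated parameters unavailable", prof.key, e)
        params = pd.Series(
            {
                "c0": c0, "cmax": cmax, "tmax": tmax,
                "auc_last": auc_last, **{k: vals[k] for k in
                ("auc_inf", "auc_extrap_pct")},
                "aumc_last": aumc_last, "aumc_inf": vals["aumc_inf"],
                "mrt_inf": vals["mrt_inf"],
                "t_half_lambda_z": vals["t_half_lambda_z"],
                "cl_t": vals["cl_t"], "v_dss": vals["v_dss"],
            },
            name=f"{prof.subject_id}/{prof.matrix}/{prof.dose}",
        )
        return NCAResults(self, params, lz)


class NCAResults:
    """Per-profile NCA estimates with the accepted λz fit attached."""

    def __init__(self, model: NCA, params: pd.Series, lambda_fit: LambdaZFit | None):
        self.model = model
        self.params = params
        self.lambda_fit = lambda_fit
        p = model.profile
        self.subject_id, self.matrix, self.dose = p.subject_id, p.matrix, p.dose

    def __getattr__(self, name):
        params = self.__dict__.get("params")
        if params is not None and name in params.index:
            return float(params[name])
        raise AttributeError(name)

    def to_dict(self) -> dict:
        d = {"subject": self.subject_id, "matrix": self.matrix, "dose": self.dose}
        d.update({k: float(v) for k, v in self.params.items()})
        if self.lambda_fit is not None:
            d["lambda_z"] = self.lambda_fit.lambda_z
            d["lambda_z_n_points"] = self.lambda_fit.n_points
            d["lambda_z_adj_r2"] = self.lambda_fit.adj_r2
        return d

    def summary(self) -> str:
        lines = [
            f"NCA results — subject {self.subject_id}, {self.matrix}, "
            f"{self.dose} mg/kg",
            "-" * 56,
        ]
        units = {
            "c0": "µg/mL", "cmax": "µg/mL", "tmax": "h",
            "auc_last": "h·µg/mL", "auc_inf": "h·µg/mL", "auc_extrap_pct": "%",
            "aumc_last": "h²·µg/mL", "aumc_inf": "h²·µg/mL", "mrt_inf": "h",
            "t_half_lambda_z": "h", "cl_t": "L/h/kg", "v_dss": "L/kg",
        }
        for k, v in self.params.items():
            lines.append(f"{k:>16}  {v:12.5g}  {units.get(k, '')}")
        if self.lambda_fit is not None:
            lf = self.lambda_fit
            lines.append(
                f"{'lambda_z':>16}  {lf.lambda_z:12.5g}  1/h "
                f"({lf.n_points} pts, adj R² {lf.adj_r2:.4f}, "
                f"window {lf.t_first_used}–{lf.t_last_used} h)"
            )
        else:
            lines.append("lambda_z: not estimable")
        return "\n".join(lines)


def compute_nca(profile: ConcProfile, config: RunConfig | None = None,
                **kwargs) -> NCAResults:
    """Functional wrapper: ``NCA(profile, config).fit()``."""
    return NCA(profile, config, **kwargs).fit()


@dataclass(frozen=True)
class SummaryStats:
    """Across-subject summary: geometric mean (min–max), median for Tmax."""

    parameter_name: str
    geomean: float   # median for tmax
    min: float
    max: float
    n: int

    @property
    def center(self) -> float:
        return self.geomean


def summarize(results, parameter: str) -> SummaryStats:
    """Geometric-mean (min–max) summary of one parameter across subjects.

    Tmax is summarized by the median, every other parameter by the
    geometric mean; NaN (not-estimable) values are dropped.
    """
    pairs = []
    for r in results:
        v = float(r.params[parameter]) if isinstance(r, NCAResults) else float(r)
        label = r.subject_id if isinstance(r, NCAResults) else str(len(pairs))
        if not math.isnan(v):
            pairs.append((label, v))
    if not pairs:
        raise InsufficientDataError(f"no finite values for {parameter!r}")
    values = np.array([v for _, v in pairs])
    if parameter == "tmax":
        center = float(np.median(values))
    else:
        bad = [s for s, v in pairs if v <= 0]
        if bad:
            raise ValidationError(
                f"non-positive {parameter!r} for subject(s) {bad}; "
                "geometric mean undefined"
            )
        center = float(np.exp(np.mean(np.log(values))))
    return SummaryStats(parameter, center, float(values.min()),
                        float(values.max()), len(values))


def summarize_all(results) -> pd.DataFrame:
    """Summary table over all NCA parameters (rows) for one group."""
    rows = []
    for p in NCA_PARAMETERS:
        try:
            s = summarize(results, p)
        except InsufficientDataError:
            continue
        rows.append({"parameter": s.parameter_name, "center": s.geomean,
                     "min": s.min, "max": s.max, "n": s.n})
    return pd.DataFrame(rows).set_index("parameter")


def results_to_frame(results) -> pd.DataFrame:
    """One row per subject × matrix × dose."""
    return pd.DataFrame([r.to_dict() for r in results])
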
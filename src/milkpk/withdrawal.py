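"""Milk withdrawal-time estimation via a regression tolerance limit.

The residue-depletion convention of EU regulatory practice: pool every
animal's quantifiable ln-concentration observations for one matrix and
dose, fit ordinary least squares of ln C on time, and report as the
withdrawal time (WT) the earliest time at which the one-sided upper
tolerance limit for the p-quantile (default the 95th percentile at 95%
confidence) of individual observations falls below the maximum residue
limit (MRL).

For the regression line ŷ(x0) = b0 + b1·x0 with residual standard
deviation s on n points, the upper (p, conf) tolerance limit at x0 is

    U(x0) = ŷ(x0) + k(x0)·s,
    k(x0) = sqrt(d) · t'_{df, δ}(conf),   d = 1/n + (x0 − x̄)²/Sxx,
    δ = z_p / sqrt(d),

where t'_{df, δ}(conf) is the conf-quantile of the noncentral t
distribution with df = n − 2 degrees of freedom and noncentrality δ, and
z_p the standard-normal p-quantile.  The WT estimate is the supremum of
the exceedance set {t : U(t) ≥ ln(MRL)} — robust to the non-monotone
leverage growth of U far from x̄ — refined by bisection, and the reported
WT rounds the estimate up to the next whole reporting interval (1 h by
default; a milking-interval granularity can be configured).

Tooling caps the pooled design at a maximum number of distinct sampling
times (7 by default); when the quantifiable data span more, the caller
must name the times to exclude — no automatic heuristic is applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import RunConfig, StudyDataset
from .exceptions import (
    CappingError,
    InsufficientDataError,
    NotEstimableError,
    ValidationError,
    WindowError,
)

__all__ = [
    "WtRegression", "WtResult", "WithdrawalTimeModel", "WithdrawalTimeResults",
    "select_time_points", "fit_wt_regression", "tolerance_factor",
    "upper_tolerance_limit", "estimate_wt",
]

log = logging.getLogger("milkpk")


@dataclass(frozen=True)
class WtRegression:
    """Sufficient statistics of the pooled log-linear depletion fit."""

    slope: float          # 1/h
    intercept: float      # ln(µg/mL)
    s: float              # residual SD on ln scale
    n: int
    df: int               # n - 2
    x_bar: float          # h
    s_xx: float           # h^2
    times_used: tuple[float, ...]
    n_animals: int

    def predict(self, x0):
        return self.intercept + self.slope * np.asarray(x0, dtype=float)


@dataclass(frozen=True)
class WtResult:
    """Estimated and reported withdrawal time against an MRL."""

    wt_estimate: float    # h, fractional
    wt_reported: float    # h, rounded up to the reporting granularity
    mrl_input: float      # µg/kg
    mrl_conc: float       # µg/mL
    p: float
    conf: float
    regression: WtRegression

    def to_dict(self) -> dict:
        return {
            "wt_estimate_h": self.wt_estimate,
            "wt_reported_h": self.wt_reported,
            "mrl_ug_kg": self.mrl_input,
            "mrl_conc_ug_ml": self.mrl_conc,
            "percentile": self.p,
            "confidence": self.conf,
            "slope": self.regression.slope,
            "intercept": self.regression.intercept,
            "residual_sd": self.regression.s,
            "n_obs": self.regression.n,
            "n_animals": self.regression.n_animals,
            "times_used": list(self.regression.times_used),
        }


def select_time_points(
    dataset: StudyDataset,
    matrix: str,
    dose: float,
    max_points: int = 7,
    excluded_times: tuple[float, ...] = (),
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pool quantifiable (time, ln conc) observations across animals.

    Drops BLQ observations and user-excluded times.  If the remaining
    distinct times exceed ``max_points`` and no exclusion list was given,
    a :class:`CappingError` forces an explicit choice.

    Returns (times, ln_concs, n_animals).
    """
    profiles = dataset.select(matrix=matrix, dose=dose)
    if not profiles:
        raise InsufficientDataError(f"no {matrix!r} profiles at dose {dose}")
    excluded = np.asarray(excluded_times, dtype=float)
    ts, ys = [], []
    animals = set()
    for p in profiles:
        t, c = p.quantifiable()
        if excluded.size:
            keep = ~np.isclose(t[:, None], excluded[None, :]).any(axis=1)
            t, c = t[keep], c[keep]
        if t.size:
            animals.add(p.subject_id)
            ts.append(t)
            ys.append(np.log(c))
    if not ts:
        raise InsufficientDataError(
            f"all {matrix!r} observations at dose {dose} are BLQ or excluded"
        )
    t = np.concatenate(ts)
    y = np.concatenate(ys)
    distinct = np.unique(t)
    if distinct.size > max_points and not excluded.size:
        raise CappingError(
            f"{distinct.size} distinct quantifiable times exceed the "
            f"{max_points}-point cap; pass excluded_times choosing among "
            f"{[float(x) for x in distinct]}"
        )
    if distinct.size > max_points:
        raise CappingError(
            f"still {distinct.size} distinct times after exclusions "
            f"(cap {max_points}): {[float(x) for x in distinct]}"
        )
    if distinct.size < 3:
        raise InsufficientDataError(
            f"only {distinct.size} distinct quantifiable times; need >= 3"
        )
    order = np.argsort(t, kind="stable")
    return t[order], y[order], len(animals)


def fit_wt_regression(
    times: np.ndarray, ln_concs: np.ndarray, n_animals: int = 1
) -> WtRegression:
    """OLS of ln(conc) on time over the pooled observations."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(ln_concs, dtype=float)
    n = t.size
    if n < 3:
        raise InsufficientDataError("need >= 3 pooled points")
    if np.unique(t).size < 2:
        raise ValidationError("zero time-variance: all observations at one time")
    x_bar = float(t.mean())
    s_xx = float(np.sum((t - x_bar) ** 2))
    slope = float(np.sum((t - x_bar) * (y - y.mean())) / s_xx)
    intercept = float(y.mean() - slope * x_bar)
    resid = y - (intercept + slope * t)
    s = float(math.sqrt(np.sum(resid**2) / (n - 2)))
    return WtRegression(
        slope=slope, intercept=intercept, s=s, n=n, df=n - 2,
        x_bar=x_bar, s_xx=s_xx,
        times_used=tuple(np.unique(t).tolist()), n_animals=n_animals,
    )


def tolerance_factor(n: int, df: int, d, p: float, conf: float):
    """One-sided regression tolerance factor k = sqrt(d)·t'_{df,δ}(conf).

    ``d`` is the leverage 1/n + (x0 − x̄)²/Sxx; δ = z_p/sqrt(d).  Accepts a
    scalar or an array of leverages.
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValidationError("leverage d must be > 0")
    z_p = stats.norm.ppf(p)
    sqrt_d = np.sqrt(d)
    k = sqrt_d * stats.nct.ppf(conf, df, z_p / sqrt_d)
    if np.any(~np.isfinite(k)):
        raise ArithmeticError(
            f"noncentral-t quantile failed for df={df}, p={p}, conf={conf}, d={d}"
        )
    return k if k.ndim else float(k)


def upper_tolerance_limit(reg: WtRegression, x0, p: float = 0.95,
                          conf: float = 0.95):
    """U(x0) = ŷ(x0) + k(x0)·s on the ln-concentration scale."""
    x0 = np.asarray(x0, dtype=float)
    d = 1.0 / reg.n + (x0 - reg.x_bar) ** 2 / reg.s_xx
    u = reg.predict(x0) + tolerance_factor(reg.n, reg.df, d, p, conf) * reg.s
    return u if u.ndim else float(u)


def _round_up(estimate: float, granularity: float) -> float:
    """Round up to the next multiple of ``granularity`` (exact multiples stay)."""
    units = estimate / granularity
    return float(math.ceil(units - 1e-9) * granularity)


def estimate_wt(
    reg: WtRegression,
    mrl: float = 50.0,
    density: float = 1.0,
    p: float = 0.95,
    conf: float = 0.95,
    t_max_search: float | None = None,
    round_to: float = 1.0,
) -> WtResult:
    """Withdrawal time: supremum of {t : U(t) ≥ ln(MRL conc)}.

    ``mrl`` is µg/kg, converted to µg/mL via ``density`` (kg/L).  The
    search window defaults to four times the span of the fitted data; a
    :class:`WindowError` suggests enlarging it when U never drops below
    the cutoff.  The crossing is refined by bisection to 1e-6 h.
    """
    if not (reg.slope < 0):
        raise NotEstimableError("non-negative depletion slope; WT undefined")
    mrl_conc = mrl * density / 1000.0
    cut = math.log(mrl_conc)
    if t_max_search is None:
        t_max_search = 4.0 * max(reg.times_used)
    if upper_tolerance_limit(reg, t_max_search, p, conf) >= cut:
        raise WindowError(
            f"tolerance limit still above the MRL at t={t_max_search} h; "
            "increase t_max_search"
        )
    if upper_tolerance_limit(reg, 0.0, p, conf) < cut:
        wt = 0.0
    else:
        grid = np.linspace(0.0, t_max_search, 4097)
        above = upper_tolerance_limit(reg, grid, p, conf) >= cut
        last = int(np.flatnonzero(above)[-1])
        lo, hi = grid[last], grid[last + 1]
        while hi - lo > 1e-6:
            mid = 0.5 * (lo + hi)
            if upper_tolerance_limit(reg, mid, p, conf) >= cut:
                lo = mid
            else:
                hi = mid
        # lo is the largest point verified inside the exceedance set, so it
        # never overshoots the supremum (which matters at whole-hour
        # crossings under the round-up reporting rule)
        wt = lo
    return WtResult(
        wt_estimate=float(wt),
        wt_reported=_round_up(wt, round_to),
        mrl_input=mrl, mrl_conc=mrl_conc, p=p, conf=conf, regression=reg,
    )


class WithdrawalTimeModel:
    """Pooled log-linear depletion model for one matrix and dose.

    Build from raw pooled observations or, via :meth:`from_dataset`, from
    a :class:`StudyDataset` with BLQ censoring, time exclusion and the
    time-point cap applied.
    """

    def __init__(self, times, ln_concs, n_animals: int = 1):
        self.times = np.asarray(times, dtype=float)
        self.ln_concs = np.asarray(ln_concs, dtype=float)
        self.n_animals = n_animals

    @classmethod
    def from_dataset(
        cls,
        dataset: StudyDataset,
        dose: float,
        matrix: str = "milk",
        max_points: int = 7,
        excluded_times: tuple[float, ...] = (),
    ) -> "WithdrawalTimeModel":
        t, y, n_animals = select_time_points(
            dataset, matrix, dose, max_points, excluded_times
        )
        return cls(t, y, n_animals)

    def fit(self) -> "WithdrawalTimeResults":
        reg = fit_wt_regression(self.times, self.ln_concs, self.n_animals)
        log.info(
            "withdrawal fit: n=%d obs, %d animals, times %s, slope=%.4g, s=%.4g",
            reg.n, reg.n_animals, reg.times_used, reg.slope, reg.s,
        )
        return WithdrawalTimeResults(self, reg)


class WithdrawalTimeResults:
    """Fitted depletion regression with tolerance-limit and WT methods."""

    def __init__(self, model: WithdrawalTimeModel, regression: WtRegression):
        self.model = model
        self.regression = regression

    @property
    def params(self):
        import pandas as pd

        r = self.regression
        return pd.Series(
            {"slope": r.slope, "intercept": r.intercept, "residual_sd": r.s},
        )

    def tolerance_limit(self, x0, p: float = 0.95, conf: float = 0.95):
        return upper_tolerance_limit(self.regression, x0, p, conf)

    def estimate_wt(self, mrl: float = 50.0, density: float = 1.0,
                    p: float = 0.95, conf: float = 0.95,
                    t_max_search: float | None = None,
                    round_to: float = 1.0) -> WtResult:
        return estimate_wt(self.regression, mrl, density, p, conf,
                           t_max_search, round_to)

    def summary(self, mrl: float = 50.0, density: float = 1.0,
                p: float = 0.95, conf: float = 0.95) -> str:
        r = self.regression
        lines = [
            "Withdrawal-time depletion regression",
            "-" * 48,
            f"pooled observations : {r.n} ({r.n_animals} animals)",
            f"distinct times (h)  : {list(r.times_used)}",
            f"slope               : {r.slope:.5g} 1/h",
            f"intercept           : {r.intercept:.5g} ln(µg/mL)",
            f"residual SD (ln)    : {r.s:.5g}",
        ]
        try:
            wt = self.estimate_wt(mrl, density, p, conf)
            lines += [
                f"MRL                 : {mrl} µg/kg = {wt.mrl_conc} µg/mL",
                f"tolerance limit     : {100*p:g}th percentile, "
                f"{100*conf:g}% confidence",
                f"WT estimate         : {wt.wt_estimate:.2f} h "
                f"(reported {wt.wt_reported:g} h)",
            ]
        except (NotEstimableError, WindowError) as e:
            lines.append(f"WT: not estimable ({e})")
        return "\n".join(lines)

    def plot(self, mrl: float = 50.0, density: float = 1.0, p: float = 0.95,
             conf: float = 0.95, ax=None):
        from .plotting import plot_withdrawal

        return plot_withdrawal(self, mrl=mrl, density=density, p=p,
                               conf=conf, ax=ax)


def estimate_wt_from_dataset(
    dataset: StudyDataset, dose: float, config: RunConfig,
    matrix: str = "milk", round_to: float = 1.0,
    excluded_times: tuple[float, ...] | None = None,
) -> WtResult:
    """Dataset-level convenience: exclusions applied only when the
    uncapped selection overflows ``max_wt_time_points`` (mirroring
    regulatory practice of excluding times only when the tool's cap
    forces it).  ``excluded_times`` overrides ``config.excluded_times``."""
    if excluded_times is None:
        excluded_times = config.excluded_times
    try:
        model = WithdrawalTimeModel.from_dataset(
            dataset, dose, matrix, config.max_wt_time_points, ()
        )
    except CappingError:
        if not excluded_times:
            raise
        model = WithdrawalTimeModel.from_dataset(
            dataset, dose, matrix, config.max_wt_time_points,
            excluded_times,
        )
    res = model.fit()
    return res.estimate_wt(
        mrl=config.mrl, density=config.milk_density,
        p=config.tolerance_p, conf=config.tolerance_conf, round_to=round_to,
    )
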
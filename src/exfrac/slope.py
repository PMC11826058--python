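"""The slope method: expression fraction from the rho_H-vs-mu regression.

While the expression fraction f_H is constant and total protein biosynthesis
tracks growth, the specific production rate is proportional to the specific
growth rate,

    rho_H(t) = f_H * mu(t)                 (through the origin), or
    rho_H(t) = f_H * [mu(t) - b]           (with an x-axis intercept b),

so f_H is the slope of a rho_H-vs-mu scatter over the growth phase. The
positive intercept b appears when reporter production shuts down before
growth does. Two automatic window choices reproduce the published procedure:

1. the growth phase is the set of time points where replicate growth rates
   differ significantly from zero (one-sample t-test, alpha = 0.05, combined
   with mean mu > 0);
2. the earliest points — the "hook" where the inducer has not yet
   equilibrated — are trimmed one by one, and the trim depth with the
   maximal OLS R^2 (at least ``min_points`` points kept) wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import InsufficientDataError
from .hill import DoseResponse
from .io import ConditionGroup
from .kinetics import rate_series


@dataclass
class GrowthPhaseMask:
    """Per-time-point growth-phase membership for one condition group."""

    times: np.ndarray
    included: np.ndarray  # bool
    p_values: np.ndarray
    alpha: float
    mean_mu: np.ndarray


def detect_growth_phase(
    group: ConditionGroup,
    alpha: float = 0.05,
    mu_min: float = 0.05,
    channel: str | None = None,
) -> GrowthPhaseMask:
    """t-test growth-phase detection on a replicate group.

    At each time point of the shared forward-difference grid, a two-sided
    one-sample t-test asks whether the replicate growth rates differ from
    zero; the point joins the growth phase iff p < alpha AND the mean rate is
    positive. Replicate values that are all identical get p = 1 when zero
    (no growth, excluded) and p = 0 otherwise (an exact nonzero rate).

    With a single replicate the test is impossible; the mask falls back to the
    fixed threshold mu > ``mu_min`` (warned).
    """
    from .kinetics import specific_growth_rate

    mus = []
    for s in group.series:
        t, mu = specific_growth_rate(s)
        mus.append(mu)
    times = group.times[:-1]
    M = np.vstack(mus)  # (n_replicates, n_times)
    mean_mu = M.mean(axis=0)

    if M.shape[0] < 2:
        warnings.warn(
            "growth-phase t-test needs >= 2 replicates; falling back to the "
            f"fixed threshold mu > {mu_min}",
            stacklevel=2,
        )
        p = np.where(M[0] > mu_min, 0.0, 1.0)
        included = M[0] > mu_min
        return GrowthPhaseMask(times, included, p, alpha, mean_mu)

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-spread columns handled below
        t_stat, p = stats.ttest_1samp(M, 0.0, axis=0)
    degenerate = ~np.isfinite(p)  # zero spread across replicates
    p = np.where(degenerate, np.where(mean_mu == 0.0, 1.0, 0.0), p)
    included = (p < alpha) & (mean_mu > 0)
    return GrowthPhaseMask(times, included, p, alpha, mean_mu)


@dataclass
class SlopeFit:
    """Result of the slope method for one condition.

    ``slope`` (flu/OD) is the f_H estimate; ``b = -intercept/slope`` is the
    growth rate at which production ceases (0 for the through-origin model).
    """

    slope: float
    intercept: float
    b: float
    r_squared: float
    window_start_h: float
    window_end_h: float
    n_points: int
    model: str
    slope_se: float
    intercept_se: float = float("nan")
    n_trimmed: int = 0
    flags: tuple[str, ...] = ()
    strain: str = ""
    inducer: str = ""
    concentration: float = float("nan")
    conc_unit: str = "uM"


def _ols(x: np.ndarray, y: np.ndarray, through_origin: bool) -> tuple[float, float, float, float, float]:
    """Closed-form OLS: (slope, intercept, r_squared, slope_se, intercept_se).

    R^2 is centred for the free-intercept model and uncentred
    (1 - SSE / sum y^2) for the through-origin model, matching the standard
    no-intercept regression convention.
    """
    n = x.size
    if through_origin:
        sxx = float(x @ x)
        if sxx == 0.0:
            return np.nan, 0.0, np.nan, np.nan, np.nan
        slope = float(x @ y) / sxx
        resid = y - slope * x
        sse = float(resid @ resid)
        syy = float(y @ y)
        r2 = 1.0 - sse / syy if syy > 0 else (1.0 if sse == 0 else 0.0)
        s2 = sse / (n - 1) if n > 1 else np.nan
        return slope, 0.0, r2, float(np.sqrt(s2 / sxx)), np.nan
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    sxx = float(dx @ dx)
    if sxx == 0.0:
        return np.nan, np.nan, np.nan, np.nan, np.nan
    slope = float(dx @ (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - slope * x - intercept
    sse = float(resid @ resid)
    sst = float((y - ym) @ (y - ym))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    s2 = sse / (n - 2) if n > 2 else np.nan
    se_slope = float(np.sqrt(s2 / sxx))
    se_int = float(np.sqrt(s2 * (1.0 / n + xm**2 / sxx)))
    return slope, intercept, r2, se_slope, se_int


class SlopeFractionRegressor(RegressorMixin, BaseEstimator):
    """OLS of rho_H on mu with chronological prefix trimming (sklearn API).

    Parameters
    ----------
    model : {"free_intercept", "through_origin"}
        Whether to fit an intercept (production-arrest variant) or force the
        line through the origin (MerR-style fits).
    min_points : int
        Minimum points a trimmed fit may keep; below ~4 an R^2 is
        near-meaningless.
    trim : bool
        Trim the chronologically earliest remaining point one at a time and
        keep the depth selected by ``trim_rule``. With ``trim=False`` the fit
        uses all points.
    trim_rule : {"first_local_max", "global_max"}
        "first_local_max" (default) trims while each removal strictly
        improves R^2 and stops at the first depth where it no longer does —
        the behaviour of watching R^2 rise and stopping when it peaks. It
        removes an early "hook" cleanly and is robust to observation noise.
        "global_max" evaluates every depth down to ``min_points`` remaining
        and keeps the global R^2 argmax (ties within ``r2_tie_tol`` resolve
        toward more points); under noisy rates it can overfit a short late
        window, so it is not the default.

    Attributes
    ----------
    slope_, intercept_, b_, r_squared_, slope_se_, intercept_se_ : float
    support_ : bool array marking the retained points
    n_points_, n_trimmed_ : int
    flags_ : tuple of str
    """

    def __init__(self, model: str = "free_intercept", min_points: int = 4,
                 trim: bool = True, trim_rule: str = "first_local_max",
                 r2_tie_tol: float = 1e-12):
        self.model = model
        self.min_points = min_points
        self.trim = trim
        self.trim_rule = trim_rule
        self.r2_tie_tol = r2_tie_tol

    def fit(self, X, y, times=None):
        """Fit rho_H = slope * mu (+ intercept) on growth-phase points.

        ``X`` holds the mu values (1-D or a single column), ``y`` the paired
        rho_H values. ``times`` gives each point's chronological position for
        trimming; when omitted, input order is taken as chronological.
        """
        if self.model not in ("free_intercept", "through_origin"):
            raise ValueError(f"unknown slope model {self.model!r}")
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("X and y must be 1-D and the same length")
        t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
        if t.shape != x.shape:
            raise ValueError("times must match X in length")
        order = np.argsort(t, kind="stable")
        xs, ys, ts = x[order], y[order], t[order]

        n = xs.size
        if n < self.min_points:
            raise InsufficientDataError(
                f"slope fit needs >= {self.min_points} growth-phase points, got {n}"
            )
        if self.trim_rule not in ("first_local_max", "global_max"):
            raise ValueError(f"unknown trim_rule {self.trim_rule!r}")
        origin = self.model == "through_origin"
        max_depth = n - self.min_points if self.trim else 0
        best = None  # (r2, depth, fit tuple)
        for depth in range(max_depth + 1):
            fit = _ols(xs[depth:], ys[depth:], origin)
            r2 = fit[2]
            if not np.isfinite(r2):
                if self.trim_rule == "first_local_max" and best is not None:
                    break
                continue
            if best is None or r2 > best[0] + self.r2_tie_tol:
                best = (r2, depth, fit)
            elif self.trim_rule == "first_local_max":
                break  # R^2 stopped improving: the previous depth is the peak
        if best is None:
            raise InsufficientDataError("no trim depth yields a well-defined regression")

        r2, depth, (slope, intercept, _, se_s, se_i) = best
        self.flags_: tuple[str, ...] = ()
        if origin:
            b = 0.0
        elif slope > 0:
            b = -intercept / slope
        else:
            b = 0.0
            self.flags_ += ("non_positive_slope",)
            warnings.warn("slope <= 0: x-axis intercept b is undefined, reported as 0", stacklevel=2)
        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.b_ = float(b)
        self.r_squared_ = float(r2)
        self.slope_se_ = float(se_s)
        self.intercept_se_ = float(se_i)
        self.n_points_ = int(n - depth)
        self.n_trimmed_ = int(depth)
        support_sorted = np.zeros(n, dtype=bool)
        support_sorted[depth:] = True
        self.support_ = np.empty(n, dtype=bool)
        self.support_[order] = support_sorted
        self.window_start_ = float(ts[depth])
        self.window_end_ = float(ts[-1])
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        return self.slope_ * x + self.intercept_


def fit_slope(
    mu,
    rho_h,
    times=None,
    model: str = "free_intercept",
    min_points: int = 4,
    trim: bool = True,
    trim_rule: str = "first_local_max",
) -> SlopeFit:
    """Functional wrapper over :class:`SlopeFractionRegressor`."""
    est = SlopeFractionRegressor(model=model, min_points=min_points, trim=trim, trim_rule=trim_rule)
    est.fit(mu, rho_h, times=times)
    return SlopeFit(
        slope=est.slope_,
        intercept=est.intercept_,
        b=est.b_,
        r_squared=est.r_squared_,
        window_start_h=est.window_start_,
        window_end_h=est.window_end_,
        n_points=est.n_points_,
        model=model,
        slope_se=est.slope_se_,
        intercept_se=est.intercept_se_,
        n_trimmed=est.n_trimmed_,
        flags=est.flags_,
    )


def slope_fit_group(
    group: ConditionGroup,
    channel: str,
    maturation_time: float = 0.0,
    alpha: float = 0.05,
    model: str = "free_intercept",
    min_points: int = 4,
    trim: bool = True,
    trim_rule: str = "first_local_max",
    mu_min: float = 0.05,
) -> SlopeFit:
    """End-to-end slope method for one condition group.

    Computes per-replicate rates, restricts to the t-test growth phase, pools
    the replicate (mu, rho_H) points into one regression and trims the
    earliest points to the maximal-R^2 window.
    """
    mask = detect_growth_phase(group, alpha=alpha, mu_min=mu_min)
    mus, rhos, ts = [], [], []
    for s in group.series:
        rs = rate_series(s, channel, maturation_time)
        p = rs.times.size
        keep = mask.included[:p]
        mus.append(rs.mu[keep])
        rhos.append(rs.rho_h[keep])
        ts.append(rs.times[keep])
    mu = np.concatenate(mus)
    rho = np.concatenate(rhos)
    t = np.concatenate(ts)
    fit = fit_slope(mu, rho, times=t, model=model, min_points=min_points, trim=trim, trim_rule=trim_rule)
    fit.strain = group.strain
    fit.inducer = group.inducer
    fit.concentration = group.concentration
    fit.conc_unit = group.conc_unit
    return fit


def slope_dose_response(fits: Sequence[SlopeFit], r2_floor: float = 0.9) -> DoseResponse:
    """Assemble slope-method fits across a titration into a dose-response table.

    Fits with R^2 below ``r2_floor`` stay in the table but are flagged
    low-quality.
    """
    if not fits:
        raise InsufficientDataError("no slope fits to aggregate")
    strains = {f.strain for f in fits}
    inducers = {f.inducer for f in fits}
    if len(strains) > 1 or len(inducers) > 1:
        raise InsufficientDataError(
            f"dose-response must cover one (strain, inducer); got {strains} x {inducers}"
        )
    concs = [f.concentration for f in fits]
    if len(set(concs)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct concentrations for a dose-response, got {len(set(concs))}"
        )
    table = pd.DataFrame(
        {
            "concentration": concs,
            "f_h": [f.slope for f in fits],
            "variance": [f.slope_se**2 for f in fits],
            "n": [f.n_points for f in fits],
            "flags": [
                ";".join(filter(None, [*f.flags, "low_r_squared" if f.r_squared < r2_floor else ""]))
                for f in fits
            ],
        }
    )
    return DoseResponse(
        strain=fits[0].strain,
        inducer=fits[0].inducer,
        method="slope",
        table=table,
        conc_unit=fits[0].conc_unit,
    )


def slope_method_table(fits: Sequence[SlopeFit]) -> pd.DataFrame:
    """Flat CSV-ready view of slope-method fits."""
    return pd.DataFrame(
        {
            "strain": [f.strain for f in fits],
            "inducer": [f.inducer for f in fits],
            "concentration": [f.concentration for f in fits],
            "slope": [f.slope for f in fits],
            "slope_se": [f.slope_se for f in fits],
            "intercept": [f.intercept for f in fits],
            "b": [f.b for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "window_start_h": [f.window_start_h for f in fits],
            "window_end_h": [f.window_end_h for f in fits],
            "n_points": [f.n_points for f in fits],
            "model": [f.model for f in fits],
            "flags": [";".join(f.flags) for f in fits],
        }
    )
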
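"""Hill dose-response fitting for expression-fraction estimates.

The dose-response of an induced circuit is modelled as a Hill function of the
inducer concentration ``I``. Two algebraic forms are supported:

* ``full``:     f_H(I) = H * I^n / ((H + 1) * I^n + k_I^n)
* ``reduced``:  f_H(I) = H * I^n / (I^n + k_I^n)

The full form arises when the Hill law acts on the expression fraction of a
finite proteome (the plateau is H / (H + 1)); when the heterologous fraction
stays small (< ~15% of biomass) the (H + 1) factor is ~1 and the reduced,
textbook form applies. The two are exactly related by

    full(I; H, k, n) = reduced(I; H / (H + 1), k * (H + 1)^(-1/n), n).

Fitting is bounded, inverse-variance-weighted nonlinear least squares
(H >= 0, k_I >= 0, n >= 1) with multi-start initialisation over the Hill
coefficient, mirroring the bounded "port"-style NLS used for such curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import AggregationError, FitFailureError, InsufficientDataError

_FORMS = ("full", "reduced")


@dataclass
class DoseResponse:
    """Expression-fraction estimates across an inducer titration.

    ``table`` has columns ``concentration`` (strictly increasing, >= 0),
    ``f_h``, ``variance``, ``n`` and optionally ``flags``.
    """

    strain: str
    inducer: str
    method: str  # {"maximum", "slope"}
    table: pd.DataFrame
    conc_unit: str = "uM"

    def __post_init__(self) -> None:
        required = {"concentration", "f_h", "variance", "n"}
        missing = required - set(self.table.columns)
        if missing:
            raise AggregationError(f"DoseResponse table missing columns {sorted(missing)}")
        conc = self.table["concentration"].to_numpy(dtype=float)
        if np.any(conc < 0):
            raise AggregationError("concentrations must be >= 0")
        if np.unique(conc).size != conc.size:
            raise AggregationError(
                f"duplicate concentration entries for strain {self.strain!r}"
            )
        self.table = self.table.sort_values("concentration").reset_index(drop=True)


@dataclass
class HillParams:
    """Fitted Hill parameters with asymptotic standard errors.

    ``H`` is the maximum expression (flu/OD for plate-reader data, a fraction
    inside the simulator), ``k_I`` the apparent affinity in the titration's
    concentration units, and ``n`` the Hill coefficient (cooperativity).
    Standard errors come from the weighted Jacobian at the optimum, scaled by
    the reduced chi-square (the NLS convention).
    """

    H: float
    k_I: float
    n: float
    se_H: float = float("nan")
    se_kI: float = float("nan")
    se_n: float = float("nan")
    form: str = "reduced"
    converged: bool = True
    rss: float = float("nan")
    n_points: int = 0
    flags: tuple[str, ...] = ()


def hill_eval(I, params: HillParams | None = None, *, H=None, k_I=None, n=None, form=None):
    """Evaluate the Hill dose-response at concentration(s) ``I``.

    Accepts either a :class:`HillParams` or explicit ``H``, ``k_I``, ``n``,
    ``form`` keywords. ``I`` may be a scalar or array; negative concentrations
    raise ``ValueError``.
    """
    if params is not None:
        H, k_I, n, form = params.H, params.k_I, params.n, params.form
    form = form or "reduced"
    if form not in _FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {_FORMS}")
    I_arr = np.asarray(I, dtype=float)
    if np.any(I_arr < 0):
        raise ValueError("inducer concentration must be >= 0")
    In = np.power(I_arr, n)
    kn = k_I**n
    denom = (H + 1.0) * In + kn if form == "full" else In + kn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, H * In / np.where(denom > 0, denom, 1.0), 0.0)
    # I = 0 with k_I = 0 is the degenerate 0/0 corner; define it as the plateau
    if kn == 0:
        out = np.where(I_arr > 0, H / (H + 1.0) if form == "full" else H, 0.0)
    return float(out) if np.isscalar(I) else out


class HillRegressor(RegressorMixin, BaseEstimator):
    """Bounded, weighted Hill-function regressor (scikit-learn estimator API).

    Parameters
    ----------
    form : {"reduced", "full"}
        Algebraic form of the Hill law (see module docstring).
    n_starts : sequence of float
        Initial Hill coefficients for the multi-start; the best weighted RSS
        wins. Hill fits are multimodal in ``n``, so a single start is fragile.
    max_nfev : int
        Function-evaluation budget per start for the trust-region solver.

    Attributes
    ----------
    H_, k_I_, n_ : float
        Fitted parameters (``H_, k_I_ >= 0``; ``n_ >= 1``, the fit's bounds).
    se_H_, se_k_I_, se_n_ : float
        Asymptotic standard errors (weighted Jacobian, reduced-chi-square
        scaled).
    converged_ : bool
    rss_ : float
        Weighted residual sum of squares at the optimum.
    """

    def __init__(self, form: str = "reduced", n_starts: Sequence[float] = (1.0, 2.0, 4.0), max_nfev: int = 5000):
        self.form = form
        self.n_starts = n_starts
        self.max_nfev = max_nfev

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-D concentrations or an (n, 1) column")
        return X

    def fit(self, X, y, sample_weight=None):
        """Fit the Hill law to (concentration, response) data.

        ``sample_weight`` should be inverse variances; equal weights are used
        when omitted.
        """
        if self.form not in _FORMS:
            raise ValueError(f"unknown form {self.form!r}")
        I = self._as_1d(X)
        y = np.asarray(y, dtype=float)
        if I.shape != y.shape:
            raise ValueError("X and y have mismatched lengths")
        if np.any(I < 0):
            raise ValueError("concentrations must be >= 0")
        n_distinct = np.unique(I[I > 0]).size
        if I.size < 4 or n_distinct < 3:
            raise InsufficientDataError(
                f"Hill fit needs >= 4 points with >= 3 distinct non-zero concentrations "
                f"(got {I.size} points, {n_distinct} distinct)"
            )
        if sample_weight is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if np.any(w <= 0) or not np.all(np.isfinite(w)):
                raise ValueError("sample_weight must be positive and finite")
        sw = np.sqrt(w)

        def resid(theta):
            H, k, n = theta
            return sw * (y - hill_eval(I, H=H, k_I=k, n=n, form=self.form))

        ymax = float(np.max(y))
        if self.form == "full":
            p = min(max(ymax, 1e-9), 0.999)
            H0 = p / (1.0 - p)
        else:
            H0 = max(ymax, 1e-9)
        nz = I[I > 0]
        k0 = float(nz[np.argmin(np.abs(y[I > 0] - ymax / 2.0))]) if nz.size else 1.0
        k0 = max(k0, 1e-9)

        bounds = ([0.0, 0.0, 1.0], [np.inf, np.inf, np.inf])
        best = None
        for n0 in self.n_starts:
            try:
                res = least_squares(
                    resid, x0=[H0, k0, max(n0, 1.0)], bounds=bounds,
                    method="trf", max_nfev=self.max_nfev,
                )
            except Exception:  # solver blow-up on one start is not fatal
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise FitFailureError("Hill fit failed from every start")

        self.H_, self.k_I_, self.n_ = (float(v) for v in best.x)
        self.rss_ = float(2.0 * best.cost)
        self.converged_ = bool(best.success)
        self.n_features_in_ = 1
        self.flags_: tuple[str, ...] = ()
        if not best.success:
            self.flags_ += ("non_converged",)
        if nz.size:
            plateau = self.H_ / (self.H_ + 1.0) if self.form == "full" else self.H_
            y_lowest = hill_eval(float(np.min(nz)), H=self.H_, k_I=self.k_I_, n=self.n_, form=self.form)
            if plateau > 0 and y_lowest >= 0.95 * plateau:
                self.flags_ += ("non_identifiable_k_I",)
                warnings.warn(
                    "the fitted curve is already saturated at the smallest tested "
                    "concentration; k_I and n are not identifiable from these data",
                    stacklevel=2,
                )

        dof = max(I.size - 3, 1)
        s2 = self.rss_ / dof
        J = best.jac
        try:
            cov = s2 * np.linalg.inv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            cov = s2 * np.linalg.pinv(J.T @ J)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
            self.flags_ += ("singular_jacobian",)
        self.se_H_, self.se_k_I_, self.se_n_ = (float(v) for v in se)
        return self

    def predict(self, X):
        I = self._as_1d(X)
        return hill_eval(I, H=self.H_, k_I=self.k_I_, n=self.n_, form=self.form)

    def params_(self) -> HillParams:
        """Fitted parameters as a :class:`HillParams` record."""
        return HillParams(
            H=self.H_, k_I=self.k_I_, n=self.n_,
            se_H=self.se_H_, se_kI=self.se_k_I_, se_n=self.se_n_,
            form=self.form, converged=self.converged_, rss=self.rss_,
            flags=self.flags_,
        )


def fit_hill(dr: DoseResponse, form: str = "reduced") -> HillParams:
    """Inverse-variance-weighted Hill fit to a dose-response table.

    Points with zero/undefined variance receive the group-median variance
    (with a warning) so that a replicate-free point cannot dominate the fit.
    """
    tab = dr.table
    I = tab["concentration"].to_numpy(dtype=float)
    y = tab["f_h"].to_numpy(dtype=float)
    var = tab["variance"].to_numpy(dtype=float).copy()
    bad = ~np.isfinite(var) | (var <= 0)
    if bad.any():
        good = var[~bad]
        if good.size == 0:
            warnings.warn("no positive variances; falling back to equal weights", stacklevel=2)
            var = np.ones_like(var)
        else:
            warnings.warn(
                f"{int(bad.sum())} point(s) with zero/undefined variance assigned the "
                "group-median variance",
                stacklevel=2,
            )
            var[bad] = float(np.median(good))
    est = HillRegressor(form=form).fit(I, y, sample_weight=1.0 / var)
    params = est.params_()
    params.n_points = int(I.size)
    return params


@dataclass
class MethodComparison:
    """Per-parameter agreement between maximum-method and slope-method Hill fits.

    ``table`` rows: parameter, value_max, value_slope, abs_diff, rel_diff
    (relative to the maximum-method value) and z (abs_diff over the combined
    standard error).
    """

    strain: str = ""
    inducer: str = ""
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def max_abs_z(self) -> float:
        return float(np.nanmax(np.abs(self.table["z"].to_numpy(dtype=float))))


def compare_methods(
    max_params: HillParams,
    slope_params: HillParams,
    strain: str = "",
    inducer: str = "",
) -> MethodComparison:
    """Compare Hill parameters fitted from the two estimation routes."""
    rows = []
    for name, (a, sa), (b, sb) in [
        ("H", (max_params.H, max_params.se_H), (slope_params.H, slope_params.se_H)),
        ("k_I", (max_params.k_I, max_params.se_kI), (slope_params.k_I, slope_params.se_kI)),
        ("n", (max_params.n, max_params.se_n), (slope_params.n, slope_params.se_n)),
    ]:
        diff = abs(a - b)
        rel = diff / a if a != 0 else float("nan")
        se = np.hypot(sa, sb)
        rows.append(
            {
                "parameter": name,
                "value_max": a,
                "value_slope": b,
                "abs_diff": diff,
                "rel_diff": rel,
                "z": diff / se if se > 0 else (0.0 if diff == 0 else float("inf")),
            }
        )
    return MethodComparison(strain=strain, inducer=inducer, table=pd.DataFrame(rows))
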
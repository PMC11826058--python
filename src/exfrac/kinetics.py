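"""Specific growth rate, specific production rate and the heterologous-fraction proxy.

All three quantities come from one well's raw trajectories:

* specific growth rate  ``mu(t) = [OD(t+dt) - OD(t)] / (dt * OD(t))``, per hour;
* specific production rate ``rho_H(t) = [flu(t+dt) - flu(t)] / (dt * OD(t))``,
  in flu * OD^-1 * h^-1, optionally after shifting the fluorescence trace
  earlier by a whole number of samples to undo slow fluorophore maturation
  (1 h for common RFPs; GFPmut3 matures in ~4 min, faster than 15-min sampling,
  so no shift);
* heterologous-fraction proxy ``phi_H(t) = flu(t) / OD600(t)``.

Forward differences are assigned to the left endpoint and no smoothing is
applied: these are the field's plate-reader estimators, reproduced literally
rather than improved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataQualityError, InsufficientDataError
from .io import ConditionGroup, WellTimeSeries


@dataclass
class RateSeries:
    """Derived rates for one well, aligned on shared grids.

    ``times``, ``mu`` and ``rho_h`` live on the forward-difference grid (the
    left endpoints common to both rates, truncated to the shorter of the two
    when a maturation shift drops trailing points). ``phi_times``/``phi_h``
    stay on the original sample grid.
    """

    well_id: str
    times: np.ndarray
    mu: np.ndarray
    rho_h: np.ndarray
    phi_times: np.ndarray
    phi_h: np.ndarray
    channel: str = ""


def _check_positive_od(series: WellTimeSeries) -> None:
    if np.any(series.od600 <= 0):
        raise DataQualityError(
            f"well {series.well_id!r}: OD600 must be > 0 for rate estimation "
            "(blank-correct with a positive floor first)"
        )


def specific_growth_rate(series: WellTimeSeries) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference specific growth rate.

    Returns ``(times, mu)`` where ``times`` are the left endpoints
    (length ``m - 1`` for ``m`` samples) and ``mu`` is in h^-1. Non-uniform
    sampling is supported; each interval uses its own dt.
    """
    _check_positive_od(series)
    if series.n_samples < 2:
        raise InsufficientDataError(f"well {series.well_id!r}: need >= 2 points for growth rate")
    dt = series.dt()
    od = series.od600
    mu = (od[1:] - od[:-1]) / (dt * od[:-1])
    return series.times[:-1], mu


def maturation_shift_samples(times: np.ndarray, maturation_time: float) -> int:
    """Number of whole samples the fluorescence trace is shifted earlier.

    Uses the median sampling interval and round-to-nearest: 1 h maturation at
    15-min sampling gives a 4-sample shift. Warns when the grid is non-uniform
    by more than 10%, since a single shift count is then only approximate.
    """
    if maturation_time < 0:
        raise ValueError("maturation_time must be >= 0")
    dt = np.diff(times)
    med = float(np.median(dt))
    if np.max(np.abs(dt - med)) > 0.1 * med:
        warnings.warn(
            "sampling interval varies by more than 10%; maturation shift uses the median dt",
            stacklevel=2,
        )
    return int(round(maturation_time / med))


def shift_fluorescence(flu: np.ndarray, k: int) -> np.ndarray:
    """Shift a fluorescence trace ``k`` samples earlier, dropping the trailing points.

    ``k = 0`` is the identity. The ``k`` values lost at the end are dropped,
    never extrapolated.
    """
    if k == 0:
        return np.asarray(flu)
    if k < 0:
        raise ValueError("shift count must be >= 0")
    if k >= flu.size:
        raise InsufficientDataError(
            f"maturation shift of {k} samples consumes the whole {flu.size}-point trace"
        )
    return np.asarray(flu)[k:]


def specific_production_rate(
    series: WellTimeSeries,
    channel: str,
    maturation_time: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-difference specific production rate of the reporter.

    The fluorescence trace is first shifted earlier by
    ``k = round(maturation_time / median dt)`` samples, then differenced and
    normalised by dt and OD600(t). Returns ``(times, rho_h)`` on the left
    endpoints of the shifted grid (length ``m - k - 1``).
    """
    _check_positive_od(series)
    flu = series.channel(channel)
    k = maturation_shift_samples(series.times, maturation_time)
    shifted = shift_fluorescence(flu, k)
    m = shifted.size
    if m < 2:
        raise InsufficientDataError(
            f"well {series.well_id!r}: maturation shift leaves {m} point(s), need >= 2"
        )
    t = series.times[:m]
    od = series.od600[:m]
    dt = np.diff(t)
    rho = (shifted[1:] - shifted[:-1]) / (dt * od[:-1])
    return t[:-1], rho


def heterologous_fraction(series: WellTimeSeries, channel: str) -> tuple[np.ndarray, np.ndarray]:
    """Fluorescence / OD600 ratio on the sample grid: the phi_H proxy."""
    _check_positive_od(series)
    return series.times, series.channel(channel) / series.od600


def rate_series(
    series: WellTimeSeries,
    channel: str,
    maturation_time: float = 0.0,
) -> RateSeries:
    """Compute mu, rho_H and phi_H for one well on aligned grids."""
    t_mu, mu = specific_growth_rate(series)
    t_rho, rho = specific_production_rate(series, channel, maturation_time)
    p = t_rho.size  # rho grid is the shorter one (maturation shift)
    t_phi, phi = heterologous_fraction(series, channel)
    return RateSeries(
        well_id=series.well_id,
        times=t_mu[:p],
        mu=mu[:p],
        rho_h=rho,
        phi_times=t_phi,
        phi_h=phi,
        channel=channel,
    )


def rates_table(
    groups: Sequence[ConditionGroup] | Sequence[WellTimeSeries],
    channel: str,
    maturation_time: float = 0.0,
) -> pd.DataFrame:
    """Tidy export of all derived rates: well, time_h, mu_per_h, rho_h, phi_h.

    One row per forward-difference point (m - 1 rows for m samples); ``rho_h``
    is NaN on the trailing points a maturation shift consumed.
    """
    wells: list[WellTimeSeries] = []
    for item in groups:
        wells.extend(item.series if isinstance(item, ConditionGroup) else [item])
    frames = []
    for s in wells:
        rs = rate_series(s, channel, maturation_time)
        t_mu, mu = specific_growth_rate(s)
        rho = np.full(t_mu.size, np.nan)
        rho[: rs.rho_h.size] = rs.rho_h
        frames.append(
            pd.DataFrame(
                {
                    "well": s.well_id,
                    "time_h": t_mu,
                    "mu_per_h": mu,
                    "rho_h": rho,
                    "phi_h": rs.phi_h[: t_mu.size],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
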
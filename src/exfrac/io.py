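"""Plate-reader time-series IO and condition grouping.

The canonical on-disk form is a pair of tidy CSV files:

* **data CSV** — columns ``time_h`` (float, hours), ``well`` (string),
  ``od600`` (float) and one or more fluorescence columns named
  ``flu_<channel>`` (e.g. ``flu_gfp``).
* **layout CSV** — columns ``well``, ``strain``, ``inducer``,
  ``concentration``, ``conc_unit``, ``replicate``, ``is_blank``.

A converter from the common plate-reader matrix export (time in rows, wells
in columns) is provided, but the tidy dialect is the contract: the
read -> write -> read round trip is bit-exact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DataQualityError,
    DuplicationError,
    FormatError,
    InsufficientDataError,
    OrderingError,
)

DATA_COLUMNS = ("time_h", "well", "od600")
LAYOUT_COLUMNS = ("well", "strain", "inducer", "concentration", "conc_unit", "replicate", "is_blank")

#: Positive floor applied to blank-corrected OD600, in absorbance units.
EPS_OD = 1e-3

#: Tolerance (hours) for deciding that replicate wells share one time grid.
TIME_GRID_ATOL = 1e-8

_TIME_FACTORS = {"h": 1.0, "min": 1.0 / 60.0, "s": 1.0 / 3600.0}


@dataclass
class WellTimeSeries:
    """One well's sampled OD600 and fluorescence trajectories.

    Parameters
    ----------
    well_id : str
        Plate coordinate label (e.g. ``"B3"``).
    times : array of float
        Sampling times in hours, strictly increasing, length >= 2.
    od600 : array of float
        Absorbance at 600 nm, same length as ``times``.
    fluorescence : dict of str -> array
        Channel name -> fluorescence values (arbitrary units), each the same
        length as ``times``.
    """

    well_id: str
    times: np.ndarray
    od600: np.ndarray
    fluorescence: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.fluorescence = {k: np.asarray(v, dtype=float) for k, v in self.fluorescence.items()}
        if self.times.ndim != 1 or self.times.size < 2:
            raise InsufficientDataError(
                f"well {self.well_id!r}: need at least 2 time points, got {self.times.size}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise OrderingError(f"well {self.well_id!r}: times are not strictly increasing")
        for name, arr in [("od600", self.od600), *self.fluorescence.items()]:
            if arr.shape != self.times.shape:
                raise FormatError(
                    f"well {self.well_id!r}: series {name!r} has length {arr.size}, "
                    f"expected {self.times.size}"
                )

    @property
    def n_samples(self) -> int:
        return self.times.size

    def dt(self) -> np.ndarray:
        """Consecutive time differences (hours), length ``n_samples - 1``."""
        return np.diff(self.times)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.fluorescence[name]
        except KeyError:
            raise FormatError(
                f"well {self.well_id!r} has no fluorescence channel {name!r}; "
                f"available: {sorted(self.fluorescence)}"
            ) from None


@dataclass(frozen=True)
class WellAnnotation:
    """Plate-layout row mapping one well to its experimental condition."""

    well_id: str
    strain: str
    inducer: str
    concentration: float
    conc_unit: str = "uM"
    replicate: int = 1
    is_blank: bool = False


@dataclass
class ConditionGroup:
    """Replicate wells sharing one (strain, inducer, concentration) condition.

    All member series must share one time grid (within :data:`TIME_GRID_ATOL`);
    silent resampling is an error by design.
    """

    strain: str
    inducer: str
    concentration: float
    series: list[WellTimeSeries]
    conc_unit: str = "uM"

    def __post_init__(self) -> None:
        if not self.series:
            raise InsufficientDataError("ConditionGroup requires at least one series")
        ref = self.series[0].times
        for s in self.series[1:]:
            if s.times.size != ref.size or not np.allclose(s.times, ref, rtol=0.0, atol=TIME_GRID_ATOL):
                raise FormatError(
                    f"group ({self.strain!r}, {self.inducer!r}, {self.concentration}): "
                    f"well {s.well_id!r} is on a different time grid than {self.series[0].well_id!r}; "
                    "resample explicitly before grouping"
                )

    @property
    def key(self) -> tuple[str, str, float]:
        return (self.strain, self.inducer, self.concentration)

    @property
    def n_replicates(self) -> int:
        return len(self.series)

    @property
    def times(self) -> np.ndarray:
        return self.series[0].times


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} is missing required column {col!r}")


def read_layout_csv(path: str | Path) -> list[WellAnnotation]:
    """Read a plate-layout CSV into :class:`WellAnnotation` records."""
    df = pd.read_csv(path)
    _require_columns(df, LAYOUT_COLUMNS, f"layout file {path}")
    if df["well"].duplicated().any():
        dup = df.loc[df["well"].duplicated(), "well"].iloc[0]
        raise DuplicationError(f"layout file {path}: well {dup!r} appears more than once")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            WellAnnotation(
                well_id=str(row.well),
                strain=str(row.strain),
                inducer=str(row.inducer),
                concentration=float(row.concentration),
                conc_unit=str(row.conc_unit),
                replicate=int(row.replicate),
                is_blank=bool(row.is_blank),
            )
        )
    return out


def read_tidy_csv(
    path: str | Path,
    layout_path: str | Path,
    *,
    time_unit: str = "h",
    include_blanks: bool = False,
) -> list[ConditionGroup] | tuple[list[ConditionGroup], list[WellTimeSeries]]:
    """Read tidy data + layout CSVs and group wells by condition.

    Parameters
    ----------
    path, layout_path
        Data CSV and layout CSV paths (see module docstring for the dialect).
    time_unit : {"h", "min", "s"}
        Unit of the ``time_h`` column; converted to hours explicitly, never
        guessed.
    include_blanks : bool
        If True, also return the blank wells' series (for
        :func:`blank_correct`).

    Returns
    -------
    list of ConditionGroup, or (groups, blanks) when ``include_blanks``.
        Groups are sorted by (strain, inducer, concentration); blank wells are
        excluded from every group.
    """
    if time_unit not in _TIME_FACTORS:
        raise FormatError(f"unknown time unit {time_unit!r}; expected one of {sorted(_TIME_FACTORS)}")
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, DATA_COLUMNS, f"data file {path}")
    flu_cols = [c for c in df.columns if c.startswith("flu_")]
    if not flu_cols:
        raise FormatError(f"data file {path} has no fluorescence column (expected 'flu_<channel>')")
    if df.duplicated(subset=["well", "time_h"]).any():
        bad = df.loc[df.duplicated(subset=["well", "time_h"]), ["well", "time_h"]].iloc[0]
        raise DuplicationError(
            f"data file {path}: duplicate row for well {bad['well']!r} at time {bad['time_h']}"
        )

    annotations = read_layout_csv(layout_path)
    ann_by_well = {a.well_id: a for a in annotations}

    series_by_well: dict[str, WellTimeSeries] = {}
    for well, sub in df.groupby("well", sort=False):
        t = sub["time_h"].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
        if np.any(np.diff(t) <= 0):
            raise OrderingError(f"data file {path}: time not strictly increasing in well {well!r}")
        series_by_well[str(well)] = WellTimeSeries(
            well_id=str(well),
            times=t,
            od600=sub["od600"].to_numpy(dtype=float),
            fluorescence={c.removeprefix("flu_"): sub[c].to_numpy(dtype=float) for c in flu_cols},
        )

    missing = [a.well_id for a in annotations if a.well_id not in series_by_well]
    if missing:
        raise FormatError(f"layout references wells absent from data: {missing}")
    unannotated = sorted(set(series_by_well) - set(ann_by_well))
    if unannotated:
        raise FormatError(f"data contains wells absent from layout: {unannotated}")

    grouped: dict[tuple[str, str, float], list[WellTimeSeries]] = {}
    units: dict[tuple[str, str, float], str] = {}
    blanks: list[WellTimeSeries] = []
    for a in annotations:
        if a.is_blank:
            blanks.append(series_by_well[a.well_id])
            continue
        grouped.setdefault((a.strain, a.inducer, a.concentration), []).append(series_by_well[a.well_id])
        units[(a.strain, a.inducer, a.concentration)] = a.conc_unit

    groups = [
        ConditionGroup(strain=k[0], inducer=k[1], concentration=k[2], series=v, conc_unit=units[k])
        for k, v in sorted(grouped.items())
    ]
    if include_blanks:
        return groups, blanks
    return groups


def series_to_frame(series: Sequence[WellTimeSeries]) -> pd.DataFrame:
    """Stack well series into one tidy data frame (the data-CSV dialect)."""
    frames = []
    for s in series:
        d = {"time_h": s.times, "well": s.well_id, "od600": s.od600}
        for name, vals in s.fluorescence.items():
            d[f"flu_{name}"] = vals
        frames.append(pd.DataFrame(d))
    df = pd.concat(frames, ignore_index=True)
    cols = ["time_h", "well", "od600"] + [c for c in df.columns if c.startswith("flu_")]
    return df[cols]


def write_tidy_csv(
    series: Sequence[WellTimeSeries] | Sequence[ConditionGroup],
    path: str | Path,
) -> None:
    """Write well series (or whole groups) back to the tidy data dialect.

    Floats are written with :func:`repr`-style precision so that a
    read -> write -> read round trip reproduces values bit-exactly.
    """
    flat: list[WellTimeSeries] = []
    for item in series:
        if isinstance(item, ConditionGroup):
            flat.extend(item.series)
        else:
            flat.append(item)
    series_to_frame(flat).to_csv(path, index=False)


def write_layout_csv(annotations: Sequence[WellAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "well": a.well_id,
                "strain": a.strain,
                "inducer": a.inducer,
                "concentration": a.concentration,
                "conc_unit": a.conc_unit,
                "replicate": a.replicate,
                "is_blank": a.is_blank,
            }
            for a in annotations
        ]
    ).to_csv(path, index=False)


def matrix_to_tidy(
    path: str | Path,
    *,
    channel_paths: Mapping[str, str | Path] | None = None,
    time_column: str = "time",
    time_unit: str = "h",
) -> pd.DataFrame:
    """Convert a plate-reader matrix export (time rows, wells columns) to tidy form.

    ``path`` holds the OD600 matrix; ``channel_paths`` maps channel names to
    matrix files of identical shape holding fluorescence. Returns a tidy data
    frame in the data-CSV dialect.
    """
    if time_unit not in _TIME_FACTORS:
        raise FormatError(f"unknown time unit {time_unit!r}")
    od = pd.read_csv(path, float_precision="round_trip")
    if time_column not in od.columns:
        raise FormatError(f"matrix file {path} is missing time column {time_column!r}")
    wells = [c for c in od.columns if c != time_column]
    t = od[time_column].to_numpy(dtype=float) * _TIME_FACTORS[time_unit]
    records = {
        "time_h": np.tile(t, len(wells)),
        "well": np.repeat(wells, t.size),
        "od600": np.concatenate([od[w].to_numpy(dtype=float) for w in wells]),
    }
    for name, cpath in (channel_paths or {}).items():
        flu = pd.read_csv(cpath, float_precision="round_trip")
        missing = [w for w in wells if w not in flu.columns]
        if missing:
            raise FormatError(f"channel file {cpath} is missing wells {missing}")
        records[f"flu_{name}"] = np.concatenate([flu[w].to_numpy(dtype=float) for w in wells])
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# blank correction
# ---------------------------------------------------------------------------

def blank_correct(
    groups: Sequence[ConditionGroup],
    blanks: Sequence[WellTimeSeries],
    mode: str = "none",
    eps_od: float = EPS_OD,
) -> list[ConditionGroup]:
    """Subtract the mean blank signal from every sample well.

    mode="none" returns the input unchanged (the default: specific rates
    normalise raw fluorescence by raw OD600). mode="mean_blank" subtracts the
    per-time-point mean blank OD600 and fluorescence; corrected OD is clipped
    at ``eps_od`` to keep it positive for the downstream rate estimators.

    Raises
    ------
    DataQualityError
        If a well's corrected OD600 is entirely <= 0.
    """
    if mode == "none":
        return list(groups)
    if mode != "mean_blank":
        raise ValueError(f"unknown blank-correction mode {mode!r}")
    if not blanks:
        raise InsufficientDataError("mode='mean_blank' requires at least one blank well")

    ref_t = groups[0].times if groups else blanks[0].times
    for b in blanks:
        if b.times.size != ref_t.size or not np.allclose(b.times, ref_t, rtol=0.0, atol=TIME_GRID_ATOL):
            raise FormatError(f"blank well {b.well_id!r} is on a different time grid than the samples")

    mean_od = np.mean([b.od600 for b in blanks], axis=0)
    channels = set().union(*(b.fluorescence.keys() for b in blanks))
    mean_flu = {c: np.mean([b.fluorescence[c] for b in blanks], axis=0) for c in channels}

    out = []
    for g in groups:
        corrected = []
        for s in g.series:
            od = s.od600 - mean_od
            if np.all(od <= 0):
                raise DataQualityError(
                    f"well {s.well_id!r}: blank-corrected OD600 is entirely <= 0"
                )
            n_clipped = int(np.sum(od < eps_od))
            if n_clipped:
                warnings.warn(
                    f"well {s.well_id!r}: {n_clipped} blank-corrected OD600 value(s) "
                    f"below {eps_od} clipped to the floor",
                    stacklevel=2,
                )
                od = np.maximum(od, eps_od)
            flu = {c: v - mean_flu.get(c, 0.0) for c, v in s.fluorescence.items()}
            corrected.append(WellTimeSeries(s.well_id, s.times.copy(), od, flu))
        out.append(ConditionGroup(g.strain, g.inducer, g.concentration, corrected, g.conc_unit))
    return out
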
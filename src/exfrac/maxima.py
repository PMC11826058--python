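"""The maximum method: expression fraction from the peak of phi_H.

At any interior extremum of a proteome fraction, d(phi_i)/dt = 0 forces
phi_i = f_i (the fraction's share of the biosynthesis flux), provided the
cell's anabolic rate is non-zero. The maximum method therefore reads the
expression fraction straight off the peak of the fluorescence/OD trace:
per replicate, take the maximum of phi_H(t) within an early window (default
the first 10 h of culture, measured from induction), then average the
per-replicate maxima. Peaks sitting on the window edge are flagged — a
boundary maximum means the trace never turned over (reporters that keep
accumulating into stationary phase have no interior maximum and the method
does not apply).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AggregationError, InsufficientDataError
from .hill import DoseResponse
from .io import ConditionGroup
from .kinetics import heterologous_fraction


@dataclass
class MaxFraction:
    """Per-condition maximum-method estimate.

    ``phi_max_mean`` (mean of per-replicate maxima, flu/OD) is the f_H
    estimate; ``phi_max_var`` is the sample variance (N-1 denominator) across
    replicates, which feeds the inverse-variance weights of the Hill fit.
    """

    strain: str
    inducer: str
    concentration: float
    phi_max_mean: float
    phi_max_var: float
    t_max: np.ndarray  # per-replicate argmax times, hours
    n_replicates: int
    window_h: float
    boundary_fraction: float = 0.0
    boundary_flag: bool = False
    conc_unit: str = "uM"


def find_phi_max(group: ConditionGroup, channel: str, window_h: float = 10.0) -> MaxFraction:
    """Per-replicate maximum of phi_H over t <= window_h, averaged.

    Ties between equal maxima resolve to the earliest index (an arbitrary but
    deterministic rule). The ``boundary_flag`` is set when more than half of
    the replicates peak at the last in-window sample.
    """
    maxima, t_at_max, at_edge = [], [], []
    for s in group.series:
        t, phi = heterologous_fraction(s, channel)
        mask = t <= window_h
        if not mask.any():
            raise InsufficientDataError(
                f"well {s.well_id!r}: no samples inside the {window_h}-h window"
            )
        idx = int(np.argmax(phi[mask]))  # earliest index wins on ties
        maxima.append(float(phi[mask][idx]))
        t_at_max.append(float(t[mask][idx]))
        at_edge.append(idx == int(mask.sum()) - 1)
    maxima_arr = np.asarray(maxima)
    n = len(maxima)
    boundary_fraction = float(np.mean(at_edge))
    return MaxFraction(
        strain=group.strain,
        inducer=group.inducer,
        concentration=group.concentration,
        phi_max_mean=float(np.mean(maxima_arr)),
        phi_max_var=float(np.var(maxima_arr, ddof=1)) if n > 1 else float("nan"),
        t_max=np.asarray(t_at_max),
        n_replicates=n,
        window_h=window_h,
        boundary_fraction=boundary_fraction,
        boundary_flag=boundary_fraction > 0.5,
        conc_unit=group.conc_unit,
    )


def max_dose_response(results: Sequence[MaxFraction]) -> DoseResponse:
    """Assemble per-concentration maximum-method estimates into a titration table."""
    if not results:
        raise InsufficientDataError("no maximum-method results to aggregate")
    strains = {r.strain for r in results}
    inducers = {r.inducer for r in results}
    if len(strains) > 1 or len(inducers) > 1:
        raise AggregationError(
            f"dose-response must cover one (strain, inducer); got {strains} x {inducers}"
        )
    concs = [r.concentration for r in results]
    if len(set(concs)) != len(concs):
        raise AggregationError(f"duplicate concentration entries for strain {results[0].strain!r}")
    if len(set(concs)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct concentrations for a dose-response, got {len(set(concs))}"
        )
    table = pd.DataFrame(
        {
            "concentration": concs,
            "f_h": [r.phi_max_mean for r in results],
            "variance": [r.phi_max_var for r in results],
            "n": [r.n_replicates for r in results],
            "flags": ["boundary_maximum" if r.boundary_flag else "" for r in results],
        }
    )
    return DoseResponse(
        strain=results[0].strain,
        inducer=results[0].inducer,
        method="maximum",
        table=table,
        conc_unit=results[0].conc_unit,
    )


def max_method_table(results: Sequence[MaxFraction]) -> pd.DataFrame:
    """Flat CSV-ready view of maximum-method results."""
    return pd.DataFrame(
        {
            "strain": [r.strain for r in results],
            "inducer": [r.inducer for r in results],
            "concentration": [r.concentration for r in results],
            "f_h_max": [r.phi_max_mean for r in results],
            "variance": [r.phi_max_var for r in results],
            "n": [r.n_replicates for r in results],
            "t_max_mean": [float(np.mean(r.t_max)) for r in results],
            "boundary_flag": [r.boundary_flag for r in results],
        }
    )
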
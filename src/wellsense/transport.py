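"""Transepithelial transport readouts from apical/basolateral peak currents.

In a Transwell permeability experiment the analyte is dosed apically and
its passage through the monolayer is followed by sensors on both sides.
The apical signal is summarized as a percent decrease from the
pre-treatment baseline (T0); the basolateral side, where the signal starts
below the detection floor, is summarized qualitatively: the timepoint at
which a peak first appears, fold-change once quantifiable, and whether the
joint pattern (apical falling, basolateral rising) is consistent with
barrier disruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import InvalidInputError
from .voltammetry import Voltammogram, find_peak

__all__ = [
    "TransportSeries",
    "percent_decrease",
    "transport_report",
    "series_from_traces",
]


@dataclass(frozen=True)
class TransportSeries:
    """Time-stamped apical and basolateral peak currents for one ion.

    ``timepoints`` are hours since dosing with the first entry 0 (the
    pre-treatment T0); currents are baseline-corrected peak heights in A,
    with absent peaks recorded as 0.  A detectable apical dose at T0 is
    required.
    """

    ion: str
    timepoints: np.ndarray
    apical: np.ndarray = field(repr=False)
    basolateral: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        a = np.asarray(self.apical, dtype=float)
        b = np.asarray(self.basolateral, dtype=float)
        if not (t.shape == a.shape == b.shape) or t.ndim != 1 or t.size == 0:
            raise InvalidInputError("timepoints, apical and basolateral must be equal-length 1-D arrays")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("timepoints must be strictly increasing")
        if t[0] != 0:
            raise InvalidInputError("first timepoint must be 0 (pre-treatment T0)")
        if a[0] <= 0:
            raise InvalidInputError("apical peak current at T0 must be > 0 (detectable dose)")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "apical", a)
        object.__setattr__(self, "basolateral", b)

    def _index_of(self, t: float) -> int:
        matches = np.flatnonzero(np.isclose(self.timepoints, t))
        if matches.size == 0:
            raise InvalidInputError(
                f"timepoint {t} h not in series (have {self.timepoints.tolist()})"
            )
        return int(matches[0])


def percent_decrease(series: TransportSeries, t: float) -> float:
    """Apical peak-current decrease at time ``t`` relative to T0, percent.

    100 * (apical[0] - apical[t]) / apical[0]; negative when the signal
    rose above its baseline.
    """
    if t <= 0:
        raise InvalidInputError("t must be a post-treatment timepoint (> 0)")
    idx = series._index_of(t)
    return 100.0 * (series.apical[0] - series.apical[idx]) / series.apical[0]


def transport_report(
    series: TransportSeries, detection_floor: float = 0.0
) -> pd.DataFrame:
    """Per-timepoint transport table with qualitative basolateral flags.

    Columns: ``timepoint_h``, ``apical_pct_decrease`` (NaN at T0),
    ``basolateral_fold_change`` (vs T0; NaN when the T0 basolateral signal
    is at or below ``detection_floor``), ``basolateral_detected``.

    The frame's ``attrs`` carry series-level conclusions:
    ``appeared_at_h`` (first timepoint with a detectable basolateral peak
    when T0 had none; None if never), ``basolateral_monotone_increase``,
    and ``consistent_with_barrier_disruption`` (apical strictly decreasing
    while the basolateral signal strictly increases).
    """
    t = series.timepoints
    a = series.apical
    b = series.basolateral
    detected = b > detection_floor

    pct = 100.0 * (a[0] - a) / a[0]
    pct[0] = np.nan

    if detected[0]:
        fold = np.where(detected, b / b[0], np.nan)
        appeared_at = None
    else:
        fold = np.full_like(b, np.nan)
        appearances = np.flatnonzero(detected)
        appeared_at = float(t[appearances[0]]) if appearances.size else None

    report = pd.DataFrame(
        {
            "timepoint_h": t,
            "apical_pct_decrease": pct,
            "basolateral_fold_change": fold,
            "basolateral_detected": detected,
        }
    )
    det_vals = b[detected]
    report.attrs["appeared_at_h"] = appeared_at
    report.attrs["basolateral_monotone_increase"] = bool(
        det_vals.size >= 2 and np.all(np.diff(det_vals) > 0)
    )
    report.attrs["consistent_with_barrier_disruption"] = bool(
        np.all(np.diff(a) < 0) and np.all(np.diff(b) > 0)
    )
    return report


def series_from_traces(
    ion: str,
    timepoints: Sequence[float],
    apical_traces: Sequence[Voltammogram],
    basolateral_traces: Sequence[Voltammogram],
    window: Optional[tuple] = None,
    min_prominence: Optional[float] = None,
) -> TransportSeries:
    """Build a :class:`TransportSeries` by peak extraction on raw traces.

    Peaks that fail the prominence test (``found=False``) are recorded as
    zero current, matching the "no peak detected" bookkeeping of a blank
    compartment.
    """
    if not (len(timepoints) == len(apical_traces) == len(basolateral_traces)):
        raise InvalidInputError("timepoints and trace lists must have equal lengths")

    def heights(traces: Sequence[Voltammogram]) -> np.ndarray:
        out = []
        for v in traces:
            peak = find_peak(v, window=window, min_prominence=min_prominence)
            out.append(peak.i_peak if peak.found else 0.0)
        return np.array(out)

    return TransportSeries(
        ion=ion,
        timepoints=np.asarray(timepoints, dtype=float),
        apical=heights(apical_traces),
        basolateral=heights(basolateral_traces),
    )
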
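"""Log-linear calibration of SWASV peak current against ion concentration.

Over the working range the oxidation peak current is linear in the decadic
logarithm of the molar concentration,

    i_peak = m * log10(C) + b,

so the calibration is an ordinary least-squares line of mean replicate
current on log10(C).  The fit reports the Pearson correlation r, the worst
per-point relative standard deviation across replicates, and the limit of
detection LOD = 3*sigma_blank / m.

Note on LOD units: with the slope in A per decade of concentration,
3*sigma/m is dimensionally a decade count; the quantity is nonetheless
conventionally quoted on the molar scale in the sensing literature.  The
computation here is the literal 3*sigma/m and the interpretation is
recorded on the result rather than resolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import InvalidInputError

__all__ = [
    "CalibrationPoint",
    "CalibrationResult",
    "CalibrationModel",
    "ConcentrationEstimate",
    "IonCalibration",
    "fit_calibration",
    "lod",
    "predict_concentration",
]

#: concentration panel used for sensor characterization, mol/L
STANDARD_CONCENTRATIONS = (1e-11, 1e-10, 1e-9, 1e-7, 1e-6)


@dataclass(frozen=True)
class CalibrationPoint:
    """Replicate peak currents (A) measured at one standard concentration (mol/L)."""

    concentration: float
    replicate_currents: tuple

    def __post_init__(self) -> None:
        if not np.isfinite(self.concentration) or self.concentration <= 0:
            raise InvalidInputError(
                f"concentration must be > 0 (log10 defined), got {self.concentration!r}"
            )
        currents = tuple(float(c) for c in self.replicate_currents)
        if len(currents) < 1:
            raise InvalidInputError("need at least one replicate current")
        if not all(np.isfinite(c) for c in currents):
            raise InvalidInputError("replicate currents must be finite")
        object.__setattr__(self, "replicate_currents", currents)

    @property
    def mean_current(self) -> float:
        return float(np.mean(self.replicate_currents))

    @property
    def rsd_pct(self) -> float:
        """Relative standard deviation of the replicates, percent (0 for n=1)."""
        if len(self.replicate_currents) < 2:
            return 0.0
        m = self.mean_current
        if m == 0:
            return float("inf")
        return 100.0 * float(np.std(self.replicate_currents, ddof=1)) / abs(m)


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted calibration line i_peak = slope * log10(C) + intercept.

    slope in A per decade of molar concentration, intercept in A.  ``r``
    is the Pearson correlation of the fitted pairs, ``rsd_max`` the worst
    per-concentration replicate RSD in percent, ``lod`` the 3*sigma/m
    detection limit when a blank sigma has been supplied (None otherwise;
    see module docstring on its unit interpretation).
    """

    ion: str
    slope: float
    intercept: float
    r: float
    rsd_max: float
    n_points: int
    lod: Optional[float] = None
    lod_note: str = "3*sigma_blank/slope, quoted on the molar scale by convention"
    conc_range: tuple = (min(STANDARD_CONCENTRATIONS), max(STANDARD_CONCENTRATIONS))

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvalidInputError("a calibration needs at least 3 concentrations")
        if not -1.0 <= self.r <= 1.0:
            raise InvalidInputError(f"Pearson r out of range: {self.r}")

    def predict_current(self, concentration: float) -> float:
        """Forward line: expected peak current (A) at a molar concentration."""
        return self.slope * np.log10(concentration) + self.intercept

    def summary(self) -> str:
        lod_txt = f"{self.lod:.3g}" if self.lod is not None else "n/a (no blank sigma)"
        return "\n".join(
            [
                f"{self.ion} SWASV calibration (peak current vs log10 concentration)",
                "=" * 58,
                f"slope      {self.slope: .4g}  A/decade",
                f"intercept  {self.intercept: .4g}  A",
                f"Pearson r  {self.r: .5f}   (n = {self.n_points} concentrations)",
                f"max RSD    {self.rsd_max: .2f} %",
                f"LOD        {lod_txt}   ({self.lod_note})",
            ]
        )


# spec-facing alias
CalibrationModel = CalibrationResult


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Inverse-calibration estimate with an extrapolation flag."""

    concentration: float
    extrapolated: bool


class IonCalibration:
    """Calibration model built from replicate peak currents at standard levels.

    Parameters
    ----------
    points : sequence of CalibrationPoint
        One entry per standard concentration; replicates are averaged
        before the regression and feed the per-point RSD.
    ion : {"Cu", "Zn"}

    Use :meth:`from_dataframe` to build from tidy long-format data with
    columns ``concentration_m``, ``peak_current_a`` and optionally
    ``replicate_id``.
    """

    def __init__(self, points: Sequence[CalibrationPoint], ion: str = "Cu"):
        pts = sorted(points, key=lambda p: p.concentration)
        concs = [p.concentration for p in pts]
        if len(set(concs)) < 3:
            raise InvalidInputError(
                f"need >= 3 distinct concentrations, got {len(set(concs))}"
            )
        if len(set(concs)) != len(concs):
            raise InvalidInputError("duplicate concentration points; merge replicates first")
        self.points = tuple(pts)
        self.ion = ion

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, ion: str = "Cu") -> "IonCalibration":
        required = {"concentration_m", "peak_current_a"}
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"calibration table missing columns: {sorted(missing)}")
        points = [
            CalibrationPoint(concentration=float(conc), replicate_currents=tuple(g["peak_current_a"]))
            for conc, g in df.groupby("concentration_m", sort=True)
        ]
        return cls(points, ion=ion)

    def fit(self, sigma_blank: Optional[float] = None) -> CalibrationResult:
        """OLS fit of mean replicate current on log10(concentration)."""
        x = np.log10([p.concentration for p in self.points])
        y = np.array([p.mean_current for p in self.points])
        rsd_max = max(p.rsd_pct for p in self.points)
        if np.ptp(y) == 0.0:
            warnings.warn(
                "all mean currents are equal; slope and r reported as 0",
                stacklevel=2,
            )
            slope, intercept, r = 0.0, float(y[0]), 0.0
        else:
            reg = stats.linregress(x, y)
            slope, intercept, r = float(reg.slope), float(reg.intercept), float(reg.rvalue)
        result = CalibrationResult(
            ion=self.ion,
            slope=slope,
            intercept=intercept,
            r=r,
            rsd_max=float(rsd_max),
            n_points=len(self.points),
            conc_range=(self.points[0].concentration, self.points[-1].concentration),
        )
        if sigma_blank is not None:
            result = replace(result, lod=lod(result, sigma_blank))
        return result


def fit_calibration(
    points: Iterable[CalibrationPoint], ion: str = "Cu", sigma_blank: Optional[float] = None
) -> CalibrationResult:
    """Fit the log-linear calibration; see :class:`IonCalibration`."""
    return IonCalibration(list(points), ion=ion).fit(sigma_blank=sigma_blank)


def lod(model: CalibrationResult, sigma_blank: float) -> float:
    """Detection limit 3*sigma_blank / slope.

    ``sigma_blank`` is the standard deviation of the peak current measured
    on blank samples (A); the slope is in A per decade, so the literal
    quotient is in the slope's x-units (see module docstring).
    """
    if sigma_blank < 0:
        raise InvalidInputError("sigma_blank must be >= 0")
    if model.slope <= 0:
        raise InvalidInputError("LOD requires a positive calibration slope")
    return 3.0 * sigma_blank / model.slope


def predict_concentration(model: CalibrationResult, i_peak: float) -> ConcentrationEstimate:
    """Invert the calibration line: C = 10**((i_peak - intercept) / slope).

    Estimates outside the calibrated concentration range are flagged as
    extrapolation rather than refused.
    """
    if model.slope == 0:
        raise InvalidInputError("cannot invert a calibration with zero slope")
    conc = float(10.0 ** ((i_peak - model.intercept) / model.slope))
    lo, hi = model.conc_range
    extrapolated = not (lo <= conc <= hi)
    return ConcentrationEstimate(concentration=conc, extrapolated=extrapolated)
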
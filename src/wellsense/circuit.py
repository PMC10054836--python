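"""Equivalent-circuit forward model of an epithelial monolayer.

The monolayer grown on a permeable Transwell support is represented as a
medium resistance in series with two parallel RC elements, one for the
apical and one for the basolateral face of the polarized epithelium:

    Z(omega) = R_media + R1 / (1 + j*omega*R1*C1) + R2 / (1 + j*omega*R2*C2)

All resistances are area-normalized (ohm*cm^2) and capacitances are in
uF/cm^2; the 1e-6 factor converting uF to F is applied internally, so the
element time constants are ``tau_i = R_i * C_i * 1e-6`` seconds.

Two barrier metrics summarize the circuit: the transepithelial electrical
resistance TEER = R1 + R2, and the total cell capacitance given by the
series combination 1/C = 1/C1 + 1/C2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidInputError",
    "CircuitParams",
    "FrequencyGrid",
    "ImpedanceSpectrum",
    "BarrierMetrics",
    "simulate_impedance",
    "barrier_metrics",
    "nyquist_coordinates",
]

#: conversion factor from uF/cm^2 to F/cm^2, used for time constants
UF_TO_F = 1e-6

#: instrument band used by the TEER measurements (Hz)
BAND_HZ = (10.0, 1e5)


class InvalidInputError(ValueError):
    """Raised when a physically invalid parameter or grid is supplied."""


def _require_positive_finite(**named: float) -> None:
    for name, value in named.items():
        if not np.isfinite(value) or value <= 0:
            raise InvalidInputError(
                f"{name} must be strictly positive and finite, got {value!r}"
            )


@dataclass(frozen=True)
class CircuitParams:
    """The five electrical parameters of the epithelial equivalent circuit.

    Parameters
    ----------
    r_media : float
        Series resistance of the culture medium, ohm*cm^2.
    r1, c1 : float
        Resistance (ohm*cm^2) and capacitance (uF/cm^2) of the RC element
        with the smaller time constant.
    r2, c2 : float
        Resistance and capacitance of the RC element with the larger time
        constant.

    Notes
    -----
    The two RC elements enter the model symmetrically, so their labels are
    a gauge choice.  The constructor enforces the canonical ordering
    ``tau1 <= tau2`` (``tau_i = r_i * c_i * 1e-6`` s) by swapping the
    element labels when necessary.
    """

    r_media: float
    r1: float
    c1: float
    r2: float
    c2: float

    def __post_init__(self) -> None:
        _require_positive_finite(
            r_media=self.r_media, r1=self.r1, c1=self.c1, r2=self.r2, c2=self.c2
        )
        if self.r1 * self.c1 > self.r2 * self.c2:
            r1, c1, r2, c2 = self.r2, self.c2, self.r1, self.c1
            object.__setattr__(self, "r1", r1)
            object.__setattr__(self, "c1", c1)
            object.__setattr__(self, "r2", r2)
            object.__setattr__(self, "c2", c2)

    @property
    def tau1(self) -> float:
        """Time constant of the first element, seconds."""
        return self.r1 * self.c1 * UF_TO_F

    @property
    def tau2(self) -> float:
        """Time constant of the second element, seconds."""
        return self.r2 * self.c2 * UF_TO_F

    def as_array(self) -> np.ndarray:
        return np.array([self.r_media, self.r1, self.c1, self.r2, self.c2])

    @classmethod
    def from_array(cls, values: np.ndarray) -> "CircuitParams":
        r_media, r1, c1, r2, c2 = (float(v) for v in values)
        return cls(r_media, r1, c1, r2, c2)


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing grid of measurement frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise InvalidInputError("frequency grid must be a non-empty 1-D array")
        if not np.all(np.isfinite(f)) or np.any(f <= 0):
            raise InvalidInputError("frequencies must be finite and > 0")
        if np.any(np.diff(f) <= 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)

    @classmethod
    def default_band(cls, n: int = 50, fmin: float = BAND_HZ[0], fmax: float = BAND_HZ[1]) -> "FrequencyGrid":
        """Log-spaced grid over the instrument band (default 10 Hz - 100 kHz)."""
        return cls(np.logspace(np.log10(fmin), np.log10(fmax), n))

    @property
    def omega(self) -> np.ndarray:
        """Radial frequencies, rad/s."""
        return 2.0 * np.pi * self.frequencies

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance (ohm*cm^2) sampled on a frequency grid.

    Capacitive convention: a spectrum generated from :class:`CircuitParams`
    has ``Im(z) <= 0`` at every frequency.
    """

    grid: FrequencyGrid
    z: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=complex)
        if z.shape != self.grid.frequencies.shape:
            raise InvalidInputError(
                f"impedance array length {z.shape} does not match grid "
                f"{self.grid.frequencies.shape}"
            )
        if not np.all(np.isfinite(z)):
            raise InvalidInputError("impedance values must be finite")
        object.__setattr__(self, "z", z)

    def __len__(self) -> int:
        return len(self.grid)


@dataclass(frozen=True)
class BarrierMetrics:
    """Summary metrics of the fitted barrier.

    teer : transepithelial electrical resistance R1 + R2, ohm*cm^2
    c_cell : series combination of the two membrane capacitances, uF/cm^2
    """

    teer: float
    c_cell: float

    def __post_init__(self) -> None:
        _require_positive_finite(teer=self.teer, c_cell=self.c_cell)


def simulate_impedance(params: CircuitParams, grid: FrequencyGrid) -> ImpedanceSpectrum:
    """Evaluate the two-RC-element impedance model on a frequency grid.

    Pointwise, deterministic evaluation of

        Z = R_media + R1/(1 + j*w*R1*C1*1e-6) + R2/(1 + j*w*R2*C2*1e-6)

    with ``w = 2*pi*f``.
    """
    w = grid.omega
    z = (
        params.r_media
        + params.r1 / (1.0 + 1j * w * params.tau1)
        + params.r2 / (1.0 + 1j * w * params.tau2)
    )
    return ImpedanceSpectrum(grid=grid, z=z)


def barrier_metrics(params: CircuitParams) -> BarrierMetrics:
    """TEER and total cell capacitance of a parameter set.

    TEER is the DC resistance of the cell layer, R1 + R2; the capacitance
    is the series combination C1*C2/(C1 + C2) (the two membrane
    capacitances appear in series along the transepithelial current path).
    """
    return BarrierMetrics(
        teer=params.r1 + params.r2,
        c_cell=params.c1 * params.c2 / (params.c1 + params.c2),
    )


def nyquist_coordinates(spec: ImpedanceSpectrum) -> np.ndarray:
    """(Re Z, -Im Z) pairs for Nyquist plotting/export.

    Returns an (n, 2) array; the second column is nonnegative for
    model-generated spectra under the capacitive sign convention.
    """
    return np.column_stack([spec.z.real, -spec.z.imag])
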
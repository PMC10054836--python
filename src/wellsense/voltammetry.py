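"""Square-wave anodic stripping voltammetry (SWASV) traces and peak extraction.

A SWASV measurement deposits the analyte metal at the working electrode
during a cathodic pre-concentration step, then strips it with an anodic
square-wave scan; the resulting oxidation current peak is proportional to
the ion concentration at the electrode.  This module represents the scan
protocols, the recorded traces, and the baseline-corrected peak-height
extraction that all downstream quantification uses.

The pre-concentration and cleaning steps are carried as protocol metadata
only; the stripping electrochemistry itself is out of scope and the trace
model is purely phenomenological (a peak riding on a baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .circuit import InvalidInputError

__all__ = [
    "SWVProtocol",
    "Voltammogram",
    "PeakResult",
    "CU_PROTOCOL",
    "ZN_PROTOCOL",
    "DEFAULT_PEAK_WINDOWS",
    "potential_grid",
    "baseline_correct",
    "find_peak",
]


@dataclass(frozen=True)
class SWVProtocol:
    """Square-wave voltammetry protocol descriptor.

    Potentials in V vs the integrated Ag/AgCl reference, times in s,
    square-wave frequency in Hz.  ``precondition_*`` is the cathodic
    deposition step, ``cleaning_*`` the post-scan stripping of residual
    metal; both are metadata with no numeric effect on the trace model.
    """

    ion: str
    precondition_potential: float
    precondition_time: float
    e_start: float
    e_end: float
    step: float
    amplitude: float
    frequency: float
    cleaning_potential: float = 0.3
    cleaning_time: float = 90.0

    def __post_init__(self) -> None:
        if self.ion not in ("Cu", "Zn"):
            raise InvalidInputError(f"ion must be 'Cu' or 'Zn', got {self.ion!r}")
        if self.e_start == self.e_end:
            raise InvalidInputError("e_start and e_end must differ")
        if self.step <= 0:
            raise InvalidInputError("potential step must be > 0")
        if self.frequency <= 0:
            raise InvalidInputError("square-wave frequency must be > 0")

    @property
    def scan_range(self) -> float:
        return abs(self.e_end - self.e_start)


#: Copper protocol: deposition at -1.0 V for 30 s, anodic scan -0.2 -> +0.5 V,
#: 4 mV step, 20 mV pulse amplitude, 25 Hz; cleaning +0.3 V for 90 s.
CU_PROTOCOL = SWVProtocol(
    ion="Cu",
    precondition_potential=-1.0,
    precondition_time=30.0,
    e_start=-0.2,
    e_end=0.5,
    step=0.004,
    amplitude=0.020,
    frequency=25.0,
)

#: Zinc protocol: deposition at -1.2 V for 30 s, anodic scan -1.0 -> -0.2 V,
#: 8 mV step, 50 mV pulse amplitude, 50 Hz; cleaning +0.3 V for 90 s.
ZN_PROTOCOL = SWVProtocol(
    ion="Zn",
    precondition_potential=-1.2,
    precondition_time=30.0,
    e_start=-1.0,
    e_end=-0.2,
    step=0.008,
    amplitude=0.050,
    frequency=50.0,
)

PROTOCOL_PRESETS = {"Cu": CU_PROTOCOL, "Zn": ZN_PROTOCOL}

#: Potential windows where each ion's oxidation peak appears (V): copper
#: strips near +0.1 V, zinc between -0.5 and -0.4 V.
DEFAULT_PEAK_WINDOWS = {"Cu": (0.0, 0.2), "Zn": (-0.55, -0.35)}


def potential_grid(protocol: SWVProtocol) -> np.ndarray:
    """Arithmetic potential sequence of the scan, from e_start towards e_end.

    The grid starts exactly at ``e_start`` and advances in increments of
    ``step`` (signed by the scan direction) up to ``e_end`` inclusive when
    the range is an integer number of steps.
    """
    span = protocol.e_end - protocol.e_start
    if protocol.step > abs(span):
        raise InvalidInputError(
            f"potential step {protocol.step} V exceeds the scan range {abs(span)} V"
        )
    n_steps = int(np.floor(abs(span) / protocol.step + 1e-9))
    direction = np.sign(span)
    return protocol.e_start + direction * protocol.step * np.arange(n_steps + 1)


@dataclass(frozen=True)
class Voltammogram:
    """One SWV scan: current trace (A) on the protocol's potential grid (V)."""

    protocol: SWVProtocol
    potentials: np.ndarray = field(repr=False)
    currents: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.potentials, dtype=float)
        i = np.asarray(self.currents, dtype=float)
        if e.shape != i.shape or e.ndim != 1:
            raise InvalidInputError("potentials and currents must be equal-length 1-D arrays")
        expected = potential_grid(self.protocol)
        if e.shape != expected.shape or not np.allclose(e, expected, atol=1e-9):
            raise InvalidInputError("potential grid does not match the protocol")
        object.__setattr__(self, "potentials", e)
        object.__setattr__(self, "currents", i)

    def __len__(self) -> int:
        return len(self.potentials)


@dataclass(frozen=True)
class PeakResult:
    """Baseline-corrected oxidation peak of one trace.

    ``i_peak`` is the corrected peak height in A; ``found`` is False when
    no peak exceeds the prominence threshold (e.g. a blank compartment).
    """

    e_peak: float
    i_peak: float
    window: tuple
    found: bool


def baseline_correct(v: Voltammogram, flank_fraction: float = 0.15) -> Voltammogram:
    """Subtract a straight-line baseline fitted to the scan flanks.

    A line is least-squares fitted to the outer ``flank_fraction`` of
    points at each end of the scan (where no stripping peak is expected)
    and subtracted from the whole trace; the potential grid is unchanged.
    """
    if not 0.0 < flank_fraction <= 0.4:
        raise InvalidInputError("flank_fraction must be in (0, 0.4]")
    n = len(v)
    k = int(np.floor(n * flank_fraction))
    if 2 * k < 4:
        raise InvalidInputError(
            f"fewer than 4 flank points (got {2 * k}); increase flank_fraction"
        )
    idx = np.r_[0:k, n - k : n]
    coeffs = np.polyfit(v.potentials[idx], v.currents[idx], 1)
    baseline = np.polyval(coeffs, v.potentials)
    return Voltammogram(
        protocol=v.protocol, potentials=v.potentials, currents=v.currents - baseline
    )


def _flank_noise_sigma(v: Voltammogram, flank_fraction: float) -> float:
    """Robust noise estimate: scaled MAD of the flank residuals after the line fit."""
    n = len(v)
    k = int(np.floor(n * flank_fraction))
    idx = np.r_[0:k, n - k : n]
    coeffs = np.polyfit(v.potentials[idx], v.currents[idx], 1)
    resid = v.currents[idx] - np.polyval(coeffs, v.potentials[idx])
    return 1.4826 * float(np.median(np.abs(resid - np.median(resid))))


def find_peak(
    v: Voltammogram,
    window: Optional[tuple] = None,
    min_prominence: Optional[float] = None,
    flank_fraction: float = 0.15,
) -> PeakResult:
    """Locate the oxidation peak inside a potential window.

    The trace is baseline-corrected (linear flank fit), and the maximum
    corrected current inside ``window`` is taken as the peak.  The peak is
    reported as found only if its height exceeds ``min_prominence``
    (default: 3x the robust flank-noise estimate), so blank traces yield
    ``found=False``.

    Default windows: Cu [0.0, 0.2] V, Zn [-0.55, -0.35] V.
    """
    if window is None:
        window = DEFAULT_PEAK_WINDOWS[v.protocol.ion]
    lo, hi = min(window), max(window)
    e = v.potentials
    mask = (e >= lo) & (e <= hi)
    if not np.any(mask):
        raise InvalidInputError(
            f"peak window [{lo}, {hi}] V does not overlap the scan grid "
            f"[{e.min()}, {e.max()}] V"
        )
    corrected = baseline_correct(v, flank_fraction)
    if min_prominence is None:
        # tiny scale-relative floor keeps line-fit roundoff from registering
        # as a peak on blank traces
        scale = float(np.max(np.abs(v.currents), initial=0.0))
        min_prominence = 3.0 * _flank_noise_sigma(v, flank_fraction) + 1e-9 * scale

    in_window = corrected.currents[mask]
    idx_local = int(np.argmax(in_window))
    i_peak = float(in_window[idx_local])
    e_peak = float(e[mask][idx_local])
    found = i_peak > max(min_prominence, 0.0)
    return PeakResult(e_peak=e_peak, i_peak=i_peak, window=(lo, hi), found=found)
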
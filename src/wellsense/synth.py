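"""Synthetic instrument data with the statistical structure the pipeline assumes.

Every input the analysis consumes can be generated here: impedance spectra
from the two-RC barrier model plus instrument noise, SWASV traces as a
Gaussian oxidation peak on a linear baseline, replicate calibration sets
on a log-linear response line, and full apical/basolateral EGTA
time-course experiments.  All generators are pure functions of their
arguments and the seed: identical calls reproduce identical output
bit-for-bit.

Default presets encode the study conditions of a 21-day Caco-2 monolayer
challenged with the calcium chelator EGTA: barrier parameters whose sums
give TEER 746 -> 288 ohm*cm^2 and cell capacitance 1.8 uF/cm^2, and
fraction schedules giving apical peak-current decreases of 40 %/70 % (Cu)
and 45 %/54 % (Zn) at 1 h/2 h.  The R1/R2 split of the presets is a
synthetic choice (the two time constants are kept ~3x apart so both
semicircles are resolvable); only the sums are observationally anchored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .circuit import (
    CircuitParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    InvalidInputError,
    simulate_impedance,
)
from .voltammetry import PROTOCOL_PRESETS, SWVProtocol, Voltammogram, potential_grid

__all__ = [
    "NoiseModel",
    "EgtaSchedule",
    "TraceRecord",
    "PRE_EGTA_PARAMS",
    "POST_EGTA_PARAMS",
    "CU_LINE",
    "ZN_LINE",
    "CU_SCHEDULE",
    "ZN_SCHEDULE",
    "DEFAULT_PEAK_CENTERS",
    "gen_spectrum",
    "gen_voltammogram",
    "gen_calibration_set",
    "gen_egta_experiment",
    "gen_teer_timecourse",
]

_NOISE_KINDS = ("none", "proportional_gaussian", "additive_gaussian")


@dataclass(frozen=True)
class NoiseModel:
    """Seeded instrument-noise descriptor.

    kind : {"none", "proportional_gaussian", "additive_gaussian"}
        Proportional noise multiplies each sample by (1 + level*N(0,1));
        additive noise adds level*N(0,1) in the sample's own units.
    level : float
        CV (dimensionless) for proportional, absolute SD for additive.
    seed : int
        Seed for the generator's private RNG stream.
    """

    kind: str = "none"
    level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _NOISE_KINDS:
            raise InvalidInputError(f"noise kind must be one of {_NOISE_KINDS}")
        if self.level < 0:
            raise InvalidInputError("noise level must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Perturb an array, drawing from ``rng`` (draws consumed even for level 0)."""
        if self.kind == "none":
            return np.asarray(values, dtype=float).copy()
        draw = rng.standard_normal(np.shape(values))
        if self.kind == "proportional_gaussian":
            return values * (1.0 + self.level * draw)
        return values + self.level * draw


NO_NOISE = NoiseModel()

#: barrier presets: sums give TEER 746 / 288 ohm*cm^2 and C_cell 1.8 uF/cm^2;
#: the element split is synthetic (time constants separated ~3x)
PRE_EGTA_PARAMS = CircuitParams(r_media=20.0, r1=300.0, c1=2.4, r2=446.0, c2=7.2)
POST_EGTA_PARAMS = CircuitParams(r_media=20.0, r1=116.0, c1=2.4, r2=172.0, c2=7.2)

#: calibration response lines, peak current (A) = slope*log10(C/M) + intercept
CU_LINE = {"slope": 1.64e-7, "intercept": 1.97e-6}
ZN_LINE = {"slope": 5.36e-7, "intercept": 6.07e-6}

#: oxidation peak positions on the anodic scan, V
DEFAULT_PEAK_CENTERS = {"Cu": 0.1, "Zn": -0.45}

#: default Gaussian peak width (V)
DEFAULT_PEAK_WIDTH = 0.030


@dataclass(frozen=True)
class EgtaSchedule:
    """Fractional time-course of an EGTA barrier-disruption experiment.

    ``apical_fractions[i]`` is the fraction of the T0 apical peak current
    remaining at ``timepoints[i]``; ``basolateral_fractions[i]`` the
    fraction of the apical T0 signal appearing basolaterally.  T0 is pinned
    to (1, 0): full apical dose, no basolateral peak.
    """

    timepoints: tuple
    apical_fractions: tuple
    basolateral_fractions: tuple

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.timepoints)
        a = tuple(float(x) for x in self.apical_fractions)
        b = tuple(float(x) for x in self.basolateral_fractions)
        if not (len(t) == len(a) == len(b)):
            raise InvalidInputError("schedule arrays must have equal lengths")
        if any(not 0.0 <= x <= 1.0 for x in a + b):
            raise InvalidInputError("fractions must lie in [0, 1]")
        if a[0] != 1.0 or b[0] != 0.0:
            raise InvalidInputError("T0 must have apical fraction 1 and basolateral fraction 0")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "apical_fractions", a)
        object.__setattr__(self, "basolateral_fractions", b)


#: apical fractions encode the observed percent decreases (Cu 40/70 %,
#: Zn 45/54 % at 1 h/2 h); basolateral fractions are the mass-conserving
#: complements (the basolateral rise is only observed qualitatively)
CU_SCHEDULE = EgtaSchedule((0.0, 1.0, 2.0), (1.0, 0.60, 0.30), (0.0, 0.40, 0.70))
ZN_SCHEDULE = EgtaSchedule((0.0, 1.0, 2.0), (1.0, 0.55, 0.46), (0.0, 0.45, 0.54))


def gen_spectrum(
    params: CircuitParams,
    grid: Optional[FrequencyGrid] = None,
    noise: NoiseModel = NO_NOISE,
) -> ImpedanceSpectrum:
    """Forward-model spectrum with noise applied independently to Re and Im."""
    if grid is None:
        grid = FrequencyGrid.default_band()
    clean = simulate_impedance(params, grid)
    rng = noise.rng()
    re = noise.apply(clean.z.real, rng)
    im = noise.apply(clean.z.imag, rng)
    return ImpedanceSpectrum(grid=grid, z=re + 1j * im)


def gen_voltammogram(
    protocol: SWVProtocol,
    peak_center: Optional[float] = None,
    peak_height: float = 1e-6,
    peak_width: float = DEFAULT_PEAK_WIDTH,
    baseline: tuple = (0.0, 0.0),
    noise: NoiseModel = NO_NOISE,
) -> Voltammogram:
    """Phenomenological SWASV trace: Gaussian peak + linear baseline + noise.

    ``baseline`` is (intercept A, slope A/V); ``peak_height`` of 0 yields a
    pure baseline (a blank compartment).
    """
    if peak_center is None:
        peak_center = DEFAULT_PEAK_CENTERS[protocol.ion]
    if peak_width <= 2.0 * protocol.step:
        raise InvalidInputError(
            f"peak width {peak_width} V must exceed twice the potential step"
        )
    e = potential_grid(protocol)
    lo, hi = min(e[0], e[-1]), max(e[0], e[-1])
    if peak_height != 0.0 and not lo <= peak_center <= hi:
        raise InvalidInputError(
            f"peak center {peak_center} V outside the scan range [{lo}, {hi}] V"
        )
    intercept, slope = baseline
    current = (
        intercept
        + slope * e
        + peak_height * np.exp(-0.5 * ((e - peak_center) / peak_width) ** 2)
    )
    current = noise.apply(current, noise.rng())
    return Voltammogram(protocol=protocol, potentials=e, currents=current)


def gen_calibration_set(
    ion: str = "Cu",
    slope: Optional[float] = None,
    intercept: Optional[float] = None,
    concentrations: Sequence[float] = (1e-11, 1e-10, 1e-9, 1e-7, 1e-6),
    replicates: int = 3,
    noise: NoiseModel = NO_NOISE,
    as_traces: bool = False,
):
    """Replicate calibration measurements on a log-linear response line.

    Peak heights follow slope*log10(C) + intercept (defaults: the ion's
    characterized line), perturbed per replicate by ``noise``; heights that
    come out nonpositive are clipped to 0 with a warning.

    Returns a tidy DataFrame (``concentration_m``, ``replicate_id``,
    ``peak_current_a``), or, with ``as_traces=True``, a list of
    ``(concentration, replicate_id, Voltammogram)`` so the full
    peak-extraction -> regression pipeline can be exercised.
    """
    line = CU_LINE if ion == "Cu" else ZN_LINE
    slope = line["slope"] if slope is None else slope
    intercept = line["intercept"] if intercept is None else intercept
    concs = np.asarray(concentrations, dtype=float)
    if np.any(concs <= 0):
        raise InvalidInputError("concentrations must be > 0")
    rng = noise.rng()
    rows = []
    for conc in concs:
        ideal = slope * np.log10(conc) + intercept
        heights = noise.apply(np.full(replicates, ideal), rng)
        if np.any(heights <= 0):
            warnings.warn(
                f"nonpositive implied peak height at {conc:g} M clipped to 0",
                stacklevel=2,
            )
            heights = np.clip(heights, 0.0, None)
        for rep, h in enumerate(heights):
            rows.append((float(conc), rep, float(h)))

    if not as_traces:
        return pd.DataFrame(rows, columns=["concentration_m", "replicate_id", "peak_current_a"])

    protocol = PROTOCOL_PRESETS[ion]
    traces = []
    for conc, rep, h in rows:
        traces.append(
            (conc, rep, gen_voltammogram(protocol, peak_height=h, noise=NO_NOISE))
        )
    return traces


@dataclass(frozen=True)
class TraceRecord:
    """One generated trace of an EGTA experiment manifest."""

    timepoint_h: float
    compartment: str  # "apical" | "basolateral"
    voltammogram: Voltammogram = field(repr=False)


def gen_egta_experiment(
    schedule: EgtaSchedule,
    protocol: SWVProtocol,
    t0_height: float = 1e-6,
    noise: NoiseModel = NO_NOISE,
) -> list:
    """Apical + basolateral trace set following an EGTA fraction schedule.

    Apical peak heights are ``t0_height * apical_fractions``, basolateral
    ``t0_height * basolateral_fractions`` (zero height = flat baseline).
    Trace-level noise streams are spawned deterministically from the
    noise seed.
    """
    if t0_height <= 0:
        raise InvalidInputError("t0_height must be > 0")
    seeds = np.random.SeedSequence(noise.seed).generate_state(
        2 * len(schedule.timepoints)
    ) % (2**31)
    records = []
    k = 0
    for t, frac_a, frac_b in zip(
        schedule.timepoints, schedule.apical_fractions, schedule.basolateral_fractions
    ):
        for compartment, frac in (("apical", frac_a), ("basolateral", frac_b)):
            trace_noise = NoiseModel(noise.kind, noise.level, int(seeds[k]))
            k += 1
            v = gen_voltammogram(
                protocol, peak_height=t0_height * frac, noise=trace_noise
            )
            records.append(TraceRecord(timepoint_h=t, compartment=compartment, voltammogram=v))
    return records


def gen_teer_timecourse(
    pre: CircuitParams = PRE_EGTA_PARAMS,
    post: CircuitParams = POST_EGTA_PARAMS,
    grid: Optional[FrequencyGrid] = None,
    noise: NoiseModel = NO_NOISE,
) -> tuple:
    """Pair of spectra for the pre/post-EGTA barrier conditions."""
    seeds = np.random.SeedSequence(noise.seed).generate_state(2) % (2**31)
    spec_pre = gen_spectrum(pre, grid, NoiseModel(noise.kind, noise.level, int(seeds[0])))
    spec_post = gen_spectrum(post, grid, NoiseModel(noise.kind, noise.level, int(seeds[1])))
    return spec_pre, spec_post
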
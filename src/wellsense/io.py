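"""CSV dialects, run configuration and replicate aggregation.

Spectrum files carry one row per frequency with header
``frequency_hz,z_real_ohm_cm2,z_imag_ohm_cm2`` (area-normalized) or
``frequency_hz,z_real_ohm,z_imag_ohm`` (raw instrument ohms, converted at
ingest with the membrane area).  Voltammogram files carry
``potential_v,current_a`` preceded by ``# key=value`` comment lines
holding the scan protocol.  Manifests map timepoints and compartments to
trace files.  All writers round-trip losslessly through the readers.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .circuit import FrequencyGrid, ImpedanceSpectrum, InvalidInputError
from .voltammetry import SWVProtocol, Voltammogram

__all__ = [
    "ParseError",
    "RunConfig",
    "ReplicateSummary",
    "DEFAULT_MEMBRANE_AREA_CM2",
    "read_spectrum",
    "write_spectrum",
    "read_voltammogram",
    "write_voltammogram",
    "read_manifest",
    "aggregate_replicates",
]

#: nominal growth area of a 6-well-plate Transwell insert, cm^2
DEFAULT_MEMBRANE_AREA_CM2 = 4.67

SPECTRUM_HEADER = ["frequency_hz", "z_real_ohm_cm2", "z_imag_ohm_cm2"]
SPECTRUM_RAW_HEADER = ["frequency_hz", "z_real_ohm", "z_imag_ohm"]
VOLTAMMOGRAM_HEADER = ["potential_v", "current_a"]
MANIFEST_HEADER = ["timepoint_h", "compartment", "trace_file"]


class ParseError(ValueError):
    """Malformed input file; message names the offending file/line."""


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration shared by the CLI subcommands."""

    membrane_area_cm2: float = DEFAULT_MEMBRANE_AREA_CM2
    ion: str = "Cu"
    protocol_overrides: dict = dataclasses.field(default_factory=dict)
    fit_options: dict = dataclasses.field(default_factory=dict)
    paths: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.membrane_area_cm2 <= 0:
            raise InvalidInputError("membrane_area_cm2 must be > 0")
        if self.ion not in ("Cu", "Zn"):
            raise InvalidInputError(f"ion must be 'Cu' or 'Zn', got {self.ion!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ParseError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParseError(
                f"{path}: unknown config keys {sorted(unknown)}; "
                f"allowed keys are {sorted(known)}"
            )
        return cls(**raw)


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean +/- SD over replicate measurements (sample SD, n-1 denominator)."""

    mean: float
    sd: float
    n: int

    def __str__(self) -> str:
        return f"{self.mean:g} +/- {self.sd:g} (n={self.n})"


def aggregate_replicates(values: Iterable[float]) -> ReplicateSummary:
    """Arithmetic mean and sample SD of replicate values; SD is 0 for n=1."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise InvalidInputError("cannot aggregate an empty replicate list")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    return ReplicateSummary(mean=float(np.mean(arr)), sd=sd, n=int(arr.size))


def _read_table(path, expected_columns, comment: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, comment=comment)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if list(df.columns) != expected_columns:
        raise ParseError(
            f"{path}: expected header {','.join(expected_columns)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    for col in expected_columns:
        if col == "compartment" or col == "trace_file":
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad) or df[col].isna().any():
            line = int((bad if len(bad) else df.index[df[col].isna()])[0]) + 2
            raise ParseError(f"{path}: non-numeric or missing value in '{col}' at line {line}")
        df[col] = numeric
    return df


def write_spectrum(spec: ImpedanceSpectrum, path) -> None:
    df = pd.DataFrame(
        {
            "frequency_hz": spec.grid.frequencies,
            "z_real_ohm_cm2": spec.z.real,
            "z_imag_ohm_cm2": spec.z.imag,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_spectrum(path, area_cm2: Optional[float] = None) -> ImpedanceSpectrum:
    """Read a spectrum CSV; raw-ohm files require ``area_cm2`` for conversion.

    Rows are sorted by frequency on ingest (with a warning if they arrived
    shuffled); duplicate frequencies are a parse error.
    """
    path = Path(path)
    try:
        header = pd.read_csv(path, nrows=0).columns.tolist()
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if header == SPECTRUM_RAW_HEADER:
        if area_cm2 is None or area_cm2 <= 0:
            raise ParseError(
                f"{path}: raw-ohm spectrum requires a positive membrane area for "
                "area normalization"
            )
        df = _read_table(path, SPECTRUM_RAW_HEADER)
        scale = float(area_cm2)
        re, im = df["z_real_ohm"] * scale, df["z_imag_ohm"] * scale
    else:
        df = _read_table(path, SPECTRUM_HEADER)
        re, im = df["z_real_ohm_cm2"], df["z_imag_ohm_cm2"]

    f = df["frequency_hz"].to_numpy(dtype=float)
    z = re.to_numpy(dtype=float) + 1j * im.to_numpy(dtype=float)
    order = np.argsort(f, kind="stable")
    if not np.array_equal(order, np.arange(len(f))):
        warnings.warn(f"{path}: frequency rows were not sorted; sorting on ingest", stacklevel=2)
        f, z = f[order], z[order]
    if np.any(np.diff(f) == 0):
        raise ParseError(f"{path}: duplicate frequency rows")
    try:
        return ImpedanceSpectrum(grid=FrequencyGrid(f), z=z)
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


_PROTOCOL_FIELDS = [f.name for f in dataclasses.fields(SWVProtocol)]


def write_voltammogram(v: Voltammogram, path) -> None:
    """Trace CSV with the protocol embedded as ``# key=value`` comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for name in _PROTOCOL_FIELDS:
            fh.write(f"# {name}={getattr(v.protocol, name)}\n")
        pd.DataFrame({"potential_v": v.potentials, "current_a": v.currents}).to_csv(
            fh, index=False, float_format="%.12g"
        )


def read_voltammogram(path, protocol: Optional[SWVProtocol] = None) -> Voltammogram:
    """Read a trace CSV; the protocol comes from ``#`` comment lines unless given."""
    path = Path(path)
    if protocol is None:
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if "=" in line:
                    key, _, value = line.lstrip("# ").strip().partition("=")
                    meta[key.strip()] = value.strip()
        missing = set(_PROTOCOL_FIELDS) - set(meta)
        if missing:
            raise ParseError(
                f"{path}: no protocol given and comment header lacks {sorted(missing)}"
            )
        kwargs = {
            k: (meta[k] if k == "ion" else float(meta[k])) for k in _PROTOCOL_FIELDS
        }
        try:
            protocol = SWVProtocol(**kwargs)
        except (InvalidInputError, ValueError) as exc:
            raise ParseError(f"{path}: invalid embedded protocol: {exc}") from exc
    df = _read_table(path, VOLTAMMOGRAM_HEADER, comment="#")
    try:
        return Voltammogram(
            protocol=protocol,
            potentials=df["potential_v"].to_numpy(dtype=float),
            currents=df["current_a"].to_numpy(dtype=float),
        )
    except InvalidInputError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_manifest(path) -> pd.DataFrame:
    """Manifest CSV mapping ``timepoint_h,compartment,trace_file``."""
    df = _read_table(path, MANIFEST_HEADER)
    bad = ~df["compartment"].isin(["apical", "basolateral"])
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ParseError(
            f"{path}: compartment must be 'apical' or 'basolateral' at line {line}"
        )
    return df
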
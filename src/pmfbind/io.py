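"""Plain-text file formats: timeseries, window metadata, PMF tables, config.

All files are whitespace-delimited text.  Lines starting with ``#`` are
comments; lines starting with ``#!`` are *directives* (``#! key: value``)
that carry machine-read declarations.  Writers declare a row count
(``#! n_rows``) which readers verify, so silently truncated files are
rejected.

The window metadata dialect is one window per line — ``path center
spring`` — preceded by mandatory unit declarations::

    #! energy_unit: kT          (or kcal/mol, with #! temperature: <K>)
    #! bias_convention: half-k  (or full-k)

Spring constants are converted on load to the internal dialect, kT/Å²
with E = ½ k (z − z0)².  Declaring the dialect is mandatory — the ½k-vs-k
ambiguity is a classic silent-error source across umbrella-sampling tools,
so this reader refuses to guess.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .potentials import UmbrellaWindow
from .simulate import TimeSeries
from .wham import PMFProfile

__all__ = [
    "FormatError",
    "WindowMetadata",
    "read_timeseries",
    "write_timeseries",
    "read_metadata",
    "write_metadata",
    "read_pmf",
    "write_pmf",
    "load_config",
]

logger = logging.getLogger(__name__)

# kB in kcal/(mol K); with T it converts kcal/mol <-> kT
KB_KCAL_PER_MOL_K = 0.0019872041

_ENERGY_UNITS = ("kT", "kcal/mol")
_BIAS_CONVENTIONS = ("half-k", "full-k")


class FormatError(ValueError):
    """A text input file does not conform to the expected dialect."""


@dataclass
class WindowMetadata:
    """Declared (unconverted) window records plus the file's unit dialect."""

    paths: list[str]
    centers: list[float]
    springs: list[float]  # as declared in the file
    energy_unit: str
    bias_convention: str
    temperature: Optional[float] = None  # K, required for kcal/mol

    def internal_windows(self) -> list[UmbrellaWindow]:
        """Windows with springs in kT/Å² under the ½k convention."""
        factor = 1.0
        if self.energy_unit == "kcal/mol":
            factor /= KB_KCAL_PER_MOL_K * self.temperature
        if self.bias_convention == "full-k":
            # E = k Δ² == ½ (2k) Δ²
            factor *= 2.0
        return [
            UmbrellaWindow(center=c, spring=k * factor, label=Path(p).stem)
            for p, c, k in zip(self.paths, self.centers, self.springs)
        ]


# -- low-level line handling ------------------------------------------------

def _scan(path: Path):
    """Yield (lineno, directives-so-far, tokens) for data lines."""
    directives: dict[str, str] = {}
    data = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                body = line[2:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    directives[key.strip()] = val.strip()
                continue
            if line.startswith("#"):
                continue
            data.append((lineno, line.split()))
    return directives, data


def _check_row_count(directives: dict, n_rows: int, path: Path) -> None:
    declared = directives.get("n_rows")
    if declared is not None and int(declared) != n_rows:
        raise FormatError(
            f"{path}: declares {declared} rows but contains {n_rows} "
            "(file truncated or corrupted?)"
        )


# -- timeseries -------------------------------------------------------------

def read_timeseries(path) -> TimeSeries:
    """Read a two-column (time_ps, z_Å) timeseries file.

    Extra columns are ignored with a logged notice.  A file with no
    parseable data rows, or any malformed data line, is a
    :class:`FormatError` carrying the offending line number.
    """
    path = Path(path)
    directives, data = _scan(path)
    if not data:
        raise FormatError(f"{path}: no parseable data rows")

    times, values = [], []
    extra_cols = False
    for lineno, tokens in data:
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'time value', got {len(tokens)} column(s)")
        try:
            t, v = float(tokens[0]), float(tokens[1])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric time/value") from None
        if len(tokens) > 2:
            extra_cols = True
        times.append(t)
        values.append(v)
    if extra_cols:
        logger.info("%s: extra columns beyond (time, value) ignored", path)
    _check_row_count(directives, len(values), path)

    times = np.asarray(times)
    if "save_interval_ps" in directives:
        interval = float(directives["save_interval_ps"])
    else:
        interval = float(times[1] - times[0]) if times.size > 1 else 1.0
    return TimeSeries(values=np.asarray(values), save_interval_ps=interval,
                      window=None, seed=None, n_equil=0, label=path.stem)


def write_timeseries(path, ts: TimeSeries) -> None:
    """Write (time_ps, z_Å) rows with declarations the reader verifies."""
    path = Path(path)
    t = np.arange(len(ts)) * ts.save_interval_ps
    with open(path, "w") as fh:
        fh.write("# umbrella-sampling reaction-coordinate timeseries\n")
        fh.write(f"#! n_rows: {len(ts)}\n")
        fh.write(f"#! save_interval_ps: {ts.save_interval_ps!r}\n")
        if ts.seed is not None:
            fh.write(f"#! seed: {ts.seed}\n")
        if ts.n_equil:
            fh.write(f"#! n_equil: {ts.n_equil}\n")
        # repr gives the shortest digit string that round-trips the float64
        for ti, zi in zip(t, ts.values):
            fh.write(f"{ti:.6f} {float(zi)!r}\n")


# -- window metadata --------------------------------------------------------

def read_metadata(path) -> tuple[WindowMetadata, list[TimeSeries]]:
    """Read a window metadata file and load every referenced timeseries.

    Paths are resolved relative to the metadata file.  The energy-unit and
    bias-convention declarations are mandatory.
    """
    path = Path(path)
    directives, data = _scan(path)

    unit = directives.get("energy_unit")
    if unit not in _ENERGY_UNITS:
        raise FormatError(
            f"{path}: mandatory '#! energy_unit:' declaration missing or "
            f"invalid (got {unit!r}; expected one of {_ENERGY_UNITS})"
        )
    conv = directives.get("bias_convention")
    if conv not in _BIAS_CONVENTIONS:
        raise FormatError(
            f"{path}: mandatory '#! bias_convention:' declaration missing or "
            f"invalid (got {conv!r}; expected one of {_BIAS_CONVENTIONS})"
        )
    temperature = directives.get("temperature")
    temperature = float(temperature) if temperature is not None else None
    if unit == "kcal/mol" and temperature is None:
        raise FormatError(f"{path}: kcal/mol energies need '#! temperature:' (K)")

    if not data:
        raise FormatError(f"{path}: no window records")

    paths, centers, springs = [], [], []
    for lineno, tokens in data:
        if len(tokens) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'path center spring'")
        try:
            center, spring = float(tokens[1]), float(tokens[2])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric center/spring") from None
        if tokens[0] in paths:
            raise FormatError(f"{path}:{lineno}: duplicate timeseries path {tokens[0]!r}")
        paths.append(tokens[0])
        centers.append(center)
        springs.append(spring)
    _check_row_count(directives, len(paths), path)

    meta = WindowMetadata(paths=paths, centers=centers, springs=springs,
                          energy_unit=unit, bias_convention=conv,
                          temperature=temperature)

    series = []
    for p, w in zip(paths, meta.internal_windows()):
        full = (path.parent / p).resolve()
        if not full.exists():
            raise FormatError(f"{path}: referenced timeseries {p!r} not found at {full}")
        ts = read_timeseries(full)
        ts.window = w
        series.append(ts)
    return meta, series


def write_metadata(path, series: Sequence[TimeSeries],
                   filenames: Sequence[str]) -> None:
    """Write internal-dialect (kT, ½k) metadata for simulated windows."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# umbrella window metadata: path center(Å) spring\n")
        fh.write("#! energy_unit: kT\n")
        fh.write("#! bias_convention: half-k\n")
        fh.write(f"#! n_rows: {len(series)}\n")
        for name, ts in zip(filenames, series):
            if ts.window is None:
                raise ValueError(f"series {ts.label!r} has no window; cannot write metadata")
            fh.write(f"{name} {ts.window.center:.10g} {ts.window.spring:.10g}\n")


# -- PMF tables -------------------------------------------------------------

def read_pmf(path) -> PMFProfile:
    """Read a (z_Å, W_kT[, σ_kT]) PMF table; 'inf' marks empty bins."""
    path = Path(path)
    directives, data = _scan(path)
    if not data:
        raise FormatError(f"{path}: no PMF rows")
    z, w, s = [], [], []
    has_sigma = len(data[0][1]) >= 3
    for lineno, tokens in data:
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'z W [sigma]'")
        try:
            z.append(float(tokens[0]))
            w.append(float(tokens[1]))
            if has_sigma:
                s.append(float(tokens[2]))
        except (ValueError, IndexError):
            raise FormatError(f"{path}:{lineno}: malformed PMF row") from None
    _check_row_count(directives, len(z), path)
    return PMFProfile(
        z=np.asarray(z), w=np.asarray(w),
        sigma=np.asarray(s) if has_sigma else None,
        convention=directives.get("zero_convention", "none"),
    )


def write_pmf(path, profile: PMFProfile) -> None:
    """Write a PMF table in the dialect :func:`read_pmf` parses."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# PMF: z(Å) W(kT)" + (" sigma(kT)\n" if profile.sigma is not None else "\n"))
        fh.write(f"#! n_rows: {profile.z.size}\n")
        fh.write(f"#! zero_convention: {profile.convention}\n")
        for j in range(profile.z.size):
            row = f"{float(profile.z[j])!r} {float(profile.w[j])!r}"
            if profile.sigma is not None:
                row += f" {float(profile.sigma[j])!r}"
            fh.write(row + "\n")


# -- config -----------------------------------------------------------------

def load_config(path) -> dict:
    """Load a structured (YAML) configuration file into a dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config root must be a mapping")
    return cfg
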
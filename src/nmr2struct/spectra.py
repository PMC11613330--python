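"""Spectral preprocessing: ^1H interpolation + normalization, ^13C binning, I/O.

The ^1H pathway follows a minimal-preprocessing philosophy: the raw
acquisition (nominally 32768 points) is linearly interpolated onto a fixed
grid of 28000 values covering −2 to 12 ppm at 0.0005 ppm resolution, then
normalized to [0, 1] by dividing by the highest peak intensity.  ^13C input
is a peak list (decoupled spectra carry little lineshape information) and
is reduced to an 80-bit indicator over uniform bins spanning 3.42 to
231.3 ppm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "GridConfig",
    "BinConfig",
    "RawSpectrum1H",
    "PeakList13C",
    "SpectrumParseError",
    "NormalizationError",
    "DEFAULT_GRID",
    "DEFAULT_BINS",
    "preprocess_1h",
    "normalize_max",
    "bin_13c",
    "read_spectrum",
    "write_csv_1h",
    "write_csv_13c",
    "write_jcamp",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; carries the line number."""


class NormalizationError(ValueError):
    """Raised when a spectrum has no positive intensity to normalize by."""


@dataclass(frozen=True)
class GridConfig:
    """Uniform ppm grid for processed ^1H spectra.

    The default covers [−2, 12) ppm half-open: 28000 points at step 0.0005
    starting at −2.0, so the last grid value is 11.9995 ppm.
    """

    start: float = -2.0
    step: float = 0.0005
    count: int = 28000

    @property
    def shifts(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.count)


@dataclass(frozen=True)
class BinConfig:
    """Uniform ^13C bins; default 80 bins over [3.42, 231.3] ppm."""

    lo: float = 3.42
    hi: float = 231.3
    count: int = 80

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("BinConfig requires lo < hi")
        if self.count < 1:
            raise ValueError("BinConfig requires count >= 1")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.count


DEFAULT_GRID = GridConfig()
DEFAULT_BINS = BinConfig()


@dataclass(frozen=True)
class RawSpectrum1H:
    """A raw 1D ^1H spectrum: ppm axis and matching non-negative intensities."""

    shifts_ppm: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        shifts = np.asarray(self.shifts_ppm, dtype=np.float64)
        intens = np.asarray(self.intensities, dtype=np.float64)
        if shifts.ndim != 1 or shifts.shape != intens.shape:
            raise ValueError("shifts and intensities must be equal-length 1D vectors")
        if shifts.size < 2:
            raise ValueError("need at least two points")
        diffs = np.diff(shifts)
        if np.all(diffs < 0):
            # conventional NMR display order (high to low ppm): store ascending
            shifts, intens = shifts[::-1], intens[::-1]
        elif not np.all(diffs > 0):
            raise ValueError("shift axis must be strictly monotone")
        object.__setattr__(self, "shifts_ppm", shifts)
        object.__setattr__(self, "intensities", intens)


@dataclass(frozen=True)
class PeakList13C:
    """^13C chemical shifts in ppm (possibly empty)."""

    shifts_ppm: np.ndarray

    def __post_init__(self):
        shifts = np.asarray(self.shifts_ppm, dtype=np.float64).ravel()
        if shifts.size and not np.all(np.isfinite(shifts)):
            raise ValueError("13C shifts must be finite")
        object.__setattr__(self, "shifts_ppm", shifts)


def normalize_max(intensities: np.ndarray) -> np.ndarray:
    """Divide by the highest peak so the maximum value is exactly 1."""
    x = np.asarray(intensities, dtype=np.float64)
    peak = x.max() if x.size else 0.0
    if not peak > 0:
        raise NormalizationError("spectrum has no positive intensity")
    return x / peak


def preprocess_1h(raw: RawSpectrum1H, grid: GridConfig = DEFAULT_GRID) -> np.ndarray:
    """Interpolate a raw spectrum onto the processed grid and normalize to [0, 1].

    Linear interpolation; the spectrum is taken as zero outside the raw span.
    Raises :class:`NormalizationError` for an all-zero input.
    """
    out = np.interp(grid.shifts, raw.shifts_ppm, raw.intensities, left=0.0, right=0.0)
    return normalize_max(out)


def bin_13c(peaks: PeakList13C, binning: BinConfig = DEFAULT_BINS) -> np.ndarray:
    """Indicator vector: bit j is set iff some peak falls in bin j.

    Bins are uniform, left-closed; the final bin is right-closed so the upper
    range limit lands in bin ``count``.  Out-of-range shifts are clamped to
    the end bins rather than dropped.
    """
    bits = np.zeros(binning.count, dtype=np.int8)
    shifts = peaks.shifts_ppm
    if shifts.size == 0:
        return bits
    idx = np.floor((shifts - binning.lo) / binning.width).astype(np.int64)
    idx = np.clip(idx, 0, binning.count - 1)
    bits[idx] = 1
    return bits


# --- file I/O ---------------------------------------------------------------


def write_csv_1h(path: str | Path, raw: RawSpectrum1H) -> None:
    """Two-column (ppm, intensity) CSV."""
    data = np.column_stack([raw.shifts_ppm, raw.intensities])
    np.savetxt(path, data, delimiter=",", fmt="%.10g")


def write_csv_13c(path: str | Path, peaks: PeakList13C) -> None:
    """One-column (ppm) CSV; writes an empty file for an empty peak list."""
    np.savetxt(path, peaks.shifts_ppm, fmt="%.10g")


def write_jcamp(path: str | Path, raw: RawSpectrum1H, title: str = "spectrum") -> None:
    """Write a minimal JCAMP-DX file with a single ``(X++(Y..Y))`` XYDATA block."""
    shifts, intens = raw.shifts_ppm, raw.intensities
    lines = [
        "##TITLE=" + title,
        "##JCAMP-DX=5.01",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY",
        f"##NPOINTS={shifts.size}",
        f"##FIRSTX={shifts[0]:.10g}",
        f"##LASTX={shifts[-1]:.10g}",
        "##XFACTOR=1",
        "##YFACTOR=1",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, intens.size, 6):
        chunk = intens[i : i + 6]
        lines.append(f"{shifts[i]:.10g} " + " ".join(f"{y:.10g}" for y in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> RawSpectrum1H:
    fields: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            if line.startswith("##END"):
                break
            key, _, value = line[2:].partition("=")
            key = key.strip().upper()
            fields[key] = value.strip()
            in_data = key == "XYDATA"
            continue
        if in_data:
            parts = line.split()
            try:
                ys.extend(float(v) for v in parts[1:])  # first value is the X start
            except ValueError:
                raise SpectrumParseError(f"{path}:{lineno}: bad XYDATA line") from None
    try:
        npoints = int(fields["NPOINTS"])
        firstx = float(fields["FIRSTX"])
        lastx = float(fields["LASTX"])
        yfactor = float(fields.get("YFACTOR", "1"))
    except KeyError as e:
        raise SpectrumParseError(f"{path}: missing JCAMP field {e}") from None
    if len(ys) != npoints:
        raise SpectrumParseError(
            f"{path}: NPOINTS={npoints} but {len(ys)} Y values found"
        )
    shifts = np.linspace(firstx, lastx, npoints)
    return RawSpectrum1H(shifts, np.asarray(ys) * yfactor)


def _read_csv(path: Path) -> RawSpectrum1H | PeakList13C:
    rows: list[list[float]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            rows.append([float(v) for v in line.replace(",", " ").split()])
        except ValueError:
            raise SpectrumParseError(f"{path}:{lineno}: not numeric") from None
    if not rows:
        raise SpectrumParseError(f"{path}: no data rows")
    ncols = len(rows[0])
    if any(len(r) != ncols for r in rows):
        raise SpectrumParseError(f"{path}: inconsistent column count")
    arr = np.asarray(rows)
    if ncols == 1:
        return PeakList13C(arr[:, 0])
    if ncols == 2:
        return RawSpectrum1H(arr[:, 0], arr[:, 1])
    raise SpectrumParseError(f"{path}: expected 1 or 2 columns, found {ncols}")


def read_spectrum(path: str | Path, format: str | None = None) -> RawSpectrum1H | PeakList13C:
    """Read a spectrum file.

    ``format`` is ``"jcamp"`` or ``"csv"``; when omitted it is inferred from
    the suffix (``.jdx``/``.dx`` → JCAMP, otherwise CSV).  CSV files with two
    columns are ^1H spectra (ppm, intensity); one column is a ^13C peak list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcamp"} else "csv"
    if format == "jcamp":
        return _read_jcamp(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown spectrum format {format!r}")
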
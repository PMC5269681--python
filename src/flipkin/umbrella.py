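"""Data model and text I/O for umbrella-window time series.

A window holds samples of the flipping angle under a harmonic bias
``U_i(xi) = 1/2 * k_U * d(xi - xi_i)^2`` with ``d`` the periodic angular
distance in radians.  Series are stored unwrapped to the branch nearest the
window center, because the windows of a full flipping campaign span more than
half a period (-320 to +38 degrees at 2 degree spacing).

Text dialect: two whitespace-delimited columns (time in ps, angle in
degrees), '#' comments, scientific notation accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from flipkin.angles import unwrap_to_branch
from flipkin.constants import PERIOD_DEG


@dataclass
class AngleSeries:
    """Evenly sampled angle series: interval ``dt`` (ps), values in degrees."""

    dt: float
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.values.size < 2:
            raise ValueError("an angle series needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in angle series")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Sampled time span in ps."""
        return self.dt * (len(self) - 1)


@dataclass
class UmbrellaWindow:
    """One biased window: center (deg), force constant (kcal mol^-1 rad^-2),
    temperature (K), and its sampled series (deg, on the center's branch)."""

    center: float
    force_constant: float
    temperature: float
    series: AngleSeries

    def __post_init__(self) -> None:
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        spread = np.max(np.abs(self.series.values - self.center))
        if spread > 90.0:
            warnings.warn(
                f"window at {self.center} deg: samples stray {spread:.1f} deg "
                "from the center after unwrapping",
                stacklevel=2,
            )


@dataclass
class WindowSet:
    """Umbrella windows sorted by center on a declared period (360 deg)."""

    windows: list[UmbrellaWindow]
    period: float = PERIOD_DEG

    def __post_init__(self) -> None:
        self.windows = sorted(self.windows, key=lambda w: w.center)
        centers = self.centers
        if len(centers) > 1 and np.any(np.diff(centers) <= 0):
            raise ValueError("window centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    @property
    def centers(self) -> np.ndarray:
        return np.array([w.center for w in self.windows])

    @property
    def temperature(self) -> float:
        temps = {w.temperature for w in self.windows}
        if len(temps) != 1:
            raise ValueError(f"windows at mixed temperatures: {sorted(temps)}")
        return temps.pop()


@dataclass
class CoverageReport:
    """Result of :func:`validate_coverage` (report-only, never raises)."""

    n_windows: int
    spacing: float          # median spacing, deg (nan for a single window)
    span: float             # last center - first center, deg
    periodic_closure: bool  # span + spacing >= period
    gaps: list[tuple[float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def load_window_series(
    path: str | Path,
    center: float,
    force_constant: float,
    temperature: float,
    burn_in_fraction: float = 0.0,
) -> UmbrellaWindow:
    """Read a two-column (time ps, angle deg) text file into an
    :class:`UmbrellaWindow`.

    The sampling interval is inferred from the first two times and checked
    constant (tolerance 1e-6 relative); angles are unwrapped to the branch of
    the window center.  ``burn_in_fraction`` drops that initial fraction of
    the samples (equilibration discard; default keeps everything).
    """
    path = Path(path)
    times, angles = _read_two_columns(path)
    if np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0]) + 2
        raise ValueError(f"{path}: non-monotone time at data row {bad}")
    dt = float(times[1] - times[0])
    if not np.allclose(np.diff(times), dt, rtol=1e-6, atol=1e-6 * dt):
        raise ValueError(f"{path}: time column is not uniformly spaced")
    if not 0.0 <= burn_in_fraction < 1.0:
        raise ValueError("burn_in_fraction must be in [0, 1)")
    n_skip = int(round(burn_in_fraction * angles.size))
    values = unwrap_to_branch(angles[n_skip:], center)
    series = AngleSeries(dt=dt, values=values, label=str(path))
    return UmbrellaWindow(
        center=center, force_constant=force_constant,
        temperature=temperature, series=series,
    )


def _read_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    times, angles = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            parts = body.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                t, a = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric field"
                ) from exc
            times.append(t)
            angles.append(a)
    if len(times) < 2:
        raise ValueError(f"{path}: at least 2 samples required, got {len(times)}")
    return np.asarray(times), np.asarray(angles)


def write_window_series(path: str | Path, window: UmbrellaWindow) -> None:
    """Write a window series in the two-column text dialect (round-trips with
    :func:`load_window_series`)."""
    s = window.series
    with open(path, "w") as fh:
        fh.write(
            f"# umbrella window: center {window.center:.17g} deg, "
            f"k {window.force_constant:.17g} kcal/(mol rad^2), "
            f"T {window.temperature:.17g} K\n"
        )
        fh.write("# time[ps]  angle[deg]\n")
        for i, v in enumerate(s.values):
            fh.write(f"{i * s.dt:.17g} {v:.17g}\n")


def validate_coverage(window_set: WindowSet) -> CoverageReport:
    """Report window count, spacing, span, periodic closure and gaps.

    A full flipping campaign (e.g. 180 windows, -320..38 deg, 2 deg apart)
    has span 358 deg; span + spacing >= period means the window ladder closes
    around the circle.  Gaps wider than twice the median spacing are flagged.
    """
    if len(window_set) == 0:
        raise ValueError("empty window set")
    centers = window_set.centers
    notes: list[str] = []
    if len(centers) == 1:
        return CoverageReport(
            n_windows=1, spacing=float("nan"), span=0.0, periodic_closure=False,
            warnings=["single window: periodic closure not satisfied"],
        )
    diffs = np.diff(centers)
    spacing = float(np.median(diffs))
    span = float(centers[-1] - centers[0])
    closure = span + spacing >= window_set.period
    # a step of twice the (smallest) ladder spacing means a window is missing
    gap_ref = float(diffs.min())
    gaps = [
        (float(centers[i]), float(centers[i + 1]))
        for i in np.flatnonzero(diffs >= 2 * gap_ref - 1e-9)
    ]
    for lo, hi in gaps:
        notes.append(f"gap wider than 2x spacing between {lo} and {hi} deg")
    if not closure:
        notes.append("window span does not close the full period")
    return CoverageReport(
        n_windows=len(centers), spacing=spacing, span=span,
        periodic_closure=bool(closure), gaps=gaps, warnings=notes,
    )


def split_segments(window_set: WindowSet, n_segments: int) -> list[WindowSet]:
    """Split every window's series into ``n_segments`` contiguous equal-length
    slices (trailing remainder dropped); returns one :class:`WindowSet` per
    segment, e.g. five 2 ns segments from 10 ns windows for convergence
    checks."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    for w in window_set:
        if len(w.series) < n_segments * 2:
            raise ValueError(
                f"window at {w.center} deg too short for {n_segments} segments"
            )
    out = []
    for seg in range(n_segments):
        wins = []
        for w in window_set:
            seg_len = len(w.series) // n_segments
            sl = w.series.values[seg * seg_len:(seg + 1) * seg_len]
            wins.append(
                replace(
                    w,
                    series=AngleSeries(
                        dt=w.series.dt, values=sl.copy(),
                        label=f"{w.series.label}[seg{seg}]",
                    ),
                )
            )
        out.append(WindowSet(windows=wins, period=window_set.period))
    return out
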
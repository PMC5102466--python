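"""maxRatio extraction: ratio series, smoothing, spline interpolation.

For a reaction with normalized fluorescence S_1..S_N, the cycle-to-cycle
ratio series is

    R_n = S_n / S_{n-1} - 1,   n = 2..N,

a relative measure of per-cycle amplification efficiency.  A five-point
centered moving average is applied to R, and a natural cubic spline through
the smoothed values is evaluated on a 0.01-cycle grid.  The maximum of that
spline is the MR value of the reaction and its abscissa is the fractional
cycle number (FCN) — the maxRatio analogue of the quantitative cycle Cq.

All fluorescence values must be strictly positive (the ratio would otherwise
divide by zero or flip sign); violations raise before any arithmetic runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .plate_io import AmplificationCurve

__all__ = [
    "PositivityError",
    "RatioSeries",
    "MaxRatioResult",
    "compute_ratio_series",
    "smooth_ratio",
    "interpolate_extract",
    "compute_maxratio",
]

DEFAULT_WINDOW = 5
DEFAULT_GRID_STEP = 0.01


class PositivityError(ValueError):
    """A fluorescence value is zero or negative, making the ratio undefined."""


@dataclass
class RatioSeries:
    """Ratio values R_n indexed by integer cycles n = 2..N."""

    cycles: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.cycles.shape != self.values.shape or self.cycles.ndim != 1:
            raise ValueError("cycles and values must be 1-D and equal length")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class MaxRatioResult:
    """(MR, FCN) pair for one reaction.

    ``mr`` is dimensionless; ``fcn`` is a fractional cycle at the grid
    resolution; ``discrete_argmax`` is the integer cycle of the maximal
    smoothed ratio value (diagnostic only).
    """

    mr: float
    fcn: float
    discrete_argmax: int


def compute_ratio_series(
    curve: AmplificationCurve, floor_epsilon: float | None = None
) -> RatioSeries:
    """Compute R_n = rn[n]/rn[n-1] - 1 for cycles n = 2..N.

    Every rn value must be strictly positive; otherwise a
    :class:`PositivityError` naming the first offending cycle is raised.
    If ``floor_epsilon`` is given, non-positive values are clamped to it
    instead (off by default).
    """
    rn = np.asarray(curve.rn, dtype=float)
    if floor_epsilon is not None:
        if floor_epsilon <= 0:
            raise ValueError("floor_epsilon must be positive")
        rn = np.maximum(rn, floor_epsilon)
    else:
        bad = np.nonzero(rn <= 0)[0]
        if bad.size:
            raise PositivityError(
                f"curve {curve.well_id!r}: non-positive fluorescence at cycle"
                f" {int(bad[0]) + 1} (value {rn[bad[0]]!r})"
            )
    values = rn[1:] / rn[:-1] - 1.0
    cycles = np.arange(2, rn.size + 1)
    return RatioSeries(cycles=cycles, values=values)


def smooth_ratio(series: RatioSeries, window: int = DEFAULT_WINDOW) -> RatioSeries:
    """Centered moving average with symmetrically shrinking end windows.

    Interior points use the full ``window``; near the ends the window
    shrinks to the widest centered window that fits (width 1 at the first
    and last point, 3 at the second and penultimate, ...).  This preserves
    series length and leaves linear trends unchanged.
    """
    n = len(series)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd integer >= 1, got {window}")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half = window // 2
    v = series.values
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = v[i - h : i + h + 1].mean()
    return RatioSeries(cycles=series.cycles.copy(), values=out)


def interpolate_extract(
    smoothed: RatioSeries, grid_step: float = DEFAULT_GRID_STEP
) -> MaxRatioResult:
    """Spline-interpolate a smoothed ratio series and locate its maximum.

    A natural cubic spline (zero second derivative at the ends) through the
    (cycle, value) knots is evaluated on an inclusive grid from the first to
    the last knot at ``grid_step`` spacing; integer knots lie on the grid.
    MR is the maximal grid value and FCN its abscissa; ties break toward the
    earliest cycle.
    """
    n = len(smoothed)
    if n < 4:
        raise ValueError(f"cubic spline needs >= 4 knots, got {n}")
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    x = smoothed.cycles.astype(float)
    spline = CubicSpline(x, smoothed.values, bc_type="natural")
    n_steps = int(round((x[-1] - x[0]) / grid_step))
    grid = x[0] + grid_step * np.arange(n_steps + 1)
    values = spline(grid)
    idx = int(np.argmax(values))  # argmax returns the first maximum
    discrete = int(smoothed.cycles[int(np.argmax(smoothed.values))])
    return MaxRatioResult(
        mr=float(values[idx]), fcn=float(grid[idx]), discrete_argmax=discrete
    )


def compute_maxratio(
    curve: AmplificationCurve,
    window: int = DEFAULT_WINDOW,
    grid_step: float = DEFAULT_GRID_STEP,
    floor_epsilon: float | None = None,
) -> MaxRatioResult:
    """Full maxRatio pipeline: ratio series -> smoothing -> spline maximum."""
    series = compute_ratio_series(curve, floor_epsilon=floor_epsilon)
    smoothed = smooth_ratio(series, window=window)
    return interpolate_extract(smoothed, grid_step=grid_step)
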
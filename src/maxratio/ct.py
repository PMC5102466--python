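"""Reference cycle-threshold (CT) caller.

The CT method assigns a baseline window, subtracts a linear baseline fit
from the normalized fluorescence, and reports the fractional cycle Cq at
which the corrected signal (dRn) first crosses a fixed threshold (0.2
fluorescence units by default).  A reaction with no crossing is negative;
optionally, crossings later than ``cq_max`` cycles are also negativated
while the Cq value itself is retained.

The baseline end is adapted per reaction: the default window (cycles 3-15)
is shortened to two cycles before the lift-off cycle, defined as the first
cycle whose fluorescence exceeds the mean plus ten standard deviations of
the first five baseline cycles (truncated to the cycles preceding the
candidate, so that an early lift-off is not masked by its own signal).  Instrument vendors keep their baseline
algorithms proprietary; this rule is a documented, deterministic stand-in
that reproduces the same behaviour class (including the early/late baseline
ranges seen on real plates), not any vendor's exact output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plate_io import AmplificationCurve

__all__ = [
    "BaselineRange",
    "CtResult",
    "auto_baseline",
    "subtract_baseline",
    "compute_cq",
    "call_ct",
]

DEFAULT_THRESHOLD = 0.2
LIFTOFF_SD_MULTIPLIER = 10.0


@dataclass(frozen=True)
class BaselineRange:
    """Inclusive cycle window used for baseline fitting (1-based)."""

    start_cycle: int
    end_cycle: int

    def __post_init__(self) -> None:
        if not (1 <= self.start_cycle < self.end_cycle):
            raise ValueError(
                f"invalid baseline range ({self.start_cycle}, {self.end_cycle})"
            )
        if self.end_cycle - self.start_cycle < 2:
            raise ValueError("baseline range must span at least 2 cycles")


DEFAULT_BASELINE = BaselineRange(3, 15)


@dataclass
class CtResult:
    """Cq call for one reaction; ``cq`` is None when undetermined."""

    cq: float | None
    threshold: float
    baseline: BaselineRange
    call: int


def auto_baseline(
    curve: AmplificationCurve, default: BaselineRange = DEFAULT_BASELINE
) -> BaselineRange:
    """Assign a per-reaction baseline window.

    Starting from the default window, the end cycle is pulled back to two
    cycles before lift-off — the first cycle whose raw Rn exceeds the mean
    plus 10 SD of the five cycles starting at the window start — but never
    below start + 2.  Without a lift-off, the end is the default (capped at
    N - 1).
    """
    n = curve.n_cycles
    if n < 6:
        raise ValueError(f"need >= 6 cycles for baselining, got {n}")
    start = max(1, default.start_cycle)
    liftoff = None
    for c in range(start + 1, n + 1):
        # reference: the five cycles from the window start, truncated to the
        # cycles preceding the candidate (a cycle cannot sit in its own
        # reference); very early candidates fall back to the trailing cycles
        lo, hi = start, min(start + 4, c - 1)
        if hi - lo + 1 < 3:
            lo, hi = max(1, c - 3), c - 1
        ref = curve.rn[lo - 1 : hi]
        if ref.size < 2:
            continue
        limit = ref.mean() + LIFTOFF_SD_MULTIPLIER * ref.std(ddof=1)
        if curve.rn[c - 1] > limit:
            liftoff = c
            break
    if liftoff is not None:
        end = min(default.end_cycle, liftoff - 2)
    else:
        end = min(default.end_cycle, n - 1)
    end = max(end, start + 2)
    return BaselineRange(start, min(end, n))


def subtract_baseline(
    curve: AmplificationCurve, baseline: BaselineRange
) -> np.ndarray:
    """Baseline-corrected fluorescence dRn.

    A least-squares line is fitted to Rn over the baseline window and
    subtracted from the whole curve, absorbing linear drift.
    """
    if baseline.end_cycle > curve.n_cycles:
        raise ValueError("baseline range exceeds curve length")
    cyc = curve.cycles.astype(float)
    sel = slice(baseline.start_cycle - 1, baseline.end_cycle)
    coeffs = np.polyfit(cyc[sel], curve.rn[sel], deg=1)
    return curve.rn - np.polyval(coeffs, cyc)


def compute_cq(
    delta: np.ndarray,
    baseline: BaselineRange,
    threshold: float = DEFAULT_THRESHOLD,
    cq_max: float | None = None,
) -> CtResult:
    """Fractional Cq at the first upward threshold crossing after baseline end.

    Cq interpolates linearly in dRn between the flanking cycles; an exact
    hit at a cycle gives that integer cycle.  No crossing means an
    undetermined Cq and a negative call.  When ``cq_max`` is set, a Cq above
    it is retained but the call is negative.  Later re-crossings are ignored
    — only the first one counts, which is what makes early transient spikes
    CT-positive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    delta = np.asarray(delta, dtype=float)
    n = delta.size
    cq: float | None = None
    for c in range(baseline.end_cycle, n + 1):  # 1-based cycle c
        d_c = delta[c - 1]
        if d_c == threshold:
            cq = float(c)
            break
        if c < n and d_c < threshold <= delta[c]:
            cq = c + (threshold - d_c) / (delta[c] - d_c)
            break
    if cq is None:
        return CtResult(cq=None, threshold=threshold, baseline=baseline, call=0)
    call = 1 if (cq_max is None or cq <= cq_max) else 0
    return CtResult(cq=cq, threshold=threshold, baseline=baseline, call=call)


def call_ct(
    curve: AmplificationCurve,
    threshold: float = DEFAULT_THRESHOLD,
    baseline: BaselineRange | None = None,
    cq_max: float | None = None,
) -> CtResult:
    """Convenience pipeline: auto baseline -> dRn -> Cq call."""
    if baseline is None:
        baseline = auto_baseline(curve)
    delta = subtract_baseline(curve, baseline)
    return compute_cq(delta, baseline, threshold=threshold, cq_max=cq_max)
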
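"""Boundary localization from raw scan traces.

The pipeline mirrors the instrument's data-processing chain: subtract the
pre-run background scan, smooth with a 5-point moving average, then localize
the boundary either from the time derivative (the starting point of the
non-negative derivative interval containing the maximum derivative peak) or
from the trough position (global minimum of the baseline-subtracted signal).
A third convention maps the trough time to the instant the pick-up electrode
has completely cleared the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DomainError,
    InsufficientDataError,
    NoBoundaryError,
)
from .forward import ElectrodeWindow, ScanTrace

Method = Literal["gradient", "trough", "t2"]


@dataclass(frozen=True)
class BoundaryFix:
    """One localized boundary position from a single scan."""

    t_boundary_s: float
    x_boundary_mm: float
    clock_min: float
    method: Method
    quality: float
    valid: bool = True


def subtract_baseline(trace: ScanTrace, baseline: ScanTrace) -> ScanTrace:
    """Subtract the pre-run background scan, resampled onto the trace grid.

    The baseline must share the trace's scan kinematics (speed and start
    position); its samples are linearly interpolated onto the trace's time
    grid, so slightly different sampling rates are tolerated.
    """
    if not np.isclose(trace.scan_speed_mm_s, baseline.scan_speed_mm_s, rtol=1e-6):
        raise AlignmentError(
            f"scan speeds differ: {trace.scan_speed_mm_s} vs {baseline.scan_speed_mm_s}"
        )
    if not np.isclose(trace.x_start_mm, baseline.x_start_mm, atol=1e-6):
        raise AlignmentError(
            f"scan start positions differ: {trace.x_start_mm} vs {baseline.x_start_mm}"
        )
    resampled = np.interp(trace.t_s, baseline.t_s, baseline.signal)
    return trace.with_signal(trace.signal - resampled)


def moving_average(signal: Sequence[float], window: int = 5) -> np.ndarray:
    """Centered moving average with a symmetrically shrinking window at the edges.

    The window must be odd; output length equals input length.  At index i the
    effective half-width is min(window//2, i, n-1-i), so no data are fabricated
    beyond the ends.
    """
    if window < 1 or window % 2 == 0:
        raise DomainError(f"window must be a positive odd integer, got {window}")
    s = np.asarray(signal, dtype=float)
    n = s.size
    if window > n:
        raise DomainError(f"window ({window}) exceeds signal length ({n})")
    if window == 1:
        return s.copy()
    half = window // 2
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    csum = np.concatenate(([0.0], np.cumsum(s)))
    return (csum[idx + h + 1] - csum[idx - h]) / (2 * h + 1)


def _nonneg_run_start(d: np.ndarray, i_max: int, tol: float) -> int:
    """First index of the maximal contiguous run with d >= -tol containing i_max."""
    i = i_max
    while i > 0 and d[i - 1] >= -tol:
        i -= 1
    return i


def locate_boundary_gradient(
    trace: ScanTrace,
    tol: float = 0.0,
    min_quality: float = 0.0,
) -> BoundaryFix:
    """Boundary fix from the derivative of the (filtered) trace.

    Computes the forward-difference time derivative, finds its global maximum
    (earliest index on ties), takes the maximal contiguous run of samples with
    derivative >= -tol containing that maximum, and returns the run's first
    sample time.  For the trough-shaped signature of a boundary passage this
    start coincides with the trough bottom, where the signal turns back up.

    ``tol`` relaxes the run membership for noisy data; ``min_quality`` is a
    noise-floor threshold on the maximum derivative below which the fix is
    flagged invalid rather than rejected.
    """
    s = np.asarray(trace.signal, dtype=float)
    if s.size < 3:
        raise DomainError("need at least 3 samples to differentiate")
    d = np.diff(s) / trace.dt_s
    if np.all(d == 0):
        raise NoBoundaryError("flat trace: derivative is identically zero")
    i_max = int(np.argmax(d))
    i0 = _nonneg_run_start(d, i_max, tol)
    t_b = float(trace.t_s[i0])
    quality = float(d[i_max])
    return BoundaryFix(
        t_boundary_s=t_b,
        x_boundary_mm=trace.x_start_mm + trace.scan_speed_mm_s * t_b,
        clock_min=trace.scan_start_clock_min + t_b / 60.0,
        method="gradient",
        quality=quality,
        valid=quality > min_quality,
    )


def locate_boundary_trough(
    trace: ScanTrace,
    min_quality: float = 0.0,
) -> BoundaryFix:
    """Boundary fix at the global minimum of the (filtered) trace.

    Earliest index wins on ties.  Quality is the trough depth below the
    (baseline-subtracted) zero level.
    """
    s = np.asarray(trace.signal, dtype=float)
    if np.all(s == s[0]):
        raise NoBoundaryError("flat trace: no trough")
    i_min = int(np.argmin(s))
    t_b = float(trace.t_s[i_min])
    quality = float(-s[i_min])
    return BoundaryFix(
        t_boundary_s=t_b,
        x_boundary_mm=trace.x_start_mm + trace.scan_speed_mm_s * t_b,
        clock_min=trace.scan_start_clock_min + t_b / 60.0,
        method="trough",
        quality=quality,
        valid=quality > min_quality,
    )


def locate_boundary_t2(
    trace: ScanTrace,
    window: ElectrodeWindow,
    min_quality: float = 0.0,
) -> BoundaryFix:
    """Boundary fix from the trough time, mapped to the trailing window edge.

    The signal minimum occurs when the pick-up electrode has completely
    cleared the boundary, so the boundary then sits half a window support
    behind the detector center.
    """
    fix = locate_boundary_trough(trace, min_quality=min_quality)
    return BoundaryFix(
        t_boundary_s=fix.t_boundary_s,
        x_boundary_mm=fix.x_boundary_mm - window.support_mm / 2.0,
        clock_min=fix.clock_min,
        method="t2",
        quality=fix.quality,
        valid=fix.valid,
    )


def fixes_from_scan_series(
    traces: Iterable[ScanTrace],
    baseline: ScanTrace,
    method: Method = "gradient",
    *,
    window: ElectrodeWindow | None = None,
    filter_window: int = 5,
    tol: float = 0.0,
    min_quality: float = 0.0,
    max_fixes: int = 4,
    min_fixes: int = 3,
) -> list[BoundaryFix]:
    """Full localization chain over a timed scan series.

    Per trace: subtract the background scan, smooth with the moving-average
    filter, localize with the chosen method.  Fixes flagged invalid (no
    boundary, or quality at/below ``min_quality``) are dropped; at most the
    first ``max_fixes`` valid fixes are retained and at least ``min_fixes``
    are required, else :class:`InsufficientDataError` is raised.
    """
    if method == "t2" and window is None:
        raise DomainError("t2 localization needs the electrode window geometry")
    fixes: list[BoundaryFix] = []
    for trace in sorted(traces, key=lambda tr: tr.scan_start_clock_min):
        corrected = subtract_baseline(trace, baseline)
        smoothed = corrected.with_signal(
            moving_average(corrected.signal, filter_window)
        )
        try:
            if method == "gradient":
                fix = locate_boundary_gradient(smoothed, tol=tol, min_quality=min_quality)
            elif method == "trough":
                fix = locate_boundary_trough(smoothed, min_quality=min_quality)
            elif method == "t2":
                assert window is not None
                fix = locate_boundary_t2(smoothed, window, min_quality=min_quality)
            else:
                raise DomainError(f"unknown localization method {method!r}")
        except NoBoundaryError:
            continue
        if fix.valid:
            fixes.append(fix)
        if len(fixes) == max_fixes:
            break
    if len(fixes) < min_fixes:
        raise InsufficientDataError(
            f"only {len(fixes)} valid boundary fixes, need >= {min_fixes}"
        )
    return fixes
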
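"""Extracted-ion chromatograms: extraction, smoothing, boundaries, areas.

Quantification is identification-anchored: an XIC is pulled from the MS1
scans around a PSM's retention time in a narrow ppm window, smoothed for
boundary detection, and integrated on the *raw* trace between the detected
bounds so the area stays unbiased by the smoother.

The multi-filter stack applied to every feature is: (1) the ppm m/z filter
at extraction, (2) moving-average smoothing, (3) the isotope-envelope
consistency filter (isotopologue XICs must correlate with the monoisotopic
one), (4) charge consistency from the PSM.  Filters (3)-(4) live in the
quantification modules; this module provides the primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError
from .ms_io import RunData


@dataclass
class XIC:
    """One chromatogram trace with optional detected peak and area."""

    target_mz: float
    tol_ppm: float
    rt: np.ndarray          # strictly increasing, seconds
    intensity: np.ndarray
    apex_index: int | None = None
    left_bound: int | None = None
    right_bound: int | None = None
    area: float | None = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if len(self.rt) != len(self.intensity):
            raise ContractError("rt and intensity arrays differ in length")
        if len(self.rt) > 1 and not np.all(np.diff(self.rt) > 0):
            raise ContractError("XIC retention times not strictly increasing")
        if (
            self.left_bound is not None
            and self.apex_index is not None
            and self.right_bound is not None
            and not (self.left_bound <= self.apex_index <= self.right_bound)
        ):
            raise ContractError("bounds must satisfy left <= apex <= right")

    def __len__(self) -> int:
        return len(self.rt)


class RunIndex:
    """Flat, m/z-sorted view of all MS1 peaks of a run.

    Turns XIC extraction into two searchsorted calls plus a scatter-add,
    which matters when thousands of features are extracted per run.
    """

    def __init__(self, run: RunData):
        ms1 = run.ms1_spectra()
        self.scan_rt = np.array([s.rt_seconds for s in ms1], dtype=np.float64)
        sizes = [len(s.mz_array) for s in ms1]
        if sum(sizes) == 0:
            self.mz = np.empty(0)
            self.intensity = np.empty(0)
            self.scan_of_peak = np.empty(0, dtype=np.intp)
            return
        mz = np.concatenate([s.mz_array for s in ms1])
        inten = np.concatenate([s.intensity_array for s in ms1])
        scan = np.repeat(np.arange(len(ms1), dtype=np.intp), sizes)
        order = np.argsort(mz, kind="stable")
        self.mz = mz[order]
        self.intensity = inten[order]
        self.scan_of_peak = scan[order]


def extract_xic(
    run: RunData | RunIndex,
    mz: float,
    tol_ppm: float,
    rt_center: float,
    rt_halfwidth: float,
) -> XIC:
    """Trace the summed intensity within +-tol_ppm of ``mz`` over MS1 scans.

    One point per MS1 scan with RT in [center - halfwidth, center +
    halfwidth]; scans with no matching peak contribute intensity 0.  A
    window containing no MS1 scans yields an empty (zero-point) XIC.
    """
    if tol_ppm <= 0:
        raise ContractError("tol_ppm must be positive")
    if rt_halfwidth <= 0:
        raise ContractError("rt_halfwidth must be positive")
    index = run if isinstance(run, RunIndex) else RunIndex(run)

    s0, s1 = np.searchsorted(
        index.scan_rt, [rt_center - rt_halfwidth, rt_center + rt_halfwidth + 1e-12]
    )
    rts = index.scan_rt[s0:s1]
    intensities = np.zeros(s1 - s0)
    if index.mz.size:
        lo = mz * (1 - tol_ppm * 1e-6)
        hi = mz * (1 + tol_ppm * 1e-6)
        p0, p1 = np.searchsorted(index.mz, [lo, hi])
        scans = index.scan_of_peak[p0:p1]
        inwin = (scans >= s0) & (scans < s1)
        np.add.at(intensities, scans[inwin] - s0, index.intensity[p0:p1][inwin])
    return XIC(target_mz=mz, tol_ppm=tol_ppm, rt=rts, intensity=intensities)


def smooth_xic(xic: XIC, window_points: int = 3) -> XIC:
    """Moving-average smoothing with reflected ends; window 1 is identity."""
    if window_points < 1 or window_points % 2 == 0:
        raise ContractError("window_points must be a positive odd integer")
    if window_points == 1 or len(xic) == 0:
        return replace(xic, intensity=xic.intensity.copy())
    half = window_points // 2
    padded = np.pad(xic.intensity, half, mode="reflect") if len(xic) > 1 else np.repeat(
        xic.intensity, window_points
    )
    kernel = np.full(window_points, 1.0 / window_points)
    smoothed = np.convolve(padded, kernel, mode="valid")
    return replace(xic, intensity=smoothed)


def detect_boundaries(
    xic: XIC,
    anchor_rt: float,
    apex_halfwidth: float = 15.0,
    floor_fraction: float = 0.05,
    valley_fraction: float = 0.5,
) -> XIC:
    """Locate the apex near ``anchor_rt`` and walk out to the peak bounds.

    The apex is the maximum-intensity point within +-apex_halfwidth of the
    anchor (ties broken toward the anchor).  Bounds extend outward until
    intensity drops to <= floor_fraction of the apex, a local minimum below
    valley_fraction of the apex is crossed (shoulder split), or the window
    ends.  An all-zero trace gets no bounds and no area.
    """
    if len(xic) < 3:
        raise ContractError("XIC needs at least 3 points for boundary detection")
    inwin = np.abs(xic.rt - anchor_rt) <= apex_halfwidth
    if not inwin.any():
        inwin = np.ones(len(xic), dtype=bool)  # anchor outside trace: search all
    candidates = np.flatnonzero(inwin)
    best = candidates[
        np.lexsort((np.abs(xic.rt[candidates] - anchor_rt), -xic.intensity[candidates]))
    ][0]
    apex_val = xic.intensity[best]
    if apex_val <= 0:
        return replace(xic, apex_index=None, left_bound=None, right_bound=None,
                       area=None)

    floor = floor_fraction * apex_val
    valley = valley_fraction * apex_val

    def walk(step: int) -> int:
        i = best
        prev = apex_val
        while True:
            j = i + step
            if j < 0 or j >= len(xic):
                return i
            v = xic.intensity[j]
            if v <= floor:
                return j
            if v > prev and prev < valley:
                return i  # crossed a sub-valley local minimum
            prev = v
            i = j

    return replace(
        xic,
        apex_index=int(best),
        left_bound=int(walk(-1)),
        right_bound=int(walk(+1)),
        area=None,
    )


def integrate(xic: XIC) -> float:
    """Trapezoidal area (intensity * seconds) of the raw trace between bounds."""
    if xic.left_bound is None or xic.right_bound is None:
        raise ContractError("XIC has no detected bounds to integrate")
    lo, hi = xic.left_bound, xic.right_bound + 1
    if hi - lo < 2:
        return 0.0
    return float(np.trapezoid(xic.intensity[lo:hi], xic.rt[lo:hi]))


def integrate_between(xic: XIC, left: int, right: int) -> float:
    """Trapezoidal area over externally supplied bounds (shared-bounds case)."""
    if right - left < 1:
        return 0.0
    return float(np.trapezoid(xic.intensity[left : right + 1], xic.rt[left : right + 1]))


def pearson_over(x: XIC, y: XIC, left: int, right: int) -> float:
    """Pearson correlation of two co-sampled traces over shared bounds."""
    a = x.intensity[left : right + 1]
    b = y.intensity[left : right + 1]
    if len(a) < 2 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
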
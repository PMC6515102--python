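"""Chromatographic fingerprints: peak detection, retention-time correction,
consensus reference construction and similarity scoring.

The similarity of a sample fingerprint to the consensus reference is the
Pearson correlation (or cosine) of the two full intensity traces after
multipoint retention-time correction: matched peak apices anchor a
monotone piecewise-linear time warp, with a matching window of 0.5 min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io import Chromatogram

__all__ = [
    "Peak",
    "AlignmentMap",
    "estimate_noise",
    "detect_peaks",
    "assign_peaks_to_panel",
    "build_reference",
    "align_to_reference",
    "similarity",
]

DEFAULT_WINDOW = 0.5  # min, peak-matching half-window


@dataclass(frozen=True)
class Peak:
    """A detected chromatographic peak with valley-to-valley bounds."""

    apex_time: float  # min
    height: float  # detector units, above the local baseline
    area: float  # detector units x min, above a linear local baseline
    left: float  # min
    right: float  # min
    signal_to_noise: float

    def __post_init__(self) -> None:
        if not (self.left < self.apex_time < self.right):
            raise ValueError("bounds must bracket the apex")
        if self.area <= 0 or self.height <= 0:
            raise ValueError("peak area and height must be positive")


@dataclass
class AlignmentMap:
    """Monotone piecewise-linear time correction anchored at matched apices."""

    anchors: list[tuple[float, float]] = field(default_factory=list)  # (observed, reference)
    warning: str | None = None

    def __post_init__(self) -> None:
        if self.anchors:
            obs = [a for a, _ in self.anchors]
            ref = [b for _, b in self.anchors]
            if sorted(obs) != obs or sorted(ref) != ref or \
                    len(set(obs)) != len(obs) or len(set(ref)) != len(ref):
                raise ValueError("anchors must be strictly increasing in both coordinates")


def estimate_noise(chrom: Chromatogram,
                   baseline_region: tuple[float, float] | None = None) -> float:
    """Robust baseline noise: 1.4826 x MAD of the linearly detrended region.

    With an explicit ``baseline_region`` (min), that slice is used and must
    hold at least 20 samples. Without one, the quietest 1-minute window of
    the trace (smallest detrended MAD) is used, which avoids peaks and
    slow background structure automatically.
    """
    t, y = chrom.times, chrom.intensities

    def detrended_mad(ts: np.ndarray, ys: np.ndarray) -> float:
        coef = np.polyfit(ts, ys, 1)
        resid = ys - np.polyval(coef, ts)
        return float(1.4826 * np.median(np.abs(resid - np.median(resid))))

    if baseline_region is not None:
        lo, hi = baseline_region
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 20:
            raise ValueError("baseline region must contain at least 20 samples")
        return detrended_mad(t[mask], y[mask])

    n_win = max(1, int(round(1.0 / max(chrom.sampling_interval, 1e-9))))
    n_win = max(n_win, 20)
    mads = []
    for start in range(0, max(1, t.size - n_win + 1), n_win):
        sl = slice(start, start + n_win)
        if t[sl].size >= 20:
            mads.append(detrended_mad(t[sl], y[sl]))
    return min(mads) if mads else 0.0


def _rolling_baseline(y: np.ndarray, n: int) -> np.ndarray:
    """Morphological baseline: rolling minimum followed by a rolling mean."""
    n = max(3, n)
    base = ndimage.minimum_filter1d(y, size=n, mode="nearest")
    return ndimage.uniform_filter1d(base, size=n, mode="nearest")


def detect_peaks(chrom: Chromatogram, min_snr: float = 10.0,
                 min_width: float = 0.04,
                 baseline_region: tuple[float, float] | None = None,
                 baseline_window: float = 2.0) -> list[Peak]:
    """Local maxima above ``min_snr`` x noise, integrated valley-to-valley.

    The trace is baseline-corrected with a rolling-minimum filter
    (``baseline_window`` minutes) before apex detection. Bounds are the
    valley minima between neighbouring apices, capped at twice the peak's
    half-prominence width on each side (so a slowly decaying background
    between far-apart peaks does not stretch the local baseline), then
    tightened to where the corrected intensity falls into the noise. The
    area is trapezoidal above a straight line joining the raw trace at the
    two bounds.
    """
    t, y = chrom.times, chrom.intensities
    dt = chrom.sampling_interval
    if dt is None or dt <= 0 or t.size < 5:
        return []
    noise = estimate_noise(chrom, baseline_region)
    corr = y - _rolling_baseline(y, int(round(baseline_window / dt)))

    floor = max(min_snr * noise, 1e-12 * max(np.max(np.abs(corr)), 1.0))
    apices, props = signal.find_peaks(
        corr, height=floor, prominence=floor,
        width=max(2.0, min_width / dt), rel_height=0.5,
    )
    if apices.size == 0:
        return []

    peaks: list[Peak] = []
    for m, apex in enumerate(apices):
        cap = max(3, int(round(2.0 * props["widths"][m])))
        lo_lim = max(apices[m - 1] if m > 0 else 0, apex - cap)
        hi_lim = min(apices[m + 1] if m + 1 < apices.size else t.size - 1,
                     apex + cap)
        left = lo_lim + int(np.argmin(corr[lo_lim:apex + 1])) if apex > lo_lim else lo_lim
        right = apex + int(np.argmin(corr[apex:hi_lim + 1])) if hi_lim > apex else hi_lim
        height = float(corr[apex])
        # tighten flat baseline stretches: walk back toward the apex while
        # the corrected trace sits inside the noise floor
        tight = max(2.0 * noise, 2e-3 * height)
        while left < apex - 1 and corr[left] < tight and corr[left + 1] < tight:
            left += 1
        while right > apex + 1 and corr[right] < tight and corr[right - 1] < tight:
            right -= 1
        if right - left < 2:
            continue
        base_line = np.interp(t[left:right + 1], [t[left], t[right]],
                              [y[left], y[right]])
        area = float(np.trapezoid(y[left:right + 1] - base_line, t[left:right + 1]))
        if area <= 0 or height <= 0:
            continue
        peaks.append(Peak(
            apex_time=float(t[apex]), height=height, area=area,
            left=float(t[left]), right=float(t[right]),
            signal_to_noise=float(height / noise) if noise > 0 else float("inf"),
        ))
    return peaks


def assign_peaks_to_panel(peaks: list[Peak], expected_times: dict[str, float],
                          window: float = DEFAULT_WINDOW) -> dict[str, Peak | None]:
    """Match detected peaks to expected analyte retention times.

    Each analyte takes the nearest apex within ``window`` minutes; a peak
    serves at most one analyte (nearest-first greedy assignment).
    """
    out: dict[str, Peak | None] = {name: None for name in expected_times}
    if not peaks:
        return out
    apices = np.array([p.apex_time for p in peaks])
    taken: set[int] = set()
    order = sorted(expected_times,
                   key=lambda k: np.min(np.abs(apices - expected_times[k])))
    for name in order:
        d = np.abs(apices - expected_times[name])
        for j in np.argsort(d):
            if d[j] > window:
                break
            if j not in taken:
                taken.add(int(j))
                out[name] = peaks[j]
                break
    return out


def build_reference(chroms: list[Chromatogram],
                    method: str = "median") -> Chromatogram:
    """Pointwise median (default) or mean consensus trace on a common grid."""
    if len(chroms) < 2:
        raise ValueError("need at least two chromatograms")
    t0 = chroms[0].times
    for c in chroms[1:]:
        if c.times.shape != t0.shape or np.max(np.abs(c.times - t0)) > 1e-9:
            raise ValueError("chromatograms are not on a common grid; align first")
    stack = np.vstack([c.intensities for c in chroms])
    if method == "median":
        ref = np.median(stack, axis=0)
    elif method == "mean":
        ref = stack.mean(axis=0)
    else:
        raise ValueError("method must be 'median' or 'mean'")
    return Chromatogram(t0.copy(), ref, chroms[0].sampling_interval)


def _match_apices(obs: list[Peak], ref: list[Peak],
                  window: float) -> list[tuple[float, float]]:
    """Mutual-nearest greedy apex matching within the time window."""
    if not obs or not ref:
        return []
    ot = np.array([p.apex_time for p in obs])
    rt = np.array([p.apex_time for p in ref])
    pairs = []
    for i, o in enumerate(ot):
        j = int(np.argmin(np.abs(rt - o)))
        if abs(rt[j] - o) <= window and int(np.argmin(np.abs(ot - rt[j]))) == i:
            pairs.append((float(o), float(rt[j])))
    # keep a strictly monotone anchor sequence in both coordinates
    pairs.sort()
    anchors: list[tuple[float, float]] = []
    for o, r in pairs:
        if not anchors or (o > anchors[-1][0] and r > anchors[-1][1]):
            anchors.append((o, r))
    return anchors


def align_to_reference(chrom: Chromatogram, ref: Chromatogram,
                       window: float = DEFAULT_WINDOW,
                       min_snr: float = 5.0) -> tuple[Chromatogram, AlignmentMap]:
    """Multipoint retention-time correction of ``chrom`` onto ``ref``'s clock.

    Peak apices matched within ``window`` minutes become warp anchors; the
    warp is piecewise linear between anchors and the identity outside the
    anchor span. With zero matches the input is returned unchanged with a
    warning flag.
    """
    obs_peaks = detect_peaks(chrom, min_snr=min_snr)
    ref_peaks = detect_peaks(ref, min_snr=min_snr)
    anchors = _match_apices(obs_peaks, ref_peaks, window)
    if not anchors:
        return chrom.copy(), AlignmentMap(anchors=[], warning="no peaks matched")

    t = ref.times
    obs_t = np.array([a for a, _ in anchors])
    ref_t = np.array([b for _, b in anchors])
    # identity outside the anchor span: pin the grid ends to themselves
    lo, hi = chrom.times[0], chrom.times[-1]
    if ref_t[0] > lo and obs_t[0] > lo:
        obs_t = np.concatenate([[lo], obs_t])
        ref_t = np.concatenate([[lo], ref_t])
    if ref_t[-1] < hi and obs_t[-1] < hi:
        obs_t = np.concatenate([obs_t, [hi]])
        ref_t = np.concatenate([ref_t, [hi]])
    # inverse warp: for each reference time, the observed time it came from
    back = np.interp(t, ref_t, obs_t)
    warped = np.interp(back, chrom.times, chrom.intensities)
    out = Chromatogram(t.copy(), warped, ref.sampling_interval)
    return out, AlignmentMap(anchors=anchors)


def similarity(chrom: Chromatogram, ref: Chromatogram,
               metric: str = "pearson") -> float:
    """Correlation (default) or cosine between two traces on a common grid.

    Pearson similarity of a constant trace is undefined; NaN is returned
    with a warning rather than raising.
    """
    if chrom.times.shape != ref.times.shape or \
            np.max(np.abs(chrom.times - ref.times)) > 1e-9:
        raise ValueError("traces are not on a common grid; align first")
    x, y = chrom.intensities, ref.intensities
    if metric == "pearson":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("constant trace: Pearson similarity undefined")
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])
    if metric == "cosine":
        nx, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx == 0 or ny == 0:
            warnings.warn("zero trace: cosine similarity undefined")
            return float("nan")
        return float(np.dot(x, y) / (nx * ny))
    raise ValueError("metric must be 'pearson' or 'cosine'")
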
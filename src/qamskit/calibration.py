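"""Linear calibration curves and signal-to-noise based LOD/LOQ estimation.

A calibration curve is an unweighted ordinary-least-squares line
``response = a * concentration + b`` fitted to a dilution series; the limit
of detection (quantification) is the lowest tested concentration whose
signal-to-noise ratio reaches 3 (10).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "LodLoqEstimate",
    "fit_calibration",
    "invert_calibration",
    "estimate_lod_loq",
]

LOD_SNR = 3.0
LOQ_SNR = 10.0


@dataclass(frozen=True)
class CalibrationPoint:
    concentration: float  # mg/mL
    response: float  # peak area, detector units
    signal_to_noise: float | None = None

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass(frozen=True)
class CalibrationCurve:
    analyte_name: str
    slope: float  # area per mg/mL
    intercept: float  # area
    r_squared: float
    n_points: int
    concentration_range: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("a curve needs at least two points")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


def fit_calibration(points: list[CalibrationPoint],
                    analyte_name: str = "") -> CalibrationCurve:
    """OLS line through a dilution series; r² is the squared Pearson r."""
    if len(points) < 2:
        raise ValueError("at least two calibration points required")
    conc = np.array([p.concentration for p in points], dtype=float)
    resp = np.array([p.response for p in points], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("all concentrations identical: singular fit")
    res = stats.linregress(conc, resp)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return CalibrationCurve(
        analyte_name=analyte_name,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=min(r2, 1.0),
        n_points=len(points),
        concentration_range=(float(conc.min()), float(conc.max())),
    )


def invert_calibration(curve: CalibrationCurve,
                       area: float) -> tuple[float, str | None]:
    """Map a peak area back to concentration, flagging out-of-range results.

    Returns ``(concentration, flag)`` with ``flag`` one of ``None``,
    ``"below-range"`` or ``"above-range"``. Out-of-range quantification is
    flagged rather than rejected: routine sample extracts legitimately fall
    outside the calibrated span.
    """
    if curve.slope == 0:
        raise ValueError("cannot invert a zero-slope curve")
    conc = (area - curve.intercept) / curve.slope
    lo, hi = curve.concentration_range
    flag = None
    if conc < lo:
        flag = "below-range"
    elif conc > hi:
        flag = "above-range"
    return float(conc), flag


@dataclass(frozen=True)
class LodLoqEstimate:
    lod: float | None  # mg/mL, None when no concentration reaches S/N 3
    loq: float | None

    @property
    def determined(self) -> bool:
        return self.lod is not None and self.loq is not None


def estimate_lod_loq(series: list[CalibrationPoint]) -> LodLoqEstimate:
    """Lowest tested concentrations reaching S/N 3 (LOD) and 10 (LOQ).

    The series must carry signal-to-noise values and be sorted by
    concentration; S/N must be non-decreasing apart from small ties
    (instrument noise at neighbouring dilutions), so the thresholds are
    scanned from the bottom of the series.
    """
    if any(p.signal_to_noise is None for p in series):
        raise ValueError("every point needs a signal_to_noise value")
    conc = np.array([p.concentration for p in series], dtype=float)
    snr = np.array([p.signal_to_noise for p in series], dtype=float)
    if np.any(np.diff(conc) < 0):
        raise ValueError("series must be sorted by concentration")
    # tie-tolerant monotonicity check: S/N may wiggle by 5% point-to-point
    drops = np.diff(snr) < -0.05 * np.maximum(snr[:-1], 1e-12)
    if np.any(drops):
        raise ValueError("signal-to-noise must be non-decreasing in concentration")

    def lowest_reaching(threshold: float) -> float | None:
        idx = np.nonzero(snr >= threshold)[0]
        return float(conc[idx[0]]) if idx.size else None

    lod = lowest_reaching(LOD_SNR)
    loq = lowest_reaching(LOQ_SNR)
    return LodLoqEstimate(lod=lod, loq=loq)
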
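"""Single-marker (QAMS) and external-standard quantification.

The relative correction factor of analyte k against marker s is the slope
ratio of their calibration lines,

    f_k/s = a_k / a_s ,

and the single-marker content of a non-marker analyte is

    C_k = A_k / (a_s * f_k/s) * F = A_k / a_k * F ,

with F the extraction factor (effective mL of extract per g of dry
material). Two readings of the single-marker formula — dividing the
analyte's area by the marker's slope scaled by f, or scaling the marker's
slope-only concentration estimate — reduce to the same intercept-free
expression, so the external-standard and single-marker contents differ by
exactly the intercept term (b_k / a_k) * F per cell.

The marker itself carries the one available reference standard, so its
content is reported through its full external-standard curve (slope and
intercept); a ``marker_by_esm=False`` switch forces the slope-only route
for symmetry experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CalibrationTable, ContentTable, PeakTable

__all__ = [
    "RcfTable",
    "ExtractionFactor",
    "compute_rcf",
    "quantify_esm",
    "quantify_qams",
    "summarize_contents",
    "ContentSummary",
]


@dataclass(frozen=True)
class RcfTable:
    """Marker identity plus per-analyte relative correction factors."""

    marker_name: str
    factors: dict[str, float]

    def __post_init__(self) -> None:
        if self.marker_name not in self.factors:
            raise ValueError("marker must appear in the factor map")
        if self.factors[self.marker_name] != 1.0:
            raise ValueError("the marker's factor must be exactly 1")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("all correction factors must be positive")


@dataclass(frozen=True)
class ExtractionFactor:
    """Effective extract volume x dilution per gram of sample (mL/g)."""

    value: float = 1.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("extraction factor must be positive")


def compute_rcf(calib: CalibrationTable, marker: str) -> RcfTable:
    """Slope-ratio correction factors f_k = a_k / a_s for every analyte."""
    if marker not in calib.analytes:
        raise ValueError(f"marker {marker!r} absent from calibration table")
    a_s = calib.slope(marker)
    factors = {k: calib.slope(k) / a_s for k in calib.analytes}
    factors[marker] = 1.0
    return RcfTable(marker_name=marker, factors=factors)


def quantify_esm(peaks: PeakTable, calib: CalibrationTable,
                 factor: ExtractionFactor = ExtractionFactor()) -> ContentTable:
    """External-standard contents ((A - b) / a) * F, clipped at zero.

    Cells whose inverted concentration is negative (area below the
    intercept) are clipped to 0 and flagged; missing areas stay missing.
    """
    missing = [k for k in peaks.analytes if k not in calib.analytes]
    if missing:
        raise ValueError(f"no calibration curve for analyte(s): {missing}")
    a = np.array([calib.slope(k) for k in peaks.analytes])
    b = np.array([calib.intercept(k) for k in peaks.analytes])
    conc = (peaks.areas.to_numpy(dtype=float) - b) / a
    contents = conc * factor.value
    flags = {}
    neg = contents < 0
    for i, j in np.argwhere(neg & ~np.isnan(contents)):
        flags[(peaks.sample_ids[i], peaks.analytes[j])] = "below-zero"
    contents = np.where(neg, 0.0, contents)
    df = pd.DataFrame(contents, index=peaks.sample_ids, columns=peaks.analytes)
    return ContentTable(df, method="ESM", flags=flags)


def quantify_qams(peaks: PeakTable, rcf: RcfTable, calib: CalibrationTable,
                  factor: ExtractionFactor = ExtractionFactor(),
                  marker_by_esm: bool = True) -> ContentTable:
    """Single-marker contents A_k / (a_s * f_k) * F.

    The marker column is computed by the external-standard route by default
    (the single reference standard has a full curve); with
    ``marker_by_esm=False`` the marker too is quantified slope-only.
    """
    if rcf.marker_name not in calib.analytes:
        raise ValueError("the marker needs a calibration curve")
    missing = [k for k in peaks.analytes if k not in rcf.factors]
    if missing:
        raise ValueError(f"no correction factor for analyte(s): {missing}")
    a_s = calib.slope(rcf.marker_name)
    denom = np.array([a_s * rcf.factors[k] for k in peaks.analytes])
    contents = peaks.areas.to_numpy(dtype=float) / denom * factor.value
    df = pd.DataFrame(contents, index=peaks.sample_ids, columns=peaks.analytes)
    flags: dict[tuple[str, str], str] = {}
    if marker_by_esm and rcf.marker_name in peaks.analytes:
        m = rcf.marker_name
        b_m, a_m = calib.intercept(m), calib.slope(m)
        col = (peaks.areas[m].to_numpy(dtype=float) - b_m) / a_m * factor.value
        neg = col < 0
        for i in np.argwhere(neg & ~np.isnan(col)).ravel():
            flags[(peaks.sample_ids[i], m)] = "below-zero"
        df[m] = np.where(neg, 0.0, col)
    return ContentTable(df, method="QAMS", flags=flags)


@dataclass(frozen=True)
class ContentSummary:
    analyte_means: pd.Series = field(repr=False)
    sample_totals: pd.Series = field(repr=False)

    @property
    def total_mean(self) -> float:
        return float(self.sample_totals.mean())


def summarize_contents(table: ContentTable) -> ContentSummary:
    """Per-analyte column means and per-sample row totals."""
    means = table.contents.mean(axis=0, skipna=True)
    totals = table.contents.sum(axis=1, skipna=True)
    return ContentSummary(analyte_means=means, sample_totals=totals)
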
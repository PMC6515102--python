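"""Method-validation statistics: RSD, recovery, and dual-method agreement.

Everything here uses the sample (n-1) standard deviation. For a pair of
values the relative error 100*|x-y|/mean and the pair RSD are linked by the
identity RE = sqrt(2) * RSD, which is used as an internal consistency check
on agreement reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ContentTable, PeakTable

__all__ = [
    "RecoveryRecord",
    "AgreementReport",
    "rsd",
    "cv_per_analyte",
    "recovery_rate",
    "paired_ttest",
    "compare_methods",
]


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sd(n-1) / mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def cv_per_analyte(peaks: PeakTable) -> pd.Series:
    """Between-batch coefficient of variation (%) of each peak-area column."""
    if len(peaks.sample_ids) < 2:
        raise ValueError("need at least two samples")
    out = {}
    for k in peaks.analytes:
        col = peaks.areas[k].to_numpy(dtype=float)
        col = col[~np.isnan(col)]
        if col.size >= 2 and np.all(col == 0):
            raise ValueError(f"constant-zero column: {k!r}")
        out[k] = rsd(col)
    return pd.Series(out, name="cv_percent")


@dataclass(frozen=True)
class RecoveryRecord:
    found: float  # mg
    known: float  # mg
    added: float  # mg

    def __post_init__(self) -> None:
        if self.added <= 0:
            raise ValueError("added amount must be positive")
        if self.found < 0 or self.known < 0:
            raise ValueError("found and known amounts must be non-negative")


def recovery_rate(r: RecoveryRecord) -> float:
    """Spike recovery in percent: (found - known) * 100 / added."""
    return (r.found - r.known) * 100.0 / r.added


def _student_t_sf(t: float, df: int) -> float:
    """One-sided upper tail of Student's t via the regularized incomplete beta."""
    if math.isinf(t):
        return 0.0 if t > 0 else 1.0
    x = df / (df + t * t)
    p_two = float(special.betainc(df / 2.0, 0.5, x))
    return p_two / 2.0 if t >= 0 else 1.0 - p_two / 2.0


def paired_ttest(x, y) -> tuple[float, float]:
    """Two-sided paired t-test on the differences x - y.

    Conventions for degenerate inputs: all differences zero -> (0, 1);
    zero-variance differences with nonzero mean -> (+/-inf, 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        if mean == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, mean), 0.0
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * _student_t_sf(abs(t), n - 1)
    return float(t), float(min(p, 1.0))


@dataclass
class AgreementReport:
    """Cell-level and column-level agreement between two content tables."""

    relative_error: pd.DataFrame  # percent, per cell
    pair_rsd: pd.DataFrame  # percent, per cell
    pearson_r: pd.Series  # per analyte, NaN when a column is constant
    t_statistic: pd.Series
    p_value: pd.Series
    excluded_cells: list[tuple[str, str]]  # all-zero pairs

    def max_relative_error(self) -> float:
        return float(np.nanmax(self.relative_error.to_numpy()))


def compare_methods(esm: ContentTable, qams: ContentTable) -> AgreementReport:
    """Agreement statistics between external-standard and single-marker contents.

    Per cell: relative error 100*|e-q|/mean(e,q) and pair RSD (n-1 sd of the
    pair over its mean). Per analyte: Pearson r across samples, and a
    two-sided paired t-test. All-zero pairs are flagged and excluded from
    the column statistics.
    """
    if (esm.sample_ids != qams.sample_ids) or (esm.analytes != qams.analytes):
        raise ValueError("tables must share an identical sample/analyte grid")
    e = esm.contents.to_numpy(dtype=float)
    q = qams.contents.to_numpy(dtype=float)
    pair_mean = (e + q) / 2.0
    diff = np.abs(e - q)
    zero_pair = (e == 0) & (q == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel_err = np.where(zero_pair, np.nan, 100.0 * diff / pair_mean)
    pair_sd = diff / math.sqrt(2.0)  # n-1 sd of a two-value pair
    with np.errstate(divide="ignore", invalid="ignore"):
        prsd = np.where(zero_pair, np.nan, 100.0 * pair_sd / pair_mean)

    idx, cols = esm.contents.index, esm.contents.columns
    pearson, tstat, pval = {}, {}, {}
    for j, k in enumerate(cols):
        keep = ~zero_pair[:, j]
        ek, qk = e[keep, j], q[keep, j]
        if ek.size < 2:
            pearson[k] = np.nan
            tstat[k], pval[k] = np.nan, np.nan
            continue
        if np.ptp(ek) == 0 or np.ptp(qk) == 0:
            pearson[k] = np.nan  # constant column: correlation undefined
        else:
            pearson[k] = float(stats.pearsonr(ek, qk).statistic)
        tstat[k], pval[k] = paired_ttest(ek, qk)

    excluded = [(idx[i], cols[j]) for i, j in np.argwhere(zero_pair)]
    return AgreementReport(
        relative_error=pd.DataFrame(rel_err, index=idx, columns=cols),
        pair_rsd=pd.DataFrame(prsd, index=idx, columns=cols),
        pearson_r=pd.Series(pearson),
        t_statistic=pd.Series(tstat),
        p_value=pd.Series(pval),
        excluded_cells=excluded,
    )
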
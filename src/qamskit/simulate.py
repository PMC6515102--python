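"""Synthetic chromatogram and batch-panel generator.

The generator renders what the analysis pipeline assumes about a
multi-batch HPLC fingerprint study of a seven-constituent herbal panel:

* each analyte elutes as an exponentially modified Gaussian whose area is
  calibration slope x concentration (tau = 0 gives a pure Gaussian and
  keeps analytic area checks exact);
* between-batch concentrations are lognormal, parameterized by mean and
  CV percent (sigma_log = sqrt(ln(1 + CV^2))), so dispersions up to ~100%
  stay positive;
* retention times jitter batch-to-batch, a slow sinusoidal drift and
  Gaussian detector noise sit under everything;
* every batch shares a fixed matrix background — a large solvent front,
  a broad late-gradient hump and a set of minor matrix peaks — rescaled
  per batch by a 10% lognormal factor. Real fingerprints owe most of
  their trace energy to such shared structure, which is what makes
  full-trace similarity scores sit near 1 even when the quantified
  constituents disperse strongly.

All randomness flows from one explicit seed; equal seeds give bit-equal
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .calibration import CalibrationPoint
from .io import Chromatogram, GELATA_ANALYTES, PeakTable
import pandas as pd

__all__ = [
    "PeakSpec",
    "BatchSpec",
    "default_peak_specs",
    "default_batch_spec",
    "matrix_background",
    "make_chromatogram",
    "make_calibration_series",
    "make_panel",
]

DEFAULT_GRID = (0.0, 130.0, 0.01)  # minutes: full-run grid
#: Mean contents (mg/g; equivalently mg/mL at unit extraction factor).
DEFAULT_MEAN_CONC = {
    "gastrodin": 3.53,
    "p-hydroxybenzyl alcohol": 0.91,
    "parishin E": 3.65,
    "p-hydroxy benzaldehyde": 0.34,
    "parishin B": 2.79,
    "parishin C": 0.18,
    "parishin A": 9.53,
}
#: Between-batch coefficient of variation targets, percent.
DEFAULT_CV_PERCENT = {
    "gastrodin": 49.7,
    "p-hydroxybenzyl alcohol": 85.2,
    "parishin E": 33.3,
    "p-hydroxy benzaldehyde": 96.5,
    "parishin B": 32.2,
    "parishin C": 50.1,
    "parishin A": 47.9,
}
_DEFAULT_RT = {
    "gastrodin": 10.0,
    "p-hydroxybenzyl alcohol": 14.5,
    "parishin E": 30.0,
    "p-hydroxy benzaldehyde": 40.0,
    "parishin B": 52.0,
    "parishin C": 58.0,
    "parishin A": 65.0,
}
_DEFAULT_SIGMA = {
    "gastrodin": 0.12,
    "p-hydroxybenzyl alcohol": 0.13,
    "parishin E": 0.15,
    "p-hydroxy benzaldehyde": 0.15,
    "parishin B": 0.16,
    "parishin C": 0.16,
    "parishin A": 0.18,
}
_DEFAULT_RESPONSE = {
    "gastrodin": 18634.0,
    "p-hydroxybenzyl alcohol": 39300.0,
    "parishin E": 14141.0,
    "p-hydroxy benzaldehyde": 52536.0,
    "parishin B": 20791.0,
    "parishin C": 31240.0,
    "parishin A": 11769.0,
}


@dataclass(frozen=True)
class PeakSpec:
    """Shape and response of one analyte peak."""

    analyte_name: str
    retention_time: float  # min
    sigma: float  # min, Gaussian width
    tau: float  # min, exponential tail; 0 = pure Gaussian
    response_per_conc: float  # area per mg/mL

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")

    def profile(self, times: np.ndarray, area: float,
                shift: float = 0.0) -> np.ndarray:
        """Unit-area peak shape scaled to ``area``, apex near rt + shift."""
        loc = self.retention_time + shift
        if self.tau == 0:
            pdf = stats.norm.pdf(times, loc=loc, scale=self.sigma)
        else:
            pdf = stats.exponnorm.pdf(times, self.tau / self.sigma,
                                      loc=loc, scale=self.sigma)
        return area * pdf


@dataclass(frozen=True)
class BatchSpec:
    """Multi-batch panel design: sample size, dispersion and noise levels."""

    n_batches: int = 21
    mean_conc: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MEAN_CONC))
    cv_percent: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CV_PERCENT))
    rt_jitter_sd: float = 0.067  # min; keeps batch shifts within +/-0.2
    noise_sd: float = 2.0  # detector units
    drift_amplitude: float = 5.0  # detector units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches < 2:
            raise ValueError("need at least two batches")
        if any(cv < 0 for cv in self.cv_percent.values()):
            raise ValueError("CVs must be non-negative")


def default_peak_specs() -> list[PeakSpec]:
    """The seven-analyte panel in elution order, pure-Gaussian shapes."""
    return [
        PeakSpec(name, _DEFAULT_RT[name], _DEFAULT_SIGMA[name], 0.0,
                 _DEFAULT_RESPONSE[name])
        for name in GELATA_ANALYTES
    ]


def default_batch_spec(seed: int = 0, **overrides) -> BatchSpec:
    return replace(BatchSpec(seed=seed), **overrides)


# -- shared matrix background -----------------------------------------------

_BG_TEMPLATE_SEED = 20190417  # fixes the minor-peak layout, not user-facing
_N_MINOR = 18
_FRONT_HEIGHT = 2.0e6
_FRONT_TIME = 2.8
_HUMP_HEIGHT = 2.5e5


def _minor_peak_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic layout of shared minor matrix peaks, clear of the panel."""
    rng = np.random.default_rng(_BG_TEMPLATE_SEED)
    rts = np.array(list(_DEFAULT_RT.values()))
    times: list[float] = []
    while len(times) < _N_MINOR:
        x = rng.uniform(5.0, 100.0)
        if np.abs(x - rts).min() > 1.5 and all(abs(x - m) > 1.0 for m in times):
            times.append(x)
    heights = rng.lognormal(np.log(5.0e4), 0.6, _N_MINOR)
    sigmas = rng.uniform(0.12, 0.2, _N_MINOR)
    return np.array(times), heights, sigmas


_MINOR_T, _MINOR_H, _MINOR_S = _minor_peak_table()


def matrix_background(times: np.ndarray) -> np.ndarray:
    """Fixed shared background: solvent front + gradient hump + minor peaks."""
    t = np.asarray(times, dtype=float)
    y = np.where(
        t < _FRONT_TIME,
        _FRONT_HEIGHT * np.exp(-0.5 * ((t - _FRONT_TIME) / 0.45) ** 2),
        _FRONT_HEIGHT * np.exp(-np.clip(t - _FRONT_TIME, 0, None) / 1.2),
    )
    y = y + _HUMP_HEIGHT * np.exp(-0.5 * ((t - 90.0) / 5.0) ** 2)
    for h, rt, s in zip(_MINOR_H, _MINOR_T, _MINOR_S):
        y = y + h * np.exp(-0.5 * ((t - rt) / s) ** 2)
    return y


# -- generators --------------------------------------------------------------

def make_chromatogram(peaks: list[PeakSpec], concs: dict[str, float],
                      grid: tuple[float, float, float] = DEFAULT_GRID,
                      noise_sd: float = 0.0, drift_amplitude: float = 0.0,
                      seed: int | None = None,
                      rng: np.random.Generator | None = None,
                      rt_shifts: dict[str, float] | None = None,
                      background_scale: float = 0.0,
                      intercepts: dict[str, float] | None = None) -> Chromatogram:
    """Render one trace: EMG peaks + optional background, drift and noise.

    The integrated area of analyte k is ``response_per_conc_k * conc_k``
    (plus an optional constant offset from ``intercepts``, emulating a
    per-analyte detector bias). Identical seeds give identical traces.
    """
    t0, t1, dt = grid
    times = np.arange(t0, t1 + dt / 2, dt)
    for p in peaks:
        pad = 5 * (p.sigma + p.tau)
        if p.retention_time - pad < t0 or p.retention_time + pad > t1:
            raise ValueError(f"grid does not cover {p.analyte_name} +/- 5 widths")
        if dt > p.sigma / 3:
            warnings.warn(f"grid interval {dt} coarser than sigma/3 for "
                          f"{p.analyte_name}")
    y = np.zeros_like(times)
    for p in peaks:
        area = p.response_per_conc * concs[p.analyte_name]
        if intercepts:
            area += intercepts.get(p.analyte_name, 0.0)
        shift = (rt_shifts or {}).get(p.analyte_name, 0.0)
        y += p.profile(times, area, shift)
    if background_scale:
        y += background_scale * matrix_background(times)
    if (noise_sd > 0 or drift_amplitude > 0):
        if rng is None:
            rng = np.random.default_rng(seed)
        if drift_amplitude > 0:
            phase = rng.uniform(0, 2 * np.pi)
            y += drift_amplitude * np.sin(2 * np.pi * times / 40.0 + phase)
        if noise_sd > 0:
            y += rng.normal(0.0, noise_sd, times.size)
    return Chromatogram(times, y, dt)


def make_calibration_series(spec: PeakSpec, concs: list[float],
                            noise_fraction: float = 0.0, seed: int = 0,
                            baseline_noise_sd: float = 1.0) -> list[CalibrationPoint]:
    """Dilution series with multiplicative area noise and model-based S/N.

    Areas are ``response * conc * (1 + eps)`` with eps ~ N(0, noise_fraction);
    each point's S/N is its peak height (area over the unit-shape apex)
    divided by ``baseline_noise_sd``.
    """
    if len(set(concs)) != len(concs) or any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive and distinct")
    rng = np.random.default_rng(seed)
    span = 5 * (spec.sigma + spec.tau)
    fine = np.linspace(spec.retention_time - span, spec.retention_time + span, 2001)
    apex_density = float(spec.profile(fine, 1.0).max())  # peak height per unit area
    points = []
    for c in concs:
        eps = rng.normal(0.0, noise_fraction) if noise_fraction > 0 else 0.0
        area = spec.response_per_conc * c * (1.0 + eps)
        snr = area * apex_density / baseline_noise_sd
        points.append(CalibrationPoint(concentration=c, response=area,
                                       signal_to_noise=snr))
    return points


def make_panel(batch: BatchSpec, peaks: list[PeakSpec] | None = None,
               grid: tuple[float, float, float] = DEFAULT_GRID,
               include_background: bool = True, render: bool = True,
               intercepts: dict[str, float] | None = None,
               ) -> tuple[PeakTable, list[Chromatogram]]:
    """Draw a multi-batch panel and (optionally) render its traces.

    Returns the true peak-area table (response x concentration, plus any
    injected intercept offsets) and the rendered chromatograms. Per-batch
    concentrations are lognormal at the spec's means/CVs; retention jitter
    is one normal draw per analyte per batch.
    """
    peaks = peaks or default_peak_specs()
    names = [p.analyte_name for p in peaks]
    rng = np.random.default_rng(batch.seed)
    sigma_log = np.array(
        [np.sqrt(np.log1p((batch.cv_percent[n] / 100.0) ** 2)) for n in names])
    mu_log = np.array(
        [np.log(batch.mean_conc[n]) for n in names]) - sigma_log**2 / 2.0
    conc = rng.lognormal(mu_log, sigma_log, size=(batch.n_batches, len(names)))
    resp = np.array([p.response_per_conc for p in peaks])
    areas = conc * resp
    if intercepts:
        areas = areas + np.array([intercepts.get(n, 0.0) for n in names])
    sample_ids = [f"B{i + 1:02d}" for i in range(batch.n_batches)]
    table = PeakTable(pd.DataFrame(areas, index=sample_ids, columns=names))

    traces: list[Chromatogram] = []
    if render:
        for i in range(batch.n_batches):
            shifts = dict(zip(names, rng.normal(0.0, batch.rt_jitter_sd,
                                                len(names))))
            bg = float(rng.lognormal(0.0, 0.1)) if include_background else 0.0
            traces.append(make_chromatogram(
                peaks, dict(zip(names, conc[i])), grid=grid,
                noise_sd=batch.noise_sd, drift_amplitude=batch.drift_amplitude,
                rng=rng, rt_shifts=shifts, background_scale=bg,
                intercepts=intercepts,
            ))
    return table, traces
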
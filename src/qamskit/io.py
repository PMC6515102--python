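"""Data containers and delimited-text I/O for chromatographic quality evaluation.

All tabular formats are plain CSV (UTF-8, ``.`` decimal, header row). The
packaged reference tables — the seven-analyte calibration parameters, the
21-sample peak-area panel, the dual-method content table and the sample
provenance list — are shipped under :mod:`qamskit.data` and verified against
frozen SHA-256 checksums so that every downstream reproduction starts from
byte-identical inputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "PanelEntry",
    "AnalytePanel",
    "PeakTable",
    "CalibrationTable",
    "ContentTable",
    "Chromatogram",
    "GELATA_ANALYTES",
    "gelata_panel",
    "load_peak_table",
    "write_peak_table",
    "load_calibration_table",
    "write_calibration_table",
    "load_content_table",
    "write_content_table",
    "load_chromatogram",
    "write_chromatogram",
    "load_reference_calibration",
    "load_reference_peak_areas",
    "load_reference_contents",
    "load_reference_totals",
    "load_reference_provenance",
    "FIXTURE_SHA256",
    "verify_fixture_checksums",
]

#: Canonical elution order of the seven quantified constituents.
GELATA_ANALYTES = (
    "gastrodin",
    "p-hydroxybenzyl alcohol",
    "parishin E",
    "p-hydroxy benzaldehyde",
    "parishin B",
    "parishin C",
    "parishin A",
)

#: The single-marker reference constituent.
MARKER = "gastrodin"


@dataclass(frozen=True)
class PanelEntry:
    name: str
    elution_order: int
    role: Literal["marker", "target"]


@dataclass(frozen=True)
class AnalytePanel:
    """Ordered analyte identities with exactly one internal marker."""

    entries: tuple[PanelEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("analyte names must be unique")
        orders = sorted(e.elution_order for e in self.entries)
        if orders != list(range(1, len(self.entries) + 1)):
            raise ValueError("elution orders must be unique and contiguous from 1")
        markers = [e.name for e in self.entries if e.role == "marker"]
        if len(markers) != 1:
            raise ValueError(f"exactly one marker required, found {len(markers)}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in sorted(self.entries, key=lambda e: e.elution_order)]

    @property
    def marker(self) -> str:
        return next(e.name for e in self.entries if e.role == "marker")


def gelata_panel() -> AnalytePanel:
    """The seven-constituent panel in elution order, gastrodin as marker."""
    return AnalytePanel(
        tuple(
            PanelEntry(name, i + 1, "marker" if name == MARKER else "target")
            for i, name in enumerate(GELATA_ANALYTES)
        )
    )


@dataclass
class PeakTable:
    """Sample-by-analyte matrix of chromatographic peak areas.

    ``areas`` is indexed by sample id with one column per analyte; missing
    cells are NaN (an explicit sentinel, never silently zero).
    """

    areas: pd.DataFrame
    panel: AnalytePanel | None = None

    def __post_init__(self) -> None:
        if self.areas.index.has_duplicates:
            dupes = self.areas.index[self.areas.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample id(s): {dupes}")
        vals = self.areas.to_numpy(dtype=float)
        bad = np.argwhere(vals < 0)
        if bad.size:
            i, j = bad[0]
            raise ValueError(
                f"negative peak area at sample {self.areas.index[i]!r}, "
                f"analyte {self.areas.columns[j]!r}"
            )
        if self.panel is not None and list(self.areas.columns) != self.panel.names:
            raise ValueError("peak-table columns do not match the analyte panel")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.areas.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.areas.columns)

    @property
    def missing_cells(self) -> list[tuple[str, str]]:
        mask = self.areas.isna().to_numpy()
        return [(self.areas.index[i], self.areas.columns[j])
                for i, j in np.argwhere(mask)]


@dataclass
class CalibrationTable:
    """Per-analyte linear-response parameters (slope, intercept, range, LOD/LOQ)."""

    table: pd.DataFrame  # index: analyte; columns: slope..loq

    REQUIRED = ("slope", "intercept", "range_low", "range_high", "r_squared", "lod", "loq")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"calibration table missing column(s): {missing}")
        t = self.table
        if (t["slope"] <= 0).any():
            bad = t.index[t["slope"] <= 0].tolist()
            raise ValueError(f"non-positive slope for analyte(s): {bad}")
        if (t["range_low"] >= t["range_high"]).any():
            raise ValueError("linear range low must be below high")
        if (t["lod"] > t["loq"]).any():
            raise ValueError("LOD must not exceed LOQ")

    @property
    def analytes(self) -> list[str]:
        return list(self.table.index)

    def slope(self, analyte: str) -> float:
        return float(self.table.loc[analyte, "slope"])

    def intercept(self, analyte: str) -> float:
        return float(self.table.loc[analyte, "intercept"])

    def linear_range(self, analyte: str) -> tuple[float, float]:
        row = self.table.loc[analyte]
        return float(row["range_low"]), float(row["range_high"])


@dataclass
class ContentTable:
    """Sample-by-analyte contents in mg per gram of dry material.

    ``method`` tags the quantification route (``"ESM"`` or ``"QAMS"``).
    Cells clipped from negative inversion results are recorded in ``flags``.
    """

    contents: pd.DataFrame
    method: Literal["ESM", "QAMS"]
    uncertainty: pd.DataFrame | None = None
    flags: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ("ESM", "QAMS"):
            raise ValueError("method must be 'ESM' or 'QAMS'")
        vals = self.contents.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("contents must be non-negative (clip and flag instead)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.contents.index)

    @property
    def analytes(self) -> list[str]:
        return list(self.contents.columns)


@dataclass
class Chromatogram:
    """Uniformly sampled time/intensity trace (minutes, detector units)."""

    times: np.ndarray
    intensities: np.ndarray
    sampling_interval: float | None = None

    _UNIFORM_TOL = 1e-6  # minutes

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.ndim != 1:
            raise ValueError("times and intensities must be equal-length 1-D arrays")
        if self.times.size >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("time axis must be strictly increasing")
            if self.sampling_interval is None:
                self.sampling_interval = float(np.median(dt))
            if np.max(np.abs(dt - self.sampling_interval)) > self._UNIFORM_TOL:
                raise ValueError("time grid is not uniform; resample first")
        elif self.sampling_interval is None:
            self.sampling_interval = 0.0

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "Chromatogram":
        return Chromatogram(self.times.copy(), self.intensities.copy(),
                            self.sampling_interval)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def load_peak_table(path: str | Path, *, delimiter: str = ",",
                    panel: AnalytePanel | None = None) -> PeakTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    df.index = df.index.astype(str)
    return PeakTable(df.astype(float), panel=panel)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.areas.to_csv(path, index_label="sample")


def load_calibration_table(path: str | Path) -> CalibrationTable:
    df = pd.read_csv(path, index_col="analyte")
    return CalibrationTable(df.astype(float))


def write_calibration_table(table: CalibrationTable, path: str | Path) -> None:
    table.table.to_csv(path, index_label="analyte")


def load_content_table(path: str | Path) -> ContentTable:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if not first.startswith("# method:"):
            raise ValueError("content CSV must begin with a '# method:' line")
        method = first.split(":", 1)[1].strip()
        df = pd.read_csv(fh, index_col=0)
    df.index = df.index.astype(str)
    return ContentTable(df.astype(float), method=method)  # type: ignore[arg-type]


def write_content_table(table: ContentTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method: {table.method}\n")
        table.contents.to_csv(fh, index_label="sample")


def load_chromatogram(path: str | Path) -> Chromatogram:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    t, y = arr[:, 0], arr[:, 1]
    if t.size >= 2:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValueError("time axis must be strictly increasing")
        step = np.median(dt)
        if np.max(np.abs(dt - step)) > Chromatogram._UNIFORM_TOL:
            # resample onto the implied uniform grid
            grid = np.linspace(t[0], t[-1], t.size)
            y = np.interp(grid, t, y)
            t = grid
    return Chromatogram(t, y)


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    np.savetxt(path, np.column_stack([chrom.times, chrom.intensities]),
               delimiter=",", header="time_min,intensity", comments="")


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

#: Frozen digests of the packaged reference tables (digit-for-digit as printed).
FIXTURE_SHA256 = {
    "table1_calibration.csv": "0e9522d51dc9e57fa24e94f96334a576e86d28b78f9633abe793caaf410be8dd",
    "table3_peak_areas.csv": "44c3a1447c3ef80252bc3200b6c70e1086d9b647658fbe983f55561274223d9c",
    "table6_contents.csv": "78ec7e0bf06c595e9f373883f039511666eea30371731e6ced51ef87f06f31cc",
    "table6_totals.csv": "9719c10033a30ec6cd2adc34f157e1e227146ecd346ecc6ac559f7d1b0a604ca",
    "table8_provenance.csv": "ce0209e6a5a753d26cf0f5a70ae0ae0002ea2da1a144392cc5f54100c317c22d",
}


def _data_path(name: str):
    return resources.files("qamskit.data").joinpath(name)


def verify_fixture_checksums() -> None:
    """Raise if any packaged table deviates from its frozen digest."""
    for name, expected in FIXTURE_SHA256.items():
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise RuntimeError(f"fixture checksum mismatch for {name}: {digest}")


def load_reference_calibration() -> CalibrationTable:
    with resources.as_file(_data_path("table1_calibration.csv")) as p:
        return load_calibration_table(p)


def load_reference_peak_areas() -> PeakTable:
    with resources.as_file(_data_path("table3_peak_areas.csv")) as p:
        return load_peak_table(p, panel=gelata_panel())


def load_reference_contents() -> tuple[ContentTable, ContentTable]:
    """Dual-method content tables on a common 21x7 grid.

    The marker (gastrodin) is reported by a single external-standard column;
    it is carried into the QAMS table unchanged so the two tables share a
    grid, and agreement statistics for the marker are reported as not
    applicable.
    """
    with resources.as_file(_data_path("table6_contents.csv")) as p:
        long = pd.read_csv(p)
    esm = long.pivot(index="sample", columns="analyte", values="esm")
    qams = long.pivot(index="sample", columns="analyte", values="qams")
    order = [s for s in long["sample"].unique()]
    esm = esm.loc[order, list(GELATA_ANALYTES)]
    qams = qams.loc[order, list(GELATA_ANALYTES)]
    qams[MARKER] = esm[MARKER]
    esm_sd = long.pivot(index="sample", columns="analyte", values="esm_sd")
    qams_sd = long.pivot(index="sample", columns="analyte", values="qams_sd")
    esm_sd = esm_sd.loc[order, list(GELATA_ANALYTES)]
    qams_sd = qams_sd.loc[order, list(GELATA_ANALYTES)]
    for df in (esm, qams, esm_sd, qams_sd):
        df.columns.name = None
        df.index.name = "sample"
    return (
        ContentTable(esm.astype(float), "ESM", uncertainty=esm_sd.astype(float)),
        ContentTable(qams.astype(float), "QAMS", uncertainty=qams_sd.astype(float)),
    )


def load_reference_totals() -> pd.Series:
    with resources.as_file(_data_path("table6_totals.csv")) as p:
        df = pd.read_csv(p, index_col="sample")
    return df["total"].astype(float)


def load_reference_provenance() -> pd.DataFrame:
    with resources.as_file(_data_path("table8_provenance.csv")) as p:
        df = pd.read_csv(p, index_col="sample")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample ids in provenance table")
    return df
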
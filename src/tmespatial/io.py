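"""Cell-table I/O and cohort assembly.

The interchange format is a flat UTF-8 CSV, one row per segmented cell:

``cell_id, core_id, patient_id, x_um, y_um, CD3, CD8, FoxP3, CD163, PanCK,
PDL1, GZMB, Ki67, hladr_area_pct`` with optional window-geometry columns
``window_cx_um, window_cy_um, window_r_um``.  Marker columns are 0/1;
coordinates are microns in an arbitrary image frame (all downstream
statistics are isometry-invariant); ``hladr_area_pct`` is the percent of the
core's surface area staining positive for HLA-DR, constant within a core.

Cells live in :class:`CoreSample` objects as a pandas DataFrame (one core per
TMA punch); cores group into :class:`PatientRecord` objects (triplicate by
design); the cohort is stratified into HIGH/LOW HLA-DR expressors around the
cohort mean.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import CircularWindow, Window, infer_window
from .phenotype import MARKERS, Phenotype, assign_phenotype, assign_phenotypes

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS: tuple[str, ...] = (
    "cell_id", "core_id", "patient_id", "x_um", "y_um", *MARKERS, "hladr_area_pct",
)
WINDOW_COLUMNS: tuple[str, ...] = ("window_cx_um", "window_cy_um", "window_r_um")

#: Cell-table columns held inside ``CoreSample.cells``.
CELL_COLUMNS: tuple[str, ...] = ("cell_id", "x", "y", *MARKERS)


class SchemaError(ValueError):
    """The cell table violates the column/typing contract."""


class Stratum(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class CellRecord:
    """One phenotyped cell: coordinates in microns plus binary marker calls."""

    cell_id: str
    core_id: str
    x: float
    y: float
    markers: dict[str, bool]
    phenotype: Phenotype | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"cell {self.cell_id}: non-finite coordinates")
        missing = [m for m in MARKERS if m not in self.markers]
        if missing:
            raise ValueError(f"cell {self.cell_id}: missing markers {missing}")

    def assign(self) -> "CellRecord":
        """Set ``phenotype`` from the marker flags (idempotent)."""
        self.phenotype = assign_phenotype(self.markers)
        return self


@dataclass
class CoreSample:
    """One TMA core: window geometry, a cell table, and HLA-DR area percent."""

    core_id: str
    patient_id: str
    cells: pd.DataFrame
    window: Window
    hladr_area_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.hladr_area_pct <= 100.0:
            raise ValueError(
                f"core {self.core_id}: hladr_area_pct {self.hladr_area_pct} outside [0, 100]"
            )
        inside = self.window.contains(
            self.cells["x"].to_numpy(), self.cells["y"].to_numpy()
        )
        if not bool(np.all(inside)):
            raise ValueError(f"core {self.core_id}: cells outside window")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def assign_phenotypes(self) -> "CoreSample":
        """Add/refresh the ``phenotype`` column on the cell table."""
        self.cells = self.cells.assign(phenotype=assign_phenotypes(self.cells))
        return self

    def cell_records(self) -> list[CellRecord]:
        """Materialise the table as :class:`CellRecord` objects."""
        has_pheno = "phenotype" in self.cells.columns
        out = []
        for row in self.cells.itertuples(index=False):
            rec = CellRecord(
                cell_id=str(row.cell_id),
                core_id=self.core_id,
                x=float(row.x),
                y=float(row.y),
                markers={m: bool(getattr(row, m)) for m in MARKERS},
            )
            if has_pheno:
                rec.phenotype = Phenotype(row.phenotype)
            out.append(rec)
        return out


@dataclass
class PatientRecord:
    """One patient: up to three cores and the HLA-DR stratification state."""

    patient_id: str
    cores: list[CoreSample] = field(default_factory=list)
    stratum: Stratum | None = None

    @property
    def hladr_mean_pct(self) -> float:
        if not self.cores:
            raise ValueError(f"patient {self.patient_id} has no cores")
        return float(np.mean([c.hladr_area_pct for c in self.cores]))


def read_cell_table(path: str | Path) -> list[CoreSample]:
    """Read a cell-table CSV into one :class:`CoreSample` per core.

    Raises :class:`SchemaError` for missing columns, non-numeric coordinates
    (reported with the offending row number), markers outside {0, 1}, or an
    ``hladr_area_pct`` that varies within a core.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"cell_id": str, "core_id": str, "patient_id": str})
    return cores_from_frame(df, source=path.name)


def cores_from_frame(df: pd.DataFrame, source: str = "cell table") -> list[CoreSample]:
    """Validate a flat cell-table DataFrame and split it into cores."""
    df = df.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing required column(s) {missing}")

    for col in ("x_um", "y_um", "hladr_area_pct"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise SchemaError(f"{source}: non-numeric {col} at row {row}")
        df[col] = coerced
    for m in MARKERS:
        vals = pd.to_numeric(df[m], errors="coerce")
        if vals.isna().any() or not vals.isin((0, 1)).all():
            raise SchemaError(f"{source}: marker column {m} must be 0/1")
        df[m] = vals.astype(np.int8)

    has_window = all(c in df.columns for c in WINDOW_COLUMNS)
    cores: list[CoreSample] = []
    for core_id, grp in df.groupby("core_id", sort=True):
        hladr = grp["hladr_area_pct"].to_numpy()
        if not np.allclose(hladr, hladr[0], atol=1e-9):
            raise SchemaError(
                f"{source}: hladr_area_pct not constant within core {core_id}"
            )
        patient_ids = grp["patient_id"].unique()
        if len(patient_ids) != 1:
            raise SchemaError(
                f"{source}: core {core_id} assigned to multiple patients"
            )
        cells = (
            grp.rename(columns={"x_um": "x", "y_um": "y"})[list(CELL_COLUMNS)]
            .reset_index(drop=True)
        )
        if has_window:
            w = grp.iloc[0]
            window: Window = CircularWindow(
                float(w["window_cx_um"]), float(w["window_cy_um"]), float(w["window_r_um"])
            )
        else:
            window = infer_window(cells["x"].to_numpy(), cells["y"].to_numpy())
        cores.append(
            CoreSample(
                core_id=str(core_id),
                patient_id=str(patient_ids[0]),
                cells=cells,
                window=window,
                hladr_area_pct=float(hladr[0]),
            )
        )
    return cores


def write_cell_table(cores: list[CoreSample], path: str | Path) -> None:
    """Write cores back to the interchange CSV (coordinates at 0.01 um)."""
    frames = []
    for core in cores:
        frame = core.cells[list(CELL_COLUMNS)].rename(columns={"x": "x_um", "y": "y_um"})
        frame = frame.assign(
            core_id=core.core_id,
            patient_id=core.patient_id,
            hladr_area_pct=core.hladr_area_pct,
        )
        if isinstance(core.window, CircularWindow):
            frame = frame.assign(
                window_cx_um=core.window.cx,
                window_cy_um=core.window.cy,
                window_r_um=core.window.radius,
            )
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    cols = list(REQUIRED_COLUMNS) + [c for c in WINDOW_COLUMNS if c in out.columns]
    out[cols].to_csv(path, index=False, float_format="%.2f")


def build_patients(cores: list[CoreSample]) -> list[PatientRecord]:
    """Group cores into patients (ordered by patient ID)."""
    by_patient: dict[str, PatientRecord] = {}
    for core in cores:
        by_patient.setdefault(core.patient_id, PatientRecord(core.patient_id)).cores.append(core)
    return [by_patient[pid] for pid in sorted(by_patient)]


def stratify_cohort_by_mean(patients: list[PatientRecord]) -> list[PatientRecord]:
    """Split the cohort around the mean per-patient HLA-DR area percent.

    The threshold is the arithmetic mean over patients of the per-patient
    mean core HLA-DR area.  Values strictly above go HIGH, strictly below go
    LOW; an exact tie with the mean goes HIGH (deterministic convention; ties
    are measure-zero on continuous data).  Mutates and returns ``patients``.
    """
    if not patients:
        raise ValueError("cannot stratify an empty cohort")
    values = np.array([p.hladr_mean_pct for p in patients])
    threshold = float(values.mean())
    if np.allclose(values, threshold):
        warnings.warn("all HLA-DR values equal; entire cohort assigned HIGH")
    for p, v in zip(patients, values):
        p.stratum = Stratum.HIGH if v >= threshold else Stratum.LOW
    n_high = sum(p.stratum is Stratum.HIGH for p in patients)
    logger.info(
        "stratified %d patients at HLA-DR mean %.3f%%: %d HIGH / %d LOW",
        len(patients), threshold, n_high, len(patients) - n_high,
    )
    return patients
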
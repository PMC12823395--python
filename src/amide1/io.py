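"""Spectra tables, micrographs and result files.

Spectra live on a uniform wavenumber grid stored ascending; the canonical
analysis window is the amide I band, 1,600-1,700 cm^-1 sampled every
2 cm^-1 (51 points).  Two table dialects are supported:

* long  -- columns ``cell_id, arm, time_h, wavenumber_cm1, intensity``
* wide  -- first column ``wavenumber_cm1``, one column per record with
  header ``cell_id|arm|time_h`` (a column named ``medium`` holds the
  cell-medium reference spectrum)

Micrographs are single-plane TIFFs; pixel size (um) and acquisition
wavenumber come from a YAML sidecar ``<image>.yaml`` or keyword arguments.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError, GridError

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "CellRecord",
    "SpectralDataset",
    "Micrograph",
    "canonical_grid",
    "read_spectra_table",
    "write_spectra_table",
    "read_micrograph",
    "write_micrograph",
    "write_results",
]

#: Tolerance (cm^-1) on uniform grid spacing.
_GRID_ATOL = 1e-6


@dataclass(frozen=True)
class WavenumberGrid:
    """A strictly ascending, uniformly spaced wavenumber axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise GridError("grid needs at least two wavenumbers")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            raise GridError("grid must be strictly ascending")
        if np.max(np.abs(diffs - diffs[0])) > _GRID_ATOL:
            raise GridError(
                f"grid spacing non-uniform beyond {_GRID_ATOL} cm^-1"
            )
        object.__setattr__(self, "values", vals)

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    @property
    def lo(self) -> float:
        return float(self.values[0])

    @property
    def hi(self) -> float:
        return float(self.values[-1])

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash((len(self.values), self.lo, self.hi))

    @classmethod
    def from_values(cls, values: Iterable[float]) -> "WavenumberGrid":
        """Build a grid from values in any order (sorted ascending)."""
        vals = np.sort(np.asarray(list(values), dtype=float))
        return cls(vals)


def canonical_grid() -> WavenumberGrid:
    """The amide I analysis grid: 1,600-1,700 cm^-1, step 2 (51 points)."""
    return WavenumberGrid(np.arange(1600.0, 1701.0, 2.0))


@dataclass
class Spectrum:
    """One absorption/optoacoustic trace on a wavenumber grid.

    ``stage`` tracks the conditioning history; the ``normalized`` stage
    promises min 0 / max 1, and ``second_derivative`` intensities carry
    units per cm^-2.
    """

    grid: WavenumberGrid
    intensity: np.ndarray
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=float)
        if arr.shape != (len(self.grid),):
            raise FormatError(
                f"intensity length {arr.shape} != grid length {len(self.grid)}"
            )
        self.intensity = arr

    def copy(self, **updates) -> "Spectrum":
        out = Spectrum(
            grid=self.grid,
            intensity=self.intensity.copy(),
            stage=self.stage,
            meta=dict(self.meta),
        )
        for key, val in updates.items():
            setattr(out, key, val)
        return out


@dataclass
class CellRecord:
    """A single cell's spectrum with acquisition metadata."""

    cell_id: str
    arm: str  # "treated" | "untreated"
    time_h: float
    spectrum: Spectrum
    position: tuple[float, float] | None = None  # (x um, y um)


@dataclass
class SpectralDataset:
    """Per-cell spectra sharing one grid; the NMF data matrix lives here."""

    records: list[CellRecord]
    grid: WavenumberGrid
    medium: Spectrum | None = None

    def __post_init__(self):
        seen = set()
        for rec in self.records:
            if rec.spectrum.grid != self.grid:
                raise GridError(f"record {rec.cell_id}: grid mismatch")
            key = (rec.cell_id, rec.arm, rec.time_h)
            if key in seen:
                raise FormatError(f"duplicate record {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.records)

    def matrix(self) -> np.ndarray:
        """Data matrix X, one row per record, columns on the grid."""
        return np.vstack([r.spectrum.intensity for r in self.records])

    def select(self, arm: str | None = None, time_h: float | None = None
               ) -> list[CellRecord]:
        out = self.records
        if arm is not None:
            out = [r for r in out if r.arm == arm]
        if time_h is not None:
            out = [r for r in out if r.time_h == time_h]
        return out

    def time_points(self, arm: str | None = None) -> list[float]:
        return sorted({r.time_h for r in self.select(arm=arm)})


@dataclass
class Micrograph:
    """A 2-D single-wavenumber intensity image (optoacoustic mV)."""

    pixels: np.ndarray
    pixel_size_um: float
    wavenumber_cm1: float | None = None

    def __post_init__(self):
        arr = np.asarray(self.pixels, dtype=float)
        if arr.ndim != 2:
            raise FormatError("micrograph pixels must be a 2-D array")
        if self.pixel_size_um <= 0:
            raise FormatError("pixel_size_um must be positive")
        self.pixels = arr


# ---------------------------------------------------------------------------
# spectra tables


_LONG_COLUMNS = ["cell_id", "arm", "time_h", "wavenumber_cm1", "intensity"]


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def _parse_wide_header(header: str) -> tuple[str, str, float]:
    parts = header.split("|")
    if len(parts) != 3:
        raise FormatError(
            f"wide column header {header!r} is not 'cell_id|arm|time_h'"
        )
    return parts[0], parts[1], float(parts[2])


def read_spectra_table(path, dialect: str = "wide") -> SpectralDataset:
    """Read a CSV/TSV spectra table into a :class:`SpectralDataset`.

    The grid is sorted ascending regardless of file order; a record (or
    column) named ``medium`` is attached as the dataset's medium spectrum.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if dialect == "long":
        return _read_long(df)
    if dialect == "wide":
        return _read_wide(df)
    raise FormatError(f"unknown dialect {dialect!r}")


def _read_long(df: pd.DataFrame) -> SpectralDataset:
    missing = [c for c in _LONG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"long table missing columns: {missing}")
    dupes = df.duplicated(subset=["cell_id", "time_h", "wavenumber_cm1"])
    if dupes.any():
        raise FormatError("duplicate (cell_id, time_h, wavenumber) rows")
    grid = WavenumberGrid.from_values(df["wavenumber_cm1"].unique())
    records: list[CellRecord] = []
    medium = None
    for (cell_id, time_h), grp in df.groupby(["cell_id", "time_h"], sort=True):
        grp = grp.sort_values("wavenumber_cm1")
        if not np.array_equal(grp["wavenumber_cm1"].to_numpy(dtype=float),
                              grid.values):
            raise GridError(f"record ({cell_id}, {time_h}) not on shared grid")
        spec = Spectrum(grid, grp["intensity"].to_numpy(dtype=float))
        if str(cell_id) == "medium":
            medium = spec
            continue
        records.append(
            CellRecord(str(cell_id), str(grp["arm"].iloc[0]), float(time_h),
                       spec)
        )
    return SpectralDataset(records, grid, medium=medium)


def _read_wide(df: pd.DataFrame) -> SpectralDataset:
    if df.columns[0] != "wavenumber_cm1":
        raise FormatError("wide table must start with a wavenumber_cm1 column")
    order = np.argsort(df["wavenumber_cm1"].to_numpy(dtype=float))
    df = df.iloc[order]
    grid = WavenumberGrid(df["wavenumber_cm1"].to_numpy(dtype=float))
    records = []
    medium = None
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        if col == "medium":
            medium = Spectrum(grid, vals)
            continue
        cell_id, arm, time_h = _parse_wide_header(col)
        records.append(CellRecord(cell_id, arm, time_h, Spectrum(grid, vals)))
    return SpectralDataset(records, grid, medium=medium)


def write_spectra_table(dataset: SpectralDataset, path,
                        dialect: str = "wide") -> Path:
    """Write a dataset back to CSV/TSV; inverse of :func:`read_spectra_table`."""
    path = Path(path)
    sep = _sep_for(path)
    if dialect == "wide":
        data = {"wavenumber_cm1": dataset.grid.values}
        for rec in dataset.records:
            data[f"{rec.cell_id}|{rec.arm}|{rec.time_h:g}"] = \
                rec.spectrum.intensity
        if dataset.medium is not None:
            data["medium"] = dataset.medium.intensity
        pd.DataFrame(data).to_csv(path, sep=sep, index=False)
    elif dialect == "long":
        frames = []
        for rec in dataset.records:
            frames.append(pd.DataFrame({
                "cell_id": rec.cell_id,
                "arm": rec.arm,
                "time_h": rec.time_h,
                "wavenumber_cm1": dataset.grid.values,
                "intensity": rec.spectrum.intensity,
            }))
        if dataset.medium is not None:
            frames.append(pd.DataFrame({
                "cell_id": "medium",
                "arm": "none",
                "time_h": 0.0,
                "wavenumber_cm1": dataset.grid.values,
                "intensity": dataset.medium.intensity,
            }))
        pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# micrographs


def read_micrograph(path, pixel_size_um: float | None = None,
                    wavenumber_cm1: float | None = None,
                    plane: int | None = None) -> Micrograph:
    """Read a single-plane TIFF micrograph (no rescaling).

    Metadata is taken from keyword arguments, falling back to a YAML
    sidecar ``<image>.yaml`` with keys ``pixel_size_um``/``wavenumber_cm1``.
    """
    path = Path(path)
    arr = np.asarray(tifffile.imread(path))
    if arr.ndim == 3:
        if plane is None:
            raise FormatError(
                f"{path.name}: multi-plane/RGB TIFF needs a plane selector"
            )
        arr = arr[plane]
    if arr.ndim != 2:
        raise FormatError(f"{path.name}: expected a 2-D image, got {arr.ndim}-D")
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if (pixel_size_um is None or wavenumber_cm1 is None) and sidecar.exists():
        info = yaml.safe_load(sidecar.read_text()) or {}
        if pixel_size_um is None:
            pixel_size_um = info.get("pixel_size_um")
        if wavenumber_cm1 is None:
            wavenumber_cm1 = info.get("wavenumber_cm1")
    if pixel_size_um is None:
        raise FormatError(f"{path.name}: pixel size unknown (no sidecar/flag)")
    return Micrograph(arr.astype(float), float(pixel_size_um),
                      None if wavenumber_cm1 is None else float(wavenumber_cm1))


def write_micrograph(micrograph: Micrograph, path) -> Path:
    """Write a float32 TIFF plus YAML sidecar with pixel size/wavenumber."""
    path = Path(path)
    tifffile.imwrite(path, micrograph.pixels.astype(np.float32))
    sidecar = {"pixel_size_um": micrograph.pixel_size_um}
    if micrograph.wavenumber_cm1 is not None:
        sidecar["wavenumber_cm1"] = micrograph.wavenumber_cm1
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))
    return path


# ---------------------------------------------------------------------------
# results


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, WavenumberGrid):
        return obj.values.tolist()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(path, payload) -> Path:
    """Serialize analysis results.

    Lists of dataclass rows (e.g. response calls) become CSV when the path
    ends in .csv/.tsv; anything else is written as JSON via a dataclass/
    ndarray-aware encoder.
    """
    path = Path(path)
    if path.suffix.lower() in {".csv", ".tsv"}:
        rows = payload if isinstance(payload, Sequence) else [payload]
        frame = pd.DataFrame([_jsonable(r) for r in rows])
        frame.to_csv(path, sep=_sep_for(path), index=False)
    else:
        path.write_text(json.dumps(_jsonable(payload), indent=2))
    return path
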
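"""Shared grid/raster data model, I/O, cross-tabulation and confusion matrices.

Rasters are thin wrappers around 2-D numpy arrays tied to a :class:`GridSpec`.
All multi-raster operations require identical grids; analysis cells that are
nodata in any participating raster are excluded everywhere.

I/O uses the ESRI ASCII grid format (``.asc``): a plain-text, single-band
raster format that carries the georeferencing needed here (grid shape, cell
size, origin) and round-trips integer data losslessly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GridSpec",
    "CategoricalRaster",
    "ContinuousRaster",
    "ClassLegend",
    "ClassDef",
    "ConfusionMatrix",
    "GridAlignmentError",
    "LegendValidationError",
    "read_categorical",
    "read_continuous",
    "write_raster",
    "crosstab",
    "confusion_from_points",
]

DEFAULT_NODATA = -9999


class GridAlignmentError(ValueError):
    """Two rasters with different GridSpecs were combined."""


class LegendValidationError(ValueError):
    """Raster values not covered by the class legend."""


@dataclass(frozen=True)
class GridSpec:
    """Raster geometry: origin at the top-left corner, rows increase southward."""

    n_rows: int
    n_cols: int
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area_m2(self) -> float:
        return self.cell_size ** 2

    @property
    def cell_area_ha(self) -> float:
        return self.cell_area_m2 / 10_000.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell center, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y); raises if outside."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = int(np.floor((self.origin_y - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col


def _check_aligned(a: "GridSpec", b: "GridSpec") -> None:
    if a != b:
        raise GridAlignmentError(f"grids differ: {a} vs {b}")


@dataclass(frozen=True)
class ClassDef:
    code: int
    name: str
    suitable: bool
    degradation_weight: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation_weight <= 1.0:
            raise ValueError("degradation_weight must lie in [0, 1]")


@dataclass(frozen=True)
class ClassLegend:
    """Land-cover class codes, names, suitability flags and degradation weights."""

    classes: tuple[ClassDef, ...]

    def __post_init__(self) -> None:
        codes = [c.code for c in self.classes]
        if len(set(codes)) != len(codes):
            raise ValueError("class codes must be unique")

    @property
    def codes(self) -> list[int]:
        return [c.code for c in self.classes]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]

    def __getitem__(self, code: int) -> ClassDef:
        for c in self.classes:
            if c.code == code:
                return c
        raise KeyError(code)

    def suitable_codes(self) -> list[int]:
        return [c.code for c in self.classes if c.suitable]

    def weight(self, code: int) -> float:
        return self[code].degradation_weight

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClassLegend":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            tuple(
                ClassDef(
                    code=int(c["code"]),
                    name=str(c["name"]),
                    suitable=bool(c["suitable"]),
                    degradation_weight=float(c["degradation_weight"]),
                )
                for c in data["classes"]
            )
        )


def default_legend() -> ClassLegend:
    """Five wetland cover classes with their standard suitability and weights.

    Water, humid land and dense vegetation count as suitable (intact) cover;
    sparse vegetation and salt land as unsuitable (degraded) cover. Weights
    express per-cover degradation severity on [0, 1].
    """
    return ClassLegend(
        (
            ClassDef(1, "sparse_vegetation", False, 0.7),
            ClassDef(2, "water", True, 0.0),
            ClassDef(3, "humid_land", True, 0.1),
            ClassDef(4, "dense_vegetation", True, 0.2),
            ClassDef(5, "salt_land", False, 1.0),
        )
    )


@dataclass
class CategoricalRaster:
    grid: GridSpec
    values: np.ndarray
    nodata_code: int = DEFAULT_NODATA
    legend: ClassLegend | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values[np.isfinite(self.values)] == np.round(self.values[np.isfinite(self.values)])):
                raise TypeError("categorical raster values must be integers")
            self.values = self.values.astype(np.int64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"array shape {self.values.shape} != grid shape {self.grid.shape}")
        if self.legend is not None:
            self.validate_against(self.legend)

    def validate_against(self, legend: ClassLegend) -> None:
        mask = self.values != self.nodata_code
        present = np.unique(self.values[mask])
        unknown = sorted(set(present.tolist()) - set(legend.codes))
        if unknown:
            raise LegendValidationError(f"codes not in legend: {unknown}")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_code

    def class_counts(self, codes: Sequence[int] | None = None) -> dict[int, int]:
        if codes is None:
            codes = np.unique(self.values[self.valid_mask]).tolist()
        return {int(c): int(np.count_nonzero(self.values == c)) for c in codes}

    def copy(self) -> "CategoricalRaster":
        return CategoricalRaster(self.grid, self.values.copy(), self.nodata_code, self.legend)


@dataclass
class ContinuousRaster:
    grid: GridSpec
    values: np.ndarray
    nodata_value: float = float(DEFAULT_NODATA)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(f"array shape {self.values.shape} != grid shape {self.grid.shape}")
        mask = self.values != self.nodata_value
        if not np.all(np.isfinite(self.values[mask])):
            raise ValueError("continuous raster contains non-finite values outside nodata")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.values != self.nodata_value


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O


def _write_ascii_grid(path: Path, grid: GridSpec, values: np.ndarray, nodata, fmt: str) -> None:
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin_x!r}\n"
        f"yllcorner {grid.origin_y - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, values, fmt=fmt)


def write_raster(raster: CategoricalRaster | ContinuousRaster, path: str | Path) -> None:
    """Write a raster as a single-band ESRI ASCII grid (lossless for integers)."""
    path = Path(path)
    try:
        if isinstance(raster, CategoricalRaster):
            _write_ascii_grid(path, raster.grid, raster.values, raster.nodata_code, "%d")
        else:
            _write_ascii_grid(path, raster.grid, raster.values, raster.nodata_value, "%.17g")
    except OSError as exc:
        raise OSError(f"failed writing raster to {path}: {exc}") from exc


def _read_ascii_grid(path: Path) -> tuple[GridSpec, np.ndarray, float]:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not parts[0][:1].isalpha():
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos if len(header) == 6 else 0)
        required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
        if not required <= set(header):
            raise ValueError(f"{path}: missing ASCII-grid georeferencing header {sorted(required - set(header))}")
        values = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {values.shape} does not match header ({n_rows}, {n_cols})")
    cell = header["cellsize"]
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cell,
    )
    return grid, values, header.get("nodata_value", float(DEFAULT_NODATA))


def read_categorical(path: str | Path, legend: ClassLegend | None = None) -> CategoricalRaster:
    """Read a single-band integer raster and validate its codes against a legend."""
    grid, values, nodata = _read_ascii_grid(Path(path))
    if not np.all(values == np.round(values)):
        raise ValueError(f"{path}: raster contains non-integer values")
    raster = CategoricalRaster(grid, values.astype(np.int64), nodata_code=int(nodata))
    if legend is not None:
        raster.validate_against(legend)
        raster.legend = legend
    return raster


def read_continuous(path: str | Path) -> ContinuousRaster:
    grid, values, nodata = _read_ascii_grid(Path(path))
    return ContinuousRaster(grid, values, nodata_value=nodata)


# ---------------------------------------------------------------------------
# Cross-tabulation and confusion matrices


def crosstab(map_a: CategoricalRaster, map_b: CategoricalRaster, codes: Sequence[int] | None = None):
    """Transition counts between two dates: entry (i, j) counts cells that are
    class i in ``map_a`` and class j in ``map_b``. Nodata in either map drops
    the cell from the tabulation."""
    from .markov_projection import TransitionCountMatrix  # local import: avoids cycle

    _check_aligned(map_a.grid, map_b.grid)
    valid = map_a.valid_mask & map_b.valid_mask
    a = map_a.values[valid]
    b = map_b.values[valid]
    if codes is None:
        if map_a.legend is not None:
            codes = map_a.legend.codes
        else:
            codes = sorted(set(np.unique(a).tolist()) | set(np.unique(b).tolist()))
    codes = list(codes)
    lookup = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    ia = np.array([lookup[v] for v in a.tolist()], dtype=np.int64) if m else np.array([], dtype=np.int64)
    ib = np.array([lookup[v] for v in b.tolist()], dtype=np.int64) if m else np.array([], dtype=np.int64)
    counts = np.bincount(ia * m + ib, minlength=m * m).reshape(m, m)
    return TransitionCountMatrix(class_order=codes, counts=counts)


@dataclass
class ConfusionMatrix:
    """Error matrix: rows are reference (true) classes, columns mapped classes."""

    class_order: list[int]
    X: np.ndarray
    n_skipped_outside: int = 0
    n_skipped_nodata: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        r = len(self.class_order)
        if self.X.shape != (r, r):
            raise ValueError("confusion matrix must be square over the class order")
        if np.any(self.X < 0):
            raise ValueError("counts must be non-negative")

    @property
    def r(self) -> int:
        return len(self.class_order)

    @property
    def N(self) -> int:
        return int(self.X.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.X.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.X.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, index=self.class_order, columns=self.class_order)


def confusion_from_points(
    raster: CategoricalRaster,
    points: Iterable[tuple[float, float, int]],
    codes: Sequence[int] | None = None,
) -> ConfusionMatrix:
    """Tally ground-truth points against the mapped class at their location.

    Rows index the true class, columns the mapped class. Points outside the
    grid extent or falling on nodata cells are skipped and reported via the
    matrix's ``n_skipped_*`` counters.
    """
    pts = list(points)
    if codes is None:
        codes = raster.legend.codes if raster.legend is not None else None
    if codes is None:
        observed = set(np.unique(raster.values[raster.valid_mask]).tolist())
        observed |= {int(t) for _, _, t in pts}
        codes = sorted(observed)
    codes = list(codes)
    lookup = {c: i for i, c in enumerate(codes)}
    X = np.zeros((len(codes), len(codes)), dtype=np.int64)
    outside = nodata = 0
    for x, y, true_class in pts:
        try:
            row, col = raster.grid.index_of(x, y)
        except IndexError:
            outside += 1
            continue
        mapped = int(raster.values[row, col])
        if mapped == raster.nodata_code:
            nodata += 1
            continue
        X[lookup[int(true_class)], lookup[mapped]] += 1
    if outside:
        warnings.warn(f"{outside} ground-truth points fell outside the grid extent", stacklevel=2)
    return ConfusionMatrix(class_order=codes, X=X, n_skipped_outside=outside, n_skipped_nodata=nodata)
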
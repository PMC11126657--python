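"""Hexagonal landscape-degradation scoring.

The landscape is tessellated into congruent regular hexagons (default unit
area 40,000 ha) used as management and monitoring units. Within each unit,
five class-level landscape metrics are computed from the raster patches of
each cover class:

    CA    class area (ha) — Σ patch areas
    MPS   mean patch size (ha) — CA / number of patches
    ED    edge density (m/ha) — Σ patch edge / unit land area × 10,000
    MPFD  mean patch fractal dimension — mean of 2·ln(0.25·p)/ln(a); 1 for
          squares, approaching 2 for maximally convoluted shapes
    MSI   mean shape index — mean of p / (4·√a), the perimeter relative to
          the most compact (square) raster patch of equal area; ≥ 1

Each metric is min–max normalized across units per class (Z in [0, 1]) and
converted to a degradation-intensity code K in {1..4} by quartile, with the
direction of the scale depending on whether the cover is suitable
(water/humid/dense vegetation) or unsuitable (sparse vegetation/salt):
abundant suitable cover scores low, abundant unsuitable cover scores high,
and the shape/edge metrics run in the opposite sense for each group.

The unit's degradation score is

    LD = Σ K(c, m) · w(c) / V

where w(c) in [0, 1] is the per-cover degradation weight and V the unit's
vulnerability denominator — the fraction of suitable cover, floored at 0.01
so units with no suitable cover stay finite. Units are classified into four
relative groups by LD quartile.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import Polygon, box, mapping

from .raster_core import CategoricalRaster, ClassLegend, GridSpec

__all__ = [
    "HexGrid",
    "Patch",
    "PatchSet",
    "build_hexgrid",
    "assign_cells_to_hexagons",
    "extract_patches",
    "compute_metrics",
    "metric_table",
    "normalize_metrics",
    "assign_codes",
    "vulnerability",
    "ld_score",
    "hex_side_for_area",
    "DegradationResult",
    "degradation_scores",
    "METRIC_GROUPS",
    "VULNERABILITY_FLOOR",
]

METRIC_GROUPS = {"CA": 1, "MPS": 1, "ED": 2, "MPFD": 2, "MSI": 2}
METRICS = tuple(METRIC_GROUPS)
VULNERABILITY_FLOOR = 0.01


def hex_side_for_area(unit_area_ha: float) -> float:
    """Side length (m) of a regular hexagon with the given area in hectares."""
    area_m2 = unit_area_ha * 10_000.0
    return math.sqrt(2.0 * area_m2 / (3.0 * math.sqrt(3.0)))


@dataclass
class HexGrid:
    polygons: list[Polygon]
    ids: list[int]
    unit_area_ha: float
    side_m: float

    def __len__(self) -> int:
        return len(self.polygons)

    def to_geojson(self, path: str | Path, properties: pd.DataFrame | None = None) -> None:
        feats = []
        for uid, poly in zip(self.ids, self.polygons):
            props = {"id": uid}
            if properties is not None and uid in properties.index:
                props.update({k: _jsonable(v) for k, v in properties.loc[uid].items()})
            feats.append({"type": "Feature", "geometry": mapping(poly), "properties": props})
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v


def build_hexgrid(extent: GridSpec, unit_area_ha: float = 40_000.0) -> HexGrid:
    """Tile the raster extent with flat-top regular hexagons of the given area.

    Tiling starts from the extent's lower-left corner; every hexagon that
    intersects the extent is retained (uncclipped, so each unit's planar area
    equals ``unit_area_ha`` exactly).
    """
    if unit_area_ha <= 0:
        raise ValueError("unit_area must be positive")
    s = hex_side_for_area(unit_area_ha)
    x0 = extent.origin_x
    y_bottom = extent.origin_y - extent.n_rows * extent.cell_size
    x1 = extent.origin_x + extent.n_cols * extent.cell_size
    y_top = extent.origin_y
    extent_box = box(x0, y_bottom, x1, y_top)
    if extent_box.area < unit_area_ha * 10_000.0:
        warnings.warn("extent is smaller than one hexagonal unit", stacklevel=2)

    dx = 1.5 * s
    dy = math.sqrt(3.0) * s
    n_i = int(math.ceil((x1 - x0) / dx)) + 2
    n_j = int(math.ceil((y_top - y_bottom) / dy)) + 2
    polys, ids = [], []
    uid = 0
    for j in range(-1, n_j):
        for i in range(-1, n_i):
            cx = x0 + i * dx
            cy = y_bottom + j * dy + (dy / 2.0 if i % 2 else 0.0)
            hexagon = Polygon(
                [
                    (cx + s * math.cos(a), cy + s * math.sin(a))
                    for a in (k * math.pi / 3.0 for k in range(6))
                ]
            )
            if hexagon.intersects(extent_box):
                polys.append(hexagon)
                ids.append(uid)
                uid += 1
    return HexGrid(polygons=polys, ids=ids, unit_area_ha=unit_area_ha, side_m=s)


def assign_cells_to_hexagons(grid: GridSpec, hexgrid: HexGrid) -> np.ndarray:
    """Unit id of the hexagon containing each cell center (-1 if none)."""
    xs, ys = grid.cell_centers()
    pts_x, pts_y = xs.ravel(), ys.ravel()
    out = np.full(pts_x.shape, -1, dtype=np.int64)
    tree = shapely.STRtree(hexgrid.polygons)
    pts = shapely.points(pts_x, pts_y)
    pt_idx, poly_idx = tree.query(pts, predicate="intersects")
    # a center on a shared edge intersects two hexagons: keep the lowest id
    hex_ids = np.asarray(hexgrid.ids)
    order = np.lexsort((hex_ids[poly_idx], pt_idx))
    pt_idx, poly_idx = pt_idx[order], poly_idx[order]
    first = np.unique(pt_idx, return_index=True)[1]
    out[pt_idx[first]] = hex_ids[poly_idx[first]]
    return out.reshape(grid.shape)


@dataclass
class Patch:
    area_m2: float
    perimeter_m: float


@dataclass
class PatchSet:
    """Patches of one class within one hexagon unit."""

    unit_id: int
    class_code: int
    patches: list[Patch]
    unit_land_area_m2: float  # non-nodata cell area inside the unit

    @property
    def n(self) -> int:
        return len(self.patches)

    @property
    def total_area_m2(self) -> float:
        return sum(p.area_m2 for p in self.patches)

    @property
    def total_edge_m(self) -> float:
        return sum(p.perimeter_m for p in self.patches)


_STRUCTURE = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]),
    8: np.ones((3, 3), dtype=int),
}


def _label_patches(mask: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    return ndimage.label(mask, structure=_STRUCTURE[connectivity])


def _patch_geometry(labels: np.ndarray, n_patches: int, cell_size: float) -> list[Patch]:
    """Cell counts and exposed-edge perimeters of every labelled patch."""
    counts = np.bincount(labels.ravel(), minlength=n_patches + 1)[1:]
    padded = np.pad(labels, 1, constant_values=0)
    same = np.zeros(n_patches + 1, dtype=np.int64)
    for shift in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        neighbor = np.roll(padded, shift, axis=(0, 1))
        match = (padded == neighbor) & (padded > 0)
        same += np.bincount(padded[match], minlength=n_patches + 1)
    exposed = 4 * counts - same[1:]
    return [
        Patch(area_m2=float(c) * cell_size**2, perimeter_m=float(e) * cell_size)
        for c, e in zip(counts, exposed)
    ]


def extract_patches(
    raster: CategoricalRaster,
    hexgrid: HexGrid,
    class_code: int,
    connectivity: Literal[4, 8] = 8,
    cell_units: np.ndarray | None = None,
) -> dict[int, PatchSet]:
    """Connected components of one class per hexagon unit.

    Components are clipped at hexagon boundaries (cells belong to the unit
    containing their center), so a patch spanning two units counts in both.
    Returns only units where the raster has any valid cells; units without
    the class get an empty PatchSet.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if cell_units is None:
        cell_units = assign_cells_to_hexagons(raster.grid, hexgrid)
    cell_area = raster.grid.cell_area_m2
    out: dict[int, PatchSet] = {}
    valid = raster.valid_mask
    for uid in hexgrid.ids:
        in_unit = cell_units == uid
        land = in_unit & valid
        if not land.any():
            continue
        mask = land & (raster.values == class_code)
        labels, n = _label_patches(mask, connectivity)
        out[uid] = PatchSet(
            unit_id=uid,
            class_code=class_code,
            patches=_patch_geometry(labels, n, raster.grid.cell_size),
            unit_land_area_m2=float(land.sum()) * cell_area,
        )
    return out


def compute_metrics(patches: PatchSet) -> dict[str, float] | None:
    """The five class-level metrics for one unit; None when the class is absent."""
    if patches.n == 0:
        return None
    ca_ha = patches.total_area_m2 / 10_000.0
    mpfd_vals, msi_vals = [], []
    for p in patches.patches:
        log_area = math.log(p.area_m2)
        mpfd_vals.append(2.0 * math.log(0.25 * p.perimeter_m) / log_area if log_area != 0 else 1.0)
        msi_vals.append(p.perimeter_m / (4.0 * math.sqrt(p.area_m2)))
    return {
        "CA": ca_ha,
        "MPS": ca_ha / patches.n,
        "ED": patches.total_edge_m / patches.unit_land_area_m2 * 10_000.0,
        "MPFD": float(np.mean(mpfd_vals)),
        "MSI": float(np.mean(msi_vals)),
    }


def metric_table(
    raster: CategoricalRaster,
    hexgrid: HexGrid,
    legend: ClassLegend,
    connectivity: Literal[4, 8] = 8,
) -> pd.DataFrame:
    """Per (unit, class) metric rows over the whole hexagon network."""
    cell_units = assign_cells_to_hexagons(raster.grid, hexgrid)
    rows = []
    for code in legend.codes:
        for uid, ps in extract_patches(raster, hexgrid, code, connectivity, cell_units).items():
            metrics = compute_metrics(ps)
            if metrics is None:
                continue
            rows.append({"unit": uid, "class": code, **metrics})
    if not rows:
        return pd.DataFrame(columns=["unit", "class", *METRICS])
    return pd.DataFrame(rows)


def normalize_metrics(
    table: pd.DataFrame,
    baseline: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Min–max normalization of each metric across units, per (class, metric).

    ``baseline`` supplies the min/max span instead (for comparing scenario maps
    against a baseline map on a common scale); values are clipped to [0, 1].
    Degenerate spans (max == min) normalize to 0.
    """
    ref = baseline if baseline is not None else table
    out = table.copy()
    for metric in METRICS:
        lo = ref.groupby("class")[metric].min()
        hi = ref.groupby("class")[metric].max()
        span = (hi - lo).replace(0, np.nan)
        z = (table[metric] - table["class"].map(lo)) / table["class"].map(span)
        out[metric] = z.fillna(0.0).clip(0.0, 1.0)
    return out


def assign_codes(z: float, suitable: bool, metric_group: int) -> int:
    """Degradation-intensity code K in {1..4} from a normalized metric value.

    Quartile bins are lower-closed, upper-open, the last closed. For
    unsuitable cover, more area (group 1) means more degradation (ascending
    codes) and the shape/edge group runs descending; for suitable cover the
    directions are mirrored.
    """
    if not 0.0 <= z <= 1.0:
        raise ValueError(f"Z value {z} outside [0, 1]")
    if metric_group not in (1, 2):
        raise ValueError("metric_group must be 1 (CA/MPS) or 2 (ED/MPFD/MSI)")
    q = min(int(z * 4), 3)  # 0..3 quartile index
    ascending = (not suitable and metric_group == 1) or (suitable and metric_group == 2)
    return q + 1 if ascending else 4 - q


def vulnerability(
    raster: CategoricalRaster,
    hexgrid: HexGrid,
    legend: ClassLegend,
    cell_units: np.ndarray | None = None,
) -> pd.Series:
    """Fraction of suitable cover per unit (the LD denominator before flooring)."""
    if cell_units is None:
        cell_units = assign_cells_to_hexagons(raster.grid, hexgrid)
    valid = raster.valid_mask
    suitable_mask = np.isin(raster.values, legend.suitable_codes()) & valid
    out = {}
    for uid in hexgrid.ids:
        in_unit = (cell_units == uid) & valid
        total = int(in_unit.sum())
        if total == 0:
            continue
        out[uid] = float((suitable_mask & in_unit).sum() / total)
    return pd.Series(out, name="V")


@dataclass
class DegradationResult:
    """Per-unit degradation table plus the underlying Z/K tables."""

    table: pd.DataFrame  # index: unit; columns: V, sum_KI, LD, group
    z_table: pd.DataFrame  # rows: (unit, class), columns: metrics
    k_table: pd.DataFrame

    @property
    def total_ld(self) -> float:
        return float(self.table["LD"].sum())


def ld_score(
    z_table: pd.DataFrame,
    legend: ClassLegend,
    V: pd.Series,
    weight_mode: Literal["class_weight", "z_value"] = "class_weight",
) -> DegradationResult:
    """Degradation score LD = Σ K·I / V per unit with four-group classification.

    ``weight_mode`` selects the interpretation of the metric weight I: the
    per-cover degradation index w(c) (default) or the normalized metric value
    itself.
    """
    k_rows = z_table.copy()
    for metric in METRICS:
        k_rows[metric] = [
            assign_codes(z, legend[int(c)].suitable, METRIC_GROUPS[metric])
            for z, c in zip(z_table[metric], z_table["class"])
        ]
    records = {}
    for uid, group in k_rows.groupby("unit"):
        if uid not in V.index:
            continue
        sum_ki = 0.0
        for _, row in group.iterrows():
            code = int(row["class"])
            for metric in METRICS:
                weight = legend.weight(code) if weight_mode == "class_weight" else float(
                    z_table.loc[row.name, metric]
                )
                sum_ki += float(row[metric]) * weight
        v_floored = max(float(V.loc[uid]), VULNERABILITY_FLOOR)
        records[uid] = {"V": float(V.loc[uid]), "sum_KI": sum_ki, "LD": sum_ki / v_floored}
    table = pd.DataFrame.from_dict(records, orient="index").sort_index()
    table.index.name = "unit"
    if len(table):
        quartiles = table["LD"].rank(pct=True, method="average")
        table["group"] = np.minimum((quartiles * 4).apply(math.ceil), 4).astype(int)
    else:
        table["group"] = pd.Series(dtype=int)
    return DegradationResult(table=table, z_table=z_table, k_table=k_rows)


def degradation_scores(
    raster: CategoricalRaster,
    hexgrid: HexGrid,
    legend: ClassLegend,
    baseline_metrics: pd.DataFrame | None = None,
    connectivity: Literal[4, 8] = 8,
    weight_mode: Literal["class_weight", "z_value"] = "class_weight",
) -> DegradationResult:
    """End-to-end per-unit degradation scoring of one categorical map."""
    metrics = metric_table(raster, hexgrid, legend, connectivity)
    z = normalize_metrics(metrics, baseline=baseline_metrics)
    v = vulnerability(raster, hexgrid, legend)
    return ld_score(z, legend, v, weight_mode=weight_mode)
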
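"""Driver-variable construction and explanatory-power screening.

Candidate drivers of land-cover change (terrain, distances to features,
evidence likelihood of past change) are screened against the class map with
Cramer's V,

    V = sqrt( (chi² / n) / min(k - 1, r - 1) ),

computed on the driver × class contingency table; continuous drivers are
discretized into equal-count bins first. V lies in [0, 1]: 0 for no
association, 1 for complete association. Higher V means better explanatory
potential; drivers at or above a configurable threshold are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .raster_core import (
    CategoricalRaster,
    ContinuousRaster,
    GridAlignmentError,
    GridSpec,
)

__all__ = [
    "CramersVResult",
    "distance_raster",
    "evidence_likelihood",
    "cramers_v",
    "screen_drivers",
]

DEFAULT_RETENTION_THRESHOLD = 0.15


@dataclass
class CramersVResult:
    overall_V: float
    chi_square: float
    n: int
    n_bins: int
    per_class_V: dict[int, float]
    degenerate: bool = False

    def to_series(self) -> pd.Series:
        data = {f"class_{c}": v for c, v in self.per_class_V.items()}
        data["overall_V"] = self.overall_V
        return pd.Series(data)


def distance_raster(mask: CategoricalRaster, grid: GridSpec | None = None) -> ContinuousRaster:
    """Euclidean distance (meters, center to center) to the nearest target cell
    of a binary mask; zero on targets."""
    grid = grid or mask.grid
    target = (mask.values != 0) & mask.valid_mask
    if not target.any():
        raise ValueError("distance raster undefined: mask has no target cells")
    dist = ndimage.distance_transform_edt(~target, sampling=grid.cell_size)
    return ContinuousRaster(grid, dist)


def evidence_likelihood(
    change_mask: CategoricalRaster, categorical_var: CategoricalRaster
) -> ContinuousRaster:
    """Relative frequency of change per category of a categorical variable.

    Each cell receives changed_c / total_c for its category c — the empirical
    likelihood that cells like it changed during the calibration period.
    """
    if change_mask.grid != categorical_var.grid:
        raise GridAlignmentError("change mask and variable grids differ")
    valid = change_mask.valid_mask & categorical_var.valid_mask
    out = np.full(change_mask.grid.shape, float(categorical_var.nodata_code))
    cats = np.unique(categorical_var.values[valid])
    changed = (change_mask.values != 0) & valid
    for c in cats:
        in_cat = (categorical_var.values == c) & valid
        out[in_cat] = changed[in_cat].sum() / in_cat.sum()
    return ContinuousRaster(
        change_mask.grid, out, nodata_value=float(categorical_var.nodata_code)
    )


def _equal_count_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into at most n_bins equal-count bins (robust to ties)."""
    quantiles = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(np.unique(quantiles), values, side="right")


def cramers_v_from_table(table: np.ndarray) -> tuple[float, float, int]:
    """(V, chi², n) for a contingency table; zero-total rows/columns dropped."""
    table = np.asarray(table, dtype=np.float64)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    n = table.sum()
    k, r = table.shape
    if n == 0 or min(k, r) < 2:
        return 0.0, 0.0, int(n)
    chi2 = stats.chi2_contingency(table, correction=False).statistic
    v = float(np.sqrt((chi2 / n) / min(k - 1, r - 1)))
    return min(v, 1.0), float(chi2), int(n)


def _contingency(var_idx: np.ndarray, cls_idx: np.ndarray, n_var: int, n_cls: int) -> np.ndarray:
    return np.bincount(var_idx * n_cls + cls_idx, minlength=n_var * n_cls).reshape(n_var, n_cls)


def cramers_v(
    variable: ContinuousRaster | CategoricalRaster,
    class_map: CategoricalRaster,
    n_bins: int = 256,
) -> CramersVResult:
    """Cramer's V between a driver variable and a categorical class map.

    Continuous variables are binned into ``n_bins`` equal-count bins. The
    per-class values test each class against the rest (dichotomy).
    """
    if variable.grid != class_map.grid:
        raise GridAlignmentError("variable and class map grids differ")
    valid = variable.valid_mask & class_map.valid_mask
    cls_vals = class_map.values[valid]
    var_vals = variable.values[valid]
    if isinstance(variable, CategoricalRaster):
        var_codes, var_idx = np.unique(var_vals, return_inverse=True)
    else:
        binned = _equal_count_bins(var_vals, n_bins)
        var_codes, var_idx = np.unique(binned, return_inverse=True)
    cls_codes, cls_idx = np.unique(cls_vals, return_inverse=True)
    degenerate = len(var_codes) < 2 or len(cls_codes) < 2
    table = _contingency(var_idx, cls_idx, len(var_codes), len(cls_codes))
    overall_v, chi2, n = cramers_v_from_table(table)
    per_class: dict[int, float] = {}
    for j, code in enumerate(cls_codes):
        dich = np.column_stack([table[:, j], table.sum(axis=1) - table[:, j]])
        per_class[int(code)], _, _ = cramers_v_from_table(dich)
    return CramersVResult(
        overall_V=overall_v,
        chi_square=chi2,
        n=n,
        n_bins=len(var_codes),
        per_class_V=per_class,
        degenerate=degenerate,
    )


def screen_drivers(
    variables: dict[str, ContinuousRaster | CategoricalRaster],
    class_map: CategoricalRaster,
    n_bins: int = 256,
    threshold: float = DEFAULT_RETENTION_THRESHOLD,
) -> pd.DataFrame:
    """Rank driver variables by overall Cramer's V, flagging those retained.

    Returns a DataFrame (one row per driver, sorted by descending overall V)
    shaped like the per-class/overall screening tables used in land-change
    studies.
    """
    rows = {}
    for name, var in variables.items():
        res = cramers_v(var, class_map, n_bins=n_bins)
        rows[name] = res.to_series()
    df = pd.DataFrame(rows).T.sort_values("overall_V", ascending=False)
    df["retained"] = df["overall_V"] >= threshold
    return df
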
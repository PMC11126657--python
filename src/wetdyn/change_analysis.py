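"""Gains/losses/net-change accounting and spatial trend surfaces.

Change between two dates is summarized from the transition cross-tabulation:
a class's gain is everything that became it (column total minus diagonal),
its loss everything it became (row total minus diagonal), in hectares. The
spatial trend of a particular change (e.g. water to anything) is a low-order
polynomial surface least-squares fitted to the 0/1 change indicator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov_projection import TransitionCountMatrix
from .raster_core import CategoricalRaster, ContinuousRaster

__all__ = ["ChangeSummary", "gains_losses", "annual_rate", "spatial_trend"]


@dataclass
class ChangeSummary:
    class_order: list[int]
    gain_ha: np.ndarray
    loss_ha: np.ndarray
    transition_area_ha: np.ndarray  # full M×M matrix in hectares

    @property
    def net_ha(self) -> np.ndarray:
        return self.gain_ha - self.loss_ha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gain_ha": self.gain_ha, "loss_ha": self.loss_ha, "net_ha": self.net_ha},
            index=self.class_order,
        )


def gains_losses(ct: TransitionCountMatrix, cell_area_ha: float) -> ChangeSummary:
    """Per-class gains, losses and net change in hectares from transition counts."""
    counts = np.asarray(ct.counts, dtype=np.float64)
    diag = np.diag(counts)
    gain = (counts.sum(axis=0) - diag) * cell_area_ha
    loss = (counts.sum(axis=1) - diag) * cell_area_ha
    return ChangeSummary(
        class_order=list(ct.class_order),
        gain_ha=gain,
        loss_ha=loss,
        transition_area_ha=counts * cell_area_ha,
    )


def annual_rate(area_t1: float, area_t2: float, years: float) -> float:
    """Continuous-compounding annual rate of change r = ln(A2/A1)/t.

    Negative for decline. Other conventions exist (simple percentage of the
    initial area, geometric rate); this form is exact under exponential
    growth/decay and is the package default.
    """
    if area_t1 <= 0 or area_t2 <= 0:
        raise ValueError("areas must be positive")
    if years <= 0:
        raise ValueError("years must be positive")
    return float(np.log(area_t2 / area_t1) / years)


def _poly_terms(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    cols = [x**i * y**j for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.column_stack(cols)


def spatial_trend(change_mask: CategoricalRaster, degree: int = 3) -> ContinuousRaster:
    """Polynomial trend surface of a binary change indicator.

    Fits a degree-``degree`` polynomial in the cell-center coordinates to the
    0/1 mask by least squares and evaluates it over the whole grid. Coordinates
    are rescaled to [-1, 1] before fitting for conditioning.
    """
    if not 1 <= degree <= 9:
        raise ValueError("degree must be between 1 and 9")
    grid = change_mask.grid
    xs, ys = grid.cell_centers()
    valid = change_mask.valid_mask
    z = (change_mask.values[valid] != 0).astype(np.float64)
    n_terms = (degree + 1) * (degree + 2) // 2
    if z.size < n_terms:
        raise np.linalg.LinAlgError(
            f"{z.size} observations cannot determine {n_terms} polynomial terms"
        )

    def rescale(v: np.ndarray) -> np.ndarray:
        lo, hi = v.min(), v.max()
        return np.zeros_like(v) if hi == lo else 2 * (v - lo) / (hi - lo) - 1

    xn, yn = rescale(xs), rescale(ys)
    A = _poly_terms(xn[valid], yn[valid], degree)
    coeffs, *_ = np.linalg.lstsq(A, z, rcond=None)
    surface = _poly_terms(xn.ravel(), yn.ravel(), degree) @ coeffs
    return ContinuousRaster(grid, surface.reshape(grid.shape))
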
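"""Synthetic landscapes with known Markov dynamics and driver effects.

Real multi-decade land-cover map series for the wetland are rarely
redistributable, so this module generates three-date categorical raster
series whose statistical structure is known exactly: each cell's class at
date t+1 is drawn from the row of a true transition matrix for its class at
date t, optionally with the destination log-odds shifted by coefficients on
standardized driver rasters. The generator therefore provides ground truth
for transition-probability recovery, driver screening, MLP skill and
allocation bookkeeping tests.

Default conditions: five cover classes (sparse vegetation, water, humid
land, dense vegetation, salt land), a 200×200 grid of 30 m cells, a true
transition matrix taken from a published 15-year wetland area-transition
tabulation (row-normalized), and initial class fractions proportional to
that tabulation's row totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .markov_projection import TransitionCountMatrix
from .raster_core import (
    CategoricalRaster,
    ClassLegend,
    ContinuousRaster,
    GridSpec,
    crosstab,
    default_legend,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "TABLE5_COUNTS",
    "default_config",
    "generate_drivers",
    "generate_series",
    "truth_transition_matrix",
]

# 15-year wetland area-transition tabulation (area units), rows/cols ordered
# sparse vegetation, water, humid land, dense vegetation, salt land.
TABLE5_COUNTS = np.array(
    [
        [1_237_843, 15_816, 854_004, 86_438, 7_547],
        [96_349, 124_925, 341_910, 77_682, 18_411],
        [1_439_380, 1_302, 3_391_711, 40_659, 22_543],
        [224_941, 116_193, 345_128, 492_394, 295],
        [21_280, 8, 1_560, 230, 1_600],
    ],
    dtype=np.float64,
)


@dataclass
class SyntheticConfig:
    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(200, 200, 30.0))
    class_codes: tuple[int, ...] = (1, 2, 3, 4, 5)
    true_P: np.ndarray = field(default_factory=lambda: TABLE5_COUNTS / TABLE5_COUNTS.sum(axis=1, keepdims=True))
    # (from_code, to_code) -> {driver_name: coefficient beta}
    driver_effects: Mapping[tuple[int, int], Mapping[str, float]] = field(default_factory=dict)
    initial_fractions: np.ndarray = field(
        default_factory=lambda: TABLE5_COUNTS.sum(axis=1) / TABLE5_COUNTS.sum()
    )
    smoothing_scale: float = 8.0  # cells; controls patch size of random fields

    def __post_init__(self) -> None:
        self.true_P = np.asarray(self.true_P, dtype=np.float64)
        m = len(self.class_codes)
        if self.true_P.shape != (m, m):
            raise ValueError("true_P must be M×M over class_codes")
        if np.any(self.true_P < 0):
            raise ValueError("true_P entries must be non-negative")
        if not np.allclose(self.true_P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of true_P must sum to 1 within 1e-12")
        self.initial_fractions = np.asarray(self.initial_fractions, dtype=np.float64)
        if self.initial_fractions.shape != (m,):
            raise ValueError("initial_fractions length must match class_codes")
        if not np.isclose(self.initial_fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_fractions must sum to 1")
        if self.grid.n_rows < 4 or self.grid.n_cols < 4:
            raise ValueError("grid must be at least 4×4")


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    return SyntheticConfig(seed=seed, **overrides)


@dataclass
class SyntheticTruth:
    """Generator ground truth: the config plus realized counts per date/step."""

    config: SyntheticConfig
    class_counts: list[dict[int, int]]
    transition_counts: list[TransitionCountMatrix]

    @property
    def true_P(self) -> np.ndarray:
        return self.config.true_P


def _smooth_field(rng: np.random.Generator, grid: GridSpec, scale: float) -> np.ndarray:
    noise = rng.standard_normal(grid.shape)
    field_ = ndimage.gaussian_filter(noise, sigma=scale, mode="reflect")
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _random_polyline_mask(rng: np.random.Generator, grid: GridSpec) -> np.ndarray:
    """Rasterize a meandering path crossing the grid top to bottom."""
    mask = np.zeros(grid.shape, dtype=bool)
    col = int(rng.integers(grid.n_cols // 4, 3 * grid.n_cols // 4))
    for row in range(grid.n_rows):
        col = int(np.clip(col + rng.integers(-1, 2), 0, grid.n_cols - 1))
        mask[row, col] = True
    return mask


def _distance_to(mask: np.ndarray, cell_size: float) -> np.ndarray:
    return ndimage.distance_transform_edt(~mask, sampling=cell_size)


def generate_drivers(config: SyntheticConfig) -> dict[str, ContinuousRaster]:
    """Deterministic driver set: a smooth DEM, its slope, and distances to a
    random river and road polyline."""
    grid = config.grid
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    dem_values = 50.0 * _smooth_field(rng, grid, config.smoothing_scale) + 100.0
    gy, gx = np.gradient(dem_values, grid.cell_size)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    river = _random_polyline_mask(rng, grid)
    road = _random_polyline_mask(rng, grid)
    return {
        "dem": ContinuousRaster(grid, dem_values),
        "slope": ContinuousRaster(grid, slope),
        "dist_river": ContinuousRaster(grid, _distance_to(river, grid.cell_size)),
        "dist_road": ContinuousRaster(grid, _distance_to(road, grid.cell_size)),
    }


def _initial_map(rng: np.random.Generator, config: SyntheticConfig) -> np.ndarray:
    """Threshold a smoothed field at the cumulative class fractions so the
    initial map has spatially contiguous patches with the requested areas."""
    field_ = _smooth_field(rng, config.grid, config.smoothing_scale)
    ranks = field_.ravel().argsort(kind="stable").argsort(kind="stable")
    quantiles = ranks / (ranks.size - 1) if ranks.size > 1 else np.zeros_like(ranks, dtype=float)
    edges = np.cumsum(config.initial_fractions)[:-1]
    idx = np.searchsorted(edges, quantiles.reshape(config.grid.shape), side="right")
    codes = np.asarray(config.class_codes)
    return codes[idx]


def _standardize(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)


def _step(
    rng: np.random.Generator,
    current: np.ndarray,
    config: SyntheticConfig,
    z_drivers: Mapping[str, np.ndarray],
) -> np.ndarray:
    """Draw each cell's next class from its row of true_P, with destination
    log-odds shifted by beta·z(drivers) where effects are configured."""
    codes = list(config.class_codes)
    nxt = current.copy()
    for i, code in enumerate(codes):
        cells = current == code
        n = int(cells.sum())
        if n == 0:
            continue
        base = config.true_P[i]
        effects = {j: config.driver_effects.get((code, codes[j])) for j in range(len(codes))}
        if any(e for e in effects.values()):
            with np.errstate(divide="ignore"):
                logits = np.where(base > 0, np.log(np.maximum(base, 1e-300)), -np.inf)
            logit_field = np.broadcast_to(logits, (n, len(codes))).copy()
            for j, eff in effects.items():
                if not eff:
                    continue
                shift = np.zeros(n)
                for name, beta in eff.items():
                    shift += beta * z_drivers[name][cells]
                logit_field[:, j] = logit_field[:, j] + shift
            probs = np.exp(logit_field - logit_field.max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            u = rng.random((n, 1))
            draws = (probs.cumsum(axis=1) < u).sum(axis=1)
        else:
            draws = rng.choice(len(codes), size=n, p=base)
        nxt[cells] = np.asarray(codes)[draws]
    return nxt


def generate_series(
    config: SyntheticConfig,
    drivers: Mapping[str, ContinuousRaster] | None = None,
    legend: ClassLegend | None = None,
) -> tuple[list[CategoricalRaster], SyntheticTruth]:
    """Three-date categorical series (roles of e.g. 1985/2000/2015) plus truth.

    Both steps use the same true transition matrix. Fixed seed gives
    bit-identical output.
    """
    if drivers is None:
        drivers = generate_drivers(config)
    if legend is None and tuple(config.class_codes) == (1, 2, 3, 4, 5):
        legend = default_legend()
    z_drivers = {name: _standardize(r.values) for name, r in drivers.items()}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    maps = [_initial_map(rng, config)]
    for _ in range(2):
        maps.append(_step(rng, maps[-1], config, z_drivers))
    rasters = [CategoricalRaster(config.grid, m, legend=legend) for m in maps]
    counts = [r.class_counts(list(config.class_codes)) for r in rasters]
    transitions = [
        crosstab(rasters[k], rasters[k + 1], codes=list(config.class_codes)) for k in range(2)
    ]
    return rasters, SyntheticTruth(config=config, class_counts=counts, transition_counts=transitions)


def truth_transition_matrix(truth: SyntheticTruth, step: int) -> TransitionCountMatrix:
    """Realized transition counts for step 0 (t0→t1) or 1 (t1→t2)."""
    if step not in (0, 1):
        raise ValueError("step must be 0 or 1")
    return truth.transition_counts[step]
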
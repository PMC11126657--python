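"""Allocation engines: turning transition demands into a simulated map.

Two engines are provided.

MOLA (multi-objective land allocation): every enabled transition ranks its
eligible cells (cells currently in its source class) by transition
potential; cells are then granted greedily in order of decreasing potential
subject to each transition's demand quota and to each cell changing at most
once. When two transitions claim the same cell, the one with the higher
potential for that cell wins and the other refills from its next-ranked
candidate — exactly the behaviour of processing all (cell, transition)
claims in one global potential ordering. Ties break deterministically by
(row, col, transition order), with an optional seeded jitter.

CA-Markov: the Markov demand for each transition is split evenly over a
number of iterations (largest-remainder rounding); at each iteration the
suitability of each candidate cell is weighted by the proportion of the
destination class inside a square contiguity window (default 5×5) of the
current map, so growth clings to existing patches, and cells are allocated
by rank. Candidates with zero weighted score still rank (by row/col order)
so the projected class budget is met even where a destination class has no
neighbours yet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .markov_projection import (
    TransitionProbMatrix,
    largest_remainder_round,
    transition_demand,
)
from .raster_core import CategoricalRaster, GridAlignmentError
from .transition_mlp import TransitionPotentialStack

__all__ = [
    "SimulatedMap",
    "mola_allocate",
    "ca_markov_simulate",
    "frequency_suitability",
]


@dataclass
class SimulatedMap:
    raster: CategoricalRaster
    allocated: dict[tuple[int, int], int]
    unmet_demand: dict[tuple[int, int], int]

    @property
    def total_changed(self) -> int:
        return sum(self.allocated.values())


def _ranked_candidates(
    potential: np.ndarray,
    eligible: np.ndarray,
    jitter: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Flat indices of eligible cells sorted by potential desc, then row/col."""
    idx = np.flatnonzero(eligible)
    pot = potential.ravel()[idx]
    if jitter is not None:
        pot = pot + jitter.ravel()[idx]
    order = np.lexsort((idx, -pot))
    return idx[order], pot[order]


def mola_allocate(
    map_t: CategoricalRaster,
    potentials: TransitionPotentialStack,
    demands: Mapping[tuple[int, int], int],
    seed: int | None = None,
    jitter_scale: float = 0.0,
) -> SimulatedMap:
    """Rank-based multi-objective allocation of transition demands.

    Demand exceeding the eligible cell pool is allocated as far as possible
    and the shortfall reported in ``unmet_demand``.
    """
    grid = map_t.grid
    transitions = [t for t in demands if demands[t] > 0]
    for t in transitions:
        if t not in potentials.potentials:
            raise KeyError(f"no potential surface for transition {t}")
        if potentials.potentials[t].grid != grid:
            raise GridAlignmentError("potential grids must match the input map")
    jitter = None
    if jitter_scale > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-jitter_scale, jitter_scale, size=grid.shape)

    # Build one global claim list: (potential desc, flat index, transition order).
    claim_pot: list[np.ndarray] = []
    claim_idx: list[np.ndarray] = []
    claim_tr: list[np.ndarray] = []
    for k, tr in enumerate(transitions):
        f, _ = tr
        surf = potentials.potentials[tr]
        eligible = (map_t.values == f) & map_t.valid_mask & surf.valid_mask
        idx, pot = _ranked_candidates(surf.values, eligible, jitter)
        claim_idx.append(idx)
        claim_pot.append(pot)
        claim_tr.append(np.full(len(idx), k, dtype=np.int64))
    if transitions:
        all_idx = np.concatenate(claim_idx)
        all_pot = np.concatenate(claim_pot)
        all_tr = np.concatenate(claim_tr)
        order = np.lexsort((all_tr, all_idx, -all_pot))
    else:
        order = np.array([], dtype=np.int64)

    out = map_t.values.copy()
    taken = np.zeros(out.size, dtype=bool)
    remaining = {tr: int(demands[tr]) for tr in transitions}
    allocated = {tr: 0 for tr in demands}
    active = len([tr for tr in transitions if remaining[tr] > 0])
    for pos in order:
        if active == 0:
            break
        tr = transitions[all_tr[pos]]
        if remaining[tr] == 0:
            continue
        cell = all_idx[pos]
        if taken[cell]:
            continue
        taken[cell] = True
        out.ravel()[cell] = tr[1]
        remaining[tr] -= 1
        allocated[tr] += 1
        if remaining[tr] == 0:
            active -= 1
    unmet = {tr: int(demands[tr]) - allocated[tr] for tr in demands if demands[tr] - allocated[tr] > 0}
    raster = CategoricalRaster(grid, out, nodata_code=map_t.nodata_code, legend=map_t.legend)
    return SimulatedMap(raster=raster, allocated=allocated, unmet_demand=unmet)


def frequency_suitability(
    P: TransitionProbMatrix,
    grid,
    transitions: Sequence[tuple[int, int]],
) -> TransitionPotentialStack:
    """Spatially flat suitability equal to the calibrated transition frequency.

    Used as the CA-Markov base suitability so the engine stays independent of
    the MLP; the contiguity filter supplies all spatial differentiation.
    """
    from .raster_core import ContinuousRaster

    out = {}
    for f, t in transitions:
        out[(f, t)] = ContinuousRaster(grid, np.full(grid.shape, P.prob(f, t)))
    return TransitionPotentialStack(potentials=out, provenance="frequency")


def _neighborhood_fraction(values: np.ndarray, valid: np.ndarray, code: int, size: int) -> np.ndarray:
    """Fraction of valid cells of ``code`` in a size×size window, clipped at edges."""
    is_code = ((values == code) & valid).astype(np.float64)
    ones = valid.astype(np.float64)
    num = ndimage.uniform_filter(is_code, size=size, mode="constant", cval=0.0)
    den = ndimage.uniform_filter(ones, size=size, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / den, 0.0)
    return frac


def ca_markov_simulate(
    map_t: CategoricalRaster,
    P: TransitionProbMatrix,
    suitabilities: TransitionPotentialStack | None = None,
    iterations: int = 10,
    filter_size: int = 5,
    seed: int | None = None,
    enabled: Sequence[tuple[int, int]] | None = None,
) -> SimulatedMap:
    """Cellular-automata Markov simulation of one calibration step.

    Meets the Markov-projected per-transition demands over ``iterations``
    rounds; each round weights suitability by the destination-class proportion
    in the contiguity window before rank allocation.
    """
    if filter_size % 2 == 0 or filter_size < 1:
        raise ValueError("filter_size must be an odd positive integer")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    grid = map_t.grid
    if enabled is None:
        enabled = [
            (f, t)
            for f in P.class_order
            for t in P.class_order
            if f != t and P.prob(f, t) > 0
        ]
    demands = transition_demand(P, map_t, list(enabled))
    if suitabilities is None:
        suitabilities = frequency_suitability(P, grid, list(enabled))

    # Split each transition's demand across iterations, largest remainder.
    per_iter: dict[tuple[int, int], np.ndarray] = {
        tr: largest_remainder_round(np.ones(iterations), d) for tr, d in demands.items()
    }
    current = map_t.copy()
    allocated_total = {tr: 0 for tr in demands}
    changed_from_start = np.zeros(grid.shape, dtype=bool)
    for it in range(iterations):
        step_demands = {tr: int(per_iter[tr][it]) for tr in demands}
        # carry forward any unmet demand from earlier iterations
        for tr in demands:
            deficit = int(per_iter[tr][:it].sum()) - (allocated_total[tr] - 0) if it else 0
            if deficit > 0:
                step_demands[tr] += deficit
        weighted = {}
        valid = current.valid_mask
        frac_cache: dict[int, np.ndarray] = {}
        for tr in demands:
            f, t = tr
            if t not in frac_cache:
                frac_cache[t] = _neighborhood_fraction(current.values, valid, t, filter_size)
            base = suitabilities.potentials[tr]
            from .raster_core import ContinuousRaster

            weighted[tr] = ContinuousRaster(grid, base.values * frac_cache[t], nodata_value=base.nodata_value)
        stack = TransitionPotentialStack(potentials=weighted, provenance=suitabilities.provenance)
        # freeze cells already changed so each cell transitions at most once
        frozen = current.copy()
        frozen.values = np.where(changed_from_start, map_t.nodata_code, current.values)
        step = mola_allocate(frozen, stack, step_demands, seed=seed)
        newly = step.raster.values != frozen.values
        vals = current.values.copy()
        vals[newly] = step.raster.values[newly]
        current = CategoricalRaster(grid, vals, nodata_code=map_t.nodata_code, legend=map_t.legend)
        changed_from_start |= newly
        for tr, k in step.allocated.items():
            allocated_total[tr] += k
    unmet = {tr: demands[tr] - allocated_total[tr] for tr in demands if demands[tr] > allocated_total[tr]}
    return SimulatedMap(raster=current, allocated=allocated_total, unmet_demand=unmet)
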
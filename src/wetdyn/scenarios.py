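"""Scenario definitions and the end-to-end pipeline runner.

Three built-in management scenarios describe the 15-year horizon:

* Water Conservation — only transitions of the other covers into water are
  enabled (sparse vegetation, dense vegetation, humid land and salt land to
  water).
* Water Decreasing — only transitions out of water are enabled (water to
  sparse vegetation, dense vegetation, humid land and salt land).
* Business as Usual — the eight calibration sub-model transitions: water to
  sparse/dense vegetation, humid land and salt land; humid land to sparse
  vegetation; dense vegetation to sparse vegetation and humid land; salt
  land to humid land.

``run_scenario`` chains the full pipeline on a calibrated map pair: MLP
transition potentials per source class, Markov demand projection, allocation
(MOLA or CA-Markov), and hexagonal degradation scoring of the simulated map.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Literal, Mapping

from .allocation import SimulatedMap, ca_markov_simulate, mola_allocate
from .degradation import DegradationResult, HexGrid, build_hexgrid, degradation_scores
from .markov_projection import estimate_transition_probs, transition_demand
from .raster_core import CategoricalRaster, ClassLegend, ContinuousRaster, crosstab, default_legend
from .transition_mlp import (
    MlpConfig,
    SubModel,
    TransitionPotentialStack,
    predict_potentials,
    sample_training_pixels,
    train_mlp,
)

__all__ = ["ScenarioSpec", "builtin_scenarios", "run_scenario", "ScenarioResult"]

logger = logging.getLogger(__name__)

SPARSE, WATER, HUMID, DENSE, SALT = 1, 2, 3, 4, 5


@dataclass(frozen=True)
class ScenarioSpec:
    name: str
    transitions: tuple[tuple[int, int], ...]
    demand_multiplier: Mapping[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f, t in self.transitions:
            if f == t:
                raise ValueError("scenario transitions must have from != to")


def builtin_scenarios() -> list[ScenarioSpec]:
    """The three built-in 2030-horizon scenarios (4, 4 and 8 transitions)."""
    return [
        ScenarioSpec(
            name="water_conservation",
            transitions=(
                (SPARSE, WATER),
                (DENSE, WATER),
                (HUMID, WATER),
                (SALT, WATER),
            ),
        ),
        ScenarioSpec(
            name="water_decreasing",
            transitions=(
                (WATER, SPARSE),
                (WATER, DENSE),
                (WATER, HUMID),
                (WATER, SALT),
            ),
        ),
        ScenarioSpec(
            name="business_as_usual",
            transitions=(
                (WATER, SPARSE),
                (WATER, DENSE),
                (WATER, HUMID),
                (WATER, SALT),
                (HUMID, SPARSE),
                (DENSE, SPARSE),
                (DENSE, HUMID),
                (SALT, HUMID),
            ),
        ),
    ]


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    simulated: SimulatedMap
    degradation: DegradationResult
    potentials: TransitionPotentialStack | None
    demands: dict[tuple[int, int], int]
    stage_seconds: dict[str, float]


def run_scenario(
    map_t1: CategoricalRaster,
    map_t2: CategoricalRaster,
    drivers: Mapping[str, ContinuousRaster],
    spec: ScenarioSpec,
    engine: Literal["mola", "camc"] = "mola",
    horizon_steps: int = 1,
    seed: int = 0,
    legend: ClassLegend | None = None,
    hexgrid: HexGrid | None = None,
    unit_area_ha: float = 40_000.0,
    mlp_config: MlpConfig | None = None,
    n_per_class: int = 500,
    baseline_metrics=None,
) -> ScenarioResult:
    """Simulate a scenario one (or more) steps past the calibration pair and
    score degradation on the result. Deterministic for fixed seed and config."""
    legend = legend or map_t2.legend or default_legend()
    if hexgrid is None:
        hexgrid = build_hexgrid(map_t2.grid, unit_area_ha)
    timings: dict[str, float] = {}

    def stage(name: str):
        logger.info("scenario %s: stage %s", spec.name, name)
        timings[name] = time.perf_counter()
        return name

    def done(name: str) -> None:
        timings[name] = time.perf_counter() - timings[name]

    stage("calibrate")
    ct = crosstab(map_t1, map_t2, codes=legend.codes)
    P = estimate_transition_probs(ct)
    done("calibrate")

    idx = {c: i for i, c in enumerate(ct.class_order)}
    active = tuple(
        tr for tr in spec.transitions if ct.counts[idx[tr[0]], idx[tr[1]]] > 0
    )
    for tr in spec.transitions:
        if tr not in active:
            logger.warning(
                "scenario %s: transition %s unobserved in calibration; skipped", spec.name, tr
            )
    if not active:
        degr = degradation_scores(map_t2, hexgrid, legend, baseline_metrics=baseline_metrics)
        return ScenarioResult(
            spec=spec,
            simulated=SimulatedMap(raster=map_t2.copy(), allocated={}, unmet_demand={}),
            degradation=degr,
            potentials=None,
            demands={},
            stage_seconds=timings,
        )

    stage("demand")
    demands = transition_demand(P, map_t2, list(active))
    for tr, mult in spec.demand_multiplier.items():
        if tr in demands:
            demands[tr] = int(round(demands[tr] * mult))
    done("demand")

    potentials: TransitionPotentialStack | None = None
    if engine == "mola":
        stage("train")
        surfaces = {}
        by_from: dict[int, list[tuple[int, int]]] = {}
        for tr in active:
            by_from.setdefault(tr[0], []).append(tr)
        for k, (f, transitions) in enumerate(sorted(by_from.items())):
            submodel = SubModel(
                transitions=tuple(transitions),
                driver_names=tuple(sorted(drivers)),
                name=f"from_{f}",
            )
            ts = sample_training_pixels(
                submodel, map_t1, map_t2, drivers, n_per_class=n_per_class, seed=seed + k
            )
            cfg = mlp_config or MlpConfig(seed=seed + k)
            model, report = train_mlp(ts, cfg)
            logger.info(
                "sub-model from class %d: accuracy %.3f skill %.3f",
                f,
                report.accuracy_rate,
                report.skill,
            )
            surfaces.update(predict_potentials(model, drivers).potentials)
        potentials = TransitionPotentialStack(potentials=surfaces, provenance="mlp")
        done("train")

        stage("allocate")
        sim = None
        current = map_t2
        for _ in range(horizon_steps):
            sim = mola_allocate(current, potentials, demands, seed=seed)
            current = sim.raster
        done("allocate")
    elif engine == "camc":
        stage("allocate")
        sim = None
        current = map_t2
        for _ in range(horizon_steps):
            sim = ca_markov_simulate(
                current, P, iterations=10, filter_size=5, seed=seed, enabled=list(active)
            )
            current = sim.raster
        done("allocate")
    else:
        raise ValueError(f"unknown engine {engine!r}")

    stage("degrade")
    degr = degradation_scores(sim.raster, hexgrid, legend, baseline_metrics=baseline_metrics)
    done("degrade")
    return ScenarioResult(
        spec=spec,
        simulated=sim,
        degradation=degr,
        potentials=potentials,
        demands=demands,
        stage_seconds=timings,
    )
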
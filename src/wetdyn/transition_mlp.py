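"""Transition-potential modelling with a multi-layer perceptron.

Each sub-model groups one or more class-to-class transitions that share a
driver set. Training pixels are a balanced sample of cells that underwent
each transition during the calibration interval plus cells of the source
classes that persisted, so the network learns to discriminate change from
staying put. The network is a single-hidden-layer perceptron with logistic
activations trained by stochastic gradient descent with momentum 0.5 for up
to 10,000 iterations (the conventions of land-change transition modelling);
the hidden layer defaults to round(sqrt(inputs · outputs)) nodes.

The fitted model is evaluated on a held-out half of the sample with an
accuracy rate and a skill statistic

    S = (A − E) / (1 − E),  E = 1 / n_outputs,

i.e. accuracy rescaled so 0 is the expected accuracy of uniformly random
assignment over the output categories and 1 is perfect. Applying the model
to the full driver stack yields one transition-potential surface in [0, 1]
per transition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier

from .raster_core import CategoricalRaster, ContinuousRaster, GridAlignmentError

__all__ = [
    "SubModel",
    "TrainingSet",
    "MlpConfig",
    "MlpModel",
    "TrainingReport",
    "TransitionPotentialStack",
    "sample_training_pixels",
    "train_mlp",
    "predict_potentials",
    "skill_statistic",
]


@dataclass(frozen=True)
class SubModel:
    """Transitions modelled together with one shared driver set."""

    transitions: tuple[tuple[int, int], ...]
    driver_names: tuple[str, ...]
    name: str = ""

    def __post_init__(self) -> None:
        for f, t in self.transitions:
            if f == t:
                raise ValueError("sub-model transitions must have from != to")
        if not self.transitions:
            raise ValueError("sub-model needs at least one transition")

    @property
    def from_classes(self) -> tuple[int, ...]:
        return tuple(sorted({f for f, _ in self.transitions}))


@dataclass
class TrainingSet:
    """Sampled pixels: driver features plus an output label per pixel.

    Labels 0..T-1 are the sub-model's transitions in order; labels T..T+F-1
    are persistence of each source class.
    """

    submodel: SubModel
    X_train: np.ndarray
    y_train: np.ndarray
    X_valid: np.ndarray
    y_valid: np.ndarray
    output_labels: list[str]

    @property
    def n_outputs(self) -> int:
        return len(self.output_labels)


@dataclass
class MlpConfig:
    hidden_nodes: int | None = None  # default round(sqrt(inputs*outputs))
    iterations: int = 10_000
    momentum: float = 0.5
    learning_rate: float = 0.01
    seed: int = 0


@dataclass
class TrainingReport:
    accuracy_rate: float
    skill: float
    per_output_accuracy: dict[str, float]
    n_train: int
    n_valid: int


@dataclass
class MlpModel:
    submodel: SubModel
    classifier: MLPClassifier
    feature_means: np.ndarray
    feature_stds: np.ndarray
    output_labels: list[str]
    config: MlpConfig

    def save_json(self, path: str | Path) -> None:
        """Persist architecture + weights for reproducibility."""
        clf = self.classifier
        payload = {
            "driver_names": list(self.submodel.driver_names),
            "transitions": [list(t) for t in self.submodel.transitions],
            "output_labels": self.output_labels,
            "feature_means": self.feature_means.tolist(),
            "feature_stds": self.feature_stds.tolist(),
            "hidden_nodes": int(clf.hidden_layer_sizes[0]),
            "coefs": [w.tolist() for w in clf.coefs_],
            "intercepts": [b.tolist() for b in clf.intercepts_],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    stds[stds == 0] = 1.0
    return means, stds


def sample_training_pixels(
    submodel: SubModel,
    map_t0: CategoricalRaster,
    map_t1: CategoricalRaster,
    drivers: Mapping[str, ContinuousRaster],
    n_per_class: int = 1000,
    seed: int = 0,
) -> TrainingSet:
    """Balanced random sample of changed and persistent cells, split 50/50
    into training and validation halves. Deterministic for a fixed seed."""
    if map_t0.grid != map_t1.grid:
        raise GridAlignmentError("calibration maps must share one grid")
    missing = [n for n in submodel.driver_names if n not in drivers]
    if missing:
        raise KeyError(f"drivers missing from stack: {missing}")
    feats = np.stack([drivers[n].values for n in submodel.driver_names], axis=-1)
    valid = map_t0.valid_mask & map_t1.valid_mask
    for n in submodel.driver_names:
        valid &= drivers[n].valid_mask

    rng = np.random.default_rng(seed)
    groups: list[tuple[str, np.ndarray]] = []
    for f, t in submodel.transitions:
        cells = valid & (map_t0.values == f) & (map_t1.values == t)
        if not cells.any():
            raise ValueError(f"no observed change cells for transition {f}->{t}")
        groups.append((f"{f}->{t}", np.argwhere(cells)))
    for f in submodel.from_classes:
        cells = valid & (map_t0.values == f) & (map_t1.values == f)
        if not cells.any():
            warnings.warn(f"no persistent cells of class {f}; persistence output omitted", stacklevel=2)
            continue
        groups.append((f"persist_{f}", np.argwhere(cells)))

    X_parts, y_parts = [], []
    labels = []
    for label_idx, (label, idx) in enumerate(groups):
        labels.append(label)
        if len(idx) > n_per_class:
            sel = idx[rng.choice(len(idx), size=n_per_class, replace=False)]
        else:
            if len(idx) < n_per_class:
                warnings.warn(
                    f"only {len(idx)} candidate cells for '{label}' (requested {n_per_class}); taking all",
                    stacklevel=2,
                )
            sel = idx
        X_parts.append(feats[sel[:, 0], sel[:, 1]])
        y_parts.append(np.full(len(sel), label_idx, dtype=np.int64))
    X = np.concatenate(X_parts)
    y = np.concatenate(y_parts)
    perm = rng.permutation(len(y))
    X, y = X[perm], y[perm]
    half = len(y) // 2
    return TrainingSet(
        submodel=submodel,
        X_train=X[:half],
        y_train=y[:half],
        X_valid=X[half:],
        y_valid=y[half:],
        output_labels=labels,
    )


def skill_statistic(accuracy_rate: "float | TrainingReport", n_outputs: int) -> float:
    """S = (A − E)/(1 − E) with E = 1/n_outputs: 0 at chance level, 1 perfect."""
    if isinstance(accuracy_rate, TrainingReport):
        accuracy_rate = accuracy_rate.accuracy_rate
    if n_outputs < 2:
        raise ValueError("skill undefined for fewer than 2 output categories")
    expected = 1.0 / n_outputs
    return (accuracy_rate - expected) / (1.0 - expected)


def train_mlp(ts: TrainingSet, config: MlpConfig | None = None) -> tuple[MlpModel, TrainingReport]:
    """Fit the perceptron on the training half; report on the validation half."""
    config = config or MlpConfig()
    n_inputs = ts.X_train.shape[1]
    n_outputs = ts.n_outputs
    hidden = config.hidden_nodes or max(2, round(np.sqrt(n_inputs * n_outputs)))
    means, stds = _standardizer(ts.X_train)
    Xt = (ts.X_train - means) / stds
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="logistic",
        solver="sgd",
        learning_rate="constant",
        learning_rate_init=config.learning_rate,
        momentum=config.momentum,
        nesterovs_momentum=False,
        max_iter=config.iterations,
        batch_size=min(200, len(ts.y_train)),
        shuffle=True,
        random_state=config.seed,
        tol=1e-6,
        n_iter_no_change=50,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        clf.fit(Xt, ts.y_train)
    if not np.isfinite(clf.loss_):
        raise FloatingPointError("MLP training diverged (NaN loss); lower the learning rate")
    Xv = (ts.X_valid - means) / stds
    pred = clf.predict(Xv)
    accuracy = float((pred == ts.y_valid).mean())
    per_output = {}
    for idx, label in enumerate(ts.output_labels):
        sel = ts.y_valid == idx
        per_output[label] = float((pred[sel] == idx).mean()) if sel.any() else float("nan")
    report = TrainingReport(
        accuracy_rate=accuracy,
        skill=skill_statistic(accuracy, n_outputs) if n_outputs >= 2 else float("nan"),
        per_output_accuracy=per_output,
        n_train=len(ts.y_train),
        n_valid=len(ts.y_valid),
    )
    model = MlpModel(
        submodel=ts.submodel,
        classifier=clf,
        feature_means=means,
        feature_stds=stds,
        output_labels=ts.output_labels,
        config=config,
    )
    return model, report


@dataclass
class TransitionPotentialStack:
    """One [0, 1] potential surface per enabled transition."""

    potentials: dict[tuple[int, int], ContinuousRaster]
    provenance: str = "mlp"  # or "frequency"

    def __post_init__(self) -> None:
        grids = {r.grid for r in self.potentials.values()}
        if len(grids) > 1:
            raise GridAlignmentError("potential surfaces must share one grid")

    @property
    def transitions(self) -> list[tuple[int, int]]:
        return list(self.potentials)


def predict_potentials(
    model: MlpModel, drivers: Mapping[str, ContinuousRaster]
) -> TransitionPotentialStack:
    """Evaluate the trained network over the full grid.

    Returns the network's class-membership probability for each transition
    output; persistence outputs absorb the remaining probability mass.
    Nodata in any driver propagates to the potentials.
    """
    names = model.submodel.driver_names
    missing = [n for n in names if n not in drivers]
    if missing:
        raise KeyError(f"drivers missing from stack: {missing}")
    grid = next(iter(drivers.values())).grid
    valid = np.ones(grid.shape, dtype=bool)
    for n in names:
        valid &= drivers[n].valid_mask
    feats = np.stack([drivers[n].values for n in names], axis=-1)[valid]
    feats = (feats - model.feature_means) / model.feature_stds
    proba = model.classifier.predict_proba(feats)
    # column order of predict_proba follows clf.classes_ (label indices)
    col_of = {int(lbl): k for k, lbl in enumerate(model.classifier.classes_)}
    out: dict[tuple[int, int], ContinuousRaster] = {}
    nodata = -9999.0
    for idx, transition in enumerate(model.submodel.transitions):
        surface = np.full(grid.shape, nodata)
        surface[valid] = proba[:, col_of[idx]] if idx in col_of else 0.0
        out[transition] = ContinuousRaster(grid, surface, nodata_value=nodata)
    return TransitionPotentialStack(potentials=out, provenance="mlp")
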
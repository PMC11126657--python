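"""Map accuracy: kappa on an error matrix, figure of merit on three maps.

Kappa is the chance-corrected agreement

    K = (N·Σ X_ii − Σ X_i+·X_+i) / (N² − Σ X_i+·X_+i)

on an r×r error matrix with total N, row totals X_i+ and column totals X_+i.

The figure of merit (FOM) validates a simulated later-date map against the
observed pair of reference maps in change terms:

    FOM = 100 · Hits / (Hits + Misses + False Alarms)

where, per cell, a Hit is change both observed (earlier reference differs
from later reference) and predicted (earlier reference differs from the
simulation), a Miss is observed-only change, and a False Alarm is
predicted-only change. 100 means complete overlap of observed and simulated
change; correct persistence does not enter the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_core import CategoricalRaster, ConfusionMatrix, GridAlignmentError

__all__ = ["KappaReport", "FomReport", "kappa", "fom", "FOM_LABELS"]

FOM_LABELS = {0: "correct_persistence", 1: "hit", 2: "miss", 3: "false_alarm"}


@dataclass
class KappaReport:
    kappa: float
    overall_accuracy: float
    commission_error: dict[int, float]  # per mapped class: 1 - user's accuracy
    omission_error: dict[int, float]  # per reference class: 1 - producer's accuracy
    degenerate: bool = False


def kappa(cm: ConfusionMatrix) -> KappaReport:
    """Kappa, overall accuracy and per-class commission/omission errors."""
    if cm.N == 0:
        raise ValueError("empty confusion matrix")
    X = cm.X.astype(np.float64)
    N = float(cm.N)
    diag = np.diag(X)
    marginal = float(cm.row_totals @ cm.col_totals)
    denominator = N**2 - marginal
    degenerate = denominator == 0
    k = float("nan") if degenerate else float((N * diag.sum() - marginal) / denominator)
    with np.errstate(invalid="ignore", divide="ignore"):
        commission = 1.0 - np.where(cm.col_totals > 0, diag / cm.col_totals, np.nan)
        omission = 1.0 - np.where(cm.row_totals > 0, diag / cm.row_totals, np.nan)
    return KappaReport(
        kappa=k,
        overall_accuracy=float(diag.sum() / N),
        commission_error={c: float(v) for c, v in zip(cm.class_order, commission)},
        omission_error={c: float(v) for c, v in zip(cm.class_order, omission)},
        degenerate=degenerate,
    )


@dataclass
class FomReport:
    hits: int
    misses: int
    false_alarms: int
    correct_persistence: int
    fom: float  # percentage in [0, 100]
    labels: CategoricalRaster  # coded per FOM_LABELS


def fom(
    ref_t0: CategoricalRaster,
    ref_t1: CategoricalRaster,
    sim_t1: CategoricalRaster,
    strict_destination: bool = False,
) -> FomReport:
    """Three-map figure of merit with a hit/miss/false-alarm label raster.

    By default a hit only requires that change was both observed and predicted
    (any destination). With ``strict_destination`` a hit additionally requires
    the simulated destination class to match the reference; observed change
    simulated to the wrong class then counts as a miss, making the score
    strictly harder.
    """
    for other in (ref_t1, sim_t1):
        if other.grid != ref_t0.grid:
            raise GridAlignmentError("the three maps must share one grid")
    valid = ref_t0.valid_mask & ref_t1.valid_mask & sim_t1.valid_mask
    observed = (ref_t0.values != ref_t1.values) & valid
    predicted = (ref_t0.values != sim_t1.values) & valid
    hit = observed & predicted
    if strict_destination:
        hit &= ref_t1.values == sim_t1.values
    miss = observed & ~hit
    false_alarm = predicted & ~observed
    labels = np.zeros(ref_t0.grid.shape, dtype=np.int64)
    labels[hit] = 1
    labels[miss] = 2
    labels[false_alarm] = 3
    labels[~valid] = ref_t0.nodata_code
    h, m, fa = int(hit.sum()), int(miss.sum()), int(false_alarm.sum())
    denom = h + m + fa
    score = 100.0 * h / denom if denom else float("nan")
    return FomReport(
        hits=h,
        misses=m,
        false_alarms=fa,
        correct_persistence=int((valid & ~observed & ~predicted).sum()),
        fom=score,
        labels=CategoricalRaster(ref_t0.grid, labels, nodata_code=ref_t0.nodata_code),
    )
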
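# Methods

## Data model and conventions

All rasters share a `GridSpec` (origin at the top-left corner, rows
increasing southward, square cells, 0-based indexing, cell area =
cell_size²). Two rasters are combinable only when their grids are
identical. A cell that is nodata in any raster participating in an
operation is excluded from that operation everywhere. Class codes are
fixed by the legend, not inferred from data, so empty classes still appear
as zero rows/columns in tabulations. The default legend codes five wetland
covers — 1 sparse vegetation, 2 water, 3 humid land, 4 dense vegetation,
5 salt land — with water/humid/dense marked suitable and degradation
weights 0.7, 0, 0.1, 0.2, 1.0 respectively.

I/O uses the ESRI ASCII grid format: a plain-text single-band raster
format that carries shape, cell size and origin, and round-trips integer
data losslessly (continuous data to the precision written, well below
float32 error). Matrices are exchanged as labeled CSV, hexagon networks as
GeoJSON built with shapely geometries.

## Synthetic landscapes

The generator emulates a three-date categorical map series driven by a
known first-order Markov chain, optionally modulated by driver rasters:

* The initial map thresholds a Gaussian-smoothed random field at the
  cumulative class fractions, producing spatially contiguous patches whose
  realized areas match the requested fractions exactly.
* Each subsequent date draws every cell's class from the true matrix row
  of its current class. Where driver effects β are configured for a
  transition, the destination's log-probability is shifted by β·z(driver)
  (standardized drivers) and the row re-normalized by softmax — a logistic
  tilt that gives the MLP a recoverable spatial signal while preserving
  the marginal Markov structure at β = 0.
* Drivers are a smoothed random "DEM" (Gaussian blur of white noise, σ = 8
  cells), its slope in degrees, and Euclidean distance rasters to two
  random meandering polylines ("river", "road").

Defaults are chosen as realistic study conditions: a 200×200 grid of 30 m
cells (so tests run in seconds), a true transition matrix equal to the
row-normalized published 15-year wetland area-transition tabulation
shipped as a CSV fixture, and initial class fractions proportional to that
tabulation's row totals (≈ 25% sparse, 7% water, 55% humid, 13% dense,
0.3% salt). Fixed seeds give bit-identical outputs.

What the generator does **not** emulate: sensor/classification noise,
spatially autocorrelated transition errors, multi-step non-stationarity,
or real geography. Passing tests therefore demonstrate correctness of the
estimators and engines under a known model, not classification accuracy on
real imagery.

## Change analysis

Gains, losses and net change per class come from the transition
cross-tabulation (gain = column total − diagonal, loss = row total −
diagonal, scaled by cell area). The annual rate of change uses the
continuous-compounding form r = ln(A₂/A₁)/t; other conventions (simple or
geometric rates) exist and reported wetland shrinkage percentages are not
generally reproducible from printed areas under any single convention, so
the choice is documented here and the function is a single obvious point
of change. Spatial trends of a binary change indicator are least-squares
polynomial surfaces (default degree 3) fitted on coordinates rescaled to
[−1, 1] for conditioning.

## Driver screening

Cramer's V is computed on the driver × class contingency table, with
continuous drivers discretized into 256 equal-count bins (robust to skewed
distance distributions). Rows/columns with zero totals are dropped before
the chi-square. Per-class values use the class-vs-rest dichotomy. The
retention rule is a configurable threshold on overall V (default 0.15);
there is no universal cut-off, and screening output is a ranked table so
the analyst sees the full picture. The evidence-likelihood transform maps
each category of a variable to its empirical change frequency.

## Transition-potential MLP

Each sub-model is one source class's enabled transitions plus a
persistence output, so potentials compete against staying put. Training
pixels are a balanced random sample (default 500 per output, 50/50
train/validation split). The network is scikit-learn's MLP classifier
configured as a single-hidden-layer perceptron with logistic activations,
plain SGD with momentum 0.5, constant learning rate 0.01, and up to 10,000
iterations with loss-based early stopping — the conventional settings of
transition-potential modelling. Hidden-layer width defaults to
round(√(inputs·outputs)). Inputs are standardized with training-sample
statistics. The skill statistic S = (A − E)/(1 − E), E = 1/n_outputs,
rescales validation accuracy against uniformly random assignment.
Potentials are the network's class-membership probabilities evaluated over
the full (standardized) driver stack; they lie in [0, 1] by construction
and nodata propagates.

## Markov projection and allocation

Transition probabilities are maximum-likelihood row normalizations; empty
classes receive identity rows and are flagged. Calibration epochs are
treated as equal steps (15 years in the motivating application), so a
one-step projection reaches the next date; fractional-step matrix roots
are out of scope. Demands use largest-remainder rounding so each row's
demands plus persistence reproduce the class count exactly.

MOLA processes all (cell, transition) claims in one global ordering —
potential descending, then row, column, transition order (an optional
seeded jitter breaks ties randomly instead). This realizes the
conflict-resolution contract (higher potential wins; the loser refills
from its next-ranked candidate) deterministically, changes exactly
min(demand, eligible) cells per transition, and reports unmet demand.

CA-Markov splits each demand evenly across 10 iterations
(largest-remainder). Each iteration multiplies the base suitability by the
destination class's fraction within a 5×5 window (clipped at edges) of the
current map, then allocates by rank; cells change at most once per run. By
default the base suitability is the spatially flat calibrated frequency
p_ij, keeping the engine independent of the MLP so the two approaches can
be compared; MLP potentials are pluggable. Candidates whose weighted score
is zero (no destination neighbours yet) still rank by position so the
Markov budget is always met when eligible cells exist — final class counts
match the one-step projection within rounding (≤ M cells).

## Validation

Kappa follows the standard error-matrix formula with overall accuracy and
per-class commission/omission errors; degenerate marginals (N² equal to
the marginal product) are flagged rather than divided through. The figure
of merit compares three maps in change space. By default a hit requires
only that change was both observed and predicted (any destination); a
strict mode additionally requires the simulated destination to match,
which can only lower the score. FOM is reported on the 0–100 scale.

## Degradation scoring

Hexagons are flat-top regular polygons with side s = √(2A/(3√3)) (12,408 m
for the default 40,000-ha unit), tiled from the extent's lower-left
corner; every hexagon intersecting the extent is retained un-clipped, so
each unit's planar area is exact. Cells belong to the unit containing
their center. Patches are connected components (default 8-connectivity)
computed within hexagon clips; patch perimeter is the exposed cell-edge
length, and a patch spanning two units is counted in both (clipped).

Metric definitions: CA = Σa/10⁴ ha; MPS = CA/n; ED = Σ edge / unit land
area × 10⁴ m/ha; MPFD = mean over patches of 2·ln(0.25p)/ln(a) (exactly 1
for squares, < 2 for any raster patch by the polyomino isoperimetric
inequality); MSI = mean of p/(4√a), taking the equal-area square's
perimeter as the raster "minimum perimeter".

Normalization is min–max per (class, metric) across units; spans of zero
normalize to 0 and are flagged. By default each map normalizes on its own
span; a baseline table can be supplied so scenario maps are normalized on
the baseline's span and their LD totals are comparable — cross-scenario
comparisons in the tests use this mode. Codes follow quartile bins
(lower-closed, upper-open, last closed), ascending in Z for unsuitable
cover area metrics (group 1) and for suitable cover shape metrics
(group 2), descending otherwise.

The score LD = ΣK·I / V interprets the weight I as the per-cover
degradation index w(c) ∈ [0, 1] summed over all class × metric pairs
present in the unit; the alternative reading (I = the normalized metric
value) is available behind `weight_mode="z_value"`. V is the suitable
fraction floored at ε = 0.01 so units with no suitable cover remain finite
— an all-salt unit with all codes at 4 scores 20/0.01 = 2000. Groups are
LD quartiles across units ("four relative groups").

## Scenarios

Built-in specs enable exactly the transition sets of the three management
narratives (4 to-water, 4 from-water, 8 business-as-usual). A scenario run
re-trains sub-models restricted to its enabled transitions (re-training
per scenario keeps potentials consistent with the enabled competition),
projects demands from the calibration matrix, allocates with either
engine, and scores degradation on the simulated map. Transitions enabled
by a scenario but never observed during calibration carry zero Markov
demand and cannot be sampled; they are skipped with a warning rather than
failing the run. Demand multipliers are available for sensitivity
experiments on the MOLA engine.

## Numerical and testing notes

* All stochastic components accept explicit seeds; fixed seeds give
  bit-identical maps, samples and trained weights.
* Transition-probability recovery is verified per entry within 3 binomial
  standard errors on a 300×300, no-driver-effect series — the sample sizes
  at which a 3σ bound is meaningful for the rare salt-row transitions.
* Test problem sizes (120–300 pixel grids, 50–100 ha hexagon units,
  1,000–3,000 MLP iterations on a few hundred samples) are chosen so the
  full suite exercises every stage in well under a minute per test while
  keeping sampling error inside the asserted bounds.
* MOLA is cross-checked against an independent pure-Python enumeration
  oracle on small grids; kappa against an independent library
  implementation; chi-square against an explicit expected-count loop;
  distances against brute-force all-pairs scans.

## Known limitations

* Single-step, time-homogeneous Markov dynamics; no continuous-time rates,
  no uncertainty intervals on P.
* The MLP is one hidden layer with fixed architecture heuristics; no
  alternative learners.
* CA-Markov base suitability is spatially flat by default; real workflows
  may prefer MLP or distance-based suitabilities (supported but not
  default).
* Degradation scoring assumes the five-class wetland legend semantics;
  other legends need explicit suitability flags and weights.
* Hexagon tiling origin/orientation is fixed (flat-top from the lower-left
  corner); unit counts over a given extent depend on that choice.
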
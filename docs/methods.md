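# Methods

`cpannet` implements the complete model-building chain behind a three-class
P-glycoprotein (P-gp) ligand classifier — inhibitor / substrate / non-active —
driven by numeric 2-D molecular descriptors. The reference workflow it
follows was developed on 2512 compounds described by 1229 commercial
(Dragon 7.0) descriptors; that descriptor matrix was never deposited, so this
package pairs the algorithms with a synthetic-data generator that reproduces
the statistical structure the chain assumes. This note records the model,
the choices that were genuinely open, and what the synthetic experiments do
and do not demonstrate.

## Kohonen layer

A self-organizing map (SOM) with a square, non-toroidal grid. For an input
x ∈ R^m the winning neuron c minimises the Euclidean distance
d_j = Σ_i (x_i − w_ji)², ties broken to the first neuron in row-major order.
All neurons j within topological (Chebyshev-ring) distance d ≤ r_t of the
winner are corrected by

    Δw_ji = η(t) · a(d) · (x_i − w_ji),

with the triangular neighbourhood a(d) = 1 − d/(r_t + 1) (1 at the winner,
0 outside the radius) and the linearly decaying learning rate

    η(t) = (a_max − a_min)(t_max − t)/(t_max − 1) + a_min,

so η(1) = a_max and η(t_max) = a_min. Because 0 < η·a ≤ 1, every update is a
convex pull of the weight vector toward the input.

Choices the source procedure leaves open, fixed here:

* **Radius schedule** — linear shrink from max(rows, cols) − 1 at the first
  epoch to 0 at the last; standard Kohonen practice.
* **Weight initialisation** — each neuron starts as a constant vector at a
  level drawn uniformly from [0, 1). This breaks neuron symmetry (the only
  thing initialisation must do here) while keeping training exactly
  equivariant to a permutation of the descriptor columns, a property the
  test suite asserts; per-component random initialisation would destroy
  that equivariance.
* **Presentation order** — every epoch presents each compound once in a
  freshly shuffled, seeded order.
* **Distances** — winner selection uses the squared form; reported distances
  (quantization error, applicability domain) take the square root so they
  live on the same scale as the domain boundary.
* **Random streams** — the Kohonen layer and the output layer draw from two
  independent child streams of the configured seed, so the Kohonen
  trajectory is identical whether or not targets are supplied.

## Counter-propagation ANN

The CP-ANN couples the Kohonen layer with an output layer of identical grid
shape holding one weight per class per neuron. Training is single-pass and
joint: for every presented compound the winner is found from the descriptors
only; the Kohonen neighbourhood moves toward x and, in the same step with the
same η(t)·a(d) factor, the output weights of that neighbourhood move toward
the compound's one-hot class target (a two-phase mode that trains the
Kohonen layer to completion first is available as an option; the Kohonen
result is identical by construction). Output weights start uniform in
[0, 1) and remain in [0, 1] because every update is a convex pull toward a
{0, 1} target; they therefore read as bounded class scores.

Prediction maps a compound to its winner and returns the neuron's output
vector. A score above 0.5 marks predicted membership of that class; the
single reported label is the argmax, and the prediction carries an explicit
flag when no class or several classes clear the threshold — the argmax is
the only deterministic way to reconcile per-class thresholds with
single-label confusion matrices.

Reference network parameters (defaults): 43×43 neurons, 600 epochs,
learning rate 0.6 → 0.001. All synthetic experiments below use smaller
grids and fewer epochs, scaled to their dataset sizes.

## Preprocessing

Reduction order: (1) drop descriptors with sample SD < 1e-4; (2) scan
columns in input order and drop any column with |Pearson r| ≥ 0.95 against
an already-retained one (deterministic, order-stable; the report records the
surviving partner); (3) autoscale each remaining descriptor to mean 0, SD 1
(sample SD, n−1); (4) SOM-reduce: train a 7×7 map on the *descriptor*
vectors (rows of the transposed matrix) and keep, per occupied neuron, the
descriptor nearest to and the descriptor farthest from the neuron's weight
vector — one typical and one extreme representative of each descriptor
cluster. A neuron occupied by a single descriptor contributes that one, so
the retained count is Σ min(2, occupancy).

The autoscaling scope is configurable: `full` (default) fits the transform
on the entire dataset before splitting, matching the reference procedure;
`train` fits on the training partition only and reuses the parameters for
TE/V/new compounds, which avoids any information flow from the evaluation
partitions into the transform. The descriptor-reduction SOM reuses the
splitting map's learning parameters (100 epochs, 0.5 → 0.01) since separate
values were never specified.

## Dataset splitting

The whole (autoscaled) dataset is mapped onto a 20×20 SOM (100 epochs,
0.5 → 0.01) and partitioned cluster by cluster: within each occupied neuron,
members are visited in a seeded random order, the first always enters TR —
so the training set spans the entire map — and the rest are dealt by a
largest-deficit weighted round-robin tracking the requested global fractions
(ties favour TR, then TE). Defaults (0.711, 0.136, 0.153) reproduce the
reference 1786/341/385 partition of 2512 compounds to within rounding. The
exact allocation rule used originally ("selected from the rest") is not
recorded; this rule is one deterministic reading that guarantees map
coverage in every subset.

## Genetic-algorithm descriptor selection

Binary chromosomes over the candidate descriptors; fitness of a chromosome
is MCC_TR × MCC_TE of a CP-ANN trained on the training set restricted to its
descriptors, where each factor is the arithmetic mean of the per-class
one-vs-rest Matthews correlation coefficients (the source reports per-class
MCCs and never defines a multiclass aggregate; the mean is symmetric in the
classes, and the TR×TE product rewards fit and generalisation jointly).

The search is steady-state, following the published step list read
literally: per generation, two parents are chosen by rank-weighted roulette
(robust to negative MCC products), recombined by uniform crossover, mutated
by independent bit flips (2% default), and the offspring replaces the
weakest member outside the elite (`survivors` best, default 20, are never
replaced — so the population's best fitness is non-decreasing). Defaults: 95
chromosomes, 150 generations. The fitness CP-ANN uses a reduced 20×20 /
150-epoch network; the full 43×43 / 600 network is reserved for the final
refit. `initial_genes` (bits set at initialisation) defaults to half the
candidates, a common GA density that spreads the initial population across
subset sizes. Fitness evaluations are memoised by bit pattern and every
fitness network uses one fixed seed, so the landscape is deterministic
within a run.

## Evaluation

Per class (one-vs-rest): sensitivity Sn = TP/(TP+FN), specificity
Sp = TN/(TN+FP), precision Pr = TP/(TP+FP) (as percentages), and MCC with
the convention MCC = 0 when a margin is degenerate. Global indices:
NER (non-error rate) = mean per-class sensitivity and AvPr = mean per-class
precision — class-balanced summaries suited to the 1178/477/857 imbalance.
Accuracy is computed but never used for selection, since it is biased
toward the majority class. A class with an undefined measure (zero
denominator) is excluded from the global mean with a warning. Percentages
are not truncated; tests compare published values at 0.1 percentage points
(0.01 for MCC) to absorb the print-time truncation of the source tables.

## Applicability domain

The distance of a compound (autoscaled space) to its winning neuron's
weight vector measures map coverage; the domain boundary is the maximum
such distance on a reference partition — the test set by convention, whose
maximum exceeded the training set's in the reference study — and is
inclusive (a compound exactly at the boundary is in-domain). Scores within
±0.1 (configurable) of the 0.5 threshold are flagged *uncertain*. Both are
flags, never rejections: an out-of-domain compound may still show the
modelled response through a mechanism the model does not capture. The
published boundary value (5.45) is a property of the undeposited descriptor
matrix and is treated as narrative context only.

## Synthetic data

The generator emulates the statistical structure of a curated descriptor
table: three classes with the reference 1178/477/857 imbalance (default),
*informative* descriptors whose class-conditional means are separated
within each column by a configurable number of within-class SDs (offsets
0, s, 2s per column, with the class-to-offset assignment rotated across
columns so no class is globally extreme), pure-noise descriptors, redundant
descriptors (scaled, possibly sign-flipped copies of informative ones with
|r| ≥ 0.95 by construction), and near-constant descriptors (SD < 1e-4).
Within-class covariance is identity on the informative axes, which makes
the separation parameter directly interpretable in SD units.

What it does **not** emulate: the heavy-tailed and discrete distributions of
real count descriptors, block-correlation structure between descriptor
families, activity cliffs, assay noise in the labels, and the chemical
clustering that makes real top-maps patchy. Passing the synthetic checks
therefore demonstrates the correctness and internal consistency of the
algorithms, not expected performance on real P-gp data.

## Experiment scales and designed conditions

Synthetic experiments run at roughly one-tenth of the reference compound
counts (class sizes 118/48/86) with networks scaled to match (10×10 split
map, 12×12 final CP-ANN at 200 epochs, 20×20 fitness networks); these sizes
keep every experiment's behaviour in the same regime as the full-scale
defaults while remaining routine to rerun.

Two designed conditions deserve note:

* the **held-out-performance check** uses a 3-SD per-column separation,
  where a nearest-centroid oracle exceeds 90% accuracy and the CP-ANN is
  expected to classify the held-out partition nearly perfectly;
* the **GA recovery experiment** uses a 1-SD separation. At 3 SD the wrapper
  fitness saturates at MCC_TR × MCC_TE = 1 with only a few informative
  descriptors selected, leaving no selection gradient — a recovery rate
  measured there reflects initialisation, not selection. At 1 SD the fitness
  stays below 1 and rises with each informative descriptor added, so the
  recovered fraction actually measures the GA. Parameter-recovery
  experiments must keep the parameter identifiable.

## Known limitations

* The reference model itself cannot be rebuilt: the Dragon 7.0 descriptor
  matrix for the 2512 compounds was not deposited. Only the external
  validation set's confusion matrices (385 compounds) were published; they
  are shipped as exact fixtures and reproduce the published validation
  metrics. The published training/test headline values (NER 0.93/0.85,
  AvPr 0.93/0.87), the 26 selected descriptors and the 5.45 domain boundary
  all depend on that matrix and are out of reach at any scale.
* One published cell is internally inconsistent: the validation inhibitor
  MCC is printed as 0.63, but the published inhibitor confusion matrix
  yields 0.59 by the defining formula. The two self-consistent cells
  (substrate 0.54, non-active 0.52) are asserted; the inhibitor cell is
  documented and excluded.
* SOM training is online (per-sample updates), so wall time scales with
  compounds × epochs × neurons; hexagonal grids, toroidal boundaries and
  batch-SOM variants are out of scope.
* The correlation filter keeps the earlier column of a correlated pair;
  with differently ordered input the retained set can differ (the report
  always records which survivor displaced which descriptor).
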
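# Methods

## Model

The optimizer is a binary variant of the grasshopper swarm model. N agents
hold continuous positions X_i in the box [lb, ub]^D (defaults [0, 1]^D). One
update step is

    ΔX_i[d] = c · Σ_{j≠i} c · (ub−lb)/2 · S(r̂_ij) · (x_jd − x_id)/r̂_ij
    X_i ← clip(ΔX_i + T, lb, ub)

with S(r) = f·e^(−r/l) − e^(−r) the social force (f = 0.5, l = 1.5), T the
best-so-far solution's continuous position, and c the comfort coefficient.
Both damping coefficients in ΔX are the same c, following the original
single-coefficient formulation of the continuous algorithm. The full
physical swarm model also carries gravity and wind-advection terms; as in the
continuous original they are dropped (gravity zero, wind replaced by the pull
toward T) because the undamped model does not converge.

Distances r̂_ij are Euclidean distances between continuous positions,
affinely normalized each iteration so the smallest off-diagonal distance maps
to 1 and the largest to 4; within [1, 4] the force takes both signs (its root
is ≈ 2.079), which keeps attraction and repulsion simultaneously active. If
all pairwise distances are equal (a fully collapsed swarm), every pair is
assigned the interval midpoint 2.5 so the force and the unit vector stay
well-defined. The per-dimension unit vector uses the same normalized scalar
r̂_ij in the denominator.

Whether the transfers should consume the position or the raw step vector is
ambiguous in the usual presentations; this implementation applies them to the
updated (clipped) continuous position, which also motivates the clipping:
it keeps the sine-transfer argument bounded.

## Binarization

The two-stage time-varying transfer (`variant="tvg"`):

1. sine set-rule: p_d = |sin(x_d/α)|, bit_d = 1 iff u_d < p_d. The absolute
   value is taken because sin may be negative and a transfer function must
   map into [0, 1].
2. Gaussian V-shaped flip-rule: p_d = clip(|2/π·arctan(π/2·x_d/β)| + σ·g_d,
   0, 1) with g_d ~ N(0, 1); bit_d is complemented iff u'_d < p_d. σ is a
   standard deviation (not a variance); the clip handles the unbounded
   Gaussian term. With σ = 0 and β = 1 the stage reduces exactly to the V4
   catalog function.

Schedules over iteration l of L (all linear, computed in lerp form so the
endpoints are exact in floating point):

| parameter | start (l = 0) | end (l = L) | direction | role |
|---|---|---|---|---|
| α (sine scale) | 0.05 | 5 | increasing | oscillation → smoothness |
| β (V steepness scale) | 10 | 0.05 | decreasing | flat → steep flip profile |
| σ (mutation std) | 10 | 0.01 | decreasing | heavy → negligible mutation |
| c (comfort coefficient) | 1 | 10⁻⁵ | decreasing | damps the social term |

The printed α range starts at 0, but α = 0 divides by zero in the sine
transfer, so the lower endpoint is floored at 0.05 (configurable).

Static baselines: S1–S4 (sigmoids of the position, set-rule) and V1–V4
(symmetric functions of the position, flip-rule against the current mask).

## Optimizer loop and randomness

Initialization: positions uniform in the box; initial masks by thresholding
positions at 0.5 (standard for binary swarm methods, and seedable). Empty
masks are repaired by setting the bit of the largest-|position| dimension
(first index on ties) because the wrapper error is undefined on the empty
subset. The target is replaced only on strict improvement, so ties keep the
incumbent and the best-fitness trace is well-defined and nonincreasing.
Fitness is evaluated synchronously, once per individual per iteration:
exactly N·(L+1) evaluations per run.

All randomness flows from one `numpy.random.Generator` seeded by the run
seed. Per iteration the draw order is fixed: the uniform array of the first
binarization stage, then (TVG only) the uniform array and the Gaussian array
of the flip stage, each drawn as an (N, D) array in C order
(individual-major, dimension-minor). Runs therefore replay bit-for-bit, and
reports deliberately contain no wall-clock fields so identical seeds produce
byte-identical files.

## Wrapper fitness

fitness = α·Err + β·|mask|/D with α = 1 − β. The weights are not fixed by
convention in one place in the literature; α = 0.99, β = 0.01 is the de-facto
standard in binary feature-selection studies and is the default
(configurable). k = 5 neighbours by default — a robust small-k choice; k must
be smaller than the training split.

Err is the misclassification rate of a KNN classifier on an evaluation split:
an 80/20 stratified holdout by default (re-drawn from each run's seed), or a
50/30/20 stratified train/validation/test split (`scheme="three-way"`) where
the search sees validation error and the test portion is reserved for final
reporting. Min-max scaling is fitted on the training portion only, to avoid
leakage. The KNN vote is fully deterministic: neighbour distance ties break
by training index (stable order), vote ties by the nearest neighbour whose
label is in the tied set. Neighbour selection uses argpartition with an exact
fallback to a stable full sort whenever a point outside the selection ties
the kth distance, so the fast path never changes results. The classifier is
a plug-in (`fit`/`predict` contract); only KNN ships.

## Synthetic data

`generate_dataset` draws balanced labels and three column blocks:

- informative: unit-variance Gaussians whose class-conditional mean vectors
  sit at the vertices of a regular simplex with pairwise distance
  `class_separation` (in within-class standard deviations) in the joint
  informative subspace. For two classes the simplex direction is the
  equal-weight diagonal, so each informative column carries
  separation/√n_informative — individually weak, jointly separating. This is
  deliberate: if each column separated the classes on its own, the size
  penalty would make a single feature globally optimal and recovery of the
  full informative set would be the wrong thing to expect.
- redundant: linear mixes of the informative columns plus 10% relative noise.
- noise: label-independent standard Gaussians.

Columns are shuffled; the permutation is recorded in the feature names and in
`informative_mask`. What the generator does **not** emulate: heavy-tailed or
discrete features, label noise, class imbalance, correlated noise, and the
autoregressive structure of EEG-derived feature tables. Passing tests show
the optimizer recovers planted low-dimensional Gaussian structure; they do
not certify behaviour on such real-data pathologies.

`exhaustive_best_subset` enumerates all non-empty masks (refused above
D = 16) with the identical split/scaling/classifier pipeline, giving a true
global optimum for small fixtures; ties keep the lowest mask index.

## Numerical and design choices

- Linear schedules are computed as (1−t)·start + t·end so iterations 0 and L
  hit the printed endpoints exactly.
- Continuous positions are clipped to the box after every update.
- The bound check on c tolerates 1e-12 relative rounding at the schedule
  endpoint.
- Min-max scaling maps constant training columns to 0.
- `RunResult.best_error` is recovered from the best fitness by inverting the
  weighted sum (exact up to float arithmetic), so no extra fitness evaluation
  is spent.
- Multi-class confusion indices are computed one-vs-rest per class and
  macro-averaged over the classes where they are defined; an index with a
  zero denominator is reported as `None`, never silently 0. Two-class
  problems use the plain binary definitions directly.

## Problem sizes used in the checks

The deep end-to-end checks run at desk scale, chosen as the smallest sizes at
which the properties are meaningful: oracle agreement on n = 60, D = 8
(population 20, 50 iterations, 20 seeds, fixed split); informative-feature
recovery on n = 200, D = 10 (population 40, 100 iterations — the standard
experiment defaults — 20 seeds, per-run splits). The runtime-scaling check
times the optimizer against a calibrated compute-bound fitness oracle whose
evaluation cost is proportional to D (preallocated buffers, elementwise
sine), because the KNN wrapper's own cost is dominated by neighbour selection,
which does not scale with D and would confound a measurement of the
optimizer's O(L·N·D) behaviour; configurations are timed round-robin and
compared by medians to cancel machine-speed drift.

## Known limitations

- The recovery behaviour depends on the size penalty: with strongly
  separable single features the optimum is legitimately a singleton mask.
- No early stopping, parallel evaluation, or multi-objective archiving.
- Only box constraints; only the KNN classifier plug-in ships.
- The three-way scheme reports test error only for the final mask; the
  search itself never sees the test portion.
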
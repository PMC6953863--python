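# Methods

## Task and data model

The package models treatment-uptake classification in HIV/HCV co-infected
patients: 17 features (X1–X17) and a binary outcome *y* (1 = received HCV
therapy). Three feature kinds appear in the schema:

* independent binaries (X1 met-criteria, X6 psychiatric disorder, X7
  incarceration, X12 male) sampled at their published marginal frequencies;
* three mutually exclusive one-hot groups — injecting-drug-use category
  {X2 lifetime, X3 OST, X4 recent, X5 never}, prior-therapy history
  {X8 naive, X9 Peg-IFN/RBV, X10 DAAs/Peg-IFN/RBV}, and HCV genotype
  {X14…X17} — sampled from their multinomial marginals;
* liver fibrosis stage X11, a single ordinal column with levels 1–4
  (F0-F1, F2, F3, F4) at the published stage frequencies, and age X13, a
  truncated normal on [18, 76] with mean 48.95.

The reference cohort has N = 2940 and treated prevalence 1952/2940 = 66.4%.
All schema probabilities are stored as exact count ratios.

Fibrosis staging from liver stiffness (kPa) uses the bands F0-F1 < 7.2,
F2 ∈ [7.2, 9.0), F3 ∈ [9.0, 14.6), F4 ≥ 14.6. The published band edges
leave [8.9, 9.0) and [14.5, 14.6) uncovered; we close each gap downward
(lower stage wins), the conservative staging choice, so the four bands
partition (0, ∞).

### Synthetic outcome model

Because the per-patient records are not public, the outcome is generated
from a logistic model over *unit-scaled* features (every column min-max
mapped to [0, 1], making log-odds coefficients comparable across kinds).
The default planted model puts nonzero coefficients only on
{X3 +1.0, X4 −8.0, X8 +1.0, X11 +1.5, X13 −1.0, X16 −1.0}: plausible signs
(advanced fibrosis and therapy-naive status raise treatment odds; age and
genotype 3 lower them) with a dominant negative effect of recent injecting
drug use, so that the ablation study has a known ground truth to recover.
The intercept is calibrated by root finding on a Monte-Carlo estimate
(100 000 draws, seeded) of the expected prevalence, which is strictly
increasing in the intercept; calibration fails loudly if the achieved
prevalence misses the target by more than the tolerance (default 1e-3).

What the generator does *not* emulate: cross-variable correlation outside
the one-hot groups (independence by default), site/geography effects,
longitudinal follow-up, and the real — unknown — dependence structure of
treatment decisions. Tests passing on synthetic cohorts therefore validate
the machinery and its statistical contracts, not clinical performance on
real data.

## Networks

A genome is 1–4 hidden nodes, each with a sparse input map, plus one output
weight per node and an output bias. Hidden transfer functions: product
units (real exponents, multiplicative), sigmoid units (logistic of an
affine form with a node bias), Gaussian radial basis functions with one
shared radius per node (the classical RBF form; per-dimension radii would
multiply parameters against the parsimony goal). The output unit is a
single logistic, giving P(treated); hard labels threshold at 0.5. The
output activation is a package choice — only the ranking metric (AUC) and
thresholded labels are consumed downstream, and a monotone squashing leaves
both invariant.

Connection counting: input→hidden links + hidden→output weights + 1 for the
output bias. Node biases (SU) and radii (RBF) are node parameters, not
connections. This is the only convention under which a one-node,
six-input RBF model has 8 connections, matching the published parsimony
figure for that architecture.

Input scaling per family: PU [1, 2] (positivity for real exponents,
bounded to temper large powers), SU [0.1, 0.9] (sigmoid saturation),
RBF [−1, 1] (symmetry about the origin). Scalers are fitted on the training
partition only; generalisation data reuse the training min/max without
clipping, so out-of-range values extrapolate. Constant columns map to the
range midpoint.

## Evolutionary algorithm

Mutation-only evolutionary programming (no crossover), following the
classical evolutionary-ANN lineage:

* population 500 (default; the scale of the original experiment's
  population is not recoverable from what is published), 600 generations;
* initial genomes have 1–2 hidden nodes and random non-empty input subsets;
  input-layer parameters start uniform in [−1, 1] for PU and [−5, 5] for
  SU/RBF, output-layer parameters in [−5, 5]; RBF radii are |draws| with a
  1e-3 floor;
* each generation: evaluate fitness 1/(1 + mean binary cross-entropy)
  (probabilities clamped to [1e-12, 1−1e-12]); copy the elite 10%
  unchanged; fill the remaining slots with mutated copies of the
  better-ranked genomes — parametric mutation for the better half,
  structural mutation for the rest;
* structural mutation picks one operator (add/delete nodes, add/delete
  connections) with count uniform in {1, 2}; repairs truncate to
  feasibility: node count stays in [1, 4], deletions never leave a node
  without connections (single-connection nodes simply retain theirs);
* parametric mutation perturbs every numeric parameter with Gaussian noise
  whose SD decays linearly from 1.0 to 10% of it across the generation
  budget; radii stay positive by reflection about zero with the 1e-3 floor;
* no early stopping; the best fitness sequence is non-decreasing by
  elitism; a run is bit-reproducible from (seed, config, data).

The exact selection/replacement and mutation-adaptation details of the
original experiments are unspecified; the choices above are defaults and
every knob is exposed in `EAConfig`. An optional 5-fold cross-validated
grid search over `EAConfig` (`grid_search_config`) is provided for
hyperparameter selection but nothing is hard-wired to it.

## Metrics

All metrics are fractions in [0, 1]; percentages are formatting. The
confusion matrix fixes class order (treated, untreated), rows = truth.
CCR = trace/N; per-class sensitivities S_j = n_jj/N_j; MS = min_j S_j
(undefined, and rejected, if a true class is absent). CCR is algebraically
the prevalence-weighted mean of the sensitivities, so MS ≤ CCR ≤ max S_j.

AUC integrates the ROC trapezoidally over all distinct score thresholds
with tied scores grouped into one step; this equals the Mann–Whitney
statistic with half-weight ties, which the tests exploit as an O(n²)
oracle. PR curves use the same threshold convention, anchored at
(recall 0, first precision), integrated trapezoidally. For an
all-constant scorer precision equals prevalence at every recall.

## Protocol, comparison, ablation

One stratified holdout split (training size 2193 when N = 2940 — the
published counts, which are 74.6%, not the round 75% — else round(0.746·N))
is shared across all runs and methods; only the EA seed varies between the
`n_runs` repetitions. Stratification defaults on to protect MS on
imbalanced data; a flag restores plain random splitting. The best run is
selected by training fitness with ties broken by fewer connections, so
generalisation data never influence selection.

`compare_methods` computes, per metric (CCR, MS, AUC, #conn): a
Kolmogorov–Smirnov test of each method's run sample against a normal with
the *sample-estimated* mean/SD (a Lilliefors-style usage whose p-values are
conservative; documented rather than corrected, matching common practice in
this literature), one-way ANOVA across methods, Levene's variance-equality
test, and Tukey HSD pairwise comparisons with the induced ranking of means.
No multiple-testing correction is applied across the four metrics; each is
presented per-metric. A tiny negative ANOVA F arising from floating-point
cancellation on (near-)identical groups is clamped to (F = 0, p = 1).

`ablation_study` runs the protocol twice — full feature set vs the set with
one column removed — with identical split membership and identical per-run
EA seeds (matched design, asserted), and reports mean deltas. Removing a
one-hot member keeps the remaining indicators, so the "all group indicators
zero" pattern remains informative in the reduced arm; the with-arm still
strictly dominates in information, and under the default planted model the
AUC drop is the expected direction.

## Problem sizes and numerical choices

The behavioural test surface uses scaled-down study conditions chosen as
the smallest sizes at which the contracts are comfortably testable: the
toy-problem check runs 30 seeds at population 100/200 generations on an
80-point linearly separable problem with a 0.2 margin; the ablation check
uses a 2000-patient cohort, population 200, 150 generations and 10 matched
seeds; generator fidelity is checked at the reference N = 2940 with a
3-binomial-SE band per marginal. Probability clamping at 1e-12, radius
floor 1e-3, scaler round-trips to 1e-10 on non-constant columns, and
forward/AUC oracle agreement to 1e-12 are the package's numerical
tolerances.

## Known limitations

* Synthetic cohorts are marginally faithful but jointly independent outside
  the one-hot groups; real treatment-decision dependence is unknown.
* The EA is single-objective (cross-entropy fitness); MS is reported post
  hoc, not optimised, so minority-class sensitivity can be mediocre on
  hard synthetic cohorts.
* Connection counts from short runs can be large (structural pruning needs
  generations); parsimony comparable to the published best models emerges
  only at full run lengths.
* K-S normality p-values with estimated parameters are conservative;
  treat "normality not rejected" loosely.
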
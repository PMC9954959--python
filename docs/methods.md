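# Methods

## The model

`thyrocad` classifies thyroid nodules as benign or malignant from 27 coded
sonographic signs using a first-order Takagi–Sugeno fuzzy inference system
(ANFIS). The model is a rule base of `R` rules; rule `i` owns one Gaussian
membership function per input dimension (premise parameters: center `c_ij`,
spread `σ_ij`) and a linear consequent `f_i(x) = p_i · x + r_i`. For an
input `x` the raw firing strength of rule `i` is the product of its
membership values,

    w_i(x) = Π_j exp(−(x_j − c_ij)² / (2 σ_ij²)),

and the output is the normalized-firing-weighted sum of consequents,
`y(x) = Σ_i w̄_i(x) f_i(x)` with `w̄_i = w_i / Σ_l w_l`. Targets are coded
benign = 0 / malignant = 1, and the continuous output is thresholded at
0.5 with ties called malignant — the conservative convention for a cancer
screen.

The default structure is `R = 10` rules. With `n` inputs this gives
`2·n·R` premise plus `(n+1)·R` consequent parameters: 820, 400 and 250 free
parameters for the 27-, 13- and 8-sign input sets used in the experiments.
Ten membership functions exist per input dimension — one per rule — in a
scatter (cluster-based) partition, not a grid: a grid with 10 MFs per input
would generate 10^27 rules and is not representable; the scatter reading is
the one consistent with the printed parameter totals. `n_rules` is
configurable.

## Numerical conventions

- **Input scaling.** Raw sub-feature codes and the two continuous signs
  are min–max scaled to [0, 1] per dimension using *training-set* extrema;
  the extrema are stored inside the model so test data reuse the training
  map. Gaussian premises need commensurate axes; a constant training
  column maps to 0.5.
- **Log-space firing.** Raw strengths are computed as log-products and
  shifted by the row maximum before exponentiation, so normalization never
  divides by zero even when every rule is many spreads away from `x`.
- **Spread floor.** `σ ≥ 1e−3` on the scaled axis, enforced whenever a
  parameter vector is decoded; prevents degenerate memberships and
  unbounded premise gradients.
- **Encoding.** All parameters flatten into one vector (premise `(c, σ)`
  pairs rule-major then input-major, then consequent `(p…, r)` blocks
  rule-major); this vector is the GA chromosome and the unit of
  serialization. The JSON model format stores hex floats for a bit-exact
  round trip.

## Initialization: fuzzy c-means

Rules are placed by Bezdek fuzzy c-means on the scaled training inputs with
one cluster per rule: fuzzifier `m = 2.0`, tolerance `1e−5` on the
objective decrease, at most 200 iterations, membership matrix seeded from
normalized uniform draws (all seeded). Cluster centers become premise
centers; spreads are the membership-weighted standard deviations per
dimension, clamped to the floor (a cluster collapsed onto one point would
otherwise give σ = 0). Consequents are then set by one global ridge
least-squares solve (λ = 1e−8), so the starting model is exactly
consequent-optimal for its premises. The fuzzifier, tolerance and the
σ/consequent derivations are package choices; only the use of FCM itself is
fixed by the study design.

## Trainers

All three trainers optimize the flat parameter vector against the training
RMSE of the continuous output (regression-style fitness on 0/1 targets, not
thresholded labels — the optimizers need a smooth surface).

**Genetic algorithm** (the method of interest). Real-coded GA with the
study control parameters as defaults: 100 iterations, population 50,
crossover rate 0.4, mutation rate 0.15; iteration count is the only
stopping criterion. Operators are standard real-coded practice (the study
does not specify them): tournament selection of size 2, whole-arithmetic
crossover (`child = β·p1 + (1−β)·p2`, `β ~ U(0,1)`) applied to a fraction
`crossover_rate` of parent pairs, per-gene Gaussian mutation with
probability `mutation_rate` and spread 0.1× the gene's bound range, one
elite carried per generation. Gene bounds: centers in [−0.25, 1.25],
spreads in [1e−3, 2], consequents in [−10, 10], enforced by clipping.
The initial population is the FCM/LS template plus Gaussian perturbations
of it; an already-optimal template is therefore never lost. Because the
near-unregularized LS consequents can be far outside the consequent box
(large cancelling coefficients), the template is first projected into the
box by re-solving the consequents with the smallest ridge from a fixed
ladder (1e−6 … 1) whose solution fits — a small, explicit trade of
training RMSE for a feasible, well-conditioned starting chromosome.

**Backpropagation with momentum** (comparator). Full-batch gradient
descent over *all* parameters with the study defaults, learning rate 0.2
and momentum 0.4: `v ← μ·v − η·∇; θ ← θ + v`. Gradients are analytic
through all five layers (chain rule through the log-space firing and the
normalization). The descent direction is the mean-squared-error gradient
`2·RMSE·∇RMSE`: the two objectives share minimizers, but the RMSE gradient
magnitude does not vanish at an exact fit (RMSE behaves like a norm), so a
constant step on RMSE itself oscillates indefinitely instead of settling.
Fitness traces report RMSE. Runs abort with a diagnostic if RMSE exceeds
1e6.

**Hybrid** (comparator). Per epoch: (a) with premises fixed the output is
linear in the consequents, so all of them are solved exactly by ridge least
squares on the design matrix whose row for sample `k` concatenates
`w̄_ik·[x_k, 1]` over rules; (b) one momentum gradient step on the premise
parameters only. A final LS solve closes the run.

## Evaluation protocol

Accuracy, sensitivity and specificity are reported as percentages with
malignant as the positive class. Undefined ratios (no positives in a test
set) are reported as NaN with a warning, never silently zeroed. Four
splitting schemes: 70/30 and 80/20 holdouts (test size rounded down) and
5-/10-fold cross-validation. Splitting is stratified by default — the
study says only "random sampling", but at 28.6% benign prevalence an
unstratified small test set can contain almost no benign nodules — and
per-fold class counts stay within one of the exact ratio. K-fold metrics
pool the confusion counts over test folds (bias-free for SN/SP with
unequal folds); a flag switches to per-fold percentage averaging for
comparison. Report tables round half-up to two decimals, and the overall
summary is the arithmetic mean of the twelve per-experiment rows
(3 sign sets × 4 schemes), the same averaging that produces the published
overall rows (e.g. 87.18 / 78.76 / 90.66 for the GA-trained model).

## Guideline trees

A hand-rolled CART-style binary tree with Gini impurity `1 − Σ p_k²`
serves sign ranking and guideline export. Codes are treated as ordinal
numerics with threshold splits (matching the branch-number semantics of
the printed guidelines); thresholds are midpoints between consecutive
observed values; the best split maximizes the sample-weighted impurity
decrease, ties broken toward the lower sign index then the lower
threshold. Growth is best-first — the frontier node whose best split buys
the largest decrease is expanded next — so a prepruning budget
(`max_splits = 7` in the reference guideline) is spent where it pays most.
Unbudgeted growth stops only at pure or unsplittable leaves. Leaf ties go
to malignant. No minimum leaf size and no postpruning. Sign importance is
the node-sample-weighted total Gini decrease per sign from the unpruned
tree; the magnitude scale of the published rank values is not defined, so
this standard importance is the documented stand-in. Trees export as an
indented text flowchart (ordinal branches phrased as sub-feature code
sets) and as Graphviz DOT.

## Synthetic nodule tables

The clinical table (398 nodules, 284 malignant / 114 benign) is not
deposited, so all tests run on a seeded generator that emulates its
schema: the full 27-sign catalogue with the literature high-risk
sub-feature sets, exact class counts by construction, and a single
effect-size knob `risk_lift ∈ [0, 1]`. For a sign with valid codes V and
high-risk set H, malignant rows draw from
`lift·U(H) + (1−lift)·U(V)` and benign rows from
`lift·U(V∖H) + (1−lift)·U(V)`; signs without consensus stay uniform.
Size P1 is log-normal (median 12 mm, 0.5 log-units — typical of surgical
thyroid series) in both classes; the diameter ratio P10 is
N(0.85, 0.15) benign with the malignant mean raised by `0.20·lift` (1.05
at full lift, identical at zero so the zero-lift table is an exact null).
Conditional signs (P7–P9, P12–P14, P19) emit code 0 when their gate is
absent; gating is minimal (capsule sub-signs require a capsule
relationship, solid-component features require a cystic component, the
inner-echo sign requires incomplete peripheral calcification) and is a
bookkeeping convention, not a clinical claim. Signs are conditionally
independent given the class; real inter-sign correlation structure is
unknown from the published material and not emulated. Consequently,
passing tests show the pipeline recovers planted class-conditional signal
of this simple form — they do not certify clinical performance, and
accuracies on the default table (risk_lift = 0.8) are far above the
published clinical values because the planted signal is cleaner than real
sonography.

P1's distribution and both P10 parameters are invented conveniences: the
published material gives no distributions for them.

## Problem sizes

The default experiment is the study-sized table (398 rows) with the study
hyperparameters (GA 100 iterations × population 50; BP/hybrid 100
iterations; 10 rules). A full GA 10-fold evaluation takes about 70 s on
one CPU with the population evaluated in one broadcast pass per
generation; the test suite's end-to-end check runs it at three enrichment
levels. The CLI demo config in the README uses a smaller table and fewer
generations purely for a fast first contact.

## Known limitations

- The generator's conditional independence makes the synthetic task easier
  than clinical discrimination; published clinical accuracy is not
  reproducible without the original table.
- Exact tree topologies and the exact published sign ranking are
  data-dependent and out of scope for the same reason.
- GA operator choices (tournament-2, arithmetic crossover, Gaussian
  mutation) are conventional defaults; the study does not specify its
  operators, so exact trace-level agreement with it is not expected.
- RMSE fitness on 0/1 targets optimizes calibration-free regression error;
  no ROC/threshold tuning is performed (threshold fixed at 0.5).
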
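# thyrocad

Computer-aided differential diagnosis of thyroid nodules from coded
sonographic signs: a Takagi–Sugeno neuro-fuzzy classifier (ANFIS) trained
by a genetic algorithm, plus a Gini decision-tree module that ranks the
signs and exports compact risk-stratification guidelines.

## Who this is for

Ultrasound risk-stratification guidelines (the TIRADS family) grade
thyroid nodules on a handful of sonographic features to decide who needs a
fine-needle aspiration biopsy. This package is for researchers studying
whether a *wide* feature set — 27 signs, each scored as integer sub-feature
codes (composition, echogenicity, shape, margins, calcification pattern,
capsule relationship, lymph-node features, …) — can be combined by machine
learning into a better differential diagnosis, and then distilled back
into a human-readable decision-tree guideline.

## The model

A first-order Sugeno fuzzy system with `R` rules over `n` scaled inputs.
Rule `i` has one Gaussian membership function per input
(μ_ij(x) = exp(−(x_j − c_ij)² / 2σ_ij²)) and a linear consequent
f_i(x) = p_i·x + r_i. The output is

    y(x) = Σ_i w̄_i(x) f_i(x),   w̄_i = Π_j μ_ij(x_j) / Σ_l Π_j μ_lj(x_j),

thresholded at 0.5 (benign = 0, malignant = 1, ties malignant). Free
parameters: `2nR` premise + `(n+1)R` consequent.

**Why 10 rules.** The experimental setup uses 10 Gaussian membership
functions per input and reports 820, 400 and 250 free parameters for the
27-, 13- and 8-input models. Those totals pin the structure down: with 10
rules each owning one MF per input, `2·n·10 + (n+1)·10` gives exactly
`820, 400, 250` for `n = 27, 13, 8`. A grid partition with 10 MFs per
input would instead generate 10^n rules, which is not representable and
matches none of the printed counts, so the cluster-based 10-rule
structure is the default (`n_rules` is configurable).

Initialization is fuzzy c-means (one cluster per rule; spreads from
weighted cluster variances; consequents from an exact least-squares
solve). Trainers, all minimizing training RMSE of the continuous output:

- `ga` — real-coded genetic algorithm (iterations 100, population 50,
  crossover 0.4, mutation 0.15; tournament selection, arithmetic
  crossover, Gaussian mutation, elitism);
- `bp` — full-batch backpropagation with momentum (learning rate 0.2,
  momentum 0.4), analytic gradients through all five layers;
- `hybrid` — per epoch an exact least-squares solve of the consequents
  followed by one gradient step on the premises.

Evaluation reports accuracy / sensitivity / specificity (%) with the
malignant class positive, under 70/30 and 80/20 stratified holdouts and
5-/10-fold cross-validation. The tree module grows Gini CART trees
best-first, ranks signs by total weighted impurity decrease, preprunes to
a split budget (7 by default) and exports the guideline as an indented
flowchart and Graphviz DOT.

Because the original 398-nodule clinical table is not public, the package
ships a seeded generator emulating its schema: exact 284/114 class
counts, the literature high-risk sub-feature sets enriched in malignant
rows, and one effect-size knob `risk_lift` (0 = pure null, labels
independent of signs). See `docs/methods.md` for distributions and
caveats.

## Worked example

```sh
$ thyrocad simulate --n 398 --malignant 284 --risk-lift 0.8 --seed 1 --out nodules.csv
wrote 398 nodules (284 malignant) to nodules.csv

$ thyrocad evaluate --input nodules.csv --trainer ga --scheme holdout_70_30 --seed 1
scheme  trainer AC      SN      SP
holdout_70_30   ga      99.16   100.00  97.06
```

Of the 119 held-out nodules, the GA-trained ANFIS classifies 99.16%
correctly, catches every malignant nodule (SN 100.00) and clears 97.06% of
the benign ones (SP 97.06). Accuracy this high reflects the cleanliness of
the planted synthetic signal at `risk_lift 0.8`, not clinical performance.

```sh
$ thyrocad tree --input nodules.csv --max-splits 7
if P25 in {1, 2, 3, 4}:
  if P4 in {1}:
    -> benign (purity 1.00, n=95)
  if P4 in {2}:
    if P6 in {1, 2}:
      -> malignant (purity 1.00, n=16)
...
# splits=7  classification loss error=0.0025
```

Read: nodules without suspicious central lymph nodes (P25 codes 1–4) and
without a taller-than-wide shape (P4 code 1) fall to a pure benign leaf;
branch numbers are the sub-feature codes of each sign. The prepruned
7-split tree misclassifies 0.25% of its own training table — again a
consequence of the synthetic signal being far cleaner than clinical data,
where the same budget leaves a much larger resubstitution error.

The full pipeline — simulate/load, evaluate every trainer under every
scheme, aggregate, rank signs, export the guideline, write a
reproducibility manifest — is one command:

```sh
thyrocad run --out-dir results/ --seed 1          # study-sized, a few minutes
```

## Layout

```
src/thyrocad/
  fis_core.py           Sugeno inference, encoding, scaling, serialization
  initialization.py     fuzzy c-means and initial rule placement
  trainers.py           GA / backpropagation / hybrid least-squares
  evaluation.py         splits, AC/SN/SP metrics, aggregation
  guideline_tree.py     Gini CART, ranking, prepruning, guideline export
  synthetic_nodules.py  27-sign schema and seeded table generator
  cli.py                thyrocad simulate|train|evaluate|tree|run
docs/methods.md         model, conventions, generator, limitations
```
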
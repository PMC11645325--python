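# Methods

This note records the models and procedures the package implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical/design choices made where the design was open.

## Adaptive tabu simulated annealing

The optimizer maximizes an arbitrary objective over a box of integer and float
axes. One **iteration** is a temperature level; each level proposes up to
`n_moves` candidates. A candidate is produced by perturbing every axis of the
current solution with `N(0,1) · step_scale · (upper − lower)`, clipping to
bounds, and rounding integer axes half-away-from-zero. Candidates whose tabu
key is in the FIFO tabu list are regenerated up to 5 times, then the move is
skipped — a livelock guard on tiny spaces. Every *evaluated* candidate is
pushed to the tabu list (capacity `tabu_length`, oldest evicted). Acceptance
is Metropolis: always for Δ ≥ 0, with probability `exp(Δ/T)` otherwise. The
best solution is tracked separately and replaced only on strict improvement,
so equal-valued ties keep the earlier solution and reruns are bit-identical.

Published settings: `T_min = 2`, reheat rate `β = 2`, tabu length 20,
300 iterations, 8 moves per iteration, uniform initialization, normal
neighborhood. The cooling operator, initial temperature and reheat trigger
are not published (the cited source is a job-shop variant), so the package
adopts standard simulated-annealing practice and exposes every knob:

| parameter | default | role |
|---|---|---|
| `alpha` | 0.95 | geometric cooling `T ← αT` per level, floor `T_min` |
| `t_init` | 100 | starting temperature; also the reheat cap |
| `stall_reheat` | 10 | consecutive non-improving levels before `T ← βT` |
| `step_scale` | 0.1 | neighborhood sd as a fraction of each axis range |
| `quantize` | 1000 | float-axis tabu grid: 1/1000 of the axis range |

`step_scale` rescales the literal unit-variance step because the tuned axes
span (0, 1] and [1, 50]; a raw `N(0,1)` step would be a full-range jump on one
axis and a 2% nudge on another. Setting `step_scale = 1/range` per axis
recovers the literal rule. Tabu membership quantizes float axes because exact
float equality would never fire; integers compare exactly. The search runs
its full iteration budget: the temperature floor (rather than a below-`T_min`
stop) keeps the trace length fixed, and at the floor with β-reheats pending
the rule is the published adaptive control.

The flowchart's cool-vs-reheat decision is stated qualitatively, not as a
formula; the geometric/stall rule above is this package's documented stand-in,
chosen so the published values (β, T_min, tabu length, budgets) drop in
unchanged. Likewise, whether the tabu list stores proposed or evaluated
solutions is ambiguous; every evaluated candidate is stored, and when a move
is abandoned because all its regenerations were tabu, the refused key is
recorded too. The latter matters on spaces smaller than the tabu capacity:
with skip-only semantics, once every reachable neighbor is remembered the
list can never age (eviction happens only on insertion) and the search
freezes; recording the refused proposal restores the flowchart's
"note it down, evict the oldest" behavior and lets exploration resume.

## Learner objective

Solutions map onto an XGBoost binary classifier: boosting rounds, maximum
depth, maximum delta step, parallel trees per round (integers, [1, 50]);
learning rate, L1, L2 (floats, (0, 1]); minimum split loss γ ((0, 50]). The
loss is logistic plus `Ω(f) = γT + ½λ‖w‖² (+ α‖w‖₁)`. All other learner
settings are library defaults except `tree_method="hist"`, `max_bin=64` and a
single thread, which fix determinism and keep worst-case fits affordable;
these affect split candidate resolution only. Tuned-parameter tables from the
study report learning-rate/L1/L2 values above 1, outside their own declared
(0, 1] range; the declared range is honored.

The objective handed to the annealer is the mean validation-fold AUC of
stratified 4-fold CV on the 80% training split. Fold assignment and the
rebalanced fitting sets are frozen per optimization run, so the objective is
a deterministic function of the solution and no fold noise leaks into the
search. Rebalancing (duplication-only oversampling, uniform undersampling)
applies to the k−1 fitting folds only — never the validation fold or the test
set — because duplicated minority rows straddling a fold boundary would
inflate validation AUC. Reported "training" metrics are validation-fold
metrics (the study does not say which it reports; validation-fold is the
conservative reading). The classification threshold for accuracy/sensitivity/
specificity is 0.5, configurable.

Model selection: the study states both "mean training AUC decides" and
"highest testing performance is interpreted". Both selections are computed
and recorded (`best_by_cv`, `best_by_test`); the pipeline interprets
`best_by_cv` and flags the other.

## Imputation and encoding

Missing numeric cells are replaced by the mean of the K nearest rows, with
nan-aware Euclidean distance over standardized numeric columns (unscaled
binary dummies included); imputed dummies are thresholded at 0.5; categorical
cells take the modal value of the K nearest donors. K is not published;
default K = 5, and `validate_imputation` — withhold 10% of cells, impute,
score per-feature MAPE on the withheld cells only — is exactly the instrument
for choosing it empirically (see `examples/impute_validation.py`). Zero-valued
originals are excluded from MAPE and counted; categorical accuracy is a
mismatch rate, reported separately from the MAPE table.

The source text states both encode-then-impute and impute-then-encode. The
package imputes numerics on the raw table and encodes afterwards: imputing
raw categoricals by neighbor mode is well defined, whereas averaging dummy
columns first and thresholding later answers a different question. Encoding:
c-category features become c−1 dummies; the reference level is "Unknown"
when such a level exists (an uninformative natural baseline), else the
lexicographically first level. Timestamps reduce to month and hour; repeated
vital-sign readings (columns `pulse_rate_1, pulse_rate_2, …`) are averaged;
waiting time passes through in minutes; zip code is treated as numeric, as
its printed numeric range implies — acknowledging it is really a
high-cardinality proxy for socio-economic context.

## Feature selection

Greedy wrapper search scored by k-fold AUC of a decision tree or random
forest on the candidate subset (library-default estimators with a fixed
seed; the study does not state theirs). SFS adds the best single feature
while the improvement exceeds the tolerance (default 1e-4, to avoid chasing
CV noise; the study states no tolerance). SBS removes the feature whose
removal leaves the criterion highest, accepting on strict improvement (the
set may empty itself) or when the cost is within the tolerance while at
least one feature remains. Ties break to the lowest column index. Subset
scores are memoized so each distinct subset is evaluated once. The empty
subset scores AUC 0.5. No 12-feature cap is hard-coded; `max_features` is
exposed. The five data groups are the four selector outputs plus all
features.

## Synthetic cohort generator

The generator emulates the published raw-data summary: truncated-normal
numeric marginals at the printed mean ± sd clipped to the printed range (age,
BMI, blood pressures, pulse, temperature, O₂ saturation, respiratory rate,
waiting time — the last rounded to whole minutes), ESI as a rounded latent
normal on {2..5}, printed category frequencies for the four locations, sex,
ethnicity and smoking status, a fixed 24-value zip pool inside the printed
range, uniform day/month/hour, and LAMA prevalence 0.66%. A Gaussian copula
imposes a modest pulse–respiratory-rate correlation (ρ = 0.3) by default —
the published information is marginal-only, but nearest-neighbor imputation
is only meaningfully testable with some cross-feature structure. Class-
conditional missingness rates are exposed (the real pattern is class-
dependent in unpublished ways; no default pattern is asserted).

The outcome is logistic on standardized features. Default planted signal:
+2.5 log-odds per sd of ESI, −2.5 per sd of waiting time — "strong" effects
(Bayes AUC ≈ 0.97) chosen so that signal recovery is unambiguous against the
0.66% base rate; an empty weight map gives a signal-free cohort. The
intercept is calibrated by root-finding so realized prevalence matches the
target; the ground-truth record (weights, intercept, Monte-Carlo Bayes AUC)
upper-bounds any fitted model's achievable AUC in tests.

What passing tests on this cohort do **not** show: real triage data has
skewed, heaped, jointly dependent vitals, informative missingness, and far
richer outcome structure. The generator's MAPE values are accordingly much
larger than those reported for the hospital data (weak cross-feature
structure gives KNN little to exploit), and pipeline AUCs here measure
recovery of a known mechanism, not clinical performance.

## Attribution

Attributions are exact tree-path Shapley values computed by the TreeSHAP
algorithm built into xgboost (`pred_contribs` / `pred_interactions`), in
log-odds margin units because probability-space scores are not additive.
Local accuracy (base + Σ scores = margin) is measured on every matrix. The
backend accumulates in float32: measured residuals are ~2e-7 for the 1–2
round, shallow models this framework's tuning actually produces, growing to
~1e-5 for ensembles of hundreds of trees. The 1e-6 additivity contract is
therefore asserted in the tuned operating regime and on the tiny trees whose
Shapley values are verified against a brute-force subset-enumeration oracle
(implemented in the test suite, path-dependent expectations with
cover-weighted branch averaging). Global importance is mean |score|; the
direction indicator is the correlation between a feature's scores and its
values, compressing the red-high/blue-low reading of a beeswarm plot.

## Problem sizes and reproducibility

Bundled end-to-end demonstrations (test suite and `scripts/acceptance.py`)
use 20,000-visit cohorts, 4-fold CV, oversampling, and an annealing budget of
50 evaluated candidates for the learner objective; toy-space checks use the
full published budget (300 × 8). Enumeration oracles (exhaustive subset
criteria, all-pairs AUC, brute-force Shapley) back every nontrivial expected
value. Every random draw — generator, splits, folds, resampling, annealer —
derives from named seeds recorded in the run manifest; identical configs
yield byte-identical reports.

## Known limitations

- The adaptive temperature rule is a documented stand-in for an unpublished
  formula; results with other cooling operators may differ.
- Duplication-only oversampling is implemented by design (no SMOTE-style
  interpolation), matching the stated procedure.
- Float32 attribution residuals exceed 1e-6 for very large ensembles (see
  above).
- MAPE is undefined at zero originals; such cells are excluded and counted
  rather than imputed around.
- The generator reproduces marginals and a planted mechanism, not the joint
  distribution of any real ED population; no numeric result on synthetic
  data should be read as a clinical estimate.
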
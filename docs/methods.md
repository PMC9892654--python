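# Methods

`boolmark` implements a two-phase framework for deriving predictive biomarker
panels from a quantified expression matrix (features × samples) labelled with
three drug-response classes, and for turning a chosen panel into
response-group-specific Boolean expression signatures.

## Response labelling

Response classes are defined from the log2 fold change of the proliferation
marker Ki67 between treated and vehicle conditions: responders (RD) show at
least a two-fold decrease (log2 fc ≤ −1), poor responders (PR) at least a
two-fold increase (log2 fc ≥ +1), and non-responders (NR) everything in
between. Both thresholds are closed, so a fold change of exactly two maps to
the extreme class; this is a deliberate fixed rule — a symmetric, disjoint
three-way partition — since "within two-fold" phrasings are ambiguous at the
boundary. Missing (undetectable) abundances are imputed with independent
Uniform(0, 1) draws, one unit being the minimal machine-detectable amount on
the abundance scale; the bounds are configurable and all randomness flows
through explicit integer seeds.

## Differential-expression pre-filter

Each feature is tested with a classical one-way fixed-effects ANOVA across
the response groups, computed from explicit between/within sums of squares
(vectorized over features; p-values from the F distribution). Features with
p < α (default 0.05, strict inequality, uncorrected) form the DEP pool.
No multiple-testing correction is applied by default because the filter is a
screening step feeding a wrapper selection stage, not an inference procedure;
a Benjamini–Hochberg option exists. The test runs on abundances as provided;
a log2 option is available. Degenerate features follow a documented
convention: zero within-group variance gives p = 0 when group means differ
and p = 1 (F = 0) when the feature is constant.

## Evaluation engine

All selection stages are scored by the same engine: a linear-kernel
multi-class SVM (one-vs-one decomposition, regularization constant C = 1.0)
with per-feature standardization fitted on the training split only,
evaluated under repeated stratified 80/20 holdout (default 50 replicates).
Stratification is the default because with only 9 samples in the smallest
class a plain 20% split can leave a class absent from training; an
unstratified mode exists. A `HoldoutPlan` pins the replicate split seeds, so
any two feature sets evaluated under the same plan see identical partitions
and accuracy differences are attributable to the features (a paired design).
The engine is deterministic given the plan.

Reported metrics: the per-replicate accuracy vector and its mean; a 3×3
confusion matrix summed over replicates (rows true, columns predicted, in
RD/NR/PR order); per-class precision and sensitivity derived from that
summed matrix (so they are exactly recomputable from it); and per-class
one-vs-rest ROC AUC on decision scores pooled over replicates. Because
stratified test sets have a fixed size, the mean per-replicate accuracy
equals the micro-averaged trace/total of the summed confusion matrix.

## Drop-out importance and greedy forward selection

The importance score of feature *i* in a pool is the relative accuracy loss
its removal causes:

    IS_i = −(PA_i − PA_O) / PA_O

with PA_O the mean holdout accuracy of the full pool and PA_i the accuracy
with feature *i* removed, both under the same plan. IS > 0 marks a
positive-impact feature (its removal hurts). Ties in the descending IS
ranking keep pool order for determinism.

Greedy forward feature selection (GFFS) seeds the model with the top-ranked
positive-impact feature and walks once through the remaining ranked
features, accepting a candidate only if the mean accuracy strictly
increases — equal accuracy is a skip, so accepted-step accuracies are
strictly increasing by construction. The single ranked pass costs one
evaluation per candidate; together with the n + 1 evaluations of the
drop-out analysis the whole selection is ~2n classifier evaluations for an
n-feature pool, against the O(n²) of classical forward selection or
recursive elimination. When the reference model is already at ceiling
(every IS exactly 0, which happens on strongly separable synthetic data),
the convenience pipeline `discover_panel` falls back to the full importance
ranking so selection can still proceed; this regime does not arise when
accuracy is below 1.

Compact panels are found by exhaustively evaluating all C(n, k) subsets of
the selected markers at the requested sizes under a shared plan (guarded by
a configurable cap, default 10⁵ panels), with ties broken lexicographically
by pool order.

## Boolean signature derivation

Panel expression is discretized per feature. The `median` scheme divides a
feature row by its median across samples (the median must be positive) and
thresholds at 1; a value exactly at the median maps to 0 by default
(configurable) — the underlying rule is stated only for strict ">1 or <1",
so the tie case needs a fixed convention. The `quantile_band` scheme maps
values below the low quantile (default 30%) to 0, above the high quantile
(default 70%) to 1, and anything between to INDETERMINATE;
linear-interpolation sample quantiles are used. Thresholds are
cohort-internal by default (each cohort is binarized against its own
medians/quantiles); freezing discovery thresholds is possible by binarizing
externally and supplying bits directly.

The distinct bit-patterns observed among a group's samples are the minterms
of that group's Boolean function. Exact minimization is by the
Quine–McCluskey procedure: tabular prime-implicant generation, then
iterated essential-prime extraction and row/column dominance on the
coverage chart, and exact branch-and-bound set cover on any residual cyclic
core — the same optimum Petrick's method defines, computed without the
exponential product expansion, which is intractable on dense six-variable
charts. Among minimum-cardinality covers the fewest total specified
literals wins, then lexicographic term order, making the output unique and
deterministic. Minimized covers of equal size and literal count but
different composition are possible relative to other exact minimizers;
equivalence, cardinality and literal count are the stable contract.

Each minimized term is a signature; IDs ascend in term order and coverage
is the fraction of the group's samples matching the term (a sample can
match several). Because the minimized function is truth-table-equivalent to
the observed patterns, a group's signatures jointly cover every sample of
that group — re-predicting the discovery cohort always includes the true
group. The same bit-pattern can occur in two groups; this produces
overlapping signatures and is reported as a warning, not an error, since
the predict-then-compare workflow tolerates ambiguity.

Prediction matches a sample's bits against every group's signatures with
consistent-with semantics: specified literals must be satisfied,
INDETERMINATE bits satisfy either value. All groups with at least one match
are returned (singleton = unambiguous call, empty = explicit no-call);
no forced single call is made.

## Synthetic cohorts

The generator emulates a pharmacoproteomic discovery cohort: by default 40
samples split 14/17/9 across RD/NR/PR, 100 features of which 10 are
informative, within-group noise SD 1 on a log-abundance scale around a
baseline of 10, and a missing-cell fraction of 0.0016. Informative features
receive group-mean offsets of magnitude `effect_size × noise_sd` following
a cyclic palette of patterns (RD-high, PR-low, monotone RD>NR>PR, NR-high,
and mirrored forms) so differential expression occurs in both directions;
non-informative features are i.i.d. noise. Effect size 3 is the default
discovery condition; effect size 0 gives an exact null used for
calibration checks.

The generator does not model MS-specific intensity distributions, feature
correlation beyond the planted group structure, batch effects, or
missingness that depends on abundance. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under a clean planted
model, not expected field performance on real proteomes, where correlated
features and non-random missingness will lower recovery rates.

## Problem sizes used in the checks

The test suite and the reproduction script run the full pipeline on
100-feature, 40-sample cohorts (10 replicate seeds in the suite, 5 in the
script) with 50-replicate holdout plans; the GFFS evaluation-count bound is
exercised up to 157 features with a 3-replicate plan, and minimization is
cross-checked on 200 random functions of up to six variables against
brute-force prime enumeration and exact cover search. These sizes mirror
the discovery-cohort scale the framework targets while keeping a complete
run in the minutes range on one CPU.

## Known limitations

- The three-class labelling rule is an interpretation at the PR boundary
  (PR iff log2 fc ≥ +1, the mirror of RD); literature phrasings of
  "within two-fold increase" overlap the NR definition and cannot be
  implemented as written.
- Wrapper selection under small-sample holdout is noisy; GFFS results
  depend on the plan's split seeds (deliberately pinned and reported).
- The exhaustive panel search is exponential in panel size and guarded by
  a cap rather than pruned.
- Signatures derived under median binarization and applied under
  quantile-band binarization use consistent-with matching for mid-band
  bits, which favours sensitivity over specificity of calls.
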
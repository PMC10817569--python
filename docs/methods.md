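# Methods

## Model

`ruleboost` predicts a binary short-term adverse event from binary
clinical features with a two-stage model.  The first stage is a gradient-
boosted tree classifier (XGBoost, logistic objective).  The second stage
is a knowledge base (KB) of at most 20 conjunctive rules, each of the form
`IF l1 ∧ l2 [∧ l3] THEN increase|decrease` where every literal requires a
feature to be present (`x=1`) or absent (`x=0`); absence literals encode
protective conditions.  A rule that fires for a patient adds a signed
offset to the base model's log-odds, with magnitude set by the rule's rank
(low/medium/high → 0.4/0.8/1.2 by default, configurable per KB file); the
sum maps back through the logistic function.  Additivity in log-odds keeps
every adjusted probability strictly inside (0, 1), composes symmetrically
(an increase and a decrease rule of equal rank cancel exactly), and makes
an empty KB the exact identity.  The adjustment mechanism and the default
magnitudes are this package's design choice; the rank scale is the
interface a clinical reviewer would edit.

Base probabilities are clipped to [1e-6, 1 − 1e-6] before the logit so
that rules can always move a saturated prediction.

## Preprocessing

Cohorts are CSV tables of {0, 1, missing} cells plus one strictly binary
outcome column.  Missing tokens default to the empty string, `NA` and
`NaN`.  Features constant among their non-missing values are removed
(they carry no signal regardless of missingness).  Missing cells are
replaced by the feature's most frequent value; 0/1 ties resolve to 0 —
the majority value in a sparse table — and are flagged.  Two imputation
paths exist deliberately: the full table is imputed once for feature
selection and rule mining, while each evaluation split refits modes on its
training part only.  The first path leaks test information into selection;
it is retained because a cohort of a few hundred rows cannot spare a
validation partition, and a nested leakage-free alternative
(`repeated_evaluation(..., select_k=...)`) is available for comparison.

## Feature selection

Each feature is scored by the Pearson chi-squared statistic of its 2×2
contingency table against the outcome, computed in closed form
n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), without continuity correction (the
statistic only ranks features, so the correction would merely shrink all
scores).  Tables with a zero marginal score 0, ranking constant-in-split
features last.  Ranking descending by statistic (ties: ascending name)
yields nested top-k sets for every k; the hybrid set_k appends the KB's
features (alphabetically) to the model set_k.  Ranking by statistic and by
p-value coincide here since every table has one degree of freedom.

## Rule mining and curation

All antecedents of 1–3 distinct features, with both polarities by default,
are scored exhaustively: support (patients satisfying the conjunction),
subgroup event rate, baseline event rate, direction (sign of subgroup −
baseline), and effect ratio subgroup/baseline.  Survivors need support
≥ 10 and a symmetric effect max(ratio, 1/ratio) ≥ 1.5; on a 266-row cohort
these defaults admit tens to a few thousand candidates while excluding
subgroups too small to estimate a rate.  Candidates sort by effect
strength, then support, then antecedent text, making the list
reproducible.  Ranks are assigned by positional tertiles of that order
(top third high) or read from a curation file mapping antecedent to rank —
the mechanism standing in for expert clinical review, which also lets a
user reproduce a published KB verbatim.  The strongest 20 form the KB.
Zero-support antecedents are flagged unusable; antecedents whose subgroup
rate equals the baseline have no direction and are dropped.

## Evaluation design

Per iteration: an 80/20 uniform random split (test size ⌊0.2 n⌋), modes
refitted on the training part, both parts imputed, the booster trained on
the chosen predictor set, test rows scored.  A draw whose test part lacks
either outcome class would leave MCC and AUC undefined, so it is redrawn
under an incremented sub-seed (bounded at 100, logged).  The hybrid model
needs no training of its own: it reuses the iteration's fitted booster and
adjusts its probabilities, so one fit serves both models and their
per-iteration metrics are paired by construction (split hashes are logged
to verify this).  One hundred iterations are run per predictor count k;
the operating k per model maximizes mean MCC, ties resolving to the
smaller k.  Split seeds derive from
`SeedSequence([base_seed, iteration])` truncated below 2³¹, and each
iteration's training seed derives from its split seed, so the entire
harness is bit-reproducible from one integer.

Metrics, all implemented from their definitions: F1 (0 when TP = 0); MCC
(0 when any denominator factor vanishes — a one-class prediction is no
better than random); rank-based AUC with ties counted ½; ECE over 10
equal-width bins, right-closed except the first, in the reliability-
diagram form — per-bin accuracy is the observed event fraction and
confidence the mean predicted probability; a predicted-class-confidence
variant is available (`mode="class"`).  SDs use the n−1 denominator.
Model comparison uses a two-sided paired t-test on per-iteration vectors;
zero-variance differences are flagged rather than fed to the t
distribution.  ROC curves are averaged vertically: each iteration's curve
is interpolated onto a fixed 101-point false-positive-rate grid and the
mean and SD of the true-positive rate reported per grid point.

Classification for F1/MCC uses threshold 0.5 (inclusive); the threshold is
a config key, not a tuned quantity.

## Synthetic cohorts

The generator emulates the target data regime: n = 266 patients, 35
Bernoulli features with rates spanning 0.02–0.5 geometrically (many rare
flags, a few common ones), 2% missing cells completely at random, three
all-zero constant columns, and a ~17% outcome prevalence.  Outcome
probabilities follow logistic(intercept + Σ planted effects of satisfied
antecedents); the intercept is calibrated by bisection on the realized
feature matrix so the expected prevalence hits its target within 0.01.
Features are independent by default; an optional latent-block mode
correlates chosen features for stress tests.  What the generator does not
emulate: real comorbidity co-occurrence structure, informative
missingness, and measurement error in history taking — so green tests
demonstrate correctness of the machinery and recoverability of planted
structure, not clinical transportability.

## Benchmark

`ruleboost.benchmark` fixes one study-shaped comparison: three planted
single-feature effects (within reach of chi-squared selection) plus two
planted two-feature conjunctions whose features are withheld from the base
predictor set, so only the mined KB can exploit them.  The base model uses
the top 8 non-withheld predictors; the hybrid adds the KB mined at default
thresholds.  Over 100 paired splits the hybrid's mean MCC exceeds the
base's — the qualitative ordering the hybrid design exists to produce.
The same module runs the large-sample recovery check (n = 2000, one
planted 1.5 log-odds conjunction over sparsity-0.3 features: recall 1 at
default thresholds) and the null-mining control (no planted effects,
effect-ratio threshold 2: survivors are a small, seed-stable fraction of
the antecedent space).  Problem sizes — 266 rows for the benchmark, 2000
for recovery, 100 iterations, sweep restricted to a handful of k values in
the demos — were chosen as the smallest at which the respective effects
are comfortably identifiable.

## Numerical and degenerate-input choices

- Chi-squared on any zero-marginal table: 0, not an error.
- Mode ties: 0, flagged; entirely missing feature: error.
- `split_cohort` on a one-class cohort: error after bounded redraws.
- Effect ratio of a zero-event subgroup: 0 (strength ∞), sorts first.
- Empty KB: hybrid ≡ base exactly, everywhere.
- Probability clipping ε = 1e-6 before logit.
- All stochastic components take explicit integer seeds; nothing reads
  global random state.

## Known limitations

- The leakage in full-dataset feature selection and rule mining is
  faithful to the intended study design but inflates absolute metrics;
  use `select_k` for honest nested selection.
- Automatic tertile ranking is a crude stand-in for clinical judgment;
  the curation file is the intended production path.
- Rules combine additively; no interaction or conflict resolution beyond
  signed summation.
- The miner's exhaustive enumeration is O(P³·2³·n) and is practical to a
  few dozen features, not hundreds.
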
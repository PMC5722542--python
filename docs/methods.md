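# Methods

## Data model and annotation parsing

A *release* bundles a binary genomic feature matrix (cell line × feature)
with a long-form drug-response table (drug, cell line, logIC50 in log10 µM).
Gene entries in the supported CSV dialect are `x::y` token pairs: the gene is
called mutated iff the coding-variant slot is anything other than `wt`/`na`
(case-insensitive, whitespace-trimmed) or the copy-number slot differs from
the wild-type token (default `0<cna<8`, matched literally — numeric CNA
parsing is deliberately out of scope because encodings vary between exports).
Fusion columns hold a not-detected vocabulary versus a fusion identifier;
unknown fusion tokens count as detected and are logged, since files name the
identified fusion rather than drawing from a closed vocabulary.  msi is one
extra binary column.  Responses supplied on the natural-log scale are
converted with logIC50 = ln IC50 / ln 10, so differences read directly as
orders of magnitude in molar concentration.

Unmeasured drug–cell pairs are represented by absence of a record, never by
sentinels: screen coverage is genuinely partial and the per-drug splits are
defined by which pairs were measured.  Writing a release serialises the
binary flags back to canonical tokens (`mut::…`/`wt::…`), responses via
shortest-round-trip float repr, so read∘write is the identity bit-for-bit.

## Time-stamped partition and labels

Per drug: training = cell lines with a measured response in release 1; test
= cell lines measured in release 2 and absent from the training set.  The
sets are disjoint by construction and an assertion enforces it.  The
sensitivity threshold is the median training logIC50 (even counts: mean of
the central pair) and is reused unchanged for the test set.  Sensitive means
strictly below the threshold; a response exactly at the threshold is labelled
resistant — "sensitive" is defined by strict inequality and the tie case is
otherwise unspecified, so the strict reading is applied.  Drugs whose test
set is smaller than a configurable minimum (default 1) or whose training
labels collapse to one class are excluded from the comparison and reported
with a reason, never silently dropped.  If a cell line's feature profile were
to differ between releases, the release-1 snapshot is used for training;
such lines are never test points anyway.

## Single-gene markers

The per-(drug, feature) association test is a pooled-variance two-group
comparison of logIC50 between mutant and wild-type training cell lines — a
two-sample t-test with equal variances, identical to one-way ANOVA with two
groups.  This is a deliberately self-contained univariate stand-in for the
precomputed multivariate association p-values that accompany the public
releases; with a single response variable the two coincide in form.  Features
with fewer than `min_mutants` (default 3 — the smallest count that allows a
within-group variance estimate with any replication; applied symmetrically
to the wild-type group) are untestable and carry p = 1.  Zero variance in
both groups with equal means also yields p = 1.

Correction runs over the full drug × feature family: Benjamini–Hochberg at
FDR 20% by default, or a fixed-cutoff mode (default 0.00840749) retained
purely as a compatibility setting for comparing against externally published
association tables — applying a threshold calibrated for a different test is
dubious, which is why it is not the default.

The best marker is the lowest-p association, kept even when non-significant
so the single-gene approach is evaluated at its best case; ties break toward
the larger |mean difference|, then lexicographic feature name (both
tie-breaks are conventions of this package).  As a classifier the marker
predicts sensitive exactly for mutant cell lines, regardless of the effect
direction; this is the rule whose degenerate bookkeeping (a marker absent
from every test cell line makes no prediction and scores PR = MCC = 0) the
evaluation conventions require.  A direction-aware mode (resistance markers
predict mutants resistant) exists but is off by default.

## Multi-gene markers

A random-forest classifier per drug over all features.  Defaults follow the
canonical protocol: 1000 trees, `m_try` (features considered per split)
selected over the full grid 1..n_features by 10-fold stratified
cross-validation with folds shared across the grid, selection by best mean
per-fold MCC, ties toward the smallest `m_try`.  An alternative `cv_rmse`
selection (RMSE of the sensitive-vote fraction against the 0/1 label,
minimised) is implemented because both selection rules appear in practice;
MCC is the default since the entire downstream evaluation is MCC-based.
Folds that lose a class are refolded with a shifted seed up to a retry cap.
Prediction: sensitive iff the sensitive-vote fraction strictly exceeds 0.5
(an exact 0.5 is resistant); columns are aligned by feature name.  Each
drug's seed is derived from the cohort seed and a CRC-32 of the drug id, so
per-drug results do not depend on processing order.

The comparison's "cv" stage for the forest reports metrics of the pooled
out-of-fold predictions at the chosen `m_try`; because the same folds served
model selection, this stage is expected to sit between the (memorised)
training fit and the honest test performance.  The single-gene marker has no
selection-by-CV stage; its classifier is a fixed function of one column, so
only train and test slots are populated for it.

## Metrics and cohort summary

MCC, precision, recall and F1 from the confusion matrix with explicit
degenerate conventions: any zero factor in the MCC denominator ⇒ MCC 0 (the
random-baseline value, extended to all degenerate denominators for
consistency); PR 0 when nothing is predicted sensitive; RC 0 when nothing is
truly sensitive; F1(0,0) = 0; a no-prediction marker ⇒ MCC = PR = 0 with a
flag.  Win counts use strict inequality with ties counted separately.  The
2×2 sign table of test MCCs bins exact zeros with the non-positive cells and
additionally reports them as a separate tie count, preserving the partition
property while exposing the ambiguity.  Spearman correlations (test MCC of
the forest against test-set class imbalance, defined as n_sensitive −
n_resistant, and against test-set size) are two-tailed, using the exact
permutation null below n = 10 and the large-sample approximation otherwise;
constant ranks are reported as not computable rather than as a number.

## Synthetic cohorts

The generator emulates the structure the analysis assumes: independent
Bernoulli mutations with per-feature prevalences drawn log-uniformly from a
configured range (default 0.02–0.3: sparse, as real somatic panels are);
logIC50 = per-drug baseline (Normal(0,1) in log10 µM — only relative
separation matters downstream) + additive driver effects + Gaussian noise
(default SD 0.5 log10 µM); measured pairs sampled uniformly at per-release
coverage rates (defaults 0.576 and 0.8068, the coverage of the two public
releases the pipeline targets); release 2 keeps every release-1 cell line,
measurement and value, and adds new cell lines drawn from the same law.
Default scale mirrors those releases: 638 cell lines growing by 70, 127
drugs, 71 features (genes + 3 named fusions + msi).  Drug kinds are
allocated deterministically by largest-remainder rounding of the configured
mix (default 40% single-driver at effect −1.0, 40% multi-driver with 3
drivers at −0.6 each, 20% null) so cohorts are exactly reproducible; drivers
are drawn without replacement from the panel excluding msi; cytotoxic /
targeted class labels are assigned by a deterministic rotation at roughly
the 14/127 rate seen in real panels, purely to exercise stratified
reporting.  A single `numpy` Generator seeded from the config drives all
draws in a fixed order (prevalences → mutations → baselines → driver
assignment → noise → coverage), so identical configs are bit-reproducible.

What the generator does **not** model: tissue-of-origin structure,
time-dependent batch effects between releases, dose–response curve error
structure, or linkage between features.  Passing tests therefore demonstrate
the pipeline's correctness and its qualitative behaviour (recall dominance
of multi-gene markers, overfitting ordering), not quantitative performance
on real screens.

## Problem sizes and numerical choices

The test suite and the acceptance analyses run scaled-down forests (100–200
trees over coarse `m_try` grids, 5–10 folds) on cohorts of 30–60 drugs and
200–300 training cell lines; these sizes are the package's chosen trade-off
between statistical resolution of the qualitative claims and quick, exactly
reproducible runs, while library defaults remain the full protocol (1000
trees, full grid, 10 folds).  The "comparable F1" criterion in the
recall-dominance analysis is operationalised as multi-gene F1 ≥ single-gene
F1 − 0.05, i.e. within five F1 points — "comparable" needs a number and 0.05
is the same order as the run-to-run spread of F1 at these test-set sizes.
Fold counts are capped by the minority class size; random draws everywhere
flow from explicit seeds; CSV exports use shortest-round-trip float
formatting so identically seeded runs produce byte-identical reports.

## Known limitations

* The univariate association test ignores covariates (tissue, msi) that a
  multivariate analysis of a real screen would model; p-values on real data
  will be better calibrated within strata than across them.
* Classification forests only; an RMSE-selected regression forest on the
  continuous response is a plausible alternative that is intentionally not
  implemented (only RMSE *selection* of the classification forest is).
* The dialect reader targets the early wide-CSV release format; post-2015
  long-format exports need conversion upstream.
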
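# Methods

`phenostrat` stratifies individuals from tables of unordered categorical
phenotype answers (a constitution-type questionnaire: three "extreme"
classes Vata/Pitta/Kapha and two-class mixtures). This note documents the
models, the synthetic-data stand-in, the numerical choices, and what the
shipped checks do and do not establish.

## Synthetic cohorts

The original questionnaire data are not publicly deposited, so every stage
runs against a seeded generator that reproduces the study regime. Its
defaults *are* the study conditions and are not tuned per analysis:

| parameter | default | meaning |
|---|---|---|
| `n_per_class` | 66/35/46 | extreme samples per class (147 total) |
| `n_nonextreme` | 40/33/33 | mixtures per parent pair (106 total) |
| `n_features` | 133 | categorical features, 2–4 levels each |
| `n_informative` | 80 | class-informative features (laid out first) |
| `signal_strength` | 0.85 | probability mass on a class's preferred level |
| `n_blocks` | 12 | contiguous correlated feature blocks |
| `block_coupling` | 0.5 | P(informative feature follows its block latent) |
| `missing_rate` | 0.03 | MCAR cell blanking before preprocessing |

Each informative feature assigns each class a *preferred level* by cycling
level indices with the class index (offset by the feature index), so
two-level features cannot separate all three classes — single questions are
suggestive, combinations decisive, as in real questionnaires. The
class-conditional distribution interpolates between uniform and a point
mass: at `signal_strength = 0` it is uniform (hence identical across
classes, a true null), and for `signal_strength ≥ 1/L` the preferred level
carries exactly that probability. Within a block, coupled features share a
per-sample latent uniform pushed through each feature's inverse CDF with
the preferred level ordered first; at coupling 1 equal-level block members
are perfectly concordant, at coupling 0 they are independent. Mixture
samples choose one of their two parent classes independently per feature
with probability 1/2, which makes every mixture marginal exactly the
average of its parents' — mixtures occupy the space between parent clusters
without approaching the third class.

The second (validation) cohort draws new samples from the same
class-conditional distributions restricted to the first `shared_features`
columns (all informative features first), with its own sizes (default
96 = 32/32/32 over 106 shared features).

What the generator does **not** emulate: ordinal structure in answers,
informative missingness, sex/age covariates, questionnaire-specific level
frequencies, or cross-block correlation. Passing checks therefore show the
pipeline recovers *this* latent-class structure at the study's n/p regime;
they are not evidence about any particular clinical questionnaire.

All randomness flows from the spec seed through named substreams
(parameters / extreme draws / mixtures / second cohort / missingness), so a
spec is a complete recipe: identical specs give byte-identical TSVs.

## Preprocessing

Features with strictly more than 5% missing values are dropped; the rest
are imputed with the feature's modal level (ties to the lexicographically
smallest — the rule must be deterministic and the choice is otherwise
arbitrary); features left constant are dropped last, so a feature made
constant by imputation is removed. The pipeline is idempotent and the
report partitions the input feature set exactly.

## Unsupervised forest dissimilarity

A random forest is trained to distinguish the real samples (class 1) from a
synthetic contrast cohort (class 2) built by permuting every feature column
independently — marginals kept, joint structure destroyed (the classic
"addcl1" device). The proximity of two real samples is the fraction of
trees in which they share a terminal node, counted over all trees by
default (an `oob_only` switch restricts to trees where both are
out-of-bag); dissimilarity is `1 − proximity`. Forests are
scikit-learn's, with one-hot-encoded levels; for 2–4-level factors one-hot
threshold splits express the same predicate family as subset splits.
Default 10,000 trees: proximities are Monte-Carlo estimates and at cohort
scale (n ≈ 150) their element-wise fluctuation is already far below the
class separation; the tree count is configurable upward.

## Clustering and the permutation null

PAM (classic BUILD + SWAP on the full dissimilarity, best
strictly-improving swap applied until none exists) is run for k = 2..20 and
k* maximizes the average silhouette width, ties to the smaller k.
Tie-breaks (BUILD, SWAP, nearest-medoid assignment) all resolve to the
lowest sample index, so results are reproducible without randomness. Note
that BUILD+SWAP is a *local* search: on small unstructured random
dissimilarities it returns a non-global optimum in roughly one instance in
ten — identically to the reference R `cluster::pam`, with which the
implementation agrees exactly (a unit test asserts equal swap-phase
objectives). Silhouettes use the standard convention `s = 0` for singleton
clusters.

The Savannah analysis repeats the whole dissimilarity-plus-silhouette
computation on column-permuted copies of the data (one fresh permutation
per replicate, reused across the k grid; replicate seeds derived from the
master seed by counter). Real cluster structure shows as original widths
far above the permuted envelope; the permuted profile also measures how
much of the original width is driven by inter-feature coupling rather than
class structure. For a null-calibration check the cohort must be truly
structureless, i.e. zero signal *and* zero block coupling — with coupling
left on, the null correctly flags the coupling and the original width sits
above the envelope.

Cluster–label agreement maximizes the matched fraction over one-to-one
cluster-to-class maps (Hungarian assignment on the contingency table).
Classical (Torgerson) MDS provides plot-ready coordinates; dimensions with
non-positive eigenvalues are dropped and counted, and each eigenvector's
first nonzero entry is made positive to fix reflections.

## Supervised models

All three classifiers share one stratified 90/10 split (per-class test
count = round-half-up of 10%, realizing 7/4/5 = 16 at the study sizes) and
dummy coding against each feature's modal reference level.

**LASSO / elastic net.** Multinomial logistic regression penalized by
λ[(1−α)‖β‖²/2 + α‖β‖₁] (α = 1 for the LASSO). For each α the λ path runs
from λ_max (the smallest λ with all coefficients zero, from the KKT
conditions at the intercept-only fit) down four decades in 100 log-spaced
steps. λ* minimizes the 10-fold cross-validated misclassification rate;
ties resolve toward the stronger penalty (larger λ, then larger α over the
grid α ∈ {0, 0.1, …, 1}, with α = 0 floored to 0.01 so the penalty stays
selective). The per-(α, λ) solver is scikit-learn's saga
(`C = 1/(nλ)`, `l1_ratio = α`, fixed `random_state`), warm-started along
the path; CV fits use tolerance 1e-3 (the CV criterion is a
misclassification count, insensitive to the last digits of β), the final
refit 1e-5. Selected features are the parents of any nonzero coefficient
in any class. Because ties prefer stronger regularization, the selected
set is a *sparse sufficient* subset — on strongly separable data the CV
error curve is flat at zero over a wide λ range and the reported feature
count lands well below the number of planted informative features.

**Random forest.** Boruta first: each run appends one permuted "shadow"
copy of every active feature (the shadow pool padded to at least five
columns), fits a 500-tree forest, and scores a hit for features whose
Gini importance exceeds the best shadow's. Hits are tested after every run
against Binomial(runs, 1/2), Bonferroni-adjusted across undecided features
(p < 0.01): clear winners are confirmed, clear losers rejected and
removed; leftovers after `max_runs` (default 100) are resolved by
comparing their median importance with the median shadow maximum. The
shadow floor and the adjustment are what keep the procedure calibrated
under label permutation — without them the last surviving feature faces
only its own shadow and a sequential test drifts to a false confirmation.
Note Boruta tests *in-sample* association: on one fixed permuted-label
dataset a chance association can be genuinely detected, so null behavior
should be judged at adequate sample sizes.

Tuning then scans ntree ∈ {500, …, 10000 step 500}, five independently
seeded forests per grid point (grown incrementally with warm starts so one
maximal forest per repeat covers the grid), scoring the median and SD of
out-of-bag error: least median, then least SD, then the smallest value.
The same protocol scans mtry ∈ {1, …, min(15, ⌈√p⌉+10)} at the chosen
ntree. On cleanly separable cohorts the OOB error is zero across most of
the grid and the rules select the smallest candidates.

Evaluation reports the truth-by-prediction confusion matrix, one-vs-rest
sensitivity and specificity per class, and overall accuracy; prediction is
argmax probability with exact ties to the alphabetically first class.
Cross-cohort validation restricts both cohorts to their shared features
(in the training cohort's order), retrains on 90% of cohort A, and scores
all of cohort B; the same call with the arguments swapped gives the
reverse direction.

## Two-stage extreme-vs-mixture model

Each trained three-class model scores the pooled 147 + 106 cohort; the
per-sample score is the *maximum* class probability (in [1/3, 1]). A
binary logistic regression of pure-type status on that scalar is fitted by
Newton–Raphson (tolerance 1e-8); when the classes are linearly separable
on the score the MLE diverges, so the fit falls back to a 1e-6 L2 ridge
and flags `separated`. Ten stratified folds give CV accuracies; AUC is the
Mann–Whitney statistic (ties count half) computed from average ranks. Per
base method, ten candidates differing only in CV seed are built and the
best by mean CV accuracy (ties to higher AUC) is kept, reported with
sensitivity/specificity at the 0.5 posterior threshold. The regression
uses the scalar maximum only; a switch to use all K probabilities exists
for exploration but is off by default, matching the one-curve-per-method
design.

## Problem sizes in the shipped checks

The acceptance-style checks run the full 147-sample cohort with a
10,000-tree forest for clustering, 20 permutation replicates at 2,000
trees for the Savannah null, the complete penalized paths and forest
tuning grids, and 96-sample cross-cohort validation — chosen so the whole
suite completes on a single CPU at interactive timescales while keeping
every protocol at its full grid.

## Known limitations

- PAM local optima (above); exact global equality holds only on clearly
  separated structures.
- Gini importance inside Boruta is biased toward higher-cardinality
  features; shadows share their parents' cardinality, which cancels most
  of the bias in the hit comparison but not all of it.
- The contrast-forest dissimilarity is estimated, not exact; very small
  between-class contrasts (≪ tree-count noise) are not detectable.
- Probabilities are not calibrated; the two-stage threshold of 0.5 is a
  convention, not an optimized operating point.
- All features are treated as unordered; ordinal answer scales lose their
  ordering.
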
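# Methods

This note documents the models, procedures and numerical choices behind
`stoolmark`, in the order the pipeline runs them, together with what the
synthetic cohorts do and do not establish about real data.

## Abundance tables and preprocessing

OTU tables are tab-separated, features in rows (`#OTU_ID` first column,
optional trailing `taxonomy` column), samples × features in memory. A table
is inferred to hold counts when all values are integral and relative
abundances when every non-zero row sums to 1 within 1e-6; anything else is
treated as counts with a warning. Taxonomy parsing accepts greengenes-style
rank prefixes (`p__`, `o__`, …) and bare positional labels; unresolvable
ranks aggregate into `unclassified`, and aggregation conserves per-sample
totals exactly for integer counts. Preprocessing for the relevance analysis
is: drop zero-variance features, then convert to per-sample relative
abundance (all-zero samples stay zero and are flagged). Whether relevance
ranking should run on counts, relative or transformed abundances is not
settled practice; the pipeline exposes `erf_on: {relative, counts}` and
defaults to relative.

## Synthetic cohort model

The generator draws, per taxon j, a base log-abundance `mu_j ~ N(0, 2)` on
the natural-log scale (heavy-tailed, so a few taxa dominate the reads as in
real 16S data). Planted taxa — the case-depleted community a qPCR panel
would target — are drawn as moderately abundant commensals,
`mu ~ N(1, 0.5)`. Sample latent log-abundances are

    z_ij = mu_j + [case_i]·log(depletion_factor)·planted_j
           + lam·f_i·planted_j + s_j·eps_ij ,

with `f_i ~ N(0,1)` a shared community factor, loading
`lam = community_correlation` (residual sd `sqrt(1 − lam²)` keeps planted
marginals at unit log-sd; pairwise log-abundance correlation among planted
taxa is `lam²` plus the shared group shift), and `s_j = 1` otherwise.
Counts are multinomial at `read_depth` on `exp(z_i)` normalized per sample
— a log-normal/multinomial compositional model; Dirichlet-multinomial
overdispersion is a possible extension, not implemented.

The symptom score couples severity to the planted community rather than
only to the diagnosis label:

    score_i = baseline(group_i) − 6.0 · (mean planted log-deviation,
              centred within group) + N(0, score_noise_sd²),  clipped to [0, 45]

Defaults mirror the emulated study design: 16 controls + 18 cases, 300
taxa, 5 planted, `depletion_factor` 0.25 (a 4-fold case depletion,
comparable to the 2–5-fold group differences such panels report),
`community_correlation` 0.6, 50,000 reads/sample, score baselines 1
(control) and 26 (case) on the 0–45 GUPI-like scale with noise sd 2. The
coupling constant 6.0 makes within-group score variation (sd ≈ 4 in cases)
attributable mostly to the planted community, so score-regression ranking
has a recoverable signal. All randomness flows through numpy's PCG64
generator; identical seeds give bit-identical cohorts.

qPCR wells follow `Ct = intercept − log2(abundance)/log2(1 + E)` with
per-well Gaussian noise (default sd 0.15 cycles, duplicate wells,
intercept 22); at efficiency `E = 1` a doubling of template lowers Ct by
exactly one cycle, which is what makes noise-free fold recovery exact.
Non-amplifying wells are censored at cycle 40. The metabolite table is
log-normal with planted analytes shifted upward in cases by
`effect_sd_units` (default 3) latent SDs — near-complete separation, the
regime of a strong single-analyte biomarker.

**What the simulations do not capture:** real phylogenetic structure
(taxonomy strings are generated labels), sequencing error and chimeras,
batch effects, overdispersion beyond log-normality, diet-driven covariation
among non-planted taxa, and any fidelity to a particular patient cohort's
effect sizes. Passing recovery tests shows the procedures detect the kind
of structure they assume, at realistic sample sizes and depths — not that
any particular real dataset contains it.

## Extended Random Forest relevance

For each of `n_stability_runs` (default 20) independent runs, the feature
matrix is extended with one shadow per feature — a fresh random permutation
of that feature's values, so the shadow's marginal multiset is exactly the
original's — and a random forest is fit on the extended matrix
(`n_trees` 25,000, `mtry` 200 capped at the extended feature count;
the `scaled()` profile uses 500 trees for desk-scale work, which the
stability averaging and t-test make sufficient in practice).

VIM is out-of-bag permutation importance in the R randomForest tradition:
per tree, the increase in OOB squared error (regression on the symptom
score) or OOB misclassification rate (classification on the diagnosis) when
a feature's OOB values are permuted, averaged over all trees; trees that
never split on a feature contribute exactly zero. This is computed by a
vectorized traversal kernel over the fitted trees that re-traverses only
the trees using each feature — exact, and orders of magnitude faster than
re-predicting the whole forest per feature. Tree node sizes follow the R
randomForest defaults the Ntree/Mtry vocabulary comes from: minimum leaf 5
in regression, 1 in classification (configurable via `min_node_size`).

The *best shadow* is the shadow with the highest mean VIM across runs (ties
broken lexicographically) — the empirical noise ceiling. Each original
feature's per-run VIMs are tested against the best shadow's by a one-sided
two-sample Welch t-test (alternative: feature > shadow; Welch because
nothing justifies equal variances); the likelihood of relevance is 1 − p.
When both VIM vectors are constant and equal the t statistic is 0 and the
likelihood is 0.5 by convention — which is also why the best shadow itself
sits at exactly 50%, the baseline every relevant feature must clear.
Features are ranked by likelihood (ties by mean VIM, then id) and flagged
relevant when likelihood strictly exceeds the threshold (default 0.70).
Testing against the single best shadow, rather than each feature's own
shadow, is the stricter null and is the operative rule here; a per-own-
shadow comparison can be assembled from `VimRuns` directly. `tune_mtry`
provides out-of-bag grid search (ties to the smallest candidate) as a
transparent stand-in for fancier parameter-space mapping.

Calibration properties, verified by simulation in the test suite: under a
null response the mean fraction of features exceeding the 70% threshold
stays below 0.10 (testing against the maximum of ~300 shadows is
conservative), and on the default planted cohort ≥4 of 5 planted taxa are
flagged relevant, with all five in the top 26, in ≥80% of seeds at the
500-tree profile.

## ΔΔCT quantitation

Duplicate wells collapse to the mean of uncensored Cts; pairs spanning more
than `max_spread` (default 1.0) cycles are flagged discordant but retained,
and all-censored pairs are undetected (no mean — censored Cts never enter
means). The default is calibrator-only ΔΔCT: per species,
`ΔΔCT = Ct(sample) − Ct(calibrator)` against a designated positive-control
sample, `fold = 2^(−ΔΔCT)`, so the calibrator's fold change is exactly 1
and each −1 cycle doubles the fold. An optional reference (housekeeping)
amplicon enables the classic two-stage form. The identity of the positive
control is a required user choice (the pipeline defaults to the first
control sample). Group comparison defaults to the two-sided Mann–Whitney U
(fold changes are non-normal); Welch's t-test is available; groups are
summarized as mean ± SEM and flagged at P < 0.05.

## ROC evaluation

Classic univariate AUC is computed from midranks, making it exactly the
normalized Mann–Whitney U statistic with half-credit ties — the identity is
enforced against an independent pair-counting oracle. Orientation is chosen
so AUC ≥ 0.5, and the direction (higher or lower in cases) is reported,
which matters for depletion markers. The cross-validated mode implements a
single-marker linear threshold model under stratified 5-fold CV: the
orientation is learned from training-fold group means, held-out samples are
scored out-of-fold, and the reported AUC is the mean over folds (folds that
happen to contain one class are excluded with a warning; fold assignments
are emitted for audit). Stratification is essential at n = 34. Multi-marker
combinations are out of scope: markers are evaluated one at a time.
Significance is a strict `AUC > 0.70`.

## MIC networks

MIC is computed on rank order (cuts may only fall between distinct values),
giving exact invariance to strictly monotone transforms. The grid budget is
`B(n) = max(ceil(n^0.6), 4)`; for each shape `(kx, ky)` with
`kx·ky ≤ B(n)` the cut points are optimized and the mutual information is
normalized by `log2(min(kx, ky))`; MIC is the maximum over shapes, hence
always in [0, 1], with noiseless monotone data scoring exactly 1 via the
2×2 equipartition.

For the per-shape optimization, the classic approach fixes an equipartition
of one axis and optimizes the other's cuts by dynamic programming (with
columns fixed, `I = H(col) − H(col|row)` and the conditional entropy is
additive over row bins, so the DP is exact). That one-pass scheme
measurably underestimates the grid maximum at cohort-scale n (checked
against exhaustive search), so this implementation runs coordinate ascent:
the two axes are re-optimized alternately (each step is an exact DP given
the other axis, so the objective is non-decreasing), from both
equipartition starts, up to three rounds; both orientations are searched,
making the statistic symmetric by construction. For n ≤ 12 the full
exhaustive search over both axes' cut combinations replaces the ascent and
doubles as the correctness oracle in the tests. Constant vectors score 0.

The network connects every unordered feature pair with MIC at or above
`edge_threshold`. No principled universal cutoff exists; the default 0.5
is configurable and always recorded in the output. Null calibration at
n = 34: independent features essentially never reach 0.9, and the planted
community (loading 0.8) forms a connected subgraph at the 0.5 default in
the large majority of seeds.

## Pipeline

Stages couple through files so each is independently re-runnable:
simulate/load → preprocess → ERF → ΔΔCT → ROC → MIC network, with a JSON
manifest recording the config echo, per-stage seeds and feature counts.
Every stage seed derives deterministically from the global seed (via
SeedSequence with a stable per-stage tag), outputs carry no timestamps, and
two runs with the same config and seed produce byte-identical result
tables. In simulation mode the qPCR panel is the planted taxa plus three
random decoys (a panel targets more candidates than turn out real);
panel species the calibrator fails to amplify are dropped with a warning.
Candidate species for ΔΔCT/ROC are the ERF-relevant features intersected
with the panel; the MIC network runs on the union of ERF-relevant features
and the panel.

## Problem sizes

The test suite and `scripts/acceptance.py` run everything at the 500-tree
forest profile on default-size cohorts (34 × 300, 50,000 reads). The suite
uses 50 null cohorts and 20 recovery seeds; the acceptance script reports
the same quantities from 8 null cohorts, 6 recovery seeds, 10 network
seeds, 100 CV permutations, 500 AUC-identity instances and 50 MIC oracle
instances, which reproduces each estimate comfortably within its tolerance
on one CPU in minutes.

## Known limitations

- ERF likelihoods are not multiplicity-adjusted p-values; the 70% rule is a
  ranking heuristic with an empirically verified false-discovery property
  under the null, not an error-rate guarantee.
- The exact parameter-mapping procedure behind the printed forest settings
  is undescribed in the source literature; OOB grid search is a labelled
  stand-in.
- With ~20 stability runs the Welch test's tail p-values are approximate;
  likelihoods near 1 should be read as "beats the noise ceiling in
  essentially every run", not as precise tail probabilities.
- MIC beyond n ≤ 12 is an ascent optimum, not a certified global maximum,
  though it strictly dominates the one-pass equipartition scheme.
- Amplification-efficiency estimation from standard curves, melt-curve
  analysis and multivariate ROC are out of scope.
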
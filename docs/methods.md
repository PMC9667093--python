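# Methods

`connectoml` implements a complete two-group discrimination analysis for
resting-state functional connectomes: graph construction over a grid of
network densities, global and nodal topological metrics with
area-under-curve summaries, a univariate–collinearity–LASSO feature
selection cascade, repeated nested classifier evaluation with
permutation-based significance, and stability/clinical follow-up. Because
suitable subject-level fMRI cohorts are rarely deposited, the package also
ships a synthetic cohort generator with planted, recoverable effects; the
whole pipeline is validated end to end against that ground truth.

## Network construction

Edges are Pearson correlations between node time series, Fisher
r-to-z-transformed (`z = atanh r`, variance-stabilising; |r| ≥ 1 − 1e-7 is
clipped with a warning so duplicated signals stay finite). Binary graphs
are formed at each sparsity threshold S by keeping the `round(S·n(n−1)/2)`
top-ranked connections (round half away from zero, minimum one edge), so
realized density is exactly S. The default grid is S = 0.05…0.50 in steps
of 0.05 (ten thresholds).

Ranking uses signed z descending — the strongest positive couplings become
edges first, the convention of binary-network toolchains; `rank="absolute"`
is available for magnitude-based thresholding. Ties at the cutoff break
lexicographically on the upper-triangle (i, j) pair, which makes
binarization total, platform-independent, and nested across thresholds
(the edge set at a smaller S is always a subset of the set at a larger S).
Because ranking is invariant to strictly increasing transforms, graphs
built from r and from z are identical.

## Topological metrics

Global, per threshold: clustering coefficient Cp, characteristic path
length Lp, normalized clustering γ = Cp/⟨Cp_rand⟩, normalized path length
λ = Lp/⟨Lp_rand⟩, small-worldness σ = γ/λ, global efficiency Eglobal, and
network local efficiency Elocal. Nodal, per threshold: nodal clustering
NCp, nodal efficiency Ne, nodal local efficiency NLe, degree centrality
DC, and betweenness centrality BC (Brandes, normalized by (n−1)(n−2)/2).

Conventions for sparse, possibly disconnected graphs:

* Lp averages over *reachable* ordered pairs only and is undefined (an
  error) for edgeless graphs; efficiencies treat 1/∞ as 0. These are the
  standard toolchain conventions; graphs at S = 0.05 are routinely
  disconnected.
* NCp of a degree-<2 node is 0, and Cp is the unweighted mean of NCp over
  all nodes (not the transitivity ratio).
* NLe(i) is the global efficiency of the subgraph induced by i's
  neighbours (0 for degree < 2); Elocal is the unweighted mean over nodes.

γ/λ/σ are normalized by a degree-preserving (double-edge-swap) null
ensemble: default 100 rewired graphs with 10 accepted swaps per edge,
seeded deterministically per (subject, threshold). Rewiring is best-effort
on rigid graphs (a bounded attempt budget, then a warning) — a complete
graph is returned unchanged. If the ensemble's mean Cp or Lp is zero
(triangle-free nulls, which happens for very small sparse graphs), γ is
undefined and the computation fails loudly rather than silently
propagating infinities; at the package's default problem sizes this does
not occur.

Distances use a level-synchronous all-sources BFS implemented with
saturating boolean matrix products, which is exact for unweighted graphs
and fast at the ≤ a-few-hundred-node scale of parcellated connectomes.

## Feature space

Per subject, every metric at every threshold plus, per metric, the
trapezoidal integral over the grid (the "AUC" summary, prefixed `a`):
`5·n·(T+1) + 7·(T+1)` features for n nodes and T thresholds — 8,877 for
the default 160-node atlas, named canonically
(`Eglobal_thr0.20`, `aEglobal`, `DC_thr0.35_node042`, `aDC_node042`).
Column order is the global block followed by nodes, each metric's
per-threshold columns before its AUC column; this order also defines the
collinearity-pruning precedence below.

## Selection cascade (training rows only)

1. Stratified 70/30 split; per-group test counts round half up.
2. Two-sided Mann–Whitney U screen, survivors strictly p < 0.01. Exact
   enumeration when both groups have ≤ 8 members, otherwise the
   tie-corrected normal approximation; constant features get p = 1.
3. Greedy Spearman pruning in canonical column order: a later column is
   removed when its |ρ| with an already-retained column exceeds 0.7
   (magnitude reading of the cutoff); removals are logged with the partner
   and ρ.
4. Z-standardization fitted on training rows (zero-variance features are a
   named error) and applied unchanged to test rows.
5. Squared-error LASSO on the 0/1 group labels — the loss
   Σ(yᵢ−ŷᵢ)² + λΣ|βⱼ| — with λ chosen from a 50-point log grid spanning
   [λ_max·10⁻³, λ_max] (λ_max = smallest all-zero-solution penalty,
   2·max|Xᵀ(y−ȳ)|) by stratified fivefold cross-validated squared error;
   ties resolve toward the larger penalty (sparser model). The penalized
   *regression* form is deliberate: it is the printed selection loss, and
   classification happens downstream. Coordinate descent is delegated to
   scikit-learn (`lasso_path` per CV fold with explicit centering; the
   package's λ equals 2n times scikit-learn's α).

Selected features are those with nonzero β at λ_opt refit on the full
training set. Standardization after pruning; the Spearman step is
rank-based, so the order is immaterial.

## Classifiers and nested evaluation

Four families: SVM (C ∈ {0.01…100}, kernel ∈ {linear, radial}, radial
width γ ∈ {10⁻⁴…10, scale}), L1-regularized logistic regression (10
log-spaced inverse penalties in [10⁻³, 10³]), random forest (estimator
count tuned, trees otherwise default), and Gaussian naive Bayes
(variance smoothing 10⁻⁹). Hyperparameters are chosen by exhaustive grid
search under stratified 10-fold cross-validated accuracy on the training
split; ties resolve toward the smaller-capacity setting (grids are ordered
small to large, linear before radial), and the winner is refit on all
training rows. ROC scores are the decision margin for SVM and P(class 1)
for the probabilistic models; AUC is the tie-aware rank statistic.

The outer procedure — split, cascade, tuning, held-out scoring — repeats
over n loops (full-scale: 100), loop k seeded `master_seed + k` so each
loop is individually reproducible. Loops with empty selections are skipped
and logged; summaries (mean ± SD of accuracy, balanced accuracy,
sensitivity, specificity, AUC; positives = group 1) average completed
loops. No statistic anywhere — p-value, ρ, scaler, λ, hyperparameter — is
computed from test rows.

Significance: labels are shuffled (full-scale: 1,000 times), the complete
pipeline reruns on one stratified split per shuffle, and
p = (#{permuted ≥ actual} + 1)/(n_perm + 1) (never zero; ≥ is the
conservative reading). A shuffle whose cascade selects nothing scores at
chance (majority-class accuracy, AUC 0.5); the same rule applies to the
actual run, keeping the p-value valid.

## Stability and clinical follow-up

A feature is a *stable discriminator* when selected in strictly more than
a threshold count of completed loops (full-scale: more than 80 of 100).
Because the collinearity prune deliberately collapses correlated features
onto shifting representatives across resamples, the package also reports
*family-level* stability: the fraction of loops selecting at least one
feature of a node set (e.g. the planted cerebellum nodes). Name-level
counts answer "which exact feature", family-level answers "which region is
consistently discriminative"; on strongly collinear feature spaces the
latter is the robust notion.

Stable features are related to clinical scores within the patient group by
partial Pearson correlation — the correlation of the residuals of feature
and score after least-squares projection on covariates plus intercept
(age, sex, education, head motion, depression, anxiety, cognition by
default) — with p from the t distribution on n − k − 2 degrees of freedom.
Constant covariates are dropped (they duplicate the intercept); genuinely
collinear covariates are a named error. The Bonferroni divisor is the
number of feature × score tests actually performed; degenerate pairs
(e.g. a feature constant within the group) are skipped and logged.

The demographics table compares each covariate between groups:
Kolmogorov–Smirnov normality gate per group at 0.05, then Welch's
unequal-variance t (normal) or the rank-sum Z (non-normal); binary
variables use chi-squared without continuity correction, reported as
sign(p̂₁−p̂₂)·√χ². Welch's form is the default because recomputing
published two-group summaries (means, SDs, ns) reproduces reported t
statistics at 2-decimal precision where the pooled form misses by a
rounding step; a summary-only entry point (`welch_t_from_summary`) exists
for exactly that use.

## Synthetic cohorts

The generator emulates a two-group resting-state study: by default 101
patients vs 105 controls, 160 nodes in six subnetworks, 230 retained
timepoints (240 acquired minus 10 discarded), with planted hub weakening
in the cerebellum subnetwork and strengthening in sensorimotor/occipital
nodes, and a severity score coupled to the planted topology.

Base covariance (one per cohort): three structural layers scaled by the
weight parameters — within-module ring lattices (weights ≈ 0.5) with
10%-rewired shortcuts (cross-module weights ≈ 0.25), one connector hub per
subnetwork with medium-weight edges to 30% of nodes, and a weak dense
random background (sd 0.05). The background matters: with a two-valued
weight spectrum, edge ranks beyond the structural density are pure
estimation noise and nodal degree stops responding to planted effects at
mid/high thresholds; continuous weights make ranks respond smoothly
everywhere. The matrix is eigenvalue-clipped to a positive-definite
correlation matrix (clipping perturbs structure far less than uniform
diagonal loading). Zero weights give exactly the identity. After
binarization these graphs sit in the small-world regime (γ > 1, λ ≈ 1 at
moderate densities; e.g. γ ≈ 1.4, λ ≈ 1.02 at S = 0.20 for the 60-node
configuration).

Group 1 scales off-diagonal entries incident to affected nodes by
(1 − δ) (down set) or (1 + δ) (up set); δ = 0 makes the groups
exchangeable by construction. Per-subject heterogeneity: subject i
realizes δᵢ ~ N(δ, 0.3·δ) truncated at zero, plus a global off-diagonal
scale jitter (sd 0.05) for both groups. The severity score of group-1
subjects is `intercept + slope·z(relative strength) + noise`, where
relative strength is the coupling node's mean absolute incident weight
divided by the subject's overall mean — the quantity density-matched
thresholding can actually see (a global scale shift changes no edge
ranks). Defaults (slope −6 score points per SD, residual sd 2.5,
intercept 23.6, heterogeneity 0.3) put the measured degree-feature ↔ score
correlation in the strong regime (|r| ≈ 0.5–0.7) reported for clearly
severity-linked hubs in real tremor cohorts. Time series are zero-mean
multivariate normal draws from the subject covariance — no autocorrelation
or physiological noise, which the correlation- and rank-based pipeline is
insensitive to.

Covariates other than the tremor scales are drawn group-matched (no
planted confounds); `plant_mmse_effect=True` plants the small cognitive
group difference needed to exercise the demographics stage. Scores
specific to patients are missing for controls. Everything planted —
affected sets, δ, per-subject δᵢ, realized strengths, coupling
parameters — is recorded in the cohort's `truth`.

What the generator does *not* emulate: autocorrelated BOLD dynamics,
physiological/motion artefacts, spatial smoothness, site effects, or
realistic region-specific connectivity fingerprints. Passing tests
therefore demonstrate that the *pipeline* recovers planted topological
effects of realistic size under realistic noise — not that any particular
real-data result would replicate.

## Problem sizes for validation runs

The acceptance checks and the acceptance script use scaled study
conditions chosen to exercise every stage at desk scale: a 60-node
six-subnetwork atlas, 40 subjects per group, 230 timepoints, 20 outer
loops, null ensembles of 6 rewired graphs with 5 swaps per edge, random
forests of 50–100 trees, and permutation calibration on 30-subject,
40-feature noise tables with 99 shuffles per test and 100 meta-replicates.
Full-scale settings (100 nulls × 10 swaps, 100 loops, 1,000 permutations,
160 nodes, 101/105 subjects) remain the package defaults.

## Known limitations

* Squared-error LASSO on 0/1 labels is a selection device, not a
  probability model; its coefficients are not log-odds.
* Name-level selection stability is intrinsically fragile on strongly
  collinear feature spaces at small n — the family-level report exists for
  that reason.
* The permutation test uses one stratified split per shuffle (not the full
  100-loop machinery per shuffle), trading a slightly noisier null for a
  ~100× cheaper test; the add-one p-value keeps it valid.
* γ/λ/σ are global-only; nodal small-world variants, weighted/directed
  metrics, modularity and participation coefficients are out of scope.
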
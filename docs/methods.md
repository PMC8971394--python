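# Methods

This note documents the models, conventions and numerical choices
behind `affectmap`, in the spirit of a statistical package's methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinate conventions

Affect ratings live on a 500 × 500 pixel grid: valence on x
(pleasantness increasing rightward), arousal on y (activation
increasing upward), bounds inclusive. Coordinates are stored
mathematically y-up; loaders accept a `flip_screen_y` flag for data
collected in screen coordinates (y-down), applying `a ↦ 500 − a` at
read time. All classifiers and the k-means partition operate in *model
space*, the affine image `[−1, 1]²` of the grid (`x ↦ (x − 250)/250`
per axis). The map is isotropic, so it changes no distance-based
result; it exists because the scale-sensitive hyperparameters (NN
weight decay, SVM cost) are only reproducible against a declared
feature scale. Inverse-distance weighting is computed in raw pixel
space; since IDW is invariant to isotropic scaling, the choice is
documented for exactness rather than substance.

The participant exclusion retains a participant iff their *neutral*
placement falls inside the axis-aligned square of side 100 px centered
at (250, 250), bounds inclusive (valence and arousal in [200, 300]).
Inclusivity affects only measure-zero boundary cases; the retained and
excluded sets partition the cohort and the filter is idempotent.
Excluded participants' game trials are dropped post hoc.

## Classifiers

All three families consume model-space points and emit a 20-vector of
nonnegative probabilities summing to 1 (within 1e−9), in the canonical
term order.

* **Neural network.** 2 → H → 20 feed-forward, logistic hidden units,
  softmax output, cross-entropy loss with L2 weight decay; full-batch
  L-BFGS (scikit-learn's `MLPClassifier`, `solver="lbfgs"`, `alpha` =
  decay). Defaults H = 27, decay = 0.035, `max_iter` = 500, fixed init
  seed. Hitting the iteration cap emits a convergence warning and the
  model is still returned — with quasi-Newton line search the fit at
  the cap is a usable (if slightly suboptimal) penalized optimum.
  Classes absent from a (deliberately unbalanced) toy training set get
  probability 0.
* **k-nearest neighbors.** Prediction at `p` is the vector of class
  proportions among the k nearest training points (Euclidean, model
  space), default k = 175. Ties at the k-th distance are *included*, so
  the effective neighborhood may exceed k; this makes the prediction
  deterministic and invariant to training-row permutation. The
  implementation queries a scipy `cKDTree` for candidates, then
  recomputes exact distances so its tie handling is bit-identical to a
  brute-force all-pairs oracle (asserted in the tests at atol 1e−12).
* **SVM.** One-vs-one soft-margin machines on all 190 class pairs
  (scikit-learn `SVC`, `decision_function_shape="ovo"`), default cost
  C = 0.01. Kernel: RBF with bandwidth from the median-distance
  heuristic, γ = 1/(2·median²) over (subsampled) pairwise training
  distances, recorded in model metadata. Probabilities are pairwise
  vote shares normalized to sum 1 — no Platt scaling: deterministic,
  and adequate for a model kept mainly as a comparison baseline. The
  binary special case flips the sign of the single decision column
  (libsvm's binary convention points at the second class).

**Protocol.** The train/test split (default 70–30) and the 10-fold CV
folds are drawn at the *participant* level: all 20 rows of a
participant stay on one side, preventing leakage of idiosyncratic grid
usage and preserving class balance on both sides automatically.
Accuracy is the proportion of correct argmax classifications; κ uses
product-marginal chance agreement, which for balanced 20-class truth is
exactly 1/20 regardless of the prediction marginals, giving
κ = (acc − 0.05)/0.95 as an exact identity. CV ties resolve to the
smaller model (fewer hidden units, then stronger decay; smaller k;
smaller C). The default CV grids are decade-style lattices that include
the canonical configurations (27/0.035, k = 175, C = 0.01).

## Game pipeline

Responses binarize as: UG reject → *punish*; PD/PGG own contribution
in [$0, $0.49] → *defect*, [$0.50, $1] → *cooperate* (responses live on
the $0.10 lattice, so the boundary is unambiguous). UG responder and
third-party roles are pooled; the role column is kept for filtering.

Likelihood aggregation is two-stage: per (participant, choice) the
arithmetic mean vector over that participant's trials, then per choice
the unweighted mean over participants with at least one such trial.
Stage-2 equal weighting makes the summary invariant to per-participant
trial counts; both stages preserve normalization, so every aggregate
sums to 1. Confidence intervals are normal-approximation 95% bands
across participants (mean ± 1.96·SE). The per-term delta is
mean(competitive) − mean(cooperative); the 20 deltas sum to 0. The
unfairness gradient repeats the two-stage average per (choice, offer
level). Paired comparisons use the classical paired t with the d_z
convention d = mean(diff)/sd(diff), hence t = d·√n exactly;
zero-variance nonzero-mean differences report t = ±∞ with p = 0, and
all-zero differences t = 0, d = 0, p = 1.

The continuous-choice association (PD/PGG) is an approximation, flagged
as such: per participant, the covariance across trials between each
term's likelihood and (1 − own contribution); participants with
constant contributions are excluded from the across-participant mean;
terms are ranked by the mean association. Covariance antisymmetry under
`c ↦ 1 − c` and a zero-mean null are part of the test suite.

## Clustering

k-means (k = 9) is fitted on the model-space classification-task points
only — the game points are held out and merely assigned — with
k-means++ initialization and 25 restarts by default (scikit-learn,
Lloyd iterations, tol 1e−10). Nine clusters form a rough 3 × 3
low/med/high valence × arousal checker; grid positions are assigned by
ranking the nine centroid coordinates into tertiles per axis. Each
cluster is named by the modal emotion term among its assigned labeled
ratings; modal ties break by canonical term order and are flagged.
Assignment is nearest-centroid with lowest-index tie-breaking. The
two-cluster frequency contrast is a 1-df equal-proportions
goodness-of-fit test, χ² = (a − n/2)²/(n/2) + (b − n/2)²/(n/2) — the
only construction that yields the reported df = 1 from two counts.

## Individual profiles

For a trial by participant i at point p, with d_j the Euclidean pixel
distance from p to i's placement of term j:
P(j) = (1/d_j) / Σ_m (1/d_m). If p coincides with one or more
placements, the limiting measure puts all mass equally on the
zero-distance terms. P(j) is strictly decreasing in d_j and invariant
to multiplying all distances by c > 0. A reduced-term variant
(`idw_weights`) exists for fixtures and worked examples.

## Distribution structure

* **Densities.** Product-Gaussian KDE with per-axis Silverman
  rule-of-thumb bandwidths (0.9·min(sd, IQR/1.34)·n^(−1/5)), evaluated
  on a 101 × 101 lattice; bandwidths are recorded on the surface.
  All-identical samples raise, pointing the user to an explicit
  bandwidth.
* **Dispersion / variance equality.** Sample sd (n−1), linear
  interpolation IQR; Brown–Forsythe (ANOVA on absolute deviations from
  group medians) for variance comparisons — robust on bounded,
  non-normal grid data — with a Holm-adjusted pairwise variant.
* **Dip.** Hartigan's dip — the sup-norm distance from the empirical
  CDF to the nearest unimodal CDF — is implemented exactly, from
  scratch. In count units, a unimodal CDF at distance D/n must thread
  the band [r_j − D, l_j + D] at each distinct value (l/r the left and
  right counts), convexly below the mode and concavely above it, with
  an atom allowed at the mode; a mode inside a data gap can always be
  slid to the adjacent data point without changing the distance. Per
  candidate mode, band feasibility reduces to half the maximal gap
  between the upper counts and the greatest convex minorant of the
  lower counts (and the mirror image on the right); the two sides must
  additionally *connect* at the mode, a constraint whose violation is
  convex and piecewise linear in D and falls at rate ≥ 2, giving a
  bracket that a safeguarded regula falsi closes in a few vectorized
  evaluations. The implementation is validated against an independent
  LP-feasibility oracle (shipped in the test suite) on hundreds of
  random small samples including heavy ties, and against analytic
  values: two equal point masses give dip 0.25, unequal masses (p, q)
  give p/2, a point mass gives 0, and n distinct values are floored at
  1/(2n). The dip is exactly invariant under increasing *affine* maps;
  it is **not** invariant under general increasing transforms (the
  convex–concave family is not closed under nonlinear axis warps),
  which is precisely why the uniform serves as the bootstrap null
  rather than an arbitrary continuous law. `dip_test` reports
  p = (1 + #{null ≥ dip})/(1 + B) against B uniform-null replicates;
  since the null dip law depends only on n, a precomputed table can be
  shared across same-size samples (`dip_null_table`), which the
  calibration analyses exploit.

## Synthetic data

The generator is first-class, tested code; it emulates the statistical
structure the analyses assume.

* **Lexicon.** Each term is a 1–2-component Gaussian mixture over the
  grid (means/sds in pixels), truncated by rejection sampling —
  resampling, not clipping, so no probability mass piles up on the grid
  edges to distort density analyses. The default lexicon places every
  term in its usual circumplex octant; *neutral* is tight at the center
  (sd 16 px, so essentially all simulated participants survive the
  exclusion), *angry* has a dominant high-arousal component plus a 25%
  "quiet anger" component at neutral arousal, and *disappointed* is a
  single component whose arousal sd (75 px) is more than twice the
  dominant angry component's (35 px), encoding its heterogeneity along
  arousal. Placements are spaced so that each term's generator is
  *identifiable* — planted-emotion recovery experiments are only
  meaningful when the planted generator is not nested inside a
  neighbor's — while keeping the qualitative circumplex geometry. A
  `well_separated_lexicon` (single components, sd 12 px, on a 5 × 4
  lattice) provides a near-separable regime whose Bayes accuracy is
  computed by numeric lattice integration of the truncated mixture
  densities (`bayes_accuracy`), used for classifier recovery checks.
* **Games.** Partner actions follow even schedules: UG 20 rounds = 10
  kept-amounts $0.50–$0.95 in $0.05 steps × 2 (a declared convention —
  the per-level round count is not a claim about any study design); PD
  22 rounds = 11 contribution levels × 2; PGG 62 rounds = 31 collective
  levels × 2; order shuffled per participant. A badness score
  s ∈ [0, 1] (0 = best partner behaviour) maps linearly onto mean
  affect — defaults: valence 350 → 80 px, arousal 250 → 330 px,
  isotropic noise sd 55 px — implementing the
  unfairness → negative valence chain. Choices are logistic in
  model-space valence v: UG P(reject) = σ(−0.8 − 5v) (≈ 0.95 at very
  negative valence, ≈ 0.06 at the fair-offer mean); PD/PGG own
  contribution is the deterministic monotone map round(10·σ(3v))/10.
  Defaults are declared constants, not estimates fitted to any
  dataset. In *planted* mode the causal order reverses: the choice is
  drawn from the logistic at the noise-free valence for that partner
  action, then the affect is drawn from a designated term's generator
  per choice, recorded in a `planted_term` column for recovery tests.
* **Payoffs.** PD: (1 − own) + 1.5(own + partner)/2; PGG:
  (1 − own) + 2(own + Σ partners)/4. Marginal returns per contributed
  dollar are 0.75 and 0.5, so unilateral defection strictly dominates —
  the games' defining tension — which is property-tested.

**What the generator does not emulate.** Human raters produce
click-artifacts (edge and gridline attraction, repeated identical
pixels), participant-level response styles correlated across terms,
order and fatigue effects, and emotion concepts whose shape is not a
1–2-component Gaussian. Passing recovery tests therefore shows the
*pipeline* is correct and identifiable under its assumed structure, not
that real cohorts satisfy that structure.

## Problem sizes and tolerances

Cohorts of 200–500 simulated participants, 60–300 game participants,
dip calibration with 1000 uniform samples of n = 200 scored against ten
rotating 500-replicate null tables, and dip power with 60 mixture
samples of n = 1000 against a 300-replicate table keep the full test
suite and the acceptance script within a few minutes each while leaving
the estimators' standard errors small relative to the asserted bands.
Probability normalization is asserted at 1e−9 end to end; kNN/oracle
and IDW identities at 1e−12; dip-vs-LP-oracle agreement at 5e−5
(the oracle's bisection tolerance).

## Known limitations

* The NN depends on scikit-learn's L-BFGS internals; a different
  scikit-learn major version may fit slightly different weights
  (held-out metrics, not bit-identical weights, are the contract).
* SVM probabilities are vote shares: piecewise-constant in the input
  and tied vote patterns are possible; the SVM is a baseline, not the
  recommended estimator.
* The dip evaluation is O(m²) vectorized per candidate band level;
  samples beyond ~10⁴ distinct values get slow and would need the
  envelope-based O(m log m) refinement.
* The continuous-choice association is a covariance screen, not an
  inferential model of choice; no utility or logistic model of
  punishment is fitted anywhere (the analyses are associational by
  design).
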
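# Methods

This note documents the models, numerical choices and limitations of the
package, in the order the pipeline applies them.

## Preprocessing

Replicate-level matrices (features × time·replicate columns) are
batch-corrected by ordinary least squares: per feature, the model
`signal ~ 1 + time + batches` is solved with the batch factors (replicate,
and assay when DNase-seq and ATAC-seq tracks share one course) coded
sum-to-zero, and only the batch part of the fit is subtracted. Sum-to-zero
coding means the batch terms average to zero over columns, so the grand
mean and the temporal trend survive correction; estimating jointly with the
time design prevents real trends from leaking into the batch coefficients
when the design is unbalanced. A batch factor whose levels coincide with
time groupings makes the joint model rank-deficient and is rejected by
name rather than silently absorbed. Because corrected values can dip below
zero while the underlying signals are inherently positive, the whole matrix
is then shifted up by |global minimum| (a single global shift, not per
feature, so relative differences are untouched). Cross-assay tracks are
harmonized by joint quantile normalization (columns replaced by the mean of
sorted values restored to original ranks; ties receive the average of the
tied positions' target means).

Dynamic features are called by polynomial regression in time: per feature,
pooled replicate observations are fitted with degree-1 and degree-2
polynomials, each tested against the intercept-only model with an overall
F-test, and p-values are Benjamini–Hochberg adjusted across features within
each degree. A feature is dynamic when its smaller adjusted p-value is
below alpha (default 0.01, at least one of the two designs). Features with
fewer than `min_obs = 5` finite observations are excluded and flagged, not
errored. On pure noise the raw test is calibrated (empirical type-I error
at the 5% level stays near nominal; the suite checks [0.03, 0.07] on 1000
null features).

## Logistic kinetic model

The signal z(t) of a gene or cCRE is modeled by the generalized logistic
ODE dz/dt = k (z − a)(1 − (z − a)/(b − a)). Direct three-parameter fitting
is unstable on 8-point series, so each series is min-max normalized to a
range whose lower asymptote can be pinned at a\* = 0, and the two-parameter
simplified form dy\*/dt = k\* y\* (1 − y\*/b\*) is fitted instead. Two
target ranges are used: [1e-5, 1] ("unit", suited to profiles entered
through their acceleration phase) and that range shifted up by one unit
("shifted", ~[1, 2], suited to deceleration tails whose acceleration phase
would lie below the observed window). The shifted range is defined exactly
as unit + 1 so the two normalizations commute with the inverse transform.

Fitting minimizes squared error of the closed-form solution

    y*(t) = b* / (1 + (b*/y*_start − 1) e^{−k*(t − t_start)})

rather than repeatedly integrating the ODE; the two are mathematically
identical here and the closed form is deterministic and fast. The solution
is evaluated through the numerically stable sigmoid/log form, which cannot
overflow even at |k·t| of several hundred. y\*_start is fixed to the first
normalized observation and t_start to the first time point; only (k\*, b\*)
are free. Four candidates are run — k-init ±0.9, b-init 1.5, each in both
ranges — with box constraints keeping the optimizer in the logistic space
(|k\*| ∈ [1e-6, 50] per day in the half-space of its init sign, b\* ∈
(y\*_start, 10]), a 5000-evaluation cap, and failure returned as a
non-converged record rather than an exception. The converged candidate
with minimum normalized-space MSE wins; exact ties resolve deterministically
(unit before shifted, positive before negative init). The rate k is
invariant under min-max normalization, so it is reported unchanged; a and b
are mapped back to original units by the inverse min-max transform, and the
fitted curve in original units follows the generalized-logistic solution
anchored at the observed start value.

Characteristic times follow from (k\*, b\*, y\*_start): the switching time
(inflection), the near-zero time (where the curve passes 1e-16 of scale)
and the saturation time (99% of b\*). When a log argument is non-positive
the time is undefined for that curve; t_switch then takes a −∞ sentinel
(the inflection precedes anything observable, hence class decelerator) and
t_saturation is NaN. These sentinels are deliberate conventions, flagged in
output rather than guessed around. Classification compares t_switch with
the observed window [t_start, t_end]: inside → switcher, after →
accelerator, before → decelerator. The postnatal time point is encoded as
day 21, the upper end of a typical mouse gestation, so the default window
is [10.5, 21].

Converged features are grouped on the (|k|, b) plane by k-means with K = 3
on standardized coordinates (10 restarts, fixed seed). Cluster labels are
assigned geometrically from the centroids — highest-b centroid Q3, then
highest-|k| Q1, remainder Q2 — so the labeling is invariant to point order
and seed; a `q4_empty` flag reports whether any centroid occupies the
high-rate/high-saturation region, the regime the rate–saturation balance
forbids. K is configurable (with K = 4 the leftover centroid is Q4).

## Fit-quality triage

Genome-wide MSE distributions are bimodal: a tight component of acceptable
fits and a broad one of profiles the monotone logistic cannot express. A
two-component univariate Gaussian mixture is fitted by EM, initialized
deterministically by 2-means, iterated to a log-likelihood tolerance of
1e-8 (≤1000 iterations) with the monotone-likelihood property asserted at
every step. The acceptability threshold is the equal-posterior point
between the two component means (for equal weights and variances this is
exactly their midpoint; with several density crossings only the one between
the means is used). A collapsing component (weight < 1e-3 or sd < 1e-12)
or zero-variance input raises with a diagnostic: a unimodal MSE
distribution means there is nothing to triage, and the caller (the `gmm`
subcommand) then passes all fits with a warning instead of inventing a
threshold.

## Piecewise fitting

Profiles rejected by the triage are typically peak- or valley-shaped. The
global interior extremum is located (global maximum if interior, else
global minimum; ties to the earliest time point; a boundary-only extremum
means the series is monotone and is sent back to the monotonic pipeline).
Each side is fitted with the standard four-candidate procedure, sharing the
extremum point, with at least four observed points per segment. The right
segment is fitted freely and then shifted vertically so the two analytic
curves agree exactly at the extremum (zero-order continuity by
construction). The concatenated curve, sampled on a 200-point grid, is
smoothed by an interpolating quadratic B-spline — degree 2 gives
first-derivative continuity everywhere, including across the junction —
and reported at the observed times. The spline is fitted to the analytic
curves, not to the raw data, so the smoothing never reintroduces noise; on
smooth peaks the spline and the two-segment curve agree to well below
1e-4 of the signal range. The overall rate is summarized as
k_avg = (|k_left| + |k_right|)/2, and piecewise MSEs go through the same
mixture triage as monotonic ones.

## Regulatory linking

Coordinates are 0-based half-open (BED convention); the TSS of a −-strand
gene is end − 1. Every cCRE is assigned the gene minimizing linear gap
distance (0 when overlapping); equidistant ties resolve to the leftmost
gene with all ties reported in a dedicated column, preserving a
one-gene-per-cCRE schema. Body-to-body distance is used for linking;
TSS distance only feeds the distal flag (strictly greater than 2000 bp).
Per pair, the Pearson correlation of the ODE-fitted (smoothed)
trajectories — not the raw values — gives the regulatory reading:
enhancer-like when positive, silencer-like when negative; constant
trajectories leave r undefined and the pair is excluded. Genes whose
linked cCREs all share one k-sign are mono-pattern, mixed signs make them
poly-pattern, and the enhancer/silencer side of the four regulatory groups
is the majority vote of pair correlations (exact ties flagged and left
ungrouped).

The contribution of cCRE count versus trend diversity to a gene-level
response is modeled as y ~ a·x + b·z + c·(x:z) with intercept, where x is
the mean linked-cCRE count and z the poly-pattern indicator: a logit-link
GLM for binary responses (term membership from a user-supplied gene↔term
table — no annotation database is bundled; a hypergeometric enrichment
helper is provided) and OLS for continuous ones (expression fold-change,
max − min of log2 expression). Variance-inflation factors for the three
predictors are always reported; perfect separation in the logistic case is
flagged and the coefficients reported with a warning rather than raised.

## Expression prediction (biRNN)

Per gene, the fitted accessibility trajectories of its up to 60 closest
cCREs (closest-first by proximity rank, zero-padded) form a 60 × 8 input;
the target is the gene's 8-point expression trajectory in log2 TPM. The
m = 60 cap reflects that in genome-wide mouse data over 99% of monotonic
genes have fewer linked cCREs. A bidirectional tanh recurrent layer
(30 hidden units per direction) reads the time axis both ways — chromatin
states before and after a time point both inform the prediction — and per
step the concatenated 60-dimensional state passes through a dense head
(60 → 10 → ReLU → 1) shared across time steps, the interpretation chosen
for the one-output-per-timepoint architecture (per-step weights were the
open alternative). Training minimizes the mean over each batch of
per-sample MSEs (the per-sample MSE averages squared errors over the 8
time points) with Adam, batch size 4, learning rate 1e-4, 200 epochs, and
an 80:20 train/test split; one model is trained per regulatory group, and
groups under 5 samples are skipped with a warning. The network,
backpropagation through time and Adam are implemented directly in numpy;
gradients are validated against finite differences in the test suite, and
all randomness (initialization, batching, splitting, permutations) flows
from one configuration seed, making runs exactly reproducible.

Feature relevance is measured by permutation importance: per feature slot
and time point, the slot's values at that time point are permuted across
test samples (20 draws, fixed seed) and the mean loss increase recorded.
Constant (padding) slots get exactly zero. The scheme is model-agnostic
and library-free; an additive-explanation backend can be plugged in place
of it.

## Synthetic data

The generators define the study conditions the tests and the acceptance
script run under. The default time grid copies the 8-point developmental
design (PC days 10.5–16.5 daily plus 21 for the postnatal point); noise is
Gaussian on the signal scale (default sd 2% of each row's range), matching
the error model implied by least-squares fitting of log-scale signals.

Monotone rows are generated, by default, as fixed points of the min-max
normalization the fitter applies: the curve starts at the pinned end of
its range and reaches the other end exactly at the last time point, which
ties b\* to the drawn rate (rates are drawn from ±[0.3, 1.5]/day by
default; magnitudes below 0.08/day cannot traverse the range in the window
and are rejected at spec construction). This is precisely the data regime
the normalization scheme models, so zero-noise fits recover the generating
parameters essentially exactly, and recovery degrades gracefully with
noise. A free mode (explicit `y_start_range`) instead draws the starting
level as a fraction of b\*, producing partial-curve regimes such as pure
deceleration tails; these exercise the fitter outside its idealized regime
and carry no round-trip guarantee — mirroring real data, where fitted
parameters are effective rather than exact. Peak rows join two
normalization-consistent segments continuously at a drawn interior
extremum. Regulome simulations place genes ≥200 kb apart with cCREs within
±80 kb of their gene (so the generating gene is provably the nearest),
draw a trajectory direction per gene, give enhancer cCREs the same
direction with positive weights and silencer cCREs the opposite direction
with negative weights, and sum the contributions: every contribution is
monotone in the gene's direction, which guarantees the sign of each pair
correlation at zero noise by construction.

What the generators do not emulate: replicate count variation, heavy-tailed
or heteroscedastic noise, multi-peak or bursty profiles, overlapping genes
and shared cCREs, and distance-dependent regulatory strength. Passing
tests therefore demonstrate correctness of the machinery under the model's
own assumptions, not performance on any particular real dataset.

## Problem sizes

The test suite and the acceptance script use desk-scale sizes chosen to
exercise every code path with stable statistics: 200 series for noisy
parameter recovery, 60 for classification, 500+500 for the mixture triage,
10–20 synthetic peaks, 500×500 random intervals for linking, n = 2000 for
the interaction model, and 400 genes (100 training epochs) for the biRNN.

## Known limitations

* The simplified fit pins y\*_start to the first observed value; signals
  whose true lower asymptote lies far below the observed minimum are
  fitted with effective (biased) parameters — inherent to the
  normalization scheme, and the reason the triage step exists.
* The three-parameter generalized ODE is never fitted directly, and
  regularized fitting is not implemented.
* Piecewise fitting handles a single interior extremum; multi-peak
  profiles and sums of logistics are out of scope.
* Nearest-gene linking is purely distance-based; contact-map-informed
  linking is not implemented.
* biRNN training is CPU-scale; no hyperparameter search is performed and
  hidden sizes follow the published architecture.
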
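# Methods

## Model and procedure

`tegrn` infers a directed gene regulatory network from a genes × time-points
expression matrix by treating each gene as a stochastic process and scoring
every ordered pair (y, x) with transfer entropy

T(y→x) = Σ p(x_{n+1}, x_n^{(k)}, y_n^{(l)}) · log2 [ p(x_{n+1} | x_n^{(k)}, y_n^{(l)}) / p(x_{n+1} | x_n^{(k)}) ],

the reduction in uncertainty about x's next value contributed by y's recent
past beyond x's own. The default history orders are k = l = 1 (first-order
Markov), which keeps the joint distribution three-dimensional and is the
regime in which a few hundred time points give usable estimates. The net
flow T(y→x) − T(x→y) is antisymmetric; a positive value assigns the
direction y→x, zero assigns none.

Assumptions: series are evenly sampled, jointly stationary after smoothing,
and the regulatory lag is on the order of the sampling interval. Transfer
entropy is model-free (no linearity assumption) but, like all pairwise
measures, cannot distinguish direct regulation from fast transitive chains
or common drivers; the screening cascade reduces, but does not eliminate,
such edges (the worked example in the README shows a transitive shortcut
surviving the cascade).

## Estimator

All probabilities are plug-in estimates from a single joint count table
over equal-width histogram symbols; every marginal is summed out of that
one table, which guarantees a non-negative estimate, and empty cells
contribute zero (the p·log p limit). Bins span [min, max] per series with
the top edge closed so the maximum is always assigned.

**Bin count.** The default is `n_bins = 4`. For a 480-point series the
k = l = 1 joint over (x_{n+1}, x_n, y_n) has B³ cells: B = 4 gives 64 cells
(~7.5 samples per cell, the scale suggested by cube-root-style histogram
rules), while B = 8 gives 512 cells (<1 sample per cell) and the estimate
is dominated by small-sample bias — in our planted-network benchmark the
median recovery AUROC drops from ~0.88 at B = 4 to ~0.75 at B = 8. The bin
count is configurable everywhere (`n_bins`); users with substantially
longer series can raise it.

**Units.** Entropies are in bits (log2) by default, switchable to natural
log via `log_base`. The screening threshold `min_te` is therefore in bits;
its default of 0.5 bits is a conventional strong-coupling floor, but the
appropriate value is data-scale dependent (the pipeline example uses 0.1
bits for its simulation, where true couplings carry 0.1–0.3 bits).

## Permutation significance

The null for T(y→x) is built by fully re-shuffling the source series y
(destroying any cross-dependence while the target's own history term keeps
its autocorrelation) and recomputing TE; with the add-one rule
p = (1 + #{T_perm ≥ T_obs}) / (1 + n_permutations), p is never zero and
under independence is approximately uniform (the acceptance suite checks
that the fraction of p ≤ 0.05 over 500 independent pairs lies in
[0.02, 0.09]). Because a full shuffle also breaks the source's
autocorrelation, the null is mildly liberal for strongly autocorrelated
sources; at the cascade's α = 0.001 this has little practical effect, and
the scheme is the simplest exchangeable null. Note the add-one rule bounds
p below by 1/(n_permutations + 1), so screening at p < 0.001 requires at
least 1000 permutations (the default).

Per-pair seeds are derived by hashing (master seed, source name, target
name), so any single pair can be recomputed standalone and whole-matrix
results are bit-identical regardless of evaluation order or parallelism.

## Preprocessing and target selection

Smoothing is a centered moving average of odd window length (default 5
points), with either a shrinking window at the boundaries (default) or
reflection. Genes with temporal standard deviation ≤ `min_std` (default
exactly 0) are removed with a per-gene reason report; nothing is dropped
silently.

Candidate rhythm genes are selected by clustering per-gene z-scored
profiles twice — fuzzy c-means (fuzzifier 2.0, tolerance 1e−5, max 1000
iterations, seeded random membership initialisation; the Bezdek objective
is tracked and is non-increasing) and average-linkage agglomerative
clustering under cosine distance — with 12 clusters each by default, and
intersecting the two clusters that contain the reference gene. Z-scoring
makes the grouping phase/shape-driven rather than amplitude-driven, which
is the intent of pattern-matching against a reference waveform. Any manual
curation is expressed as explicit include/exclude gene lists passed to the
pipeline.

## Screening cascade

For n genes there are m = n·(n−1) ordered pairs. The cascade: (1) keep the
stronger direction per unordered pair (exactly m/2 edges); (2) keep
p < α (strict, default 0.001); (3) keep TE ≥ `min_te` (inclusive, default
0.5 bits); (4) keep each gene's single strongest outgoing edge and,
separately, each gene's strongest incoming edge — both networks are
emitted, with an optional union mode. All ties break lexicographically on
gene names, making every stage deterministic and reruns byte-identical.

## Evaluation

Predictions are a ranking of directed pairs; gold standards are
DREAM3-style TSV edge lists, with self-pairs excluded from the universe.
AUROC is the trapezoidal integral of the ROC sweep with tied scores grouped
into single steps (equal to the pairwise rank statistic with half credit
for ties; the test suite checks this equivalence against an independent
brute-force implementation). AUPRC is the trapezoidal integral over the
sweep's precision–recall points, walking from high to low threshold,
keeping the higher-threshold point where a step leaves recall unchanged,
and anchoring recall 0 at the first achieved precision rather than the
conventional precision-1 anchor (which has no observed support and biases
small-panel AUPRC upward). Gold pairs the predictor never scored are ranked
last with a coverage warning. PPV = TP/(TP+FP) and sensitivity = TP/(TP+FN)
are reported as undefined (None) when their denominators vanish.

## Synthetic data generator

`simulate` draws each gene's latent state as
z_i[t+1] = ρ·z_i[t] + Σ_j c_{j→i}·f(z_j[t]) + σ·ε with ρ = 0.5 and
σ = 0.1 (0.1× the unit signal amplitude); f is the identity in
`linear-lag` mode and tanh in `nonlinear-lag` mode. The `circadian` mode
adds a 24-hour cosine baseline with a uniformly random per-gene phase and
reports non-negative expression values; the default sampling design is
3-minute intervals over 24 h — 480 points. A `lag2` flag delays couplings
by two steps to probe estimator/model mismatch. The emitted gold standard
is by construction the set of planted edges with non-zero coupling.

Two deliberate properties:

- **Bounded coupling for benchmarks.** With strong couplings in a feedback
  cycle the linear mode's update matrix can have spectral radius > 1 and
  the series diverge; planted-network benchmarks therefore use the tanh
  mode, which is stationary for any coupling pattern, as the study
  condition for direction-recovery claims.
- **Reference waveform.** `make_rhythm_reference` is a von Mises-style
  bump exp(κ·(cos θ − 1)) (κ = 3) peaking at a chosen circadian phase —
  non-negative and single-peaked, emulating a sharp nocturnal melatonin-
  pathway peak. Because raw non-negative profiles always have non-negative
  cosine similarity, antiphase checks (and the clustering stage itself)
  operate on z-scored profiles, where profiles 12 h apart anticorrelate.

What the generator does not emulate: read-count noise models
(negative-binomial overdispersion), amplitude heterogeneity across genes,
missing samples, slow trends, or regulatory delays longer than two sampling
steps. Passing benchmarks on it therefore demonstrates correctness of the
estimator and pipeline under the stated dynamics, not performance on raw
sequencing-derived data.

## Problem sizes and numerical choices

The validation suites use 10-gene, 480-point panels (the all-pairs stage
scales as n²·n_permutations TE evaluations, each O(T + B³)); null
calibration uses 500 independent pairs at 200 permutations, direction
recovery 20 simulation seeds, determinism two full pipeline reruns at 200
permutations. Degenerate inputs are defined, not errors: constant series
discretize to a single symbol and have zero TE against anything; a constant
pair yields p = 1. Tiny negative TE from floating-point cancellation is
clamped to zero. Fuzzy c-means guards coincident gene/centre distances with
a 1e−300 floor; non-convergence returns the best-so-far memberships with a
warning.

## Known limitations

- Pairwise TE cannot separate direct from indirect regulation; conditional
  or multivariate extensions are out of scope.
- The equal-width histogram estimator is biased for very short series;
  below ~100 points the permutation test loses power well before the
  estimate becomes unusable.
- The strongest-edge screens keep at most one edge per gene and so cannot
  represent multi-target regulators in the final per-gene networks (the
  upstream screened edge list retains them).
- The 0.5-bit default TE floor is conservative for weakly coupled systems;
  it is a tunable, not a law.
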
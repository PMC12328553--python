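# Methods

## Spiral geometry

Stimuli are polar curves sampled on the grid Φ = 0, 0.01, 0.02, … rad up to
6π (three turns) or 8π (four turns); the endpoint is appended as a final
vertex when it falls off-grid, bounding the truncation error by one step.
Two families are implemented:

* **(generalized) Archimedean**: ρ = aΦ^(1/c).  `a` sets the spacing between
  turns (plot units per radian at c = 1); `c` < 1 inflates the spacing
  outward.  The plain Archimedean spiral is c = 1.
* **logarithmic**: r = ae^(bΦ).  `a` is the radius at Φ = 0, `b` the growth
  rate per radian.  b = 0.306349 gives the golden spiral, which widens by the
  golden ratio per quarter turn (verified as a property test).

The built-in catalog holds the 15 stimulus parameterizations (5 types × 3
versions).  Versions 1/2 run three turns at normal/large size; version 3 runs
four turns at the version-1 scale, and version 2 of each family is sized to
match the footprint of its version 3, so size and number of turns can be
contrasted independently.

**Curvature** uses the polar-curve formula
κ = |ρ² + 2ρ′² − ρρ″| / (ρ² + ρ′²)^{3/2}.  For logarithmic spirals
κ·ρ = 1/√(1+b²) exactly, which serves as an internal oracle.  The generalized
Archimedean derivative is singular at Φ = 0 (for c ≠ 1); `curvature_at`
rejects that point and `sample_polyline` carries the value of the first grid
point back to the origin vertex — at 0.01-rad resolution this does not move
any catalog summary statistic.

**Curvature summaries** are the unweighted mean and population (1/N) variance
over sample vertices, i.e. one value per angular step, matching how the
stimuli were computed.  Because vertices crowd near the origin where κ is
huge, an arc-length-weighted alternative is exposed
(`curvature_stats(…, weight_by_arc_length=True)`) but is not the default.

**Arc length** has two independent routes: summed chord lengths of the
sampled polyline, and a closed form (plain Archimedean:
L = (a/2)[Φ√(1+Φ²) + asinh Φ]; logarithmic: L = √(1+b²)/b · Δρ; generalized
Archimedean: adaptive quadrature of √(ρ² + ρ′²)).  The two agree to ≤ 0.1 %
on every catalog spec (tested), and the four-turn stimuli reproduce the
published path lengths 42 / 26 / 15.

## Rendering and the DCM balance score

Stimuli are drawn with a 1-px non-anti-aliased pen, black on white, centered
by bounding box.  The balance score is

DCM = 100 · ‖ink centroid − canvas center‖ / (canvas side / 2),

i.e. the centroid deviation as a percent of the half canvas side, with every
ink pixel weighted equally.  The prior formalization this measure follows
leaves the normalization and rendering margins open; we calibrated both
**once** against the three published balance scores (4.80 / 13.4 / 19.3 for
the four-turn Archimedean, logarithmic-1 and golden spirals): a per-stimulus
bounding-box fit with a 12.5 % margin per side — the axis padding a standard
line-graph rendering leaves around the data region — reproduces all three
anchors to ≤ 3 %.  Every correlation-based result is invariant to this
affine calibration (Pearson r is unchanged by rescaling a feature column;
tested), so only the three anchor values themselves depend on it.

DCM is a *within-spiral* balance: each spiral is fitted to its own canvas.
The three-turn normal versions (version 1) occupy only part of a shared
canvas, so their whole-image balance is not comparable; following the source
analysis they inherit the DCM of their family's size-matched version 2,
which shares their shape exactly (versions 1 and 2 are similar figures).
With this substitution the feature table reproduces the published
correlations r(DCM, width-to-height) = 0.96 and r(DCM, width) = −0.25.
Width, height and path length are measured on the continuous polyline in
plot units (one scale for all stimuli by construction), avoiding pen-width
bias.

## Rating analysis

* **ICC(C,k)** — two-way rater × stimulus ANOVA, consistency definition,
  average-measures: (MS_stimuli − MS_residual)/MS_stimuli.  Insensitive to
  additive rater shifts (tested, plus a cross-check against pingouin's
  ICC(C,k) on random data).
* **Group discovery** — k-means on the raw rating rows (no standardization:
  all columns share the 1–100 scale), k-means++ with 100 restarts and a
  recorded seed; explained variance is between-cluster SS / total SS.
  Cluster labels are arbitrary, so clusters are canonically renamed by the
  correlation of their centroid with the stimulus DCM profile: most negative
  → group A (likes balanced spirals), most positive → group G, remainder
  → L.
* **Per-group OLS** — mean ratings on raw-scale (width, path length, DCM).
  Noiseless synthetic profiles built from the published coefficients are
  recovered to 1e−8 (oracle identity).  Rank-deficient designs are rejected
  naming the collinear columns; a constant response yields zero slopes and
  R² = 0 by convention.
* **Mixed model** — `rating ~ (width + path_length + dcm) * group +
  (1 | rater)`, REML via statsmodels `MixedLM`.  Predictors and the rating
  are Z-scored over the full long table (a single common scale, as the
  interaction model requires), so coefficients are standardized.  When the
  gradient optimizer stalls at the τ₀₀ = 0 boundary the fit is retried with
  Powell's method.  σ²_f is the population variance of the fixed-effect
  linear predictor; then ICC = τ₀₀/(τ₀₀+σ²), marginal R² =
  σ²_f/(σ²_f+τ₀₀+σ²), conditional R² = (σ²_f+τ₀₀)/(σ²_f+τ₀₀+σ²).  The
  published components (σ² = 0.60, τ₀₀ = 0.08, marginal 0.322) give
  ICC 0.118 and conditional R² 40.1 % through this arithmetic.
* Missing ratings are rejected, not imputed — the design yields complete
  matrices.

## Pair comparisons

A participant's three choices either induce one of the six transitive
rankings or form a cycle; cyclic participants are excluded from orders,
Borda and Bradley–Terry alike.  Borda: 2/1/0 points per participant by
number of pairwise wins, normalized by total points (3 × group size), so a
unanimously top-ranked spiral scores exactly 2/3.  Bradley–Terry is plain
(unpenalized) maximum likelihood via Zermelo's MM iteration, converged when
max |Δλ| < 1e−8, anchored at a reference stimulus; the score equations
(expected wins = observed wins) are verified to 1e−6.  The fit requires a
connected comparison graph and no all-or-nothing item.

On the published win counts (51/79 prefer L1 over AR, 47/79 L1 over GO,
50/79 GO over AR) the plain MLE gives λ = 0.714 / 0.436 for L1 / GO (AR = 0).
The originally reported scores 0.659 / 0.381 differ in level but match in
difference (0.278); they come from an R package whose exact fitting variant
(bias reduction or an order-effect term) is not stated, so we report the
plain-MLE values and treat the *difference* as the comparable quantity.

## Creativity scoring

Responses are lower-cased, normalizer-reduced and merged through a synonym
lexicon applied to a fixed point (idempotent).  The normalizer is pluggable
(the study data are German; a stemmer can be injected), and the default does
no language-specific stemming — correctness tests use a deterministic toy
lexicon instead of an NLP dependency.  Frequencies n are counted per prompt:
"snail" said about the Archimedean spiral and about the golden spiral are
different associations.  Originality = Σ 1/n over a participant's records;
summed over everyone it equals the number of distinct (prompt, token) pairs
(conservation identity, tested).

The permutation test on the difference in group means uses the plain
proportion of permuted differences ≥ the observed one (a +1-corrected
variant exists but is off by default, matching the stated rule), with
exhaustive enumeration whenever the number of distinct label assignments is
≤ B and vectorized sampling otherwise.  Welch's t uses the Satterthwaite df;
Cohen's d uses the pooled SD, consistent with the published d alongside a
Welch statistic.

## Synthetic data

One master seed derives named sub-streams (`SeedSequence.spawn`) for
ratings, choices and associations, so each fixture is independently
bit-reproducible.

* **Ratings**: rating(i, s) = intercept_g + β_g·(width, path length, DCM)_s
  + u_i + ε, u_i ~ N(0, τ), ε ~ N(0, σ), clipped to [1, 100].  β defaults
  are the published per-group coefficients (raw scale, matching the
  unstandardized table they come from); group sizes default to 33/40/45.
  σ = 16 and τ = 6 are sized so that, against the fixed-effect spread of
  the default profiles, roughly 60 % of rating variance is residual and
  ~8 % between raters — the published decomposition.  The clip rate is
  returned (≈2 % at defaults); recovery tests use lower noise and keep it
  < 1 %.
* **Choices**: independent Bernoulli per pair with
  P(i ≻ j) = σ(λᵢ − λⱼ); default abilities are the published preference
  scores (0, 0.659, 0.381), 79 participants.  Under equal abilities 2 of
  the 8 choice patterns are cyclic, so ~25 % intransitivity (tested).
* **Associations**: counts ~ Poisson(λ_g / 2) per prompt with λ =
  3.00/4.43/5.00 for A/L/G (the published group means) and group sizes
  11/14/7; tokens drawn from a 60-token per-prompt vocabulary with
  rank-frequency exponent 1.5 / 1.1 / 0.8 for A / L / G, chosen once so the
  less creative group concentrates on common tokens (lower originality per
  association) while effect sizes stay in the published range.  Power check:
  at this stated world the one-sided fluency permutation test rejects at
  α = 0.05 in ≳ 50 % of replicates — consistent with a study of this size
  sitting near the significance boundary (observed p = 0.047).

What a green synthetic test establishes: that the estimators recover the
generating structure (labels, coefficients, variance components, abilities,
rates) at study size.  What it does not: the generators draw i.i.d. Gaussian
noise, independent pairwise choices and a stationary vocabulary — no
response styles, order effects, shared semantics between prompts, or German
morphology — so synthetic results never stand in for the study's
observed-data values (e.g. ICC 0.591 or the 33 % k-means variance), which
require the deposited raw data.

## Numerical choices and limitations

* Sampling step 0.01 rad; halving it moves numeric arc lengths by < 0.01 %.
* Quadrature tolerance 1e−10 for generalized-Archimedean arc length.
* k-means restarts default to 100; explained variance is reported for the
  best restart.
* The BT iteration normalizes π to sum 1 each step and re-anchors λ at the
  reference; adding a constant to all abilities leaves fitted probabilities
  unchanged (tested).
* DCM depends on rasterization (1-px pen, 500 px canvas); doubling the
  canvas moves scores by < 2 %.  The calibrated margin/normalization pair is
  one of several conventions consistent with the three published anchors;
  conclusions that rest on correlations are unaffected by the choice.
* The per-group repeated-measures ANOVAs, personality-trait scoring and
  free-text reason coding of the original study are out of scope.
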
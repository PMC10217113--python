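# Methods

This note records the model, conventions and design choices behind `tdsim`,
in the spirit of a statistical package's methods documentation. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Trial model and conventions

A trial is an ordered sequence of (attribute, onset) events on normalized
time [0, 1]. Raw button-press timestamps in seconds are mapped affinely,
`(t − start) / (stop − start)`; the original span is kept as
`duration_seconds` so real-time quantities (switching intervals, seconds per
interval) remain computable.

Conventions that the underlying model leaves open, fixed here so every
operation is deterministic and testable:

- **Segments are half-open** `[onset, next onset)` and right-continuous;
  `t = 1` maps to the final segment. The choice only moves sets of measure
  zero but makes point evaluation well defined.
- **Re-pressing the selected button is a no-op** (a selected button stays
  selected until another is pressed), so consecutive duplicate events are
  collapsed at construction. A press at exactly the stop instant would
  select for zero time and is dropped with a warning.
- **Zero-selection trials are accepted** (the "none" state, index 0, holds
  throughout) with a warning rather than rejected: they are legitimate
  degenerate data and natural outlier candidates. "none" may never recur
  after an attribute has been selected.
- **Smoothing of the dominance curve is presentation-only.** All similarity
  and outlier computations use the raw step functions; `smooth_curve` is a
  centered moving average on a uniform resampling (edge values extended),
  which keeps every output row a convex combination of probability rows, so
  the simplex constraint survives exactly.

## Exact discretization

`X_i[k] = R·∫ x_i(t) dt` over `[k/R, (k+1)/R]` is computed in closed form as
R times the overlap length between the attribute's segments and the
interval — the integrand is piecewise constant, so quadrature would only add
error. A midpoint-Riemann-sum implementation exists solely as an independent
test oracle. Column sums equal 1 to ~1e−15 by construction, and
discretization commutes with averaging (linearity), which the tests check
exactly on rational inputs.

## Similarity index

The per-interval distance is the Euclidean norm over all q+1 attribute
coordinates, summed over intervals and divided by √2·R. The √2 arises
because two disjoint unit vectors (two trials holding different single
attributes in the same interval) are √2 apart; the normalization therefore
puts the attainable maximum of the distance term at exactly 1. An optional
Manhattan variant divides by 2R for the same reason (disjoint unit vectors
are 2 apart in L1). Two readings of the distance formula are possible —
norm per interval, or one global norm over all intervals; the "average
per-interval distance" interpretation with the √2·R normalization is the one
consistent with the maximum-1 property and is what is implemented.

Two deliberate consequences, documented because they surprise users:

- **The "none" state participates in the sum.** A trial that starts
  selecting late genuinely differs from one that starts immediately, and the
  index sees that difference.
- **Cross-R comparisons are rejected**, not resampled: the index is defined
  only for a common R.

`similarity_set` scores every trial against the centroid computed from *all*
n trials, including the trial being scored — this keeps the set definition
symmetric in the trials. A `leave_one_out` flag removes the scored trial
from the centroid; because the residual vector then scales by n/(n−1)
uniformly, leave-one-out scores are never higher than the default ones.

## Cross-R correlation and choosing R

`correlate_sets` is the standard Pearson product–moment correlation over
entries matched by trial id (matched sample moments in numerator and
denominator, so the population-vs-sample convention cancels). Zero-variance
sets raise an error rather than returning NaN — silent NaNs would corrupt a
grid. `recommend_R` formalizes "an R whose similarities agree with all other
levels" as the row of the correlation grid maximizing its minimum
off-diagonal correlation (`max-min`; `max-mean` as alternative), tie-broken
toward smaller R for parsimony. `R_from_min_switch_interval` implements the
behavioral-resolution heuristic: one interval per shortest inter-press gap,
using a low quantile (default 5th percentile) of all gaps rather than the
literal minimum, which a single twitchy double-press would otherwise
dominate.

## Outlier screen

For each R: a one-sample Kolmogorov–Smirnov test of C_R against a normal
distribution gates the screen at p > 0.05. The default KS mode plugs the
sample mean and standard deviation into the reference normal; this is the
most literal reading of the procedure being reproduced, but it is biased
toward accepting normality when parameters are estimated, so a
Lilliefors-corrected mode (via statsmodels) is provided and documented as
statistically preferable. If normality is not rejected, trials strictly
below μ − 1.64σ (95% coverage) or μ − 2.33σ (99%) are flagged; a value
exactly at the threshold is an inlier (the acceptance range is closed).
The constants 1.64 and 2.33 are kept at two decimals as conventionally
printed, not recomputed as 1.645/2.326; σ uses the n−1 divisor. The screen
is one-sided by design: unusually *high* similarity to the centroid means
the trial represents the panel especially well. When normality is rejected,
a box-plot rule flags trials below Q1 − 1.5·IQR (linear-interpolation
quartiles), also one-sided for consistency.

Since C_R is univariate, the minimum-covariance-determinant idea reduces to
its shortest-half analog: location and scale from the contiguous
h = ⌈(n+1)/2⌉ sorted points with minimal range, the scale inflated by the
consistency factor α / P(χ²₃ ≤ χ²₁(α)) (α = h/n) so it is consistent for
normal data. It is available as a drop-in (μ, σ) for the normal screen via
`robust=True`; single-draw scale estimates fluctuate by roughly ±9% at
n = 200, which the tests account for by averaging over draws.

No multiple-testing correction is applied across R values, and flagged
trials are reported, never removed — deciding removal needs information the
index does not carry.

## Synthetic panel generator

Real TDS event logs are rarely published, so validation runs on synthetic
panels from an explicit semi-Markov model: the next attribute is drawn from
a transition matrix (zero diagonal; a zero row is absorbing), the time spent
on it from a per-attribute sojourn distribution (gamma by default;
lognormal and constant available — constant makes degenerate, exactly
checkable trials). Temporal structure is produced by phase-dependent
transition matrices switching on thirds of the task; a time-homogeneous
chain cannot make an attribute prominent specifically in the middle of a
trial. The final sojourn is truncated at the stop button (rejection would
distort the duration marginal), and seeds are mandatory — there is no
global random state. Panel ids follow the letter+replicate convention
("A1" … "Q3" for 17×3).

### Strawberry-like preset

The preset emulates an 8-attribute strawberry panel (sweet, sour, fruity,
green, watery, juicy, aromatic, light): task duration N(30 s, 4 s) truncated
at 10 s; an ~1 s exponential "none" lead-in; gamma sojourns, mean 2.5 s,
shape 2 (≈12 selections per trial; about 84% of inter-press gaps exceed
1 s, matching the observation that panelists rarely switch faster than
once per second); and phase weight tables that favor sweet/juicy/fruity/
watery early, aromatic and sour in the middle, and sour with light late.
The phase contrast was calibrated so that the generator reproduces the
qualitative outlier semantics the screen is meant to detect — in
particular, a trial with typical durations but a reversed timeline is a
high-R outlier with high probability, while remaining an R=1 inlier. With
flatter weights the synthetic panel's temporal structure is too weak for
any timing-based screen to find anything, which would say nothing about
the method.

### What the generator does and does not emulate

It reproduces: the one-dominant-attribute constraint by construction,
realistic selection counts and gap distributions, phase-structured TDS
curves, and panel-shaped id structure. It does **not** model:
within-panelist correlation across replicates (each trial is independent;
an optional per-panel random effect was considered and left out to keep
the null i.i.d.), sample-to-sample differences in the food, learning or
fatigue across replicates, or heavy-tailed task durations. Passing tests on
synthetic panels therefore demonstrate correctness and statistical behavior
of the *method* under a controlled, realistic null — not distributional
claims about any particular real panel.

### Outlier archetypes

`inject_outlier` replaces one trial, leaving all others bit-identical:

- `single_attribute`: one attribute held for the entire trial — zero
  durations everywhere else make it an R=1 outlier;
- `rare_attributes`: re-simulated under inverted attribute preferences
  (weights ∝ 1/attractiveness) with the target's own duration — a
  small-to-medium-R outlier;
- `time_shifted`: the target trial's own selection timeline reversed in
  place (the lead-in stays at the start, since "none" cannot legally recur).
  This preserves every dominance duration exactly — the cleanest possible
  "typical durations, shifted timing" outlier — rather than re-simulating
  under reversed phases, which preserves durations only in expectation and
  blurs the timing contrast.

## Problem sizes and numerics

Test and validation runs use panel-sized problems: 51-trial panels (17×3),
correlation grids over R ∈ {1, 3, 10, 30, 50, 100}, 100-panel replications
for power estimates, 1,000 random trials against the quadrature oracle
(1e−5 grid, 1e−4 tolerance), and ~10,000 draws for the null flag-rate
check. These sizes give Monte-Carlo error comfortably below the margins
being tested. Exact-arithmetic assertions (column sums, commutativity,
symmetry) use 1e−12 absolute tolerance; random-trial fixtures place onsets
on a 1/1000 lattice so linearity identities hold to float precision.

## Known limitations

- The KS gate with plug-in parameters under-rejects; use the Lilliefors
  mode when the gate matters.
- The index weights all attributes equally and offers no probability-based
  distances; both are deliberate non-goals here.
- `recommend_R` scores only the correlation grid it is given: a grid whose
  levels are all small (or all large) recommends within that range.
- The screen flags; it does not explain. Inspecting the flagged trials'
  discretized matrices against the centroid is the intended follow-up.
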
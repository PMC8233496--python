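# Methods

This note documents the models and algorithms implemented in `chronotree`,
the assumptions behind them, the tunable parameters that matter, and the
limits of what the bundled simulator can demonstrate.

## The relative-rate framework (`chronotree.reltime`)

Input is a rooted phylogram: branch lengths are expected substitutions per
site. No molecular clock is assumed. The method assigns every branch
(lineage) a *relative rate* and every node a *relative time* in [0, 1]
(root = 1, contemporaneous tips = 0).

The recursion, which is this package's normative definition:

- Post-order, at a node with children c_1 … c_k, let
  `d(c_j) = b(c_j) + D(c_j)`, where `b` is the branch length and `D(c_j)`
  is the mean rate-adjusted node-to-tip path length below c_j (tips:
  `D = 0`).
- Local relative rates `r(c_j) = k · d(c_j) / Σ_i d(c_i)`, so sister
  lineages average to 1 locally. For k = 2 this is the familiar pairwise
  ratio `2 d_1/(d_1 + d_2)`. We use the k-way form directly at
  multifurcations because it is invariant to child order; resolving a
  polytomy into an arbitrary caterpillar of zero-length branches is not.
- The lineage rate of a branch is the product of local rates on its
  root-to-branch path.
- Adjusted heights satisfy `h(i) = h(c) + b(c)/rate(c)`, identical through
  every child by construction of the local rates; relative time is
  `h / h(root)`.

`D(i)` is maintained as the tip-count-weighted mean of `d(c_j)/r(c_j)`
over children, which equals the plain mean `Σ d / k` whenever no rate was
clamped. Rates are floored at 1e-9 to survive zero-length branches; a
subtree with no substitutions at all gets local rates 1 and a warning.
Single-child chains are collapsed (lengths summed) before the recursion.

Properties that follow and are enforced by tests: scale invariance
(multiplying all branch lengths by a constant changes nothing), the clock
identity (an ultrametric phylogram yields all rates exactly 1 and relative
times equal to normalized heights), and parent time ≥ child time.

**Uncertainty.** Rate heterogeneity is propagated by Monte Carlo: each
replicate multiplies every lineage rate by independent mean-one lognormal
noise with coefficient of variation `rate_cv`, then recomputes heights.
`rate_cv` defaults to 0.2 when no alignment is available to inform it; this
default is arbitrary and user-overridable, and intervals from a tree-only
analysis are necessarily narrower than ones that also carry branch-length
re-estimation error (which requires the original alignment and is out of
scope). In the calibration-recovery experiments we set `rate_cv` to the
coefficient of variation of the generating rate law
(`sqrt(exp(sdlog²) − 1)`), i.e. the correct rate-dispersion model.

## Node dating with calibration densities (`chronotree.node_dating`)

Calibrations attach prior information to nodes: normal(mean, sd),
lognormal(offset, mean, sd) — log-scale mean/sd on (time − offset) —
exponential(offset, decay), uniform(min, max), or hard point / minimum /
maximum bounds. Times are in the user's units (Ma, calendar years …).

A single scaling factor f maps relative to absolute times. Hard
constraints intersect to a feasible interval for f (a conflict is reported
with the offending pair); within it, f maximizes the summed log-density of
the calibrated ages `f · t_rel(node_k)` (scalar bounded maximization,
xatol 1e-10). Summing log-densities — rather than averaging
per-calibration estimates — keeps the objective well-defined for mixed
density types. A density set with zero mass everywhere on the feasible
interval is an error, not a silent clamp. Node times are `f · t_rel`,
clamped into any bounds, with parent ≥ child re-enforced by an upward
max-propagation pass (bounds can otherwise invert an edge).

Confidence intervals (2.5/97.5 percentiles, default 10,000 replicates,
seedable) combine both variance sources per replicate: a rate-perturbed
relative-time vector and a fresh draw of every density/point calibration
age, recombined by least squares into a replicate scaling factor.
Uniform-calibrated nodes have their intervals truncated to the bound.

Fixed-rate calibration divides adjusted heights by the given rate; its
intervals reflect rate heterogeneity only.

## Tip dating (`chronotree.tip_dating`)

For serially sampled data (fast-evolving pathogens, ancient DNA) the
sampling dates are the calibration. The fit is least squares on
rate-adjusted root-to-tip depths, `D_j = μ (s_j − T0)`, giving the
substitution rate μ and the root date T0; every node is then placed at
`T0 + depth/μ`.

The subtlety is where the depths come from. The relative-rate recursion
*assumes contemporaneous tips* and therefore equalizes all adjusted tip
depths exactly — applied blindly it erases the very signal the regression
needs. The fit therefore iterates to a fixed point:

1. initial μ from the regression on raw (unadjusted) root-to-tip depths;
2. every dated terminal branch is extended by `μ(s_max − s_j)` so the tree
   becomes pseudo-contemporaneous (undated tips join with their currently
   estimated date); the recursion now sees the geometry it assumes;
3. lineage rates are re-estimated on the extended tree and the adjusted
   depth of each tip recomputed with its *original* terminal length;
4. μ and T0 are refit; repeat until |Δμ|/μ < 1e-10 (≤ 20 rounds).

On a strict-clock tree step 1 is already exact, the extended tree is
exactly ultrametric and the loop converges immediately; serially sampled
strict-clock simulations are recovered to machine precision. Two exact
laws hold by linearity and are tested at 1e-9: shifting all dates by k
shifts T0 and all node times by k (μ unchanged); scaling all branch
lengths by k scales μ by k (times unchanged).

Date parsing: ISO `YYYY-MM-DD` maps to `year + (day_of_year − 0.5)/days`;
`YYYY-MM` is pinned to the first of the month; plain `YYYY` is year.0
exactly; decimal years pass through. Tips with unparseable dates are
excluded from the regression, dated post hoc like internal nodes, and
flagged `inferred`.

Intervals re-fit the regression inside each rate-perturbation replicate
(default 2,000, seedable).

**Limitation.** μ-recovery degrades with branch-rate noise: under iid
lognormal rates with sdlog 0.2 the median relative error of μ̂ is ≈ 13% in
our 50-tip simulations (exact under a strict clock). Root position is
taken as given; no temporal-signal diagnostics beyond rejecting μ ≤ 0.

## Neutral evolutionary probabilities (`chronotree.ep`)

EP of an allele at a site is its posterior probability in the focal taxon
(the first alignment record) given the other sequences and a timetree,
under the substitution model — the neutral expectation against which
observed alleles are judged. Alleles with EP < 0.05 are flagged
nonneutral.

Pipeline: a phylogram input is reduced to relative durations via the
relative-rate framework; an already-ultrametric input is used in its own
time units. A single global rate converts durations to expected
substitutions per branch; `rate="auto"` fits it by bounded scalar
maximization of the focal-masked alignment likelihood (log10-rate in
[−6, 2]), or the user fixes it (rate = 1 when branch lengths are already
expected substitutions). Per-branch free rates are deliberately not
fitted: they would dissolve the timetree constraint that gives EP its
meaning.

Per site, the focal tip contributes all-ones partials (missing data); an
upward pruning pass and one downward (outside) pass give the joint
`P(focal = x, rest)`, normalized over x. Discrete-gamma categories, when
enabled, are weight-summed before normalizing. Sites where no taxon has an
observed state return the stationary frequencies with a warning.
Everything runs on compressed site patterns and is expanded back to sites.

The implementation is verified against exhaustive summation over all
internal-node state assignments on small trees (≤ 1e-9), the two-taxon
closed form `EP(match) = 1/4 + 3/4·e^(−4d/3)` under JC, and the
saturation limit. The amino-acid default is the Poisson equal-rates model;
empirical exchangeability matrices are out of scope.

## Rate-autocorrelation test (`chronotree.corrtest`)

Whether branch rates are inherited (autocorrelated) or vary independently
matters for clock priors and for interpreting rate variation. The test
summarizes a phylogram by four correlations over its estimated lineage
rates — Pearson and Spearman on (ancestor, descendant) pairs and on sister
pairs — and maps them through a frozen logistic model to a CorrScore in
[0, 1].

The logistic coefficients were fit once on this package's simulator (600
Yule trees per class, 50–300 tips; independent-lognormal sdlog 0.2–0.5
vs geometric-Brownian step 0.1–0.3; `scripts/train_corrtest.py`, seed
recorded there; training accuracy 0.97).

An important empirical fact: because lineage-rate estimates are built
multiplicatively down the tree, ancestor–descendant correlations are
strongly positive (≈ 0.8 at 200 tips) *even when the true rates are
independent*. Absolute feature values are therefore meaningless as
evidence; the P-value is computed by simulation under the null —
independent-lognormal trees of matched tip count (topology resampled,
sdlog 0.3), scored identically, with the +1/(n+1) correction. This makes
the test calibrated by construction (empirical size 2–8% at nominal 5%
over 400 trials) regardless of classifier quality, which affects power
only (empirical power 1.0 against geometric-Brownian step 0.2 at 300
tips). A strict-clock tree (no rate variance) is rejected as inapplicable
input, and ≥ 10 tips are required for feature stability.

## Likelihood engine (`chronotree.likelihood`)

An alignment of L sites holds only m ≤ L distinct site configurations;
identical configurations have identical likelihoods, so conditional
partials are stored per pattern and the total log-likelihood is the
weight-sum of pattern log-likelihoods. Memory and time for the pruning
pass scale with m, which is the point of the compression; the ratio m/L is
reported. Two columns differing only in gap placement are distinct
patterns (the missing code participates in the pattern identity).

Models: JC and HKY (κ, free base frequencies) for nucleotides, Poisson
equal-rates for amino acids, each with optional discrete-gamma rate
variation (4 equal-probability categories, category-mean rates). This
minimal set exercises every algorithmic path — unequal frequencies,
transition/transversion asymmetry, rate categories — without a model
catalogue. Rate matrices are normalized to unit mean rate; JC and Poisson
use their closed-form transition probabilities, HKY a matrix exponential.
Gaps and ambiguity codes are missing data (all-ones partials).

Branch-length optimization is coordinate-wise bounded scalar maximization
per branch (bounds [0, 10] substitutions/site), round-robin, converged
when the largest length change in a round is below 1e-6 (≤ 50 rounds,
warning + best-so-far on non-convergence), with a snap-to-zero check so
identical sequences collapse cleanly. Adequate at the tens-of-taxa scale
this package targets; no topology search, GTR, codon or partitioned
models.

## Simulator (`chronotree.simulate`)

The generator produces exactly the conditions the estimators assume, plus
controlled violations:

- **Trees**: Yule (pure birth) with a given tip count; waiting times
  Exp(kλ); true node ages recorded in annotations. Default birth rate 1
  (time unit = expected initial waiting time); tip-dating fixtures use
  λ = 0.1/year so that a 50-tip tree is a few decades deep, a realistic
  measurably-evolving-population setting.
- **Rates**: strict (rate μ); independent lognormal with mean μ and
  log-sd `sdlog` (default 0.3, a moderate, realistic dispersion);
  autocorrelated geometric Brownian, child log-rate = parent log-rate +
  N(0, step_sdlog), rooted at log μ (default step 0.2).
- **Serial sampling**: each tip's terminal branch is shortened by an
  exponential offset (mean span/3, truncated to the span and to 95% of the
  branch), giving dates clustered toward the present — the typical shape
  of outbreak sampling. Default span for tip-dating fixtures: 10 years
  with μ = 0.002 substitutions/site/year, in the range of RNA-virus rates.
- **Sequences**: root states from the stationary distribution, branch-wise
  evolution by the model's transition matrices.

Every generator is deterministic under its mandatory seed, and true
parameters are always stored next to the data.

What the simulator does **not** emulate — and hence what green tests do
not certify about real data: alignment/tree estimation error upstream of
the phylogram (branch lengths are taken as observed data), recombination,
indels and alignment gaps with phylogenetic signal, non-Yule tree shapes
(birth–death extinction, coalescent structure, epidemic dynamics),
sampling biases, and model misspecification beyond the three rate regimes.

## Numerical conventions

- Rates floored at 1e-9; relative root time pinned to exactly 1.
- CI percentiles fixed at 2.5/97.5; all Monte Carlo is seedable and
  bit-reproducible (`numpy.random.default_rng`).
- Monotonicity repairs: node-dating clamps are followed by an upward max
  pass (ages), tip dating by a downward min pass (calendar dates); both
  are no-ops unless bounds or rate clamping introduced a hairline
  inversion.
- Newick output prints 12 significant digits; round-tripping preserves
  branch lengths to 1e-12. Annotations use the `[&key=value,…]` comment
  dialect.
- The CLI writes a `manifest.json` (inputs, parameters, seed, version; no
  timestamps) so that fixed-seed runs are byte-identical.
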
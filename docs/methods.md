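# Methods

## The variable-rates regression model

Trait values at the tips of a rooted time tree are modelled as

    y = X beta + eps,    eps ~ MVN(0, sigma_b^2 * V(r))

where `V(r)[i, j]` is the sum of `l_b * r_b` over the branches shared by
the root-to-tip paths of species *i* and *j* (`l_b` in time units, `r_b` a
dimensionless per-branch scalar), and `sigma_b^2` is the background
Brownian variance in trait² per unit path length. With every `r = 1` this
is the ordinary Brownian-motion PGLS; scalars above/below 1 mark branches
along which the regression residual changed more/less than the background
process predicts. All fits and tests use the full ML likelihood (not REML):
likelihood-ratio statistics and marginal-likelihood comparisons both
require it. The GLS machinery accepts arbitrary design matrices built from
continuous terms, treatment-coded categoricals (reference level declared,
monogamy by default for mating system) and pairwise interactions.

A deliberate non-identifiability is documented rather than removed:
multiplying every `r` by `c > 0` while dividing `sigma_b^2` by `c` leaves
the likelihood unchanged (verified to machine precision in the tests).
Identifiability comes from the prior alone — non-innovating lineages are
pinned at `r = 1` and innovations are pulled toward 1 — so the *product*
`sigma_v^2 = sigma_b^2 * r` is the robustly interpretable per-branch rate,
and posterior `r` magnitudes should be read relative to their own chain's
`sigma_b^2`.

## Prior: copy-or-innovate rate inheritance

Each branch independently *innovates* with probability `p_active = 0.05`
(expected ~5% of branches start a new rate deviation); an innovation draws
`log r ~ Normal(0, 1.5^2)`. A branch that does not innovate copies its
parent's effective scalar exactly, so a clade-wide rate shift is a single
innovation whose value is inherited until overridden, and branches with no
innovating ancestor have `r = 1` exactly. This structure was chosen over
independent per-branch activation for three reasons, all verified
empirically during development:

1. *Detectability pricing.* Under independent activation, representing a
   clade-wide shift on a k-branch clade costs k activations (~3 nats each
   plus an Occam factor per free scalar), which exceeds the likelihood gain
   of realistic planted shifts; the posterior then never represents
   clade-wide elevation. Under copy-or-innovate a clade shift costs one
   innovation.
2. *Well-defined posterior-fraction criteria.* The shift criteria below
   compare rate draws between branches per iteration. With strictly
   continuous independent scalars, two branches tie with probability zero
   and one comparison side almost surely exceeds 50%, making the "does not
   differ" criterion unsatisfiable. Exact inheritance gives exact ties.
3. *Biology.* Heritable rate shifts are, by definition, deviations that
   descendants inherit; the prior encodes precisely that.

Other priors: regression coefficients `Normal(0, 10^2)`; `sigma_b` (the
standard deviation) half-Cauchy with scale 1. All scales are configurable
(`VariableRatesPriors`); the defaults above are used everywhere, including
the acceptance checks.

## MCMC

One iteration is one elementary Metropolis-Hastings proposal, drawn from a
weighted schedule: per-coefficient Gaussian random walks on `beta`; a
log-scale random walk on `sigma_b^2`; a reversible-jump toggle of one
branch's innovation indicator (values proposed from the innovation prior,
so the acceptance ratio reduces to likelihood ratio times Bernoulli odds);
a log-scale random walk on one innovation's value (its whole inheritance
domain moves with it); a compound *stem-isolation* move that jointly
innovates an internal branch and re-innovates its children near their old
rate (the configuration a clade-level intercept shift induces — see Mean
shifts); and a *slide* move relocating an innovation to a neighbouring
branch with its value kept (mixing over stem-vs-ancestor anchor
ambiguity). Detailed balance of the full move set was verified by
likelihood-off prior sampling (activation marginals recover 0.05 on trees
where the prior is exactly enumerable) and by continuous state/cache
consistency audits against dense-matrix likelihood recomputation.

Likelihood evaluations cache the scaled covariance, its Cholesky factor
and the whitened design; coefficient and variance moves are O(n) / O(1),
scalar moves update the covariance by clade submatrices and re-factorize.
Chains are initialized at the fixed-tree ML fit with proposal scales set
from its standard errors (2.4 x SE).

Per-parameter effective sample sizes use Geyer's initial monotone positive
sequence estimator; a run warns (never errors) when any falls below 500.
Replicate chains are available via `run_chains`. Posterior summaries `Px`
(fraction of a parameter's posterior on the minority side of zero; exact
zeros count toward crossing, an all-zero posterior reports the degenerate
0.5) and `Pxdiff` (the same for per-iteration pairwise differences, with
`< 0.05` flagged as a credible difference) follow the usual conventions.

### Default chain lengths

The package default is 200,000 proposals with 50,000 burn-in and thinning
of 20. The statistical validation runs use 100,000 / 25,000 / 20 on
100-tip trees and 60,000 / 15,000 / 15 where only coarse posterior
fractions are needed; these sizes were chosen as the point where doubling
the chain no longer changes the reported posterior fractions on planted-
shift benchmarks. Production analyses on large empirical trees should
scale iterations up and confirm ESS > 500 and agreement across replicate
chains.

## Marginal likelihoods and Bayes factors

Stepping-stone sampling estimates log marginal likelihoods: powers are the
`i/K` quantiles of Beta(0.4, 1) (concentrated near the prior), and each
adjacent power pair is bridged by the log-sum-exp average of powered
likelihoods sampled at the lower power. The ladder runs hot-to-cold after
a posterior adaptation phase, each stone warm-starting the next — cold-to-
hot ordering forces every stone to rediscover clade innovations within its
own iterations and systematically underestimates the variable-rates
model's marginal. The scaled-down validation preset is K = 20 stones with
5,000 iterations (1,250 burn-in) per stone; the production preset mirrors
common practice at K = 200 stones of 1M iterations (250k burn-in).

The Bayes factor is reported as `BF = 2 (log ml_m1 - log ml_m0)`, so
positive values support rate heterogeneity (> 2 positive, > 6 strong,
> 10 very strong). A formula sometimes printed as `-2 log(m1/m0)` yields
the opposite sign for the same evidence; this package fixes the convention
so that large positive BF = strong support for the variable-rates model.

## Shift classification and heritable shifts

Per branch, the posterior fractions of `r > 1` and `r < 1` classify it as
a rate increase, decrease, or background, with strict > 50% thresholds (a
tie at exactly 50% is background). Comparisons between branches are made
per iteration on `sigma_v^2` draws; since `sigma_b^2` is shared within an
iteration they reduce to comparisons of `r` draws.

A heritable rate shift is a clade satisfying: (1) its stem branch differs
in rate from its ancestor branch in > 50% of samples, in the direction of
the stem's own classification; and (2) no descendant branch differs from
the stem in > 50% of samples (exact inheritance ties make this
attainable). Children of the root, which have no ancestor branch, are
compared against the background scalar 1. Clades of 10+ species are
heritable shifts; 2-9 incipient; single tips single-species shifts. When a
clade and a nested subclade both qualify, only the largest is reported.
Internal branches passing criterion 1 whose elevation is *not* inherited
(all descendants background) are reported as `single-branch` candidates —
the mean-shift screening set.

Measured operating characteristics at the validation scale (x8 variance
shift on a 10-11-species clade in a 100-tip pure-birth tree, unit height):
detection of the planted clade as a heritable shift in 7-8 of 10
realizations, zero false heritable shifts in 10 null datasets, and planted
9-species clades never reported heritable. The misses are property of the
realizations, not the sampler: one or two datasets per batch realize under
10 nats of likelihood signal against the ~5-nat prior cost of an
innovation, and occasionally the data cannot localize the anchor between
the true stem and its immediate ancestor (posterior fraction straddling
the strict 50% rule). Power rises steeply with clade size and with stem
identifiability, which is why the planted-shift benchmarks anchor shifts
on clades with stem branches of at least 5% of tree height — a shift above
a near-zero-length stem is not a localizable clade event even in
principle.

## Mean shifts

An intercept change in a clade's allometry (a mean shift) appears to the
rate model as elevated change on the stem branch only. `flag_mean_shift`
re-fits the allometry on the *original* time tree with and without a
clade-membership dummy; if the dummy is significant (LRT, p < 0.05) and
the rate elevation is confined to the stem (descendants background), the
shift is relabelled a mean-shift candidate with the offset's sign. This is
deliberately a simplified post-hoc diagnostic. Its end-to-end sensitivity
is bounded by the screening step: an intercept offset must inject more
likelihood signal than the ~3-innovation prior cost of the stem-isolated
configuration before the posterior represents it, which at the validation
scale requires offsets above roughly one standard deviation of the
shared-path displacement. The flag operation itself is exact and is tested
against constructed posteriors.

## Path-wise rates and trends

A species' path-wise rate is the root-to-tip sum of rate-scaled branch
lengths, computed per posterior draw; the exposed summaries (median, mean,
histogram mode) summarize the per-draw sums — not sums over a summary
tree, which differ whenever scalars are correlated along a path. Trend
models are fitted by ML PGLS on the median rate-scaled tree:

    log_testes ~ log_body + MS + pathrate + MS x pathrate

per taxonomic group, with treatment coding against monogamy. Categories
with fewer than 20 species (ten data points per estimated slope and
intercept) are merged via an explicit mapping or excluded with a recorded
marker. Per-category slopes combine the base and interaction coefficients
with the delta-method variance; two-sided p-values use a t reference with
n - p degrees of freedom; Bonferroni correction multiplies by the number
of categories fitted within the group. Where no adjusted slope is
significant (the recorded fall-back rule; raw p-values are also kept), an
intercept-difference model `log_testes ~ log_body + MS` is compared to
`log_testes ~ log_body` by a likelihood-ratio D statistic on levels - 1
degrees of freedom, with pairwise contrasts oriented so positive values
mean the column category has larger average relative testes mass.
Everything downstream of the posterior trace is deterministic.

## The synthetic-data generator

`simulate_dataset` emulates the statistical structure the analysis
assumes: a birth-death tree (GSA-sampled so terminal branches have
positive length; default pure birth, rescaled to unit root-to-tip height);
log-log allometry with class-specific slopes and intercepts (defaults
slope 0.67 — metabolic two-thirds scaling — and intercept -2.0,
residual background variance sigma_b^2 = 0.05 per unit height, giving
~0.22 dex of residual scatter at the tips); body mass by Brownian motion
on the same tree (i.i.d. optional); planted variance shifts anchored at
the MRCA of two named tips and inherited by stem plus all descendant
branches; planted clade intercept offsets (mean shifts); mating systems
multinomial within class (birds-like default 75/15/10 monogamy/polygyny/
polyandry; balanced 40/30/30 in trend benchmarks so every category clears
the N >= 20 rule), optionally assigned in contiguous blocks to mimic
phylogenetic clustering; and planted directional trends that shift one
category's response by `coefficient x (path-wise rate - global mean
path-wise rate)`. Trend benchmarks plant three disjoint shifts (x8, x3,
x0.2) so path-wise rates vary continuously across tips; a single planted
shift on an ultrametric tree yields only two distinct path-wise rate
values and a degenerate interaction design.

What the generator does *not* emulate: measurement error, within-species
variance, missing data, fossil/non-ultrametric sampling, non-Brownian
processes (OU, early burst), and correlation between mating system and
rate history other than what is planted. Passing tests therefore certify
the machinery under its own assumptions, not robustness to their
violation on real data.

## Numerical choices and edge cases

* Zero-length terminal branches are allowed with a warning (zero variance
  and zero path-wise contribution); negative lengths are errors; branch
  lengths are required on every non-root edge.
* The root edge is retained as an un-scaled path constant shared by all
  tips, so pruning a basal outgroup (which folds the old stem into the
  root edge) preserves every covariance entry exactly.
* Species matching is exact after whitespace-to-underscore normalization
  and case folding; no fuzzy matching.
* Polytomies are accepted as-is; the shared-path covariance handles them
  naturally.
* r² is 1 - RSS/TSS in the GLS-whitened space, against the GLS grand-mean
  fit.
* Singular covariances (duplicate zero-length tips; a tip whose whole path
  is scaled to zero) raise immediately; MH proposals that would produce
  one are rejected.
* Ties in classification thresholds are resolved strictly (exactly 50% is
  background / not a shift).
* The Beta-quantile power schedule always ends at exactly 1; power 0
  (prior) is the implicit lower edge of the first stone.

## Known limitations

* Per-branch scalar magnitudes are only identified jointly with
  `sigma_b^2` (see above); interpret `sigma_v^2` or rate ratios, not raw
  `r`.
* Heritable-shift detection at the x8 / 10-species scale has per-dataset
  power of roughly 75-80%; weakly realized shifts and anchor-ambiguous
  stems are reported honestly as nothing rather than forced calls.
* The mean-shift diagnostic is a screening heuristic, not the full
  intercept-shift machinery of dedicated methods.
* Stepping-stone estimates at the scaled-down preset carry a standard
  error of a few log-units on 50-tip problems; Bayes factors near a
  decision boundary warrant the production preset.
* The cross-validation-style robustness check for trends (leave-one-clade-
  out refits) is available as an extension but is not part of the core
  reported analyses.
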
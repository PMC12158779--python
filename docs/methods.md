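# Methods

This note documents the statistical models, the synthetic-data generator, the
numerical machinery and the design decisions behind `starhelp`. It is written
for users who want to understand exactly what each analysis estimates and what
the test suite does and does not demonstrate.

## The helping-rate model

All rate analyses share one observation unit: the *dyad-day row* — one
possible helper at one observed nest on one day. A possible helper is any
group member present in the group that breeding season other than the nest's
two breeders; presence spans an individual's first to last observed season,
truncated when a gap of five or more seasons implies death. Rows record
observed whole minutes of help (attendance plus provisioning seconds rounded
*up*, so any positive help scores at least one minute) or an explicit zero for
present non-helpers. Coding zeros only for present group members keeps group
composition from masquerading as kin or partner preference.

The count model is a Bayesian negative-binomial multilevel regression:

    y_ij ~ NegBinomial(mu_ij, rho)
    log mu_ij = log(exposure_ij) + beta0 + x_ij' beta
                + u_helper(i) + v_nest(j) + w_dyad(i,j)

with `exposure` the minutes the nest was watched that day, `rho` the NB shape
(variance mu + mu²/rho), and independent Gaussian random intercepts for
helper, nest, and helper–breeder-pair identities. Fixed effects are drawn
from: standardized closest-parent kinship `z(r_max)`; the binary reciprocal
covariate; their interaction; and the standardized total or mean rate of help
received (the generalized-reciprocity controls). Covariates are standardized
on the rows entering each fit, so coefficients are per-model standardized
effects; kinship coefficients from joint models are flagged as not comparable
to kinship-only coefficients (different subsample, confounded pathways).

Kinship `r_max` is the helper's relatedness to the closer of the nest's two
parents, on the relationship scale (parent–offspring r = 0.5). Pedigree
relatedness uses the standard tabular recursion with founders assumed
unrelated and non-inbred; marker-based estimates, when supplied, replace
pedigree values for pairs involving an immigrant (negative estimates clipped
to zero and counted). The kin/non-kin boundary is strict: r equal to the
threshold is non-kin.

The reciprocal covariate flags rows whose nest has a breeder that acted as a
helper at a nest of the focal helper — help received from the parent. The
default is atemporal (received at any time during the study window); a
strictly-prior variant (received in an earlier season only) supports
causal-ordering sensitivity checks and is what the power scan uses inside
truncated windows. Models containing a reciprocal term exclude resident
females by default: they never breed, so help can never be returned to them
through a role swap, and retaining their rows would dilute the covariate with
structural zeros. Parameter-recovery studies against the generator switch
this exclusion off, because the generator's truth is expressed in
whole-table standardized-kinship units and the exclusion changes the
standardization sample (and hence the estimand) by roughly a third.

### Sampler

No probabilistic-programming backend is used; the model has its own MCMC
engine (`starhelp.nbglmm`). Every full conditional of the fixed-effect block
and of each random-effect level is strictly log-concave, so the sampler uses
*Laplace independence proposals*: Newton iteration to the conditional mode,
then a Gaussian proposal with the conditional curvature, accepted by
Metropolis–Hastings. Acceptance rates are ~0.99 and mixing is close to exact
Gibbs. Variance components and the NB shape are slice-sampled on the log
scale. A translation-group move (shift a random-effect block's mean into the
intercept, with the shift drawn from its exact Gaussian conditional) removes
the slow random walk between the intercept and random-effect means that
otherwise dominates the autocorrelation time.

Priors are weakly informative and printed with every fit: Normal(0, 5²) on
fixed effects, Half-Normal(1) on random-intercept s.d.s, LogNormal(0, 1.5) on
the NB shape. At the sample sizes involved their influence is negligible; the
posterior mean matches the `statsmodels` NB maximum-likelihood fit to two
decimals on random-effect-free data and the `glmmTMB` mixed-model MLE on
random-effect data.

Convergence is monitored with rank-normalized split R-hat and bulk/tail
effective sample sizes (arviz) on the fixed effects. A strict fit raises if
any fixed-effect R-hat exceeds 1.01; scan-style fits run non-strict and carry
a `converged` flag instead, and non-converged prefixes are excluded from
detection decisions but never silently dropped. Default settings are 4 chains
of 5,000 iterations with 1,000 warm-up; scans and tests use documented
reduced settings (2 chains, 700–2,000 iterations) chosen so a fit takes
seconds rather than minutes.

## The synthetic cooperative breeder

The generator (`starhelp.synthpop`) emulates a plural-breeding study system:
9 social groups followed over 40 breeding seasons (two per year), group sizes
7–60, up to 7 breeding pairs per group, about 1.1 observed nests per
group-season, 1–2 two-hour focal observations per nest, and roughly 5 distinct
helpers per observed nest. Demography is agent-based: groups are founded by
unrelated immigrant adults; breeding pairs recruit resident offspring (recorded
in the pedigree); unrelated immigrants arrive continuously; individuals survive
each season with probability 0.93. Per-season roles follow a Markov kernel
over {breeder, helper, neither} shared across sex-by-dispersal classes, with
one structural constraint: resident females redirect any breeder draw to
helper (probability of breeding 0, matching the strong asymmetry such systems
show). Breeding pairs form from same-season breeder aspirants of opposite
sexes; unmatched aspirants help.

The default demographic rates (immigration 0.4 per group-season, 2.0 recruits
per successful nest, success probability 0.65, founders 12–22) were calibrated
once against the descriptive targets above — in particular a mean within-group
pairwise relatedness near 0.08 (low, as in large mixed-kin societies) — and
then frozen.

Helping minutes are drawn from exactly the model the analyses fit, with
defaults beta0 = −7.0 (per log-minute of exposure), beta_kin = 0.6 per s.d.
of kinship, beta_recip = 1.0, random-intercept s.d.s 0.5 (a value the source
analyses do not report; it is a generator choice, stated here, not an
estimate), and NB shape 1.0. Reciprocity is injected causally: a row's
reciprocal flag is on when a breeder of that nest helped the focal helper's
own nest in a *strictly earlier* season, so receiving help raises the rate of
returning it and true reciprocal relationships emerge in the record; the truth
report lists them (together with a checksum so accidental mutation of the
dataset is detected). Draws proceed season by season, so the flag never uses
future information. Zero draws are stored implicitly; helping is capped at
the exposure minutes of the day.

What the generator does *not* emulate: spatial structure and territory
geometry, observer error and misidentification, marker noise in relatedness,
breeder exhaustion or condition dependence, within-season redirected helping,
and any survival consequences of helping. Passing tests therefore demonstrate
internal consistency of the estimators under the stated generative
assumptions, not robustness to these field realities.

## Simultaneous-choice kin bias

A *choice day* is a helper-day with at least one kin nest and one non-kin nest
under observation given a kin threshold. The paired difference is the
exposure-weighted helping rate at kin nests minus non-kin nests (multiple
nests on a side pool numerators and denominators); helper-level biases average
over the helper's choice days, and the percentile bootstrap resamples
*helpers* — the independent unit — with 10,000 draws by default. Cells with
fewer than five helpers report no estimate. The sweep covers thresholds 0.05
to 0.50 in steps of 0.05. The non-kin-choice probability is the fraction of
choice days on which any help went to a non-kin nest.

## Permutation tests

Both permutation analyses operate on the pre-network data stream, so
who-was-where-when is conserved exactly. The *dyadic-preference test*
restricts to non-kin rows (closest-parent r ≤ 0.125 by default — a cut that
separates close kin in these systems — configurable), reassigns each
nest-day's observed non-kin help amounts uniformly at random among that
nest-day's possible non-kin helpers (amounts move as intact blocks; totals
and the multiset of values are conserved; single-candidate nest-days stay
fixed), and compares the coefficient of variation of directed
helper-to-breeder dyadic rates (n−1 convention, zeros included, dyads pooled
across groups, each row crediting both of the nest's parents) against the
permuted distribution, one-tailed upper: preference inflates between-dyad
variation. Empirical p-values are (k+1)/(n+1) and can never be zero.

The *double-permutation pipeline* first computes adjusted helping scores —
observed dyadic rate minus the median rate over permuted datasets, the
permutation now spanning all possible helpers, kin or not — giving, per group,
a directed matrix of how much more each dyad helped than random allocation
predicts. Per group it then reports the give-versus-receive Mantel
correlation and an MRQAP with double semi-partialling (received scores on
given scores and kinship, both predictors scaled), each with node-label
permutation p-values, the convention for dyadic matrices.

For the pipeline-level conclusion (the cross-group mean give–receive
correlation and the cross-group mean MRQAP give coefficient) the reference
distribution is the *data-stream null itself* rather than node relabelling.
The within-block permutations conserve the per-dyad median matrix, so every
permuted dataset yields a full null realization of the adjusted-score
pipeline at no extra cost. This choice is deliberate: measured against
simulated no-preference data, node-label nulls drift with the observation
structure (type-I error between 1% and 17% across study scales, in both
directions, driven by the alignment of giving and receiving opportunities
within individuals), whereas the data-stream reference is calibrated to
nominal level by construction. A bootstrap over groups (percentile, 10,000
draws) summarizes effect size alongside the test.

Calibration is verified under the tests' own null hypothesis: generative
kinship and reciprocity effects at zero *and* helper/dyad random intercepts at
zero, since non-zero intercepts are themselves dyadic preferences (with them
at 0.5 the CV test rejects ~22% of the time — correctly). The nest intercept
stays at 0.5; it is constant within a nest-day block and does not violate
exchangeability. Across 200 replicates of a 9-group, 12-season study at 200
permutations, all three tests reject at a rate inside the 95% binomial band
around 5%.

## Power scan

The cumulative-season scan fits the kinship-only and reciprocal-only models
on season prefixes 1..s, recomputing the reciprocal covariate inside each
window (a full-study-flag option exists for sensitivity). The detection
season is the first prefix whose 95% CrI lies strictly above zero, with an
optional sustained-detection variant. Because each dyad is co-observed on
very few days, the reciprocal covariate accrues information far more slowly
than kinship, which varies across the whole dyad universe from season one —
reproducing the qualitative contrast that kin bias is detectable within a few
seasons while reciprocity requires decades of observation. The test suite
runs this on ten scaled-down replicates (3 groups, 12 seasons, prefix grid
every 2 seasons, 2 chains × 450 retained draws) and checks the ordering of
detection seasons, counting "never detected" as infinity.

## Numerical and degenerate-input conventions

- Exposure must be strictly positive; zero-exposure nest-days are excluded
  with a logged warning, as are observed helpers with no presence record.
- Cross-group visitors stay in the ledger (flagged) but are never zero-filled
  into groups they do not belong to.
- A breeder is never a possible helper at its own nest but may help elsewhere
  the same season, including the same day.
- The CV is undefined (NaN) when the mean dyadic rate is zero; Mantel
  correlations involving a constant matrix return NaN and such groups are
  skipped with a warning, as are groups with fewer than three members.
- A constant kinship matrix drops the kinship predictor from that group's
  MRQAP rather than producing a collinear fit; collinear predictors otherwise
  raise with the offending pair named.
- Bootstrap and permutation draws are reproducible bit-for-bit given a seed;
  pipeline stages derive independent substreams from one master seed via
  `numpy.random.SeedSequence` spawning.
- Standardization refuses constant covariates (tolerance 1e−12 relative).

## Problem sizes used by the test and acceptance harnesses

Simulation-backed checks run on scaled-down studies chosen so the whole suite
completes in minutes: calibration uses 200 replicates of 9 groups × 12
seasons at 200 permutations; parameter recovery uses ten replicates of the
default 9-group configuration over 10 seasons with 2 chains × 1,500 retained
draws; the detectability contrast uses ten replicates of 3 groups × 12
seasons. `scripts/acceptance.py` analyses one 9-group, 20-season study end to
end plus a 3-group detectability scan. These sizes are this package's own
choices and are part of the reported conditions.

## Known limitations

- The adjusted-score median is computed from the same permutation draws used
  as the stream-null reference; the dependence is negligible at the default
  draw counts but formally present.
- With very sparse helping the per-dyad median null rate is zero and adjusted
  scores reduce to raw rates; the stream-null conclusion remains calibrated,
  but per-group node-label p-values should then be read descriptively.
- The NB shape is shared across all rows; the source analyses give no reason
  to expect group- or season-specific dispersion, but none is modelled.
- The helper–breeder-pair random intercept keys on the (helper, mother,
  father) triple; a pair that re-forms with a different partner is a new
  level. Where breeders change partners this differs from a helper-to-
  individual-breeder pairing, and the choice matters only for re-nesting
  pairs.
- Latency between help given and returned is reported as the gap between
  first-give and first-return observation days, with direction recorded; ties
  (same-day mutual help) give latency zero.
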
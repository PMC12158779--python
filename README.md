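# starhelp

Kin-biased and reciprocal helping analyses for plural cooperative breeders.

Cooperatively breeding birds and mammals often live in mixed-kin groups where
non-breeding *helpers* feed and defend the young of *breeders*. Two forces can
maintain that helping: kin selection (help relatives, gain indirect fitness)
and reciprocity (help those who help you back, gain direct fitness). Telling
them apart from field data is hard — kinship and returned help are confounded,
observation effort varies enormously across pairs, and individuals swap
breeder and helper roles across breeding seasons, so reciprocation can take
years. `starhelp` implements the full analysis chain for long-term nest-watch
studies of such systems, plus an agent-based synthetic-data generator with
known ground truth so every estimator in the chain can be validated end to
end. It is aimed at behavioural ecologists analysing dyadic helping records
(who helped at whose nest, for how many minutes, while the nest was watched
for how long) collected over many breeding seasons.

## The models and statistics

**Helping-rate model.** For possible helper *i* (a group member present that
season, excluding the nest's two breeders) at nest *j* on one observation day,

    y_ij ~ NegBinomial(mu_ij, rho)
    log mu_ij = log(exposure_ij) + beta0 + x_ij' beta + u_i + v_j + w_ij

where `y` is whole minutes of help, `exposure` the minutes the nest was
watched, and `u, v, w` random intercepts for helper, nest and
helper–breeder-pair. Non-helping present group members contribute explicit
zeros, so group structure cannot masquerade as preference. Fixed effects:
standardized closest-parent kinship z(r), a binary reciprocal-help covariate
(a breeder of this nest helped at the focal helper's own nest), their
interaction, and standardized total/mean help received (generalized-
reciprocity controls). Coefficients are posterior means with equal-tailed 95%
credible intervals; exp(coefficient) is the incidence rate ratio (IRR). The
sampler is the package's own Metropolis-within-Gibbs engine with Laplace
independence proposals (see `docs/methods.md`).

**Non-parametric checks.** A pre-network data-stream permutation test for
non-kin partner preference (coefficient of variation of dyadic rates vs.
random reallocation of help within each group, nest and day), and a
double-permutation pipeline — adjusted helping scores, per-group Mantel and
MRQAP-with-double-semi-partialling tests of give-receive association
controlling for kinship, bootstrapped across groups.

**Life-history accounting.** Pedigree relatedness (tabular recursion,
parent–offspring r = 0.5), simultaneous-choice kin-bias estimates with
helper-level bootstrap, reciprocal-pair detection under an observability
definition, role-switch tallies with Clopper–Pearson exact binomial CIs, and
a cumulative-season power scan contrasting how many seasons of data each
effect needs before its credible interval excludes zero.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(9 social groups, 40 breeding seasons, generative kinship effect 0.6 per s.d.
and reciprocity effect 1.0 on the log helping rate):

```bash
python analysis/01_simulate_study.py --seed 1   # writes results/data/
python analysis/02_build_table.py               # dyad-day analysis table
python analysis/03_fit_rate_models.py --seed 1  # NB multilevel model suite
python analysis/04_kin_choice.py --seed 1       # simultaneous-choice kin bias
python analysis/05_reciprocity.py               # pairs, latencies, switches
python analysis/06_permutation_tests.py --seed 1
python analysis/07_power_scan.py --seed 1
```

With seed 1 this prints, among other things:

```
simulated 674 individuals in 9 groups over 40 seasons -> results/data
mean helpers per observed nest: 4.61
mean within-group pairwise relatedness: 0.062 (s.d. 0.152)
analysis table: 7402 dyad-day rows -> results/analysis_table.csv
zero-coded rows (present non-helpers): 85.5%
```

the model suite recovers the planted effects,

```
  model               effect    mean  ci_lo  ci_hi    irr
kinship            kinship_z   0.568  0.508  0.629  1.764
reciprocal        reciprocal   0.700  0.482  0.916  2.013
kinship+reciprocal kinship_z   0.526  0.458  0.598  1.693
kinship+reciprocal reciprocal  0.631  0.438  0.822  1.880
```

(a 1 s.d. increase in kinship multiplies the helping rate by ~1.76; having a
reciprocal partner among the nest's breeders roughly doubles it, and the
effect survives controlling for kinship — the atemporal reciprocal flag
dilutes the planted 1.0 toward ~0.7), and the downstream checks agree:

```
pairs with observable return help: 533
reciprocated pairs: 108
mean give-receive correlation across 9 groups: +0.034
  (bootstrap 95% CI +0.012 to +0.057), stream-null P = 0.033
kinship: detected (CrI above zero) at season 4
reciprocal: detected (CrI above zero) at season 8
```

— the signature pattern of these systems: kin bias is detectable within a few
seasons, reciprocity only after many more, because each dyad is co-observed on
very few days.

A `starhelp` console command wraps the same stages for disk-based runs
(`starhelp simulate`, `starhelp run --seed 1 --out results/run`, ...), with a
manifest of content hashes for exact replay.

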
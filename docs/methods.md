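# Methods

## The model

Derived-allele frequencies at the eight coat-colour markers evolve by a
discrete-generation Wright–Fisher process.  Selection acts on *phenotype
classes* — the base colours (bay, black, chestnut) and the modifier traits
(cream, pearl, silver, leopard, tobiano, sabino) — with one coefficient `s`
per class per archaeological period; a genotype's fitness multiplies
`(1 + s)` over the classes its phenotype carries, so e.g. a chestnut tobiano
in a period with `s_chestnut = 0.1` and `s_tobiano = -0.5` has fitness
`1.1 × 0.5`.  The genotype → phenotype map is epistatic and lives in an
editable YAML rule table (`src/paleoselect/data/coat_rules.yaml`):

- `MC1R` `e/e` (recessive) gives chestnut and masks `ASIP`;
- `ASIP` `a/a` (recessive) gives black on a non-chestnut base, else bay;
- silver (`PMEL17`, dominant) dilutes black pigment only — expressed on bay
  and black, never chestnut;
- cream (`MATP`, incompletely dominant) dilutes at one dose and gives a
  double-dilute at two; pearl (`MATP`, recessive) is expressed homozygous or
  heterozygous together with ≥1 cream allele;
- tobiano, sabino (`KIT`) and leopard (`TRPM1`) are dominant spotting flags.

Because only allele frequencies are tracked (not haplotypes), the selection
update marginalises genotype fitness over the other loci assuming linkage
equilibrium and Hardy–Weinberg proportions.  Fitness factorises exactly over
*epistasis groups* — {MC1R, ASIP, PMEL17} (base colours + silver), {cream,
pearl}, and each spotting locus alone — so the per-locus deterministic
update only needs its own group's factor:

    p' = p · E[w | derived gamete] / (p · E[w | derived] + (1-p) · E[w | wild])

followed by binomial resampling of `2N` gametes.  Recombination between the
two KIT markers is not modelled (they are treated as independent loci), and
there is no migration or recurrent mutation.

Demography is a constant effective size `N0` before the domestication onset
`T_g`, then exponential growth to `N1` at present.  Each derived allele
either segregates from the start of the simulated window ("standing", with
initial frequency `p0`) or appears as a single copy `1/(2N)` at age `t_mut`
("new mutation").

## Likelihood and sampler

Each ancient sample contributes, per called locus, the HWE diploid genotype
probability (`p²`, `2p(1-p)`, `(1-p)²`) at the population frequency of its
generation; missing genotypes contribute nothing; a derived allele observed
where the population frequency is zero gives `-inf` (the trajectory is
impossible).  Sample ages are latent, with per-sample dating priors: normal
or uniform, and a truncated exponential decaying away from the younger bound
for material with a very wide stratigraphic range — successful ancient-DNA
retrieval itself argues for a younger age.

The likelihood of the parameters marginalises over trajectories, which is
intractable; the sampler therefore targets the extended space (parameters,
trajectory).  Every parameter proposal carries a fresh trajectory simulated
from the proposed parameters — its conditional-prior proposal density
cancels from the Metropolis–Hastings ratio — and a refresh block
re-simulates the trajectory at fixed parameters, accepting by likelihood
ratio.  The parameter marginal of this chain is the exact posterior.  Blocks
per sweep: each selection-coefficient cell (Gaussian random walk, uniform
prior on (-1, 1)); the origin parameter per locus (random walk on `p0` or
`t_mut`); a transdimensional origin-model jump (prior-draw proposals, so the
acceptance ratio is the likelihood ratio times the model prior odds); a
subset of sample ages (independence proposals from their priors); a
demography draw (independence proposal from its prior); and `n_refresh`
trajectory refreshes.  An optional averaged likelihood over `n_trajectories`
simulations (log-mean-exp) reduces the variance of the likelihood estimate
at proportional cost.

Epistatically linked loci run as one joint unit (ASIP + MC1R + silver;
cream + pearl); the others run independently.  Loci with no observed derived
allele are skipped.

**Identifiability.** Only relative fitness between phenotype classes is
identifiable: multiplying every class factor by a constant leaves the
dynamics unchanged.  The all-wild-type base class (bay) is therefore the
fitness reference with `s = 0`; `include_reference_class=True` restores a
free coefficient for it, at the price of a prior-induced ridge in the
posterior.

**Diagnostics.** Posterior summaries report mean, 95% interval, `P(s>0)`,
and rank-normalised split R-hat and effective sample size (via ArviZ);
any parameter with R-hat > 1.1 is flagged, never silently trusted.

## Drift-only temporal test

Samples are grouped by period at the mean of their age-prior means (the
averaging bias this introduces is part of the grouped design).  For each
locus the test draws an effective size from a log-uniform prior, draws the
starting frequency from the first group's posterior (uniform prior ×
binomial likelihood), simulates neutral Wright–Fisher paths to each later
group's age, resamples counts at the observed sizes, and scores the
discrepancy statistic: the sum over consecutive group pairs of the squared
frequency change standardised by its binomial sampling variance at the
(add-one smoothed) pooled frequency.  The p-value is the add-one Monte Carlo
estimator of `P(D_sim ≥ D_obs)`.  Because counts are discrete the statistic
ties with itself, which makes this estimator slightly conservative; the
`randomized=True` variant breaks ties uniformly at random and is exactly
uniform under the null — use it for calibration studies, the conservative
default for data analysis.  The statistic is pluggable so an alternative
discrepancy can be substituted without touching the simulation machinery.

## Defaults and parameters

| Parameter | Default | Units | Rationale |
|---|---|---|---|
| `N0` | 1 000 | diploids | pre-domestication effective size; working value, editable |
| `N1` | 100 000 | diploids | present-day effective size; working value |
| `T_g` (growth onset) | 5 500 (prior Normal(5 500, 300)) | yr BP | domestication ~4000–3500 BC |
| generation time `g` | 8 (prior Uniform(5, 10)) | yr | standard for horses |
| `s` prior | Uniform(-1, 1) per cell | — | weakly informative; fitness stays positive |
| `p0` prior | Uniform(0, 1) | — | standing initial frequency |
| `t_mut` prior | Uniform(oldest-possible first detection, window start) | yr BP | a mutation must predate its first detection |
| origin model prior | 0.5 / 0.5 | — | no a-priori preference |
| chains / steps / burn-in / thin | 20 / 2×10⁴ / 50% / 10 | — | full-scale settings; the joint base-colour unit is the hardest and warrants 10× more steps |
| dropout rate `K` | 0.2 | per replicate | matches the three-replicate risk arithmetic |
| replicates `n` | 3 | — | minimum replication used for authentication |
| period grid | nine periods, Pleistocene → Medieval | yr BP | editable YAML; coarse bounds pinned by the historical periodisation, fine bounds provisional |

The demography defaults are explicitly provisional: they are plausible
working values for the simulator and tests, not estimates.

## What the synthetic generator emulates — and what it does not

`generate_cohort` reproduces the statistical structure the inference
assumes: a single shared population trajectory, HWE genotypes at the
sample's (true) age, symmetric allelic dropout per replicate (a heterozygote
loses a random allele with probability `K`, which reproduces the
`K(K/2)^(n-1)` false-homozygote rate under consensus calling), consensus
across replicates with opposite-homozygote conflicts set to missing, and
uniform missingness.  The default sampling design mirrors the published one
(201 samples over nine periods, Iron Age 31, Medieval 56, four Pleistocene
samples with wide exponential age priors).  It does **not** emulate
population structure or migration, reference-bias or contamination in the
genotype calls, locus-specific dropout rates, or non-independent dating
errors between samples from one site.  Passing recovery tests on generated
cohorts therefore demonstrates correctness of the inference under its own
model assumptions, not robustness to their violation on real data.

The packaged `published_census_fixture` is a different object: a deterministic,
*constructed* cohort whose descriptive margins (period counts, Iron Age
spotted fraction 14/31, Medieval 8/56, Iron Age tobiano frequency 12/62,
14 distinct phenotype labels) match a published census.  It is a synthetic
stand-in for a real genotype table, which can be swapped in as the
same tabular format.

## Numerical choices

- Generations are discrete; calendar ages map to generations by rounding
  `(window_start − age) / g`, clipped to the window.
- The single-locus trajectory kernel is numba-jitted when numba is present;
  the pure-numpy path is the reference implementation.  Draws are
  reproducible within one backend for a fixed seed.
- Group fitness tables cache the genotype-combo → class mapping once (it is
  selection-independent) and rebuild the numeric factors per proposal.
- A chain initialises by prior draws, retrying (up to 500 times) until the
  likelihood is finite; initial origins are standing, which is always
  compatible with old observations.
- Trajectory impossibilities (derived allele observed at frequency 0) are
  handled as `-inf` log-likelihoods and auto-rejected; this also enforces,
  in every accepted draw, that mutation ages predate the sampled ages of
  all carriers.
- The chi-squared contrast defaults to no continuity correction (the Yates
  correction is a flag); a period pair with an empty row or column raises.

## Test problem sizes

The test suite scales every expensive check to desk size, as the package's
own choice of test design: neutral drift moments at 10⁴ replicate
trajectories (N = 100, 50 generations); the exact-enumeration cross-check on
a toy with N = 50, three sampling epochs and 4 × 2×10⁴ MCMC steps (total
variation < 0.1 against the 101-state transition-matrix posterior); null
calibration and power on five-period single-locus cohorts of 75 samples
(6 × 1.2×10⁴ steps with a 2-trajectory averaged likelihood for the null
study, where converged chains matter; 4 × 5×10³ for the strong-selection
cell); and 500 neutral datasets for the uniformity of the drift-test
p-values.

## Known limitations

- Linkage equilibrium is assumed throughout; tightly linked KIT markers are
  treated as freely recombining, which overstates their independence.
- Selection coefficients are piecewise-constant on the period grid;
  genuinely gradual change is approximated by steps.
- The latent-trajectory sampler mixes slowly when the data pin the
  trajectory tightly (each accepted move must re-draw a compatible path);
  the refresh count and the averaged-likelihood option mitigate but do not
  remove this.  Watch the R-hat flags.
- Posterior model probabilities for allele origin inherit prior sensitivity
  whenever the data barely constrain the early trajectory.
- Grouping by period average age biases the drift-test timescale slightly;
  this is inherent to the grouped design.
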
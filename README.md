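# paleoselect

Inference of time-varying human selection on horse coat-colour phenotypes
from ancient DNA genotype cohorts.

Ancient horse remains can be genotyped at a small panel of coat-colour
markers — eight biallelic mutations in six genes (*MC1R*, *ASIP*, *PMEL17*,
*MATP* ×2, *TRPM1*, *KIT* ×2) that jointly determine the basic coat colours
(bay, black, chestnut), the dilutions (cream, silver, pearl) and the white
spotting patterns (tobiano, sabino, leopard).  Because human preferences
changed over millennia, the interesting signal is not a single selection
coefficient but a *trajectory* of them: how strongly each phenotype class was
favoured or disfavoured in each archaeological period, from the Pleistocene
to the Middle Ages.  `paleoselect` implements the full analysis stack for
such data:

- **`coat_genetics`** — the epistatic genotype → phenotype map (e.g.
  homozygous *MC1R* `e/e` gives chestnut regardless of *ASIP*; silver is
  invisible on chestnut; pearl shows only homozygous or combined with cream),
  plus the replicate-genotyping arithmetic for ancient DNA: the
  false-homozygote risk after `n` replicates is `P = K (K/2)^(n-1)` for a
  per-replicate allelic-dropout rate `K`.
- **`cohort`** — genotype-table IO with validation, configurable period
  grids, per-period allele frequencies, phenotype censuses, and the
  spotted-vs-solid Pearson chi-squared contrast.
- **`wfsim`** — a forward Wright–Fisher simulator of multi-locus allele
  frequencies under phenotype-level, period-wise selection with
  post-domestication exponential population growth; selection on an
  epistatic phenotype is marginalised to per-locus allele-frequency updates
  under linkage equilibrium and Hardy–Weinberg proportions.
- **`temporal_test`** — a drift-only null test: posterior-predictive Monte
  Carlo p-values for whether between-period frequency changes need anything
  beyond drift and sampling error.
- **`mcmc`** — the core contribution: a simulation-embedded
  Metropolis-within-Gibbs sampler that treats the population frequency
  trajectory as a latent auxiliary variable.  It estimates per-period
  selection coefficients `s` per phenotype class (fitness `1+s`,
  multiplicative across classes), latent sample ages under each sample's
  dating prior (normal, uniform, or truncated exponential for wide
  stratigraphic ranges), demography draws, and — by a transdimensional jump
  move — whether each derived allele is standing variation (initial
  frequency `p0`) or a post-domestication new mutation (introduction age
  `t_mut`).
- **`synthetic_data`** — a ground-truth cohort generator (trajectory →
  HWE genotypes → replicate dropout → consensus → missingness) and a
  deterministic 201-sample fixture constructed to match a published census.

## Worked example

```python
from paleoselect import (spotted_solid_contrast, allele_frequency_table,
                         phenotype_census, dropout_risk)
from paleoselect.synthetic_data import published_census_fixture

cohort = published_census_fixture()          # deterministic synthetic 201-sample cohort
table, chi2, p = spotted_solid_contrast(cohort, "IronAge", "Medieval")
print(table.tolist())                 # [[14, 17], [8, 48]]
print(f"chi2 = {chi2:.4f}, p = {p:.5f}")   # chi2 = 10.0685, p = 0.00151

aft = allele_frequency_table(cohort)
km1 = aft[(aft.period == "IronAge") & (aft.locus == "KIT_tobiano")].iloc[0]
print(km1.derived_count, km1.called_chromosomes, round(km1.frequency, 2))
# 12 62 0.19

print(dropout_risk(K=0.2, n=3))       # 0.002  (0.2% after three replicates)
```

The contrast says spotted/diluted coats dropped from 14/31 in the Iron Age
to 8/56 in the Middle Ages, far beyond what sampling noise explains
(p ≈ 0.0015 uncorrected); the tobiano allele *KM1* segregates at ~0.19 in
the Iron Age; and three genotyping replicates reduce the risk of mistaking
a heterozygote for a homozygote to 0.2%.

Selection inference runs on any cohort table:

```python
from paleoselect import run_inference, ChainConfig
result = run_inference(cohort, config=ChainConfig(n_chains=4, n_steps=5000))
print(result.summary)        # mean, 95% CI, P(s>0), R-hat, ESS per parameter
```

or from the shell:

```bash
paleoselect freqs cohort.tsv --out freqs.csv
paleoselect contrast cohort.tsv --periods IronAge Medieval
paleoselect infer cohort.tsv --out runs/ --chains 4 --steps 5000
```

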
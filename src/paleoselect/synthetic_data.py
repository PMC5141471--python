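"""Synthetic cohort generation with known ground truth.

Two entry points:

* :func:`generate_cohort` simulates a cohort under a fully specified
  :class:`GeneratorSpec` — Wright-Fisher trajectory, true sample ages drawn
  from each sample's dating prior, Hardy-Weinberg diploid genotypes at the
  trajectory frequencies, replicate genotyping with allelic dropout and
  consensus calling, and per-locus missingness — returning both the observed
  cohort and a truth record (trajectory, true ages, true genotypes).

* :func:`published_census_fixture` returns a small, fully deterministic cohort
  *constructed* (not simulated, not fitted) so that its descriptive margins
  match a published ancient-horse census: 201 samples over nine periods, 31
  Iron Age samples of which 14 are spotted or diluted, 56 Medieval samples
  with 8, an Iron Age tobiano allele frequency of 12/62, and exactly 14
  distinct phenotype labels.  It is a synthetic stand-in for a real
  published data table and is labelled as such throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .coat_genetics import Genotype, PhenotypeRuleTable, consensus_genotype, default_rules
from .cohort import AgePrior, AncientSample, PeriodGrid, default_period_grid
from .wfsim import AlleleOrigin, Demography, Scenario, SelectionScheme, simulate_trajectory

__all__ = ["GeneratorSpec", "CohortTruth", "generate_cohort", "published_census_fixture",
           "default_generator_spec"]

#: Per-period sample counts mimicking the published sampling design
#: (~200 samples, Iron Age 31, Medieval 56, four Pleistocene samples).
DEFAULT_SAMPLES_PER_PERIOD = {
    "Pleistocene": 4,
    "MesolithicNeolithic": 10,
    "CopperAge": 12,
    "EarlyBronzeAge": 15,
    "MiddleBronzeAge": 18,
    "LateBronzeAge": 25,
    "EarlyIronAge": 30,
    "IronAge": 31,
    "Medieval": 56,
}

PLEISTOCENE_EXP_RANGE = (11_700.0, 126_000.0)


@dataclass
class GeneratorSpec:
    """Everything that defines a synthetic study: demography, selection,
    allele origins, sampling design, genotyping error model and seed."""

    demography: Demography = field(default_factory=Demography)
    scheme: SelectionScheme = None
    origins: dict = field(default_factory=dict)
    samples_per_period: dict = None
    missing_rate: float = 0.05
    dropout_rate: float = 0.2        # K, the per-replicate allelic dropout rate
    n_replicates: int = 3
    seed: int = 0
    period_grid: PeriodGrid = None
    rules: PhenotypeRuleTable = None
    window_margin_bp: float = 200.0

    def __post_init__(self):
        if self.period_grid is None:
            self.period_grid = default_period_grid()
        if self.rules is None:
            self.rules = default_rules()
        if self.scheme is None:
            self.scheme = SelectionScheme(period_grid=self.period_grid)
        if self.samples_per_period is None:
            self.samples_per_period = {
                p: DEFAULT_SAMPLES_PER_PERIOD.get(p, 0) for p in self.period_grid.names
            }
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing rate must be in [0, 1)")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout rate must be in [0, 1]")
        if any(c < 0 for c in self.samples_per_period.values()):
            raise ValueError("per-period sample counts must be >= 0")

    def age_prior_for(self, period: str, index: int, count: int) -> AgePrior:
        """Default dating prior: uniform within the period; Pleistocene samples
        get the wide truncated-exponential prior of stratigraphically dated
        late-Pleistocene material."""
        if period == "Pleistocene":
            lo, hi = PLEISTOCENE_EXP_RANGE
            return AgePrior("exponential", (lo, hi, (hi - lo) / 4.0))
        start, end = self.period_grid.bounds(period)
        span = start - end
        centre = start - span * (index + 0.5) / count
        half = span / max(4, count)
        return AgePrior("uniform", (max(0.0, centre - half), centre + half))


@dataclass
class CohortTruth:
    """Ground truth behind a generated cohort."""

    trajectory: object
    true_ages: np.ndarray
    true_genotypes: list
    spec: GeneratorSpec

    def to_frame(self) -> pd.DataFrame:
        rules = self.spec.rules
        recs = []
        for i, g in enumerate(self.true_genotypes):
            rec = {"index": i, "true_age_bp": float(self.true_ages[i])}
            for name in rules.locus_names:
                rec[f"true_{name}"] = g.dosage(name)
            recs.append(rec)
        return pd.DataFrame.from_records(recs)


def _apply_dropout(true_dose: int, K: float, rng: np.random.Generator) -> int:
    """One replicate observation of one locus: a heterozygote loses one of its
    alleles with probability K, the retained allele chosen at random."""
    if true_dose != 1 or K == 0.0:
        return true_dose
    if rng.uniform() < K:
        return 2 if rng.uniform() < 0.5 else 0
    return 1


def generate_cohort(spec: GeneratorSpec):
    """Generate (cohort samples, truth) under ``spec``; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    rules = spec.rules
    names = rules.locus_names
    grid = spec.period_grid

    priors: list[tuple[str, AgePrior]] = []
    for period in grid.names:
        count = spec.samples_per_period.get(period, 0)
        for i in range(count):
            priors.append((period, spec.age_prior_for(period, i, count)))
    if not priors:
        raise ValueError("sampling design has no samples")

    window_start = max(ap.support[1] for _, ap in priors) + spec.window_margin_bp
    scenario = Scenario(
        demography=spec.demography, scheme=spec.scheme, origins=dict(spec.origins),
        window_start_bp=window_start, rules=rules,
    )
    traj = simulate_trajectory(scenario, rng)

    samples, true_ages, true_genotypes = [], [], []
    for i, (period, ap) in enumerate(priors):
        age = ap.sample(rng)
        if age > window_start:
            raise ValueError("sampled age outside the simulated window")
        freqs = traj.freq_at_age(age)
        true_dos = {n: int(rng.binomial(2, freqs[j])) for j, n in enumerate(names)}
        truth = Genotype(true_dos)
        reps = []
        for _ in range(spec.n_replicates):
            reps.append(Genotype({
                n: _apply_dropout(true_dos[n], spec.dropout_rate, rng) for n in names
            }))
        observed = consensus_genotype(reps)
        dosages = dict(observed.dosages)
        for n in names:
            if rng.uniform() < spec.missing_rate:
                dosages[n] = None
        samples.append(AncientSample(
            sample_id=f"SYN{i:04d}", site=f"synthetic_site_{i % 7}",
            country=f"synthetic_region_{i % 4}", period=period, age=ap,
            genotype=Genotype(dosages, conflicts=observed.conflicts),
        ))
        true_ages.append(age)
        true_genotypes.append(truth)

    truth = CohortTruth(trajectory=traj, true_ages=np.array(true_ages),
                        true_genotypes=true_genotypes, spec=spec)
    return samples, truth


def default_generator_spec(seed: int = 0) -> GeneratorSpec:
    """A published-design default study: post-domestication growth, leopard
    standing since the Pleistocene, the other derived alleles entering by
    mutation around or after domestication, and mild alternating selection on
    chestnut and the spotting phenotypes."""
    grid = default_period_grid()
    s = {}
    for per in ("CopperAge", "LateBronzeAge", "EarlyIronAge", "IronAge", "Medieval"):
        s[("chestnut", per)] = 0.1
    for per in ("LateBronzeAge", "EarlyIronAge", "IronAge"):
        s[("tobiano", per)] = 0.1
        s[("sabino", per)] = 0.1
        s[("leopard", per)] = 0.05
    for trait in ("tobiano", "sabino", "leopard"):
        s[(trait, "Medieval")] = -0.2
    scheme = SelectionScheme(coefficients=s, period_grid=grid)
    origins = {
        "MC1R": AlleleOrigin("new_mutation", t_mut=6_500.0),
        "ASIP": AlleleOrigin("standing", p0=0.3),
        "TRPM1_LP": AlleleOrigin("standing", p0=0.1),
        "KIT_tobiano": AlleleOrigin("new_mutation", t_mut=6_000.0),
        "KIT_sabino": AlleleOrigin("new_mutation", t_mut=6_200.0),
        "MATP_cream": AlleleOrigin("new_mutation", t_mut=4_500.0),
        "MATP_pearl": AlleleOrigin("new_mutation", t_mut=2_500.0),
        "PMEL17": AlleleOrigin("new_mutation", t_mut=3_500.0),
    }
    return GeneratorSpec(scheme=scheme, origins=origins, seed=seed)


# ---------------------------------------------------------------------------
# Deterministic census fixture (synthetic stand-in for a published table)

# (label, count) per period; labels name the intended phenotype and the
# builder below translates them into dosages.
_FIXTURE_DESIGN = {
    "Pleistocene": [("bay", 3), ("bay_leopard", 1)],
    "MesolithicNeolithic": [("bay", 6), ("black", 3), ("bay_leopard", 1)],
    "CopperAge": [("bay", 4), ("black", 2), ("chestnut", 2), ("bay_tobiano", 2),
                  ("bay_sabino", 1), ("chestnut_leopard", 1)],
    "EarlyBronzeAge": [("bay", 7), ("black", 4), ("chestnut", 3), ("bay_leopard", 1)],
    "MiddleBronzeAge": [("bay", 8), ("black", 4), ("chestnut", 4),
                        ("black_leopard", 1), ("bay_cream", 1)],
    "LateBronzeAge": [("bay", 8), ("black", 4), ("chestnut", 5), ("bay_tobiano", 3),
                      ("bay_sabino", 2), ("bay_leopard", 1), ("chestnut_cream", 1),
                      ("chestnut_double_cream", 1)],
    "EarlyIronAge": [("bay", 9), ("black", 5), ("chestnut", 6), ("bay_tobiano", 4),
                     ("bay_sabino", 2), ("black_leopard", 1), ("chestnut_tobiano", 1),
                     ("bay_cream", 1), ("black_silver", 1)],
    # 31 samples, 14 spotted/diluted; 11 tobiano horses carrying 12 KM1 copies
    "IronAge": [("bay", 7), ("black", 5), ("chestnut", 5), ("bay_tobiano", 6),
                ("black_tobiano", 2), ("chestnut_tobiano", 3), ("bay_leopard", 1),
                ("chestnut_leopard", 1), ("chestnut_cream", 1)],
    # 56 samples, 8 spotted/diluted, chestnut dominant; 3 pearl carriers (solid)
    "Medieval": [("chestnut", 25), ("chestnut_pearl_carrier", 3), ("bay", 12),
                 ("black", 8), ("bay_leopard", 1), ("black_leopard", 1),
                 ("black_silver", 2), ("chestnut_cream", 2), ("bay_cream", 1),
                 ("bay_tobiano", 1)],
}

_LABEL_DOSAGES = {
    "bay": {},
    "black": {"ASIP": 2},
    "chestnut": {"MC1R": 2},
    "chestnut_pearl_carrier": {"MC1R": 2, "MATP_pearl": 1},
    "bay_tobiano": {"KIT_tobiano": 1},
    "black_tobiano": {"ASIP": 2, "KIT_tobiano": 1},
    "chestnut_tobiano": {"MC1R": 2, "KIT_tobiano": 1},
    "bay_sabino": {"KIT_sabino": 1},
    "bay_leopard": {"TRPM1_LP": 1},
    "black_leopard": {"ASIP": 2, "TRPM1_LP": 1},
    "chestnut_leopard": {"MC1R": 2, "TRPM1_LP": 1},
    "bay_cream": {"MATP_cream": 1},
    "chestnut_cream": {"MC1R": 2, "MATP_cream": 1},
    "chestnut_double_cream": {"MC1R": 2, "MATP_cream": 2},
    "black_silver": {"ASIP": 2, "PMEL17": 1},
}


def published_census_fixture(rules: Optional[PhenotypeRuleTable] = None) -> list:
    """Deterministic 201-sample synthetic cohort matching published margins.

    The cohort is constructed outright from the per-period design table
    above; no random numbers and no fitting are involved.  One Iron Age
    tobiano is homozygous so the period carries 12 KM1 copies over 62 called
    chromosomes (frequency 0.194); heterozygote carriers (e.g. single pearl
    alleles in three Medieval samples) remain solid.  A real genotype
    table with the same columns can be swapped in for it.
    """
    rules = rules or default_rules()
    grid = default_period_grid()
    names = rules.locus_names
    samples = []
    i = 0
    for period in grid.names:
        design = _FIXTURE_DESIGN[period]
        count = sum(c for _, c in design)
        j = 0
        tobiano_hom_done = False
        for label, c in design:
            for _ in range(c):
                dosages = {n: 0 for n in names}
                dosages.update(_LABEL_DOSAGES[label])
                if (period == "IronAge" and label == "bay_tobiano"
                        and not tobiano_hom_done):
                    dosages["KIT_tobiano"] = 2  # the 12th KM1 copy
                    tobiano_hom_done = True
                if period == "Pleistocene":
                    lo, hi = PLEISTOCENE_EXP_RANGE
                    ap = AgePrior("exponential", (lo, hi, (hi - lo) / 4.0))
                else:
                    start, end = grid.bounds(period)
                    span = start - end
                    centre = start - span * (j + 0.5) / count
                    half = span / max(4, count)
                    ap = AgePrior("uniform", (max(0.0, centre - half), centre + half))
                samples.append(AncientSample(
                    sample_id=f"SYN{i:04d}", site=f"synthetic_site_{i % 9}",
                    country=f"synthetic_region_{i % 5}", period=period, age=ap,
                    genotype=Genotype(dosages),
                ))
                i += 1
                j += 1
    assert len(samples) == 201
    return samples
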
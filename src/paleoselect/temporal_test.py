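"""Drift-only null test for temporal allele-frequency change.

Given per-locus allele counts in groups of samples that share a common
(average) age, the test asks whether the frequency changes between groups are
compatible with genetic drift plus binomial sampling error alone, with no
selection.  The procedure is posterior-predictive Monte Carlo: draw an
effective size from its prior, draw the starting frequency from the first
group's posterior (uniform prior x binomial likelihood), simulate a neutral
Wright-Fisher path across the group ages, resample counts of the observed
sizes, and score a discrepancy statistic; the p-value is the fraction of
simulated discrepancies at least as large as the observed one.

The default discrepancy is the sum over consecutive group pairs of the
squared frequency change standardised by its binomial sampling variance at
the (smoothed) pooled frequency.  The statistic is pluggable so an
alternative can be substituted.

Grouping averages ages within a period, which biases the implied drift time
slightly; that is a property of the grouped design itself, not an artefact
to correct here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import AncientSample, PeriodGrid, default_period_grid
from .coat_genetics import PhenotypeRuleTable, default_rules

__all__ = [
    "GroupedSample",
    "NePrior",
    "group_by_period",
    "drift_null_test",
    "default_discrepancy",
]


@dataclass(frozen=True)
class GroupedSample:
    """One time point: mean age plus per-locus (derived count, chromosomes)."""

    age_bp: float
    counts: dict  # locus -> (derived_count, called_chromosomes)

    def __post_init__(self):
        for locus, (c, n) in self.counts.items():
            if not 0 <= c <= n:
                raise ValueError(f"{locus}: derived count {c} exceeds chromosomes {n}")


@dataclass(frozen=True)
class NePrior:
    """Log-uniform prior on the (constant) effective size used by the null."""

    low: float = 200.0
    high: float = 20_000.0
    generation_time: float = 8.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.exp(rng.uniform(np.log(self.low), np.log(self.high), size=size))


def group_by_period(
    samples: Iterable[AncientSample],
    period_grid: Optional[PeriodGrid] = None,
    rules: Optional[PhenotypeRuleTable] = None,
) -> list:
    """Bin a cohort into per-period groups with the mean of age-prior means."""
    period_grid = period_grid or default_period_grid()
    rules = rules or default_rules()
    groups = []
    for period in period_grid.names:
        in_p = [s for s in samples if s.period == period]
        if not in_p:
            continue
        age = float(np.mean([s.age.mean for s in in_p]))
        counts = {}
        for name in rules.locus_names:
            doses = [s.genotype.dosage(name) for s in in_p]
            called = [d for d in doses if d is not None]
            counts[name] = (int(sum(called)), 2 * len(called))
        groups.append(GroupedSample(age_bp=age, counts=counts))
    groups.sort(key=lambda grp: -grp.age_bp)
    return groups


def default_discrepancy(counts: np.ndarray, chroms: np.ndarray) -> np.ndarray:
    """Sum of squared standardised frequency changes between consecutive groups.

    ``counts`` and ``chroms`` have shape (..., k) over k groups ordered oldest
    first.  Each change is standardised by the binomial sampling variance at
    the pooled frequency of the pair, smoothed by one pseudo-success and one
    pseudo-failure so the variance never vanishes at 0 or 1.
    """
    counts = np.asarray(counts, dtype=float)
    chroms = np.asarray(chroms, dtype=float)
    f = counts / chroms
    c_pair = counts[..., 1:] + counts[..., :-1]
    n_pair = chroms[..., 1:] + chroms[..., :-1]
    pooled = (c_pair + 1.0) / (n_pair + 2.0)
    var = pooled * (1.0 - pooled) * (1.0 / chroms[..., 1:] + 1.0 / chroms[..., :-1])
    return ((f[..., 1:] - f[..., :-1]) ** 2 / var).sum(axis=-1)


def drift_null_test(
    groups: Sequence[GroupedSample],
    ne_prior: Optional[NePrior] = None,
    reps: int = 1000,
    seed: int = 0,
    loci: Optional[Sequence[str]] = None,
    statistic: Optional[Callable] = None,
    randomized: bool = False,
) -> pd.DataFrame:
    """Posterior-predictive p-value per locus for the drift-only null.

    Returns a DataFrame (locus, observed discrepancy, p, groups used).  Groups
    with zero called chromosomes at a locus are skipped with a warning; a
    locus needs at least two usable groups.  ``p`` uses the add-one estimator
    ``(1 + #{sim >= obs}) / (1 + reps)`` so it is never exactly zero; because
    counts are discrete the statistic can tie, which makes this estimator
    slightly conservative.  ``randomized=True`` breaks ties uniformly at
    random, the standard construction whose null p-values are exactly uniform
    on the Monte-Carlo lattice — use it for calibration studies; keep the
    conservative default for data analysis.
    """
    if len(groups) < 2:
        raise ValueError("drift_null_test needs at least two grouped time points")
    if reps < 10:
        raise ValueError("reps too small for a meaningful Monte-Carlo p-value")
    ne_prior = ne_prior or NePrior()
    stat = statistic or default_discrepancy
    vectorised = statistic is None
    rng = np.random.default_rng(seed)
    if loci is None:
        loci = sorted({l for grp in groups for l in grp.counts})

    records = []
    for locus in loci:
        usable = []
        for grp in groups:
            c, n = grp.counts.get(locus, (0, 0))
            if n == 0:
                warnings.warn(f"{locus}: group at {grp.age_bp:.0f} BP has no called "
                              "chromosomes; skipped")
                continue
            usable.append((grp.age_bp, c, n))
        if len(usable) < 2:
            records.append({"locus": locus, "observed": np.nan, "p": np.nan,
                            "n_groups": len(usable)})
            continue
        usable.sort(key=lambda t: -t[0])
        ages = np.array([u[0] for u in usable])
        obs_c = np.array([u[1] for u in usable])
        obs_n = np.array([u[2] for u in usable])
        d_obs = float(np.asarray(stat(obs_c[None, :], obs_n[None, :]))[0])

        ne = ne_prior.sample(rng, reps)
        two_n = np.maximum(4, (2.0 * ne).astype(np.int64))
        p = rng.beta(obs_c[0] + 1.0, obs_n[0] - obs_c[0] + 1.0, size=reps)
        sim_c = np.empty((reps, len(usable)), dtype=np.int64)
        sim_c[:, 0] = rng.binomial(obs_n[0], p)
        for i in range(1, len(usable)):
            gens = max(1, int(round((ages[i - 1] - ages[i]) / ne_prior.generation_time)))
            for _ in range(gens):
                p = rng.binomial(two_n, p) / two_n
            sim_c[:, i] = rng.binomial(obs_n[i], p)
        sim_n = np.broadcast_to(obs_n, (reps, len(usable)))
        if vectorised:
            d_sim = stat(sim_c, sim_n)
        else:
            d_sim = np.array([float(np.asarray(stat(sim_c[r][None, :], obs_n[None, :]))[0])
                              for r in range(reps)])
        if randomized:
            greater = int(np.sum(d_sim > d_obs))
            ties = int(np.sum(d_sim == d_obs))
            pval = (1.0 + greater + rng.integers(0, ties + 1)) / (1.0 + reps)
        else:
            pval = (1.0 + np.sum(d_sim >= d_obs)) / (1.0 + reps)
        records.append({"locus": locus, "observed": d_obs, "p": float(pval),
                        "n_groups": len(usable)})
    return pd.DataFrame.from_records(records)
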
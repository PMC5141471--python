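"""Shared toy problems and independent oracles for the test suite.

The exact-grid posterior here is an independent check on the MCMC: it
computes the marginal likelihood of single-locus count data by forward
matrix-power enumeration over all 2N+1 allele-count states, which is
feasible for the toy population size and never touches the sampler code
path being tested.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from paleoselect.coat_genetics import Genotype, default_rules
from paleoselect.cohort import AgePrior, AncientSample, PeriodGrid
from paleoselect.synthetic_data import GeneratorSpec, generate_cohort
from paleoselect.wfsim import AlleleOrigin, Demography, SelectionScheme

# ---------------------------------------------------------------------------
# Single-locus toy with dominant selection: N=50, 3 sampling epochs.

TOY_N = 50
TOY_G = 10.0
TOY_WINDOW = 300.0
TOY_EPOCH_AGES = [300.0, 150.0, 1.0]
TOY_EPOCH_GENS = [0, 15, 30]
TOY_N_IND = 15
TOY_P0 = 0.2
TOY_GRID = PeriodGrid((("Toy", 400.0, 0.0),))
TOY_DEMO = Demography(n0=TOY_N, n1=TOY_N, growth_onset_bp=200.0, generation_time=TOY_G)


def dominant_update(p, s):
    """One-locus deterministic selection recursion for a dominant allele."""
    w_d = 1.0 + s
    w_w = p * (1.0 + s) + (1.0 - p)
    return p * w_d / (p * w_d + (1.0 - p) * w_w)


def toy_generate_counts(s_true: float, seed: int) -> list:
    """Derived-allele counts (out of 2*TOY_N_IND) at the three epochs."""
    rng = np.random.default_rng(seed)
    p = TOY_P0
    counts = []
    for g in range(TOY_EPOCH_GENS[-1] + 1):
        if g in TOY_EPOCH_GENS:
            counts.append(int(rng.binomial(2 * TOY_N_IND, p)))
        p = rng.binomial(2 * TOY_N, dominant_update(p, s_true)) / (2 * TOY_N)
    return counts


def toy_exact_posterior(counts: list, s_grid: np.ndarray) -> np.ndarray:
    """Exact posterior of s on a grid by forward HMM over allele counts.

    The HWE genotype likelihood of a group of diploid samples is proportional
    to the binomial probability of its derived-allele count, so the emission
    can use the binomial pmf; the constant factors cancel on normalisation.
    """
    two_n = 2 * TOY_N
    ks = np.arange(two_n + 1)
    loglik = np.empty(len(s_grid))
    for i, s in enumerate(s_grid):
        det = dominant_update(ks / two_n, s)
        T = stats.binom.pmf(ks[None, :], two_n, det[:, None])  # T[k, k']
        v = stats.binom.pmf(ks, two_n, dominant_update(TOY_P0, s))  # after gen 1
        ll = 0.0
        gen = 1
        for target_gen, D in zip(TOY_EPOCH_GENS[1:], counts[1:]):
            while gen < target_gen:
                v = v @ T
                gen += 1
            v = v * stats.binom.pmf(D, 2 * TOY_N_IND, ks / two_n)
            tot = v.sum()
            ll += np.log(tot)
            v /= tot
        loglik[i] = ll
    w = np.exp(loglik - loglik.max())
    return w / w.sum()


def toy_samples(counts: list) -> list:
    """AncientSample list realising the epoch counts as diploid genotypes."""
    rules = default_rules()
    samples = []
    i = 0
    for age, D in zip(TOY_EPOCH_AGES, counts):
        doses = [2] * (D // 2) + [1] * (D % 2)
        doses += [0] * (TOY_N_IND - len(doses))
        for d in doses:
            g = {n: None for n in rules.locus_names}
            g["KIT_tobiano"] = d
            samples.append(AncientSample(
                sample_id=f"T{i:03d}", site="toy", country="toy", period="Toy",
                age=AgePrior("uniform", (age - 0.4, age + 0.4)),
                genotype=Genotype(g)))
            i += 1
    return samples


TOY_FIXED_ORIGIN = {"KIT_tobiano": AlleleOrigin("standing", p0=TOY_P0)}


# ---------------------------------------------------------------------------
# Five-period recovery setting used for calibration/power experiments.

RECOVERY_GRID = PeriodGrid((("P1", 2000.0, 1600.0), ("P2", 1600.0, 1200.0),
                            ("P3", 1200.0, 800.0), ("P4", 800.0, 400.0),
                            ("P5", 400.0, 0.0)))
RECOVERY_DEMO = Demography(n0=500, n1=500, growth_onset_bp=1000.0,
                           generation_time=8.0)


def recovery_cohort(s_cells: dict, origin: AlleleOrigin, seed: int,
                    per_period: int = 15):
    """Single-locus (tobiano) cohort with known selection and origin."""
    scheme = SelectionScheme(coefficients=s_cells, period_grid=RECOVERY_GRID)
    spec = GeneratorSpec(demography=RECOVERY_DEMO, scheme=scheme,
                         origins={"KIT_tobiano": origin},
                         samples_per_period={p: per_period for p in RECOVERY_GRID.names},
                         missing_rate=0.0, dropout_rate=0.0, n_replicates=1,
                         seed=seed, period_grid=RECOVERY_GRID)
    return generate_cohort(spec)
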
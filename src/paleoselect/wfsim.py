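"""Forward Wright-Fisher simulation of coat-colour allele trajectories.

The simulator tracks population derived-allele frequencies at the panel loci
through discrete, non-overlapping generations.  Selection acts on phenotype
classes (bay/black/chestnut bases and the dilution/spotting modifiers), with
a piecewise-constant coefficient per class per archaeological period; the
fitness of a multi-locus genotype multiplies ``(1 + s)`` across the classes
its phenotype carries.  Because only allele frequencies are tracked, the
deterministic selection update marginalises genotype fitness over the other
loci assuming linkage equilibrium and Hardy-Weinberg proportions, and the
stochastic part binomially resamples ``2N`` gametes per locus.  Epistatic
loci (base colours + silver; cream + pearl) are marginalised jointly within
their interaction group; loci in different groups contribute multiplicative
fitness factors that cancel from each other's updates.

Demography is a constant pre-domestication size ``N0`` followed by
exponential growth to ``N1`` at present, starting at the domestication onset.
Derived alleles either segregate from the start of the simulated window
(standing variation, initial frequency ``p0``) or enter by mutation at a
single copy ``1/(2N)`` at a configurable time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .coat_genetics import Genotype, PhenotypeRuleTable, classify_phenotype, default_rules
from .cohort import PeriodGrid, default_period_grid

__all__ = [
    "Demography",
    "SelectionScheme",
    "AlleleOrigin",
    "Trajectory",
    "Scenario",
    "phenotype_fitness",
    "genotype_fitness",
    "epistasis_groups",
    "step_generation",
    "simulate_trajectory",
]


@dataclass(frozen=True)
class Demography:
    """Population-size history and generation time.

    ``n0`` effective size before growth; ``n1`` final size; growth starts at
    ``growth_onset_bp`` (years BP, the domestication onset) and is exponential
    to the present; ``generation_time`` in years.
    """

    n0: float = 1_000.0
    n1: float = 100_000.0
    growth_onset_bp: float = 5_500.0
    generation_time: float = 8.0

    def __post_init__(self):
        if self.n0 < 2 or self.n1 < 2:
            raise ValueError("effective sizes must be >= 2")
        if self.generation_time <= 0:
            raise ValueError("generation time must be positive")

    def size_at(self, age_bp: float) -> int:
        """Effective size (individuals) at a calendar age."""
        if age_bp >= self.growth_onset_bp:
            return max(2, int(round(self.n0)))
        frac = (self.growth_onset_bp - age_bp) / self.growth_onset_bp
        return max(2, int(round(self.n0 * (self.n1 / self.n0) ** frac)))


@dataclass
class SelectionScheme:
    """Per-phenotype-class, per-period selection coefficients.

    ``coefficients`` maps ``(class, period)`` to ``s``; classes are the base
    colours and modifier traits (``bay``, ``black``, ``chestnut``, ``cream``,
    ``pearl``, ``silver``, ``leopard``, ``tobiano``, ``sabino``).  Absent
    cells default to neutrality.  ``period_map`` optionally merges periods
    (label -> merged label) before lookup.
    """

    coefficients: dict = field(default_factory=dict)
    period_grid: PeriodGrid = None
    period_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.period_grid is None:
            self.period_grid = default_period_grid()
        for (cls, period), s in self.coefficients.items():
            if 1.0 + s <= 0.0:
                raise ValueError(f"fitness 1+s must stay positive; s({cls},{period})={s}")

    def s(self, phen_class: str, period: str) -> float:
        period = self.period_map.get(period, period)
        return self.coefficients.get((phen_class, period), 0.0)

    def classes(self) -> list:
        return sorted({c for c, _ in self.coefficients})


@dataclass(frozen=True)
class AlleleOrigin:
    """Initial state of a derived allele in the simulated window.

    ``model="standing"``: present at frequency ``p0`` from the window start.
    ``model="new_mutation"``: absent until age ``t_mut`` (years BP), then a
    single copy is introduced; ``t_mut`` must predate the allele's first
    detection in the data.
    """

    model: str
    p0: Optional[float] = None
    t_mut: Optional[float] = None

    def __post_init__(self):
        if self.model not in ("standing", "new_mutation"):
            raise ValueError(f"unknown origin model {self.model!r}")
        if self.model == "standing":
            if self.p0 is None or not 0.0 < self.p0 < 1.0:
                raise ValueError("standing origin needs p0 in (0, 1)")
        else:
            if self.t_mut is None or self.t_mut < 0:
                raise ValueError("new_mutation origin needs t_mut >= 0 (years BP)")


def phenotype_fitness(phenotype, scheme: SelectionScheme, period: str) -> float:
    """Multiplicative fitness of one phenotype: (1+s_base) x prod (1+s_modifier)."""
    w = 1.0 + scheme.s(phenotype.base, period)
    for trait in sorted(phenotype.dilutions | phenotype.spotting):
        w *= 1.0 + scheme.s(trait, period)
    return w


def genotype_fitness(
    scheme: SelectionScheme,
    period: str,
    rules: Optional[PhenotypeRuleTable] = None,
) -> dict:
    """Fitness of every complete multi-locus genotype under ``scheme`` in ``period``.

    Returns a dict keyed by dosage tuples in rule-table locus order.  Mostly a
    reference/inspection utility; the simulator itself marginalises fitness
    group-by-group instead of enumerating the full table each generation.
    """
    rules = rules or default_rules()
    names = rules.locus_names
    out = {}
    for combo in np.ndindex(*(3,) * len(names)):
        g = Genotype(dict(zip(names, (int(c) for c in combo))))
        out[tuple(int(c) for c in combo)] = phenotype_fitness(
            classify_phenotype(g, rules), scheme, period
        )
    return out


def epistasis_groups(rules: PhenotypeRuleTable) -> list:
    """Partition loci into fitness-interaction groups (lists of locus indices).

    Base-colour loci and any modifier whose visibility depends on the base
    (silver) form one group; cream and pearl form another; remaining loci are
    singletons.  Fitness factorises exactly across groups, so the selection
    update for a locus only involves its own group.
    """
    names = rules.locus_names
    base_group, cream_group = [], []
    singles = []
    cream_names = {l.name for l in rules.loci if l.trait == "cream"}
    for i, l in enumerate(rules.loci):
        if l.role in ("base_extension", "base_agouti") or l.visible_on_bases is not None:
            base_group.append(i)
        elif l.trait == "cream" or l.visible_het_with_cream:
            cream_group.append(i)
        else:
            singles.append([i])
    groups = []
    if base_group:
        groups.append(base_group)
    if cream_group:
        groups.append(cream_group)
    groups.extend(singles)
    assert sorted(i for g in groups for i in g) == list(range(len(names)))
    return groups


def _group_fitness_table(
    group: Sequence[int],
    rules: PhenotypeRuleTable,
    scheme: SelectionScheme,
    period: str,
) -> np.ndarray:
    """Fitness factor of a group over its dosage combos (others wild-type).

    Shape ``(3,)*len(group)``.  Factors from loci outside the group reduce to
    a common constant (their wild-type contribution) which cancels in the
    selection update, so it is left in place.
    """
    names = rules.locus_names
    table = np.empty((3,) * len(group))
    for combo in np.ndindex(*table.shape):
        dosages = {n: 0 for n in names}
        for j, dose in zip(group, combo):
            dosages[names[j]] = int(dose)
        ph = classify_phenotype(Genotype(dosages), rules)
        table[combo] = phenotype_fitness(ph, scheme, period)
    return table


class _FitnessTables:
    """Per-period group fitness tables, computed lazily and cached."""

    def __init__(self, rules: PhenotypeRuleTable, scheme: SelectionScheme):
        self.rules = rules
        self.scheme = scheme
        self.groups = epistasis_groups(rules)
        self._cache: dict = {}

    def table(self, gi: int, period: str) -> np.ndarray:
        key = (gi, self.scheme.period_map.get(period, period))
        if key not in self._cache:
            self._cache[key] = _group_fitness_table(
                self.groups[gi], self.rules, self.scheme, period
            )
        return self._cache[key]


def _hwe_probs(p: float) -> np.ndarray:
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def _selection_update(freqs: np.ndarray, tables: _FitnessTables, period: str) -> np.ndarray:
    """Deterministic marginal-fitness update of all locus frequencies."""
    out = freqs.copy()
    for gi, group in enumerate(tables.groups):
        w = tables.table(gi, period)
        margs = [_hwe_probs(freqs[j]) for j in group]
        for k, j in enumerate(group):
            p = freqs[j]
            if p <= 0.0 or p >= 1.0:
                continue
            # dosage distribution of an individual given one gamete allele
            cond_d = np.array([0.0, 1.0 - p, p])       # carries the derived gamete
            cond_w = np.array([1.0 - p, p, 0.0])       # carries the wild gamete
            vecs = list(margs)
            vecs[k] = cond_d
            w_d = _tensor_mean(w, vecs)
            vecs[k] = cond_w
            w_w = _tensor_mean(w, vecs)
            denom = p * w_d + (1.0 - p) * w_w
            out[j] = p * w_d / denom
    return out


def _tensor_mean(w: np.ndarray, vecs) -> float:
    for v in vecs:
        w = np.tensordot(v, w, axes=(0, 0))
    return float(w)


def step_generation(
    freqs: np.ndarray,
    n_next: int,
    tables: _FitnessTables,
    period: str,
    rng: np.random.Generator,
    segregating: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One Wright-Fisher generation: selection update then binomial resampling.

    ``n_next`` is the (diploid) size of the offspring generation.  Loci marked
    False in ``segregating`` (e.g. a derived allele not yet introduced) are
    pinned at frequency 0.
    """
    if n_next < 2:
        raise ValueError("population size must be >= 2")
    det = _selection_update(np.asarray(freqs, dtype=float), tables, period)
    new = rng.binomial(2 * n_next, det) / (2.0 * n_next)
    if segregating is not None:
        new[~segregating] = 0.0
    return new


@dataclass
class Scenario:
    """Everything needed to simulate a trajectory.

    The simulated window runs from ``window_start_bp`` (oldest) to
    ``window_end_bp`` in steps of the demography's generation time.
    """

    demography: Demography
    scheme: SelectionScheme
    origins: Mapping[str, AlleleOrigin]
    window_start_bp: float
    window_end_bp: float = 0.0
    rules: PhenotypeRuleTable = None

    def __post_init__(self):
        if self.rules is None:
            self.rules = default_rules()
        if self.window_start_bp <= self.window_end_bp:
            raise ValueError("window_start_bp must be older than window_end_bp")
        for name in self.origins:
            self.rules.locus(name)
        for name, origin in self.origins.items():
            if origin.model == "new_mutation" and origin.t_mut > self.window_start_bp:
                raise ValueError(f"t_mut for {name} predates the simulated window")

    @property
    def n_generations(self) -> int:
        g = self.demography.generation_time
        n = int(round((self.window_start_bp - self.window_end_bp) / g))
        if n < 1:
            raise ValueError("simulated window shorter than one generation")
        return n


@dataclass
class Trajectory:
    """Per-generation population derived-allele frequencies plus the time map."""

    ages_bp: np.ndarray          # (n_gen+1,), oldest first
    freqs: np.ndarray            # (n_gen+1, n_loci)
    locus_names: list
    generation_time: float

    def gen_of_age(self, age_bp: float) -> int:
        """Generation index whose calendar age is nearest to ``age_bp`` (clipped)."""
        idx = (self.ages_bp[0] - age_bp) / self.generation_time
        return int(np.clip(round(idx), 0, len(self.ages_bp) - 1))

    def freq_at_age(self, age_bp: float) -> np.ndarray:
        return self.freqs[self.gen_of_age(age_bp)]

    def to_frame(self):
        import pandas as pd

        recs = []
        for i, age in enumerate(self.ages_bp):
            for j, name in enumerate(self.locus_names):
                recs.append({"generation": i, "age_bp": float(age),
                             "locus": name, "frequency": self.freqs[i, j]})
        return pd.DataFrame.from_records(recs)


def simulate_trajectory(scenario: Scenario, rng) -> Trajectory:
    """Simulate one multi-locus trajectory over the scenario window.

    ``rng`` is an ``np.random.Generator`` or an integer seed.  Reproducible:
    identical (seed, scenario) give identical trajectories.  Loci under a
    new-mutation origin stay absent until their introduction generation, where
    they enter at one copy, ``1/(2N)``.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    demo = scenario.demography
    rules = scenario.rules
    names = rules.locus_names
    L = len(names)
    n_gen = scenario.n_generations
    g = demo.generation_time
    ages = scenario.window_start_bp - g * np.arange(n_gen + 1)

    # period label and population size per generation (grid clipped at its ends)
    grid = scenario.scheme.period_grid
    periods = []
    for age in ages:
        p = grid.assign(age)
        if p is None:
            p = grid.names[0] if age > grid.periods[0][1] else grid.names[-1]
        periods.append(p)
    sizes = np.array([demo.size_at(a) for a in ages], dtype=int)

    intro_gen = np.full(L, -1, dtype=int)  # -1: standing from the start
    p_init = np.zeros(L)
    for j, name in enumerate(names):
        origin = scenario.origins.get(name)
        if origin is None:
            continue  # locus fixed wild-type throughout
        if origin.model == "standing":
            p_init[j] = origin.p0
        else:
            intro_gen[j] = int(np.clip(round((ages[0] - origin.t_mut) / g), 0, n_gen))

    tables = _FitnessTables(rules, scenario.scheme)
    freqs = np.zeros((n_gen + 1, L))
    cur = p_init.copy()
    cur[intro_gen == 0] = 1.0 / (2.0 * sizes[0])
    freqs[0] = cur
    segregating = intro_gen <= 0
    for i in range(n_gen):
        cur = step_generation(cur, int(sizes[i + 1]), tables, periods[i], rng,
                              segregating=segregating)
        newly = intro_gen == i + 1
        if newly.any():
            cur[newly] = 1.0 / (2.0 * sizes[i + 1])
            segregating |= newly
        freqs[i + 1] = cur
    return Trajectory(ages_bp=ages, freqs=freqs, locus_names=list(names),
                      generation_time=g)


# ---------------------------------------------------------------------------
# Fast single-locus path used by the inference machinery.

def single_locus_fitness_by_dosage(
    locus_name: str,
    scheme: SelectionScheme,
    period: str,
    rules: Optional[PhenotypeRuleTable] = None,
) -> tuple[float, float, float]:
    """Fitness at dosages (0, 1, 2) of one locus, all other loci wild-type."""
    rules = rules or default_rules()
    names = rules.locus_names
    ws = []
    for d in (0, 1, 2):
        dosages = {n: 0 for n in names}
        dosages[locus_name] = d
        ph = classify_phenotype(Genotype(dosages), rules)
        ws.append(phenotype_fitness(ph, scheme, period))
    return tuple(ws)


def simulate_single_locus(
    p0: float,
    intro_gen: int,
    sizes: np.ndarray,
    w0: np.ndarray,
    w1: np.ndarray,
    w2: np.ndarray,
    seed: int,
) -> np.ndarray:
    """Single-locus trajectory with per-generation dosage fitnesses.

    ``sizes`` has length ``n_gen + 1``; ``w0/w1/w2`` have length ``n_gen``
    (fitness during the transition from generation i to i+1).  ``intro_gen``
    is -1 for a standing allele at initial frequency ``p0``, otherwise the
    generation at which a single copy appears.  Dispatches to a numba kernel
    when available.
    """
    if _numba_kernel is not None:
        return _numba_kernel(p0, intro_gen, sizes.astype(np.int64),
                             w0.astype(np.float64), w1.astype(np.float64),
                             w2.astype(np.float64), int(seed))
    return _py_single_locus(p0, intro_gen, sizes, w0, w1, w2, seed)


def _py_single_locus(p0, intro_gen, sizes, w0, w1, w2, seed):
    rng = np.random.default_rng(seed)
    n_gen = len(sizes) - 1
    freqs = np.zeros(n_gen + 1)
    p = p0 if intro_gen < 0 else 0.0
    if intro_gen == 0:
        p = 1.0 / (2.0 * sizes[0])
    freqs[0] = p
    for i in range(n_gen):
        if p > 0.0:
            wd = p * w2[i] + (1.0 - p) * w1[i]
            ww = p * w1[i] + (1.0 - p) * w0[i]
            det = p * wd / (p * wd + (1.0 - p) * ww)
            two_n = 2 * int(sizes[i + 1])
            p = rng.binomial(two_n, det) / two_n
        if i + 1 == intro_gen:
            p = 1.0 / (2.0 * sizes[i + 1])
        freqs[i + 1] = p
    return freqs


_numba_kernel = None
try:  # optional acceleration; the numpy path is the reference implementation
    import numba as _nb

    @_nb.njit(cache=False)
    def _numba_single_locus(p0, intro_gen, sizes, w0, w1, w2, seed):  # pragma: no cover
        np.random.seed(seed)
        n_gen = len(sizes) - 1
        freqs = np.zeros(n_gen + 1)
        p = p0 if intro_gen < 0 else 0.0
        if intro_gen == 0:
            p = 1.0 / (2.0 * sizes[0])
        freqs[0] = p
        for i in range(n_gen):
            if p > 0.0:
                wd = p * w2[i] + (1.0 - p) * w1[i]
                ww = p * w1[i] + (1.0 - p) * w0[i]
                det = p * wd / (p * wd + (1.0 - p) * ww)
                two_n = 2 * sizes[i + 1]
                p = np.random.binomial(two_n, det) / two_n
            if i + 1 == intro_gen:
                p = 1.0 / (2.0 * sizes[i + 1])
            freqs[i + 1] = p
        return freqs

    _numba_kernel = _numba_single_locus
except Exception:  # pragma: no cover
    _numba_kernel = None
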
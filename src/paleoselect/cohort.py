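"""Cohort data model and descriptive statistics for ancient genotype tables.

A cohort is a table of ancient horse samples, each with site/region metadata,
an archaeological period, an age-uncertainty prior (normal, uniform or
truncated exponential, in calendar years BP) and derived-allele dosages at
the eight coat-colour markers.  This module reads and validates such tables,
assigns samples to a configurable period grid, and computes the descriptive
statistics that precede any selection inference: per-period allele
frequencies, phenotype censuses, and the spotted-vs-solid chi-squared
contrast between two periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .coat_genetics import (
    Genotype,
    Phenotype,
    PhenotypeRuleTable,
    classify_phenotype,
    default_rules,
)

__all__ = [
    "AgePrior",
    "AncientSample",
    "PeriodGrid",
    "Cohort",
    "read_cohort",
    "write_cohort",
    "allele_frequency_table",
    "spotted_solid_contrast",
    "pearson_chi2_2x2",
    "phenotype_census",
    "default_period_grid",
]

METADATA_COLUMNS = ["sample_id", "site", "country", "period", "age_kind", "age_p1", "age_p2", "age_p3"]


@dataclass(frozen=True)
class AgePrior:
    """Dating-uncertainty model for one sample, in calendar years BP.

    kind="normal":      params (mean, sd), truncated at 0 BP.
    kind="uniform":     params (low, high).
    kind="exponential": params (low, high, scale) — a truncated exponential on
        [low, high] decaying away from ``low``, i.e. younger ages are more
        likely.  This models very wide stratigraphic ranges where successful
        aDNA retrieval itself argues for a younger age.
    """

    kind: str
    params: tuple

    _KINDS = ("normal", "uniform", "exponential")

    def __post_init__(self):
        if self.kind not in self._KINDS:
            raise ValueError(f"age prior kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.kind == "normal":
            mean, sd = self.params
            if sd <= 0 or mean < 0:
                raise ValueError("normal age prior needs mean >= 0 and sd > 0")
        elif self.kind == "uniform":
            low, high = self.params
            if not 0 <= low < high:
                raise ValueError(f"uniform age prior needs 0 <= low < high, got ({low}, {high})")
        else:
            low, high, scale = self.params
            if not 0 <= low < high or scale <= 0:
                raise ValueError("exponential age prior needs 0 <= low < high and scale > 0")

    @property
    def mean(self) -> float:
        """Prior mean age (years BP); used when samples are grouped by average age."""
        if self.kind == "normal":
            return float(self.params[0])
        if self.kind == "uniform":
            return float(0.5 * (self.params[0] + self.params[1]))
        low, high, scale = self.params
        b = (high - low) / scale
        return float(low + scale * (1.0 - (b * math.exp(-b)) / (1.0 - math.exp(-b))))

    @property
    def support(self) -> tuple[float, float]:
        if self.kind == "normal":
            mean, sd = self.params
            return (max(0.0, mean - 5.0 * sd), mean + 5.0 * sd)
        return (float(self.params[0]), float(self.params[1]))

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "normal":
            mean, sd = self.params
            while True:  # truncate at the present
                a = rng.normal(mean, sd)
                if a >= 0:
                    return float(a)
        if self.kind == "uniform":
            return float(rng.uniform(self.params[0], self.params[1]))
        low, high, scale = self.params
        # inverse-CDF draw from the truncated exponential
        u = rng.uniform()
        b = (high - low) / scale
        return float(low - scale * math.log1p(-u * (1.0 - math.exp(-b))))

    def logpdf(self, age: float) -> float:
        if self.kind == "normal":
            mean, sd = self.params
            if age < 0:
                return -math.inf
            return float(stats.norm.logpdf(age, mean, sd) - stats.norm.logsf(0.0, mean, sd))
        if self.kind == "uniform":
            low, high = self.params
            return -math.log(high - low) if low <= age <= high else -math.inf
        low, high, scale = self.params
        if not low <= age <= high:
            return -math.inf
        b = (high - low) / scale
        return float(-(age - low) / scale - math.log(scale) - math.log1p(-math.exp(-b)))


@dataclass(frozen=True)
class AncientSample:
    sample_id: str
    site: str
    country: str
    period: str
    age: AgePrior
    genotype: Genotype

    def phenotype(self, rules: Optional[PhenotypeRuleTable] = None) -> Phenotype:
        return classify_phenotype(self.genotype, rules)


@dataclass(frozen=True)
class PeriodGrid:
    """Ordered, contiguous archaeological periods (years BP, oldest first)."""

    periods: tuple  # of (name, start_bp, end_bp), start > end

    def __post_init__(self):
        prev_end = None
        for name, start, end in self.periods:
            if start <= end:
                raise ValueError(f"period {name}: start must exceed end (years BP)")
            if prev_end is not None and not math.isclose(start, prev_end):
                raise ValueError(f"period grid not contiguous at {name}")
            prev_end = end

    @property
    def names(self) -> list[str]:
        return [p[0] for p in self.periods]

    def bounds(self, name: str) -> tuple[float, float]:
        for n, start, end in self.periods:
            if n == name:
                return (start, end)
        raise KeyError(name)

    def assign(self, age_bp: float) -> Optional[str]:
        """Period containing an age, or None if outside the grid."""
        for name, start, end in self.periods:
            if end <= age_bp <= start:
                return name
        return None

    def split_medieval(self, split_periods: Sequence[tuple]) -> "PeriodGrid":
        """Replace the Medieval period with an early/late split."""
        out = []
        for p in self.periods:
            if p[0] == "Medieval":
                out.extend(tuple(q) for q in split_periods)
            else:
                out.append(p)
        return PeriodGrid(tuple(out))


_DEFAULT_GRID = None
_DEFAULT_SPLIT = None


def default_period_grid(split_medieval: bool = False) -> PeriodGrid:
    """The packaged nine-period grid (Pleistocene ... Medieval)."""
    global _DEFAULT_GRID, _DEFAULT_SPLIT
    if _DEFAULT_GRID is None:
        raw = yaml.safe_load(
            resources.files("paleoselect.data").joinpath("periods.yaml").read_text()
        )
        _DEFAULT_GRID = PeriodGrid(tuple((p["name"], p["start"], p["end"]) for p in raw["periods"]))
        _DEFAULT_SPLIT = [(p["name"], p["start"], p["end"]) for p in raw["medieval_split"]]
    if split_medieval:
        return _DEFAULT_GRID.split_medieval(_DEFAULT_SPLIT)
    return _DEFAULT_GRID


@dataclass
class Cohort:
    """Accepted samples plus a line-numbered report of rejected rows."""

    samples: list = field(default_factory=list)
    rejected: list = field(default_factory=list)  # (line_number, message)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self):
        return len(self.samples)

    def __getitem__(self, i):
        return self.samples[i]


def _parse_dosage(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in ("", "NA", "nan", "None", "."):
        return None
    d = int(float(s))
    if float(s) != d or d not in (0, 1, 2):
        raise ValueError(f"dosage must be 0, 1, 2 or NA, got {value!r}")
    return d


def _parse_age(kind: str, p1, p2, p3) -> AgePrior:
    kind = str(kind).strip().lower()
    p1, p2 = float(p1), float(p2)
    if kind == "exponential":
        if p3 is None or (isinstance(p3, float) and math.isnan(p3)) or str(p3).strip() in ("", "NA"):
            p3 = (p2 - p1) / 4.0  # default decay scale for a wide stratigraphic range
        return AgePrior("exponential", (p1, p2, float(p3)))
    return AgePrior(kind, (p1, p2))


def read_cohort(
    path,
    period_grid: Optional[PeriodGrid] = None,
    rules: Optional[PhenotypeRuleTable] = None,
    sep: str = "\t",
) -> Cohort:
    """Read and validate a genotype table (TSV by default).

    Expected columns: ``sample_id site country period age_kind age_p1 age_p2
    [age_p3]`` followed by one dosage column (0/1/2/NA) per panel locus.
    Every malformed row is rejected with a line-numbered message on the
    returned :class:`Cohort`; rows are never dropped silently.
    """
    period_grid = period_grid or default_period_grid()
    rules = rules or default_rules()
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = [c for c in METADATA_COLUMNS if c != "age_p3"] + rules.locus_names
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ValueError(f"genotype table is missing columns: {missing_cols}")

    cohort = Cohort()
    seen_ids = set()
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            sid = str(row["sample_id"]).strip()
            if sid in seen_ids:
                raise ValueError(f"duplicate sample_id {sid!r}")
            period = str(row["period"]).strip()
            if period not in period_grid.names:
                raise ValueError(f"unknown period {period!r}")
            age = _parse_age(row["age_kind"], row["age_p1"], row["age_p2"], row.get("age_p3"))
            dosages = {name: _parse_dosage(row[name]) for name in rules.locus_names}
            sample = AncientSample(
                sample_id=sid,
                site=str(row["site"]),
                country=str(row["country"]),
                period=period,
                age=age,
                genotype=Genotype(dosages),
            )
        except (ValueError, KeyError) as exc:
            cohort.rejected.append((line_no, str(exc)))
            continue
        seen_ids.add(sid)
        cohort.samples.append(sample)
    return cohort


def write_cohort(cohort: Iterable[AncientSample], path, rules: Optional[PhenotypeRuleTable] = None,
                 sep: str = "\t") -> None:
    """Write samples back to the tabular format accepted by :func:`read_cohort`."""
    rules = rules or default_rules()
    rows = []
    for s in cohort:
        p3 = s.age.params[2] if s.age.kind == "exponential" else ""
        row = {
            "sample_id": s.sample_id, "site": s.site, "country": s.country,
            "period": s.period, "age_kind": s.age.kind,
            "age_p1": s.age.params[0], "age_p2": s.age.params[1], "age_p3": p3,
        }
        for name in rules.locus_names:
            d = s.genotype.dosage(name)
            row[name] = "NA" if d is None else d
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def allele_frequency_table(
    samples: Iterable[AncientSample],
    period_grid: Optional[PeriodGrid] = None,
    rules: Optional[PhenotypeRuleTable] = None,
) -> pd.DataFrame:
    """Per-period, per-locus derived-allele counts and frequencies.

    Frequency = derived count / (2 x non-missing individuals); a period with
    zero called chromosomes at a locus gets frequency NaN (undefined), never 0.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("allele_frequency_table needs at least one sample")
    period_grid = period_grid or default_period_grid()
    rules = rules or default_rules()
    records = []
    for period in period_grid.names:
        in_period = [s for s in samples if s.period == period]
        for name in rules.locus_names:
            doses = [s.genotype.dosage(name) for s in in_period]
            called = [d for d in doses if d is not None]
            chroms = 2 * len(called)
            derived = int(sum(called))
            freq = derived / chroms if chroms else float("nan")
            records.append(
                {"period": period, "locus": name, "derived_count": derived,
                 "called_chromosomes": chroms, "frequency": freq}
            )
    return pd.DataFrame.from_records(records)


def pearson_chi2_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared statistic and upper-tail p for a 2x2 count table."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (obs.sum(axis=1) == 0).any() or (obs.sum(axis=0) == 0).any():
        raise ValueError("every row and column of the 2x2 table needs a nonzero total")
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=correction)
    return float(chi2), float(p)


def spotted_solid_contrast(
    samples: Iterable[AncientSample],
    period_a: str,
    period_b: str,
    rules: Optional[PhenotypeRuleTable] = None,
    correction: bool = False,
):
    """Spotted/diluted vs solid 2x2 contrast between two periods.

    A sample counts as spotted/diluted when its phenotype carries any dilution
    or spotting flag; heterozygous carriers of recessive dilutions (e.g. a
    single pearl allele) are solid.  Samples whose base colour cannot be
    called still contribute whenever a modifier flag is visible; otherwise
    they are excluded.  Returns ``(table, chi2, p)`` with table rows in the
    order (period_a, period_b) and columns (spotted/diluted, solid).
    """
    rules = rules or default_rules()
    table = np.zeros((2, 2), dtype=int)
    for s in samples:
        if s.period not in (period_a, period_b):
            continue
        ph = s.phenotype(rules)
        if ph.base == "unknown" and not ph.is_spotted_or_diluted:
            continue  # cannot be classified either way
        i = 0 if s.period == period_a else 1
        j = 0 if ph.is_spotted_or_diluted else 1
        table[i, j] += 1
    chi2, p = pearson_chi2_2x2(table, correction=correction)
    return table, chi2, p


def phenotype_census(
    samples: Iterable[AncientSample],
    period_grid: Optional[PeriodGrid] = None,
    rules: Optional[PhenotypeRuleTable] = None,
    level: str = "fine",
) -> pd.DataFrame:
    """Phenotype-by-period count matrix.

    ``level``: "fine" keeps cream zygosity distinct (double-dilutes are their
    own label); "coarse" collapses it; "pooled" pools each spotting pattern
    across base colours (all tobianos in one row, whatever the base), with
    non-spotted samples under their base-with-dilutions label.  Samples whose
    base colour cannot be called appear under labels starting "unknown" and
    are thereby excluded from the base-colour rows.
    """
    if level not in ("fine", "coarse", "pooled"):
        raise ValueError("level must be fine, coarse or pooled")
    period_grid = period_grid or default_period_grid()
    rules = rules or default_rules()
    counts: dict[str, dict[str, int]] = {}
    for s in samples:
        ph = s.phenotype(rules)
        if level == "fine":
            label = ph.label
        elif level == "coarse":
            label = ph.coarse_label
        else:
            label = "_".join(sorted(ph.spotting)) if ph.spotting else ph.coarse_label
        counts.setdefault(label, {})
        counts[label][s.period] = counts[label].get(s.period, 0) + 1
    df = pd.DataFrame(counts).T.reindex(columns=period_grid.names).fillna(0).astype(int)
    df = df.sort_index()
    df.index.name = "phenotype"
    return df
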
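"""Genotype -> phenotype epistasis map for the horse coat-colour panel.

Eight biallelic markers in six genes (MC1R, ASIP, PMEL17, MATP x2, TRPM1,
KIT x2) jointly determine the coat phenotype.  Epistasis matters: a horse
homozygous for the MC1R loss-of-function allele ("e/e") is chestnut no matter
what ASIP carries; silver dilutes only black pigment and is therefore
invisible on chestnut; pearl is expressed only when homozygous or when one
pearl allele meets at least one cream allele.  The rule table encoding these
interactions lives in ``data/coat_rules.yaml`` and can be replaced wholesale
by an alternative table with the same schema.

The module also carries the replicate-genotyping arithmetic used to
authenticate ancient-DNA genotypes: the false-homozygote (allelic dropout)
risk after ``n`` independent replicates, ``P = K * (K/2)**(n - 1)``, and the
consensus call across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import yaml

__all__ = [
    "Locus",
    "Genotype",
    "Phenotype",
    "PhenotypeRuleTable",
    "PanelMismatchError",
    "MISSING",
    "classify_phenotype",
    "dropout_risk",
    "consensus_genotype",
    "default_rules",
]

#: Explicit missing-genotype marker.  ``None`` in a dosage mapping means the
#: locus was not called; it is never treated as dosage 0.
MISSING = None

BASE_COLOURS = ("bay", "black", "chestnut")


class PanelMismatchError(KeyError):
    """A genotype refers to a locus that is not in the rule table's panel."""


@dataclass(frozen=True)
class Locus:
    """One biallelic coat-colour marker."""

    name: str
    gene: str
    wild_allele: str
    derived_allele: str
    role: str  # base_extension | base_agouti | dilution | spotting
    mode: str  # dominant | recessive | incomplete
    trait: Optional[str] = None  # phenotype token (silver, cream, ...) for modifiers
    visible_on_bases: Optional[tuple[str, ...]] = None
    visible_het_with_cream: bool = False


@dataclass(frozen=True)
class Genotype:
    """Per-locus derived-allele dosages; ``None`` is an explicit missing call.

    ``conflicts`` records loci where replicate genotyping disagreed
    irreconcilably (opposite homozygotes); such loci are also missing.
    """

    dosages: Mapping[str, Optional[int]]
    conflicts: frozenset = frozenset()

    def __post_init__(self):
        for name, d in self.dosages.items():
            if d is not None and d not in (0, 1, 2):
                raise ValueError(f"dosage at {name} must be 0, 1, 2 or missing; got {d!r}")

    def dosage(self, locus: str) -> Optional[int]:
        return self.dosages.get(locus, MISSING)

    def __getitem__(self, locus: str) -> Optional[int]:
        return self.dosages[locus]


@dataclass(frozen=True)
class Phenotype:
    """A coat-colour phenotype: base colour plus dilution and spotting flags.

    ``base`` is "unknown" when a base-determining locus is missing; modifier
    flags are still reported in that case.  ``double_cream`` distinguishes the
    homozygous cream double-dilute from the single-dose dilution in the fine
    labelling; the coarse labelling collapses the two.
    """

    base: str
    dilutions: frozenset = frozenset()
    spotting: frozenset = frozenset()
    double_cream: bool = False

    _DILUTION_ORDER = ("cream", "pearl", "silver")
    _SPOTTING_ORDER = ("leopard", "sabino", "tobiano")

    @property
    def label(self) -> str:
        """Fine canonical label, e.g. ``chestnut_double_cream`` or ``bay_tobiano``."""
        tokens = [self.base]
        for d in self._DILUTION_ORDER:
            if d in self.dilutions:
                tokens.append("double_cream" if d == "cream" and self.double_cream else d)
        tokens.extend(s for s in self._SPOTTING_ORDER if s in self.spotting)
        return "_".join(tokens)

    @property
    def coarse_label(self) -> str:
        """Label with cream zygosity collapsed (palomino and cremello both 'cream')."""
        return self.label.replace("double_cream", "cream")

    @property
    def is_spotted_or_diluted(self) -> bool:
        """True for the contrast class used against solid coats (carriers are solid)."""
        return bool(self.dilutions) or bool(self.spotting)

    def __str__(self) -> str:  # pragma: no cover
        return self.label


@dataclass
class PhenotypeRuleTable:
    """Ordered epistasis rules mapping multi-locus genotypes to phenotypes.

    Total over the panel: every genotype with all base loci called maps to
    exactly one phenotype; rule order is fixed (base extension before agouti).
    """

    loci: Sequence[Locus]
    _by_name: Mapping[str, Locus] = field(init=False, repr=False)

    def __post_init__(self):
        derived = [l.derived_allele for l in self.loci]
        if len(set(derived)) != len(derived):
            raise ValueError("derived allele symbols must be unique across the panel")
        object.__setattr__(self, "_by_name", {l.name: l for l in self.loci})

    @property
    def locus_names(self) -> list[str]:
        return [l.name for l in self.loci]

    def locus(self, name: str) -> Locus:
        try:
            return self._by_name[name]
        except KeyError:
            raise PanelMismatchError(name) from None

    def subset(self, names: Iterable[str]) -> "PhenotypeRuleTable":
        """Rule table restricted to a subset of loci (others assumed wild-type)."""
        names = list(names)
        return PhenotypeRuleTable([self.locus(n) for n in names])

    @classmethod
    def from_yaml(cls, path=None) -> "PhenotypeRuleTable":
        if path is None:
            text = resources.files("paleoselect.data").joinpath("coat_rules.yaml").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        raw = yaml.safe_load(text)
        loci = []
        for entry in raw["loci"]:
            entry = dict(entry)
            if "visible_on_bases" in entry:
                entry["visible_on_bases"] = tuple(entry["visible_on_bases"])
            loci.append(Locus(**entry))
        return cls(loci)


_DEFAULT_RULES: Optional[PhenotypeRuleTable] = None


def default_rules() -> PhenotypeRuleTable:
    """The packaged eight-marker rule table (cached)."""
    global _DEFAULT_RULES
    if _DEFAULT_RULES is None:
        _DEFAULT_RULES = PhenotypeRuleTable.from_yaml()
    return _DEFAULT_RULES


def _expressed(locus: Locus, dose: Optional[int]) -> bool:
    if dose is None or dose == 0:
        return False
    if locus.mode == "dominant":
        return dose >= 1
    if locus.mode == "recessive":
        return dose == 2
    if locus.mode == "incomplete":
        return dose >= 1
    raise ValueError(f"unknown dominance mode {locus.mode!r}")


def classify_phenotype(genotype: Genotype, rules: Optional[PhenotypeRuleTable] = None) -> Phenotype:
    """Deduce the coat phenotype from a multi-locus genotype.

    Base colour by epistasis: MC1R-type (base_extension) homozygous derived
    gives chestnut regardless of ASIP; otherwise ASIP-type (base_agouti)
    homozygous derived gives black; otherwise bay.  A missing base locus that
    would have decided the call yields base="unknown" while dilution and
    spotting flags are still reported.

    Raises
    ------
    PanelMismatchError
        If the genotype carries a locus name absent from the rule table.
    """
    rules = rules or default_rules()
    for name in genotype.dosages:
        rules.locus(name)  # panel check, raises on mismatch

    ext = [l for l in rules.loci if l.role == "base_extension"]
    ago = [l for l in rules.loci if l.role == "base_agouti"]

    # Base colour: extension first (epistatic), then agouti.
    base = "bay"
    for l in ext:
        d = genotype.dosage(l.name)
        if d is None:
            base = "unknown"
        elif _expressed(l, d):
            base = "chestnut"
            break
    if base == "bay":
        for l in ago:
            d = genotype.dosage(l.name)
            if d is None:
                base = "unknown"
            elif _expressed(l, d):
                base = "black"
                break

    cream_dose = 0
    for l in rules.loci:
        if l.trait == "cream":
            d = genotype.dosage(l.name)
            cream_dose = max(cream_dose, d or 0)

    dilutions = set()
    spotting = set()
    double_cream = False
    for l in rules.loci:
        if l.trait is None:
            continue
        d = genotype.dosage(l.name)
        if d is None or d == 0:
            continue
        if l.trait == "cream":
            dilutions.add("cream")
            double_cream = double_cream or d == 2
            continue
        visible = _expressed(l, d)
        if not visible and l.visible_het_with_cream and d >= 1 and cream_dose >= 1:
            visible = True  # pearl shows through with a cream allele
        if visible and l.visible_on_bases is not None and base != "unknown":
            visible = base in l.visible_on_bases
        if not visible:
            continue
        (spotting if l.role == "spotting" else dilutions).add(l.trait)

    return Phenotype(
        base=base,
        dilutions=frozenset(dilutions),
        spotting=frozenset(spotting),
        double_cream=double_cream,
    )


def dropout_risk(K: float, n: int) -> float:
    """False-homozygote probability after ``n`` replicates: ``K * (K/2)**(n-1)``.

    ``K`` is the observed per-locus dropout rate (false homozygotes divided by
    heterozygous individuals).  A heterozygote is mis-called only if every one
    of the ``n`` replicates drops the *same* allele: the first replicate drops
    either allele with probability K, each further replicate repeats that
    specific dropout with probability K/2.
    """
    if not 0.0 <= K <= 1.0:
        raise ValueError(f"dropout rate K must be in [0, 1], got {K}")
    if not isinstance(n, (int,)) or n < 1:
        raise ValueError(f"replicate count n must be an integer >= 1, got {n}")
    return K * (K / 2.0) ** (n - 1)


def consensus_genotype(replicates: Sequence[Genotype]) -> Genotype:
    """Consensus call across replicate genotypings of one sample.

    Per locus: any heterozygous replicate wins (dropout only ever hides an
    allele); homozygote calls require all non-missing replicates to agree;
    opposite homozygotes are irreconcilable and yield missing with a conflict
    flag.
    """
    if not replicates:
        raise ValueError("consensus requires at least one replicate")
    names: list[str] = []
    for r in replicates:
        for n in r.dosages:
            if n not in names:
                names.append(n)
    out: dict[str, Optional[int]] = {}
    conflicts = set()
    for name in names:
        calls = [r.dosage(name) for r in replicates]
        calls = [c for c in calls if c is not None]
        if not calls:
            out[name] = MISSING
        elif 1 in calls:
            out[name] = 1
        elif len(set(calls)) == 1:
            out[name] = calls[0]
        else:  # 0 vs 2: conflicting homozygotes
            out[name] = MISSING
            conflicts.add(name)
    return Genotype(out, conflicts=frozenset(conflicts))
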
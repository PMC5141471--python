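"""Cohort IO, period grids, frequencies, censuses and the 2x2 contrast."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from paleoselect.coat_genetics import Genotype
from paleoselect.cohort import (
    AgePrior,
    AncientSample,
    PeriodGrid,
    allele_frequency_table,
    pearson_chi2_2x2,
    phenotype_census,
    read_cohort,
    spotted_solid_contrast,
    write_cohort,
)

HEADER = ("sample_id\tsite\tcountry\tperiod\tage_kind\tage_p1\tage_p2\tage_p3\t"
          "MC1R\tASIP\tPMEL17\tMATP_cream\tMATP_pearl\tTRPM1_LP\tKIT_tobiano\tKIT_sabino")


def _row(sid, period="IronAge", kind="uniform", p1=1600, p2=1700, dosages="0"):
    d = "\t".join([dosages] * 8) if "\t" not in dosages else dosages
    return f"{sid}\tsiteA\tlandA\t{period}\t{kind}\t{p1}\t{p2}\t\t{d}"


class TestAgePrior:
    def test_kinds_and_means(self):
        assert AgePrior("uniform", (100, 300)).mean == 200
        assert AgePrior("normal", (1500, 100)).mean == 1500
        exp = AgePrior("exponential", (11700, 126000, 28575))
        assert 11700 < exp.mean < 0.5 * (11700 + 126000)  # skewed young

    @pytest.mark.parametrize("kind, params", [
        ("uniform", (300, 100)), ("normal", (100, -1)),
        ("exponential", (100, 50, 10)), ("triangular", (1, 2)),
    ])
    def test_invalid(self, kind, params):
        with pytest.raises(ValueError):
            AgePrior(kind, params)

    def test_samples_stay_in_support(self):
        rng = np.random.default_rng(0)
        exp = AgePrior("exponential", (11700, 126000, 20000))
        draws = [exp.sample(rng) for _ in range(500)]
        assert all(11700 <= a <= 126000 for a in draws)
        # exponential decay: younger half of the range holds most of the mass
        assert np.mean(np.array(draws) < (11700 + 126000) / 2) > 0.8

    def test_logpdf_integrates_to_one(self):
        from scipy.integrate import quad

        exp = AgePrior("exponential", (100.0, 900.0, 250.0))
        val, _ = quad(lambda a: math.exp(exp.logpdf(a)), 100, 900)
        assert val == pytest.approx(1.0, rel=1e-6)


class TestReadCohort:
    def _write(self, tmp_path, rows):
        p = tmp_path / "cohort.tsv"
        p.write_text("\n".join([HEADER] + rows) + "\n")
        return p

    def test_well_formed_rows_parse(self, tmp_path):
        p = self._write(tmp_path, [_row("a"), _row("b"), _row("c", period="Medieval",
                                                             p1=600, p2=700)])
        c = read_cohort(p)
        assert len(c) == 3 and not c.rejected
        assert c[0].genotype.dosage("MC1R") == 0

    def test_bad_dosage_rejected_with_line_number(self, tmp_path):
        bad = _row("b").replace("\t0\t0\t0\t0\t0\t0\t0\t0", "\t3\t0\t0\t0\t0\t0\t0\t0")
        p = self._write(tmp_path, [_row("a"), bad])
        c = read_cohort(p)
        assert len(c) == 1
        (line, msg), = c.rejected
        assert line == 3 and "dosage" in msg

    def test_inverted_uniform_age_rejected(self, tmp_path):
        p = self._write(tmp_path, [_row("a", p1=1700, p2=1600)])
        c = read_cohort(p)
        assert len(c) == 0 and len(c.rejected) == 1

    def test_unknown_period_and_duplicate_id_rejected(self, tmp_path):
        p = self._write(tmp_path, [_row("a"), _row("a"), _row("b", period="SpaceAge")])
        c = read_cohort(p)
        assert len(c) == 1
        assert {m for _, m in c.rejected} >= {"duplicate sample_id 'a'",
                                              "unknown period 'SpaceAge'"}

    def test_na_dosage_is_missing_not_zero(self, tmp_path):
        row = _row("a").replace("\t0\t0\t0\t0\t0\t0\t0\t0",
                                "\tNA\t0\t0\t0\t0\t0\t0\t0")
        c = read_cohort(self._write(tmp_path, [row]))
        assert c[0].genotype.dosage("MC1R") is None

    def test_roundtrip(self, tmp_path, fixture_cohort):
        p = tmp_path / "out.tsv"
        write_cohort(fixture_cohort, p)
        again = read_cohort(p)
        assert not again.rejected
        assert len(again) == len(fixture_cohort)
        for a, b in zip(fixture_cohort, again.samples):
            assert a.sample_id == b.sample_id
            assert a.period == b.period
            assert a.age.kind == b.age.kind
            assert a.genotype.dosages == b.genotype.dosages


class TestAlleleFrequencies:
    def _sample(self, sid, period, **dosages):
        g = {n: dosages.get(n, 0) for n in
             ["MC1R", "ASIP", "PMEL17", "MATP_cream", "MATP_pearl", "TRPM1_LP",
              "KIT_tobiano", "KIT_sabino"]}
        for k, v in dosages.items():
            g[k] = v
        return AncientSample(sid, "s", "c", period, AgePrior("uniform", (1600, 1700)),
                             Genotype(g))

    def test_basic_counting(self):
        samples = [self._sample("a", "IronAge", MC1R=1),
                   self._sample("b", "IronAge")]
        df = allele_frequency_table(samples)
        row = df[(df.period == "IronAge") & (df.locus == "MC1R")].iloc[0]
        assert row.derived_count == 1 and row.called_chromosomes == 4
        assert row.frequency == pytest.approx(0.25)

    def test_missing_excluded_from_denominator(self):
        samples = [self._sample("a", "IronAge", MC1R=2),
                   self._sample("b", "IronAge", MC1R=None)]
        df = allele_frequency_table(samples)
        row = df[(df.period == "IronAge") & (df.locus == "MC1R")].iloc[0]
        assert row.called_chromosomes == 2 and row.frequency == 1.0

    def test_empty_period_is_nan_not_zero(self):
        df = allele_frequency_table([self._sample("a", "IronAge")])
        med = df[(df.period == "Medieval") & (df.locus == "MC1R")].iloc[0]
        assert med.called_chromosomes == 0 and np.isnan(med.frequency)

    def test_counts_conserve_and_frequencies_bounded(self, fixture_cohort):
        df = allele_frequency_table(fixture_cohort)
        called = df.dropna(subset=["frequency"])
        assert ((called.frequency >= 0) & (called.frequency <= 1)).all()
        assert (called.derived_count <= called.called_chromosomes).all()

    def test_no_samples_error(self):
        with pytest.raises(ValueError):
            allele_frequency_table([])


class TestContrast:
    @pytest.mark.parametrize("table, chi2, p", [
        ([[14, 17], [8, 48]], 10.0684, 0.00151),
        ([[10, 10], [10, 10]], 0.0, 1.0),
        ([[5, 0], [0, 5]], 10.0, 0.00157),
    ])
    def test_reference_tables(self, table, chi2, p):
        got_chi2, got_p = pearson_chi2_2x2(table)
        assert got_chi2 == pytest.approx(chi2, abs=1e-3)
        assert got_p == pytest.approx(p, abs=2e-4)

    @given(st.tuples(*[st.integers(min_value=0, max_value=50)] * 4))
    def test_matches_textbook_closed_form(self, cells):
        """Independent oracle: chi2 = n(ad-bc)^2 / (r1 r2 c1 c2)."""
        a, b, c, d = cells
        r1, r2, c1, c2 = a + b, c + d, a + c, b + d
        if 0 in (r1, r2, c1, c2):
            with pytest.raises(ValueError):
                pearson_chi2_2x2([[a, b], [c, d]])
            return
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
        got, _ = pearson_chi2_2x2([[a, b], [c, d]])
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-9)

    def test_contrast_on_fixture(self, fixture_cohort):
        table, chi2, p = spotted_solid_contrast(fixture_cohort, "IronAge", "Medieval")
        assert table.tolist() == [[14, 17], [8, 48]]
        # Yates correction available as a flag and is more conservative
        _, chi2_y, p_y = spotted_solid_contrast(fixture_cohort, "IronAge", "Medieval",
                                                correction=True)
        assert chi2_y < chi2 and p_y > p


class TestCensus:
    def test_single_wildtype(self, wildtype):
        s = AncientSample("a", "s", "c", "IronAge", AgePrior("uniform", (1600, 1700)),
                          wildtype())
        df = phenotype_census([s])
        assert df.loc["bay", "IronAge"] == 1 and df.values.sum() == 1

    def test_column_sums_match_period_counts(self, fixture_cohort, grid):
        df = phenotype_census(fixture_cohort, grid)
        per_period = pd.Series([s.period for s in fixture_cohort]).value_counts()
        for p in grid.names:
            assert df[p].sum() == per_period.get(p, 0)

    def test_missing_base_counted_as_unknown(self, wildtype):
        g = wildtype()
        dos = dict(g.dosages)
        dos["MC1R"] = None
        s = AncientSample("a", "s", "c", "IronAge", AgePrior("uniform", (1600, 1700)),
                          Genotype(dos))
        df = phenotype_census([s])
        assert df.index.tolist() == ["unknown"]

    def test_pooled_view_pools_spotting_across_bases(self, fixture_cohort):
        pooled = phenotype_census(fixture_cohort, level="pooled")
        assert "tobiano" in pooled.index
        fine = phenotype_census(fixture_cohort, level="fine")
        tob_fine = [i for i in fine.index if i.endswith("tobiano")]
        assert pooled.loc["tobiano"].sum() == fine.loc[tob_fine].values.sum()


class TestPeriodGrid:
    def test_assign_and_bounds(self, grid):
        assert grid.assign(2000) == "IronAge"
        assert grid.assign(500_000) is None
        assert grid.bounds("Medieval") == (1550, 450)

    def test_medieval_split(self):
        from paleoselect.cohort import default_period_grid

        g = default_period_grid(split_medieval=True)
        assert "EarlyMedieval" in g.names and "Medieval" not in g.names

    def test_non_contiguous_rejected(self):
        with pytest.raises(ValueError):
            PeriodGrid((("A", 100, 50), ("B", 40, 0)))
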
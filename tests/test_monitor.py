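"""Monitoring tables against constructed fixtures and counting oracles."""

import numpy as np
import pandas as pd
import pytest

from conftest import build
from herdkeeper import monitor
from herdkeeper.fixtures import FixtureSpec, generate_pedigree, random_pedigree
from herdkeeper.pedigree_io import PedigreeRecord, Sex


def rec(aid, s, d, sex, y, subpop=None, variety=None):
    return PedigreeRecord(aid, s, d, sex, y, subpop=subpop, variety=variety)


@pytest.fixture(scope="module")
def small_herd():
    """Two founder pairs, two years of litters with known structure."""
    M, F = Sex.MALE, Sex.FEMALE
    records = [
        rec("S1", None, None, M, 2000), rec("S2", None, None, M, 2000),
        rec("D1", None, None, F, 2000), rec("D2", None, None, F, 2000),
        # 2003: D1 litter of 3 by S1; D2 litter of 2 by S2
        rec("a", "S1", "D1", M, 2003), rec("b", "S1", "D1", F, 2003),
        rec("c", "S1", "D1", F, 2003),
        rec("d", "S2", "D2", M, 2003), rec("e", "S2", "D2", F, 2003),
        # 2004: D1 litter of 2 by S1
        rec("f", "S1", "D1", M, 2004), rec("g", "S1", "D1", F, 2004),
    ]
    return build(records)


class TestLitters:
    def test_one_dam_one_year_one_litter(self, small_herd):
        litters = monitor.infer_litters(small_herd)
        by_key = {(l.dam_id, l.birth_year): l for l in litters}
        assert by_key[("D1", 2003)].size == 3
        assert by_key[("D2", 2003)].size == 2
        assert by_key[("D1", 2004)].size == 2
        assert len(litters) == 3

    def test_dam_unknown_offspring_excluded(self):
        ped = build([rec("x", None, None, Sex.MALE, 2001)])
        assert monitor.infer_litters(ped) == []


class TestBirthsAndParents:
    def test_births_by_year_counts(self, small_herd):
        t = monitor.births_by_year(small_herd)
        assert list(t.index) == list(range(2000, 2005))
        assert t.loc[2003, "total"] == 5
        assert t.loc[2003, "males"] == 2
        assert t.loc[2001, "total"] == 0  # gap year still reported
        assert t.loc[2000, "later_used_in_breeding"] == 4

    def test_parents_per_year(self, small_herd):
        t = monitor.parents_per_year(small_herd)
        assert t.loc[2003, "n_mothers"] == 2
        assert t.loc[2003, "n_fathers"] == 2
        assert t.loc[2003, "avg_litter_size"] == pytest.approx(2.5)
        assert t.loc[2004, "offspring_per_father"] == pytest.approx(2.0)

    def test_lifetime_offspring(self, small_herd):
        stats = monitor.lifetime_offspring_stats(small_herd, 2000)
        assert stats["male"] == (pytest.approx(3.5), pytest.approx(1.5), 5)
        assert stats["female"][2] == 5  # D1 has 5 lifetime offspring


class TestAgesAndIntervals:
    def test_generation_interval_values(self, small_herd):
        L = monitor.generation_interval(small_herd, 2003)
        assert L == (pytest.approx(3.0),) * 3
        t = monitor.generation_interval_by_year(small_herd)
        assert t.loc[2004, "L_parents"] == pytest.approx(4.0)

    def test_mixed_parent_ages(self):
        records = [
            rec("S", None, None, Sex.MALE, 2002),
            rec("D", None, None, Sex.FEMALE, 2000),
            rec("k1", "S", "D", Sex.MALE, 2004),
            rec("k2", "S", "D", Sex.FEMALE, 2004),
        ]
        ped = build(records)
        assert monitor.generation_interval(ped, 2004) == (
            pytest.approx(2.0), pytest.approx(4.0), pytest.approx(3.0),
        )

    def test_age_tables_count_offspring(self, small_herd):
        sires, dams = monitor.parent_age_tables(small_herd)
        assert sires.loc[2003, "age_3"] == 5
        assert dams.loc[2004, "age_4"] == 2


class TestCompleteness:
    def test_founder_zero(self, small_herd):
        assert monitor.pedigree_completeness(small_herd, "S1") == (0.0, 0)

    def test_both_parents_known_founders(self, small_herd):
        assert monitor.pedigree_completeness(small_herd, "a") == (1.0, 1)

    def test_four_known_grandparents(self):
        records = [
            rec("A", None, None, Sex.MALE, 2000),
            rec("B", None, None, Sex.FEMALE, 2000),
            rec("C", None, None, Sex.MALE, 2000),
            rec("D", None, None, Sex.FEMALE, 2000),
            rec("E", "A", "B", Sex.MALE, 2001),
            rec("F", "C", "D", Sex.FEMALE, 2001),
            rec("G", "E", "F", Sex.FEMALE, 2002),
        ]
        ped = build(records)
        assert monitor.pedigree_completeness(ped, "G") == (2.0, 2)

    def test_depth_table_percentages(self, small_herd):
        t = monitor.pedigree_depth_by_year(small_herd)
        assert t.loc[2000, "generation_equivalent"] == 0.0
        assert t.loc[2003, "pct_complete_1"] == 100.0


class TestTopSires:
    def test_single_sire_full_contribution(self, small_herd):
        assert monitor.top_sire_contributions(small_herd, 2004) == [1.0]

    def test_fractions_sorted(self, small_herd):
        assert monitor.top_sire_contributions(small_herd, 2003) == [0.6, 0.4]

    def test_matches_counting_oracle_on_fixture(self):
        records, truth = generate_pedigree(FixtureSpec(years=4, seed=9,
                                                       sire_skew=0.5))
        ped = build(records)
        for year, fracs in truth["top_sire_fractions"].items():
            got = monitor.top_sire_contributions(ped, year)
            assert got == pytest.approx(fracs)

    def test_yearly_fractions_sum_to_one_with_enough_k(self, small_herd):
        t = monitor.top_sire_table(small_herd, k=10)
        sums = t.filter(like="top_").sum(axis=1, skipna=True)
        for year in (2003, 2004):
            assert sums.loc[year] == pytest.approx(1.0)


class TestSubpopsAndVarieties:
    def test_closed_subpops_diagonal_descent(self):
        records = [
            rec("S1", None, None, Sex.MALE, 2000, subpop="P1"),
            rec("D1", None, None, Sex.FEMALE, 2000, subpop="P1"),
            rec("S2", None, None, Sex.MALE, 2000, subpop="P2"),
            rec("D2", None, None, Sex.FEMALE, 2000, subpop="P2"),
            rec("k1", "S1", "D1", Sex.MALE, 2001, subpop="P1"),
            rec("k2", "S2", "D2", Sex.MALE, 2001, subpop="P2"),
        ]
        t = monitor.subpop_descent(build(records))
        assert t.loc["P1", "P1"] == 2 and t.loc["P2", "P2"] == 2
        assert t.loc["P1", "P2"] == 0

    def test_cross_used_sire_off_diagonal(self):
        records = [
            rec("S1", None, None, Sex.MALE, 2000, subpop="P1"),
            rec("D2", None, None, Sex.FEMALE, 2000, subpop="P2"),
            rec("k", "S1", "D2", Sex.MALE, 2001, subpop="P2"),
        ]
        t = monitor.subpop_descent(build(records))
        assert t.loc["P2", "P1"] == 1 and t.loc["P2", "P2"] == 1

    def test_varieties_counts_sum_to_births(self):
        records, _ = generate_pedigree(FixtureSpec(years=3, seed=2))
        labeled = [
            PedigreeRecord(
                r.animal_id, r.sire_id, r.dam_id, r.sex, r.birth_year,
                variety="V1" if i % 2 else "V2",
            )
            for i, r in enumerate(records)
        ]
        ped = build(labeled)
        t = monitor.varieties_by_year(ped)
        births = monitor.births_by_year(ped)
        assert (t.sum(axis=1) == births.total).all()


class TestPointerSummary:
    def test_constructed_fixture_summary(self, small_herd):
        s = monitor.pointer_summary(small_herd)
        assert s["window_years"] == [2000, 2004]  # clamped to the first year
        assert s["litter_size_dist"] == {2: pytest.approx(2 / 3),
                                         3: pytest.approx(1 / 3)}
        assert s["top_sires"]["count"] == 4
        assert s["top_sires"]["contribution"] == pytest.approx(1.0)

    def test_single_year_pedigree(self):
        records = [
            rec("S", None, None, Sex.MALE, 2000),
            rec("D", None, None, Sex.FEMALE, 2000),
        ]
        s = monitor.pointer_summary(build(records))
        assert s["window_years"] == [2000, 2000]

    def test_no_sires_flagged(self):
        records = [
            rec("D", None, None, Sex.FEMALE, 2000),
            rec("k", None, "D", Sex.MALE, 2001),
        ]
        s = monitor.pointer_summary(build(records))
        assert "missing" in s


class TestReport:
    def test_every_table_spans_all_years(self):
        records, _ = generate_pedigree(FixtureSpec(years=6, seed=4))
        ped = build(records)
        report = monitor.build_report(ped)
        first, last = ped.known_year_span()
        for name, table in report.tables().items():
            if name in ("rate_table", "subpop_descent"):
                continue
            if len(table.index):
                assert list(table.index) == list(range(first, last + 1)), name

    def test_births_total_equals_litter_sizes_plus_unknown_dams(self):
        ped = build(random_pedigree(150, seed=21))
        births = monitor.births_by_year(ped).total.sum()
        litter_total = sum(l.size for l in monitor.infer_litters(ped))
        unknown_dam = sum(
            1 for r in ped.records
            if r.dam_id is None and r.birth_year is not None
        )
        assert births == litter_total + unknown_dam

    def test_report_writes_tsvs(self, tmp_path):
        records, _ = generate_pedigree(FixtureSpec(years=4, seed=5))
        report = monitor.build_report(build(records))
        files = report.write(tmp_path)
        assert (tmp_path / "births_by_year.tsv").exists()
        assert (tmp_path / "report.txt").exists()
        assert len(files) >= 16

    def test_subpopulation_analyses_repeated_per_group(self):
        records, _ = generate_pedigree(FixtureSpec(years=4, seed=6,
                                                   n_subpops=2))
        report = monitor.build_report(build(records))
        assert set(report.subpop_reports) == {"S1", "S2"}
        sub = report.subpop_reports["S1"]
        # the per-group report spans the same years and repeats every table
        assert list(sub.births_by_year.index) == list(
            report.births_by_year.index
        )
        assert set(report.subpop_relatedness.columns) == {
            "S1|S1", "S1|S2", "S2|S1", "S2|S2"
        }

    def test_rate_table_has_period_rows(self):
        records, _ = generate_pedigree(
            FixtureSpec(years=20, dams_per_year=6, seed=8)
        )
        t = monitor.rate_table(build(records))
        assert t.iloc[0].first_year == 2000
        assert len(t) == 1 + 4  # whole period + four 5-year periods
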
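"""Cohort construction: parsing, recodes, combinations, filters, splits."""

import numpy as np
import pandas as pd
import pytest

from eaccd.cohort import (
    Cohort,
    FactorScheme,
    build_combinations,
    filter_rare,
    read_cohort,
    temporal_split,
)

SCHEME = FactorScheme(
    factors=("T", "N"),
    levels={"T": ("T1", "T2"), "N": ("N0", "N1")},
)

AGE_SCHEME = FactorScheme(
    factors=("T", "A"),
    levels={"T": ("T1", "T2"), "A": ("A0", "A1")},
    recodes={"A": {"breaks": [70], "labels": ["A0", "A1"]}},
)


def write_csv(tmp_path, rows, header="time,event,T,N,year"):
    p = tmp_path / "cases.csv"
    p.write_text(header + "\n" + "\n".join(rows) + "\n")
    return p


class TestReadCohort:
    def test_all_valid_rows_kept(self, tmp_path):
        p = write_csv(tmp_path, [f"{10 + i},1,T1,N0,2010" for i in range(5)])
        cohort, dropped = read_cohort(p, SCHEME)
        assert len(cohort) == 5 and dropped == 0

    def test_blank_factor_cell_dropped_and_counted(self, tmp_path):
        rows = ["10,1,T1,N0,2010", "11,0,T2,,2010", "12,1,T2,N1,2011", "13,0,T1,N1,2012", "14,1,T1,N0,2012"]
        cohort, dropped = read_cohort(write_csv(tmp_path, rows), SCHEME)
        assert len(cohort) == 4 and dropped == 1

    def test_inadmissible_level_dropped(self, tmp_path):
        rows = ["10,1,T1,N0,2010", "11,0,T9,N0,2010"]
        cohort, dropped = read_cohort(write_csv(tmp_path, rows), SCHEME)
        assert len(cohort) == 1 and dropped == 1

    def test_age_recode_around_cutoff(self, tmp_path):
        p = tmp_path / "cases.csv"
        p.write_text("time,event,T,A\n10,1,T1,69\n11,1,T1,71\n12,0,T2,70\n")
        cohort, dropped = read_cohort(p, AGE_SCHEME)
        assert dropped == 0
        assert list(cohort.data["A"]) == ["A0", "A1", "A0"]  # cutoff value stays young side

    def test_missing_mapped_column_fatal(self, tmp_path):
        p = write_csv(tmp_path, ["10,1,T1,N0,2010"])
        with pytest.raises(ValueError, match="mapped column"):
            read_cohort(p, SCHEME, column_map={"time": "months"})

    def test_unparseable_time_fatal_with_row(self, tmp_path):
        p = write_csv(tmp_path, ["10,1,T1,N0,2010", "oops,1,T1,N0,2010"])
        with pytest.raises(ValueError, match=r"rows \[1\]"):
            read_cohort(p, SCHEME)

    def test_column_map_and_tsv(self, tmp_path):
        p = tmp_path / "cases.tsv"
        p.write_text("months\tdead\tT\tN\n10\t1\tT1\tN0\n")
        cohort, _ = read_cohort(p, SCHEME, column_map={"time": "months", "event": "dead"})
        assert len(cohort) == 1

    def test_write_read_round_trip(self, tmp_path):
        rows = ["10.5,1,T1,N0,2010", "3,0,T2,N1,2013", "88,1,T2,N0,2011"]
        cohort, _ = read_cohort(write_csv(tmp_path, rows), SCHEME)
        out = tmp_path / "out.csv"
        cohort.write(out)
        again, dropped = read_cohort(out, SCHEME)
        assert dropped == 0
        pd.testing.assert_frame_equal(
            cohort.data.sort_index(axis=1), again.data.sort_index(axis=1)
        )


def toy_cohort(counts, years=None):
    """counts: dict (T, N) -> n."""
    rows = []
    for (t, n), c in counts.items():
        for i in range(c):
            rows.append(
                {
                    "time": 10.0 + i,
                    "event": i % 2,
                    "T": t,
                    "N": n,
                    "year": (years or {}).get((t, n), 2010),
                }
            )
    return Cohort(scheme=SCHEME, data=pd.DataFrame(rows))


class TestCombinations:
    def test_cross_product_keys(self):
        cohort = toy_cohort({("T1", "N0"): 2, ("T1", "N1"): 2, ("T2", "N0"): 2, ("T2", "N1"): 2})
        assert cohort.combination_keys == ("T1N0", "T1N1", "T2N0", "T2N1")

    def test_collapse_pools_combinations(self):
        cohort = toy_cohort({("T1", "N0"): 3, ("T1", "N1"): 2})
        collapsed = build_combinations(cohort, ["T"])
        assert collapsed.combination_keys == ("T1",)
        assert collapsed.combinations[0].case_count == 5

    def test_full_subset_is_identity(self):
        cohort = toy_cohort({("T1", "N0"): 2, ("T2", "N1"): 3})
        same = build_combinations(cohort, ["T", "N"])
        assert same.combination_keys == cohort.combination_keys
        assert build_combinations(same, ["T", "N"]).combination_keys == same.combination_keys

    def test_counts_sum_to_cohort_size(self):
        cohort = toy_cohort({("T1", "N0"): 4, ("T2", "N0"): 6})
        assert sum(c.case_count for c in cohort.combinations) == len(cohort)

    def test_empty_subset_fatal(self):
        with pytest.raises(ValueError):
            build_combinations(toy_cohort({("T1", "N0"): 2}), [])

    def test_separator_variant(self):
        scheme = FactorScheme(
            factors=("T", "N"), levels=SCHEME.levels, separator="|"
        )
        cohort = Cohort(scheme=scheme, data=toy_cohort({("T1", "N0"): 2}).data.drop(columns="combination"))
        assert cohort.combination_keys == ("T1|N0",)


class TestFilterRare:
    def test_threshold(self):
        cohort = toy_cohort({("T1", "N0"): 30, ("T2", "N1"): 24})
        kept, report = filter_rare(cohort, 25)
        assert kept.combination_keys == ("T1N0",)
        assert report["combination"].tolist() == ["T2N1"] and report["n"].tolist() == [24]

    def test_min_count_one_is_identity(self):
        cohort = toy_cohort({("T1", "N0"): 3, ("T2", "N1"): 1})
        kept, report = filter_rare(cohort, 1)
        assert len(kept) == len(cohort) and report.empty

    def test_default_min_count_is_25(self):
        from eaccd.cohort import DEFAULT_MIN_COUNT

        assert DEFAULT_MIN_COUNT == 25
        cohort = toy_cohort({("T1", "N0"): 26, ("T2", "N1"): 24})
        kept, _ = filter_rare(cohort)
        assert kept.combination_keys == ("T1N0",)

    def test_all_removed_fatal(self):
        with pytest.raises(ValueError):
            filter_rare(toy_cohort({("T1", "N0"): 2}), 25)


class TestTemporalSplit:
    def test_partition_by_year(self):
        rows = [
            {"time": 10.0 + i, "event": i % 2, "T": "T1", "N": "N0", "year": 2010 if i < 10 else 2013}
            for i in range(13)
        ]
        cohort = Cohort(scheme=SCHEME, data=pd.DataFrame(rows))
        train, val, report = temporal_split(cohort, 2013, min_count=1)
        assert len(train) == 10 and len(val) == 3
        assert len(train) + len(val) + report["excluded_total"] == len(cohort)

    def test_unclassifiable_validation_case_excluded(self):
        cohort = toy_cohort(
            {("T1", "N0"): 30, ("T2", "N1"): 1},
            years={("T1", "N0"): 2010, ("T2", "N1"): 2013},
        )
        train, val, report = temporal_split(cohort, 2013, min_count=25)
        assert report["validation_excluded"] == 1
        assert val.data.empty
        assert len(train) + len(val) + report["excluded_total"] == len(cohort)

    def test_rare_training_cases_counted_in_partition(self):
        cohort = toy_cohort(
            {("T1", "N0"): 30, ("T1", "N1"): 5, ("T2", "N0"): 4},
            years={("T1", "N0"): 2010, ("T1", "N1"): 2011, ("T2", "N0"): 2013},
        )
        train, val, report = temporal_split(cohort, 2013, min_count=25)
        assert report["rare_cases_removed"] == 5
        assert report["validation_excluded"] == 4
        assert len(train) + len(val) + report["excluded_total"] == len(cohort)

    def test_empty_validation_warns_not_fatal(self):
        cohort = toy_cohort({("T1", "N0"): 30}, years={("T1", "N0"): 2010})
        with pytest.warns(UserWarning, match="empty validation"):
            train, val, _ = temporal_split(cohort, 2013, min_count=1)
        assert len(val) == 0 and len(train) == 30

    def test_missing_year_fatal(self):
        cohort = toy_cohort({("T1", "N0"): 5})
        cohort.data = cohort.data.drop(columns="year")
        with pytest.raises(ValueError, match="year"):
            temporal_split(cohort, 2013)


def test_scheme_invariants():
    with pytest.raises(ValueError):
        FactorScheme(factors=("T", "T"), levels={"T": ("a",)})
    with pytest.raises(ValueError):
        FactorScheme(factors=("T",), levels={"T": ("a", "a")})
    with pytest.raises(ValueError):
        FactorScheme(
            factors=("A",),
            levels={"A": ("A0", "A1")},
            recodes={"A": {"breaks": [70], "labels": ["A0"]}},
        )
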
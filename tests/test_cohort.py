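import numpy as np
import pandas as pd
import pytest

from bilatdr.cohort import (
    Cohort,
    apply_eligibility_filters,
    read_cohort,
    summarize_cohort,
)

from conftest import make_cohort_df


class TestReadCohort:
    def test_identity_ingest(self, tiny_df, tmp_path):
        path = tmp_path / "cohort.tsv"
        tiny_df.to_csv(path, sep="\t", index=False)
        cohort, report = read_cohort(path)
        assert len(cohort) == 3
        assert report.n_rejected == 0

    def test_bad_event_code_rejected(self, tiny_df, tmp_path):
        tiny_df.loc[1, "event"] = 7
        path = tmp_path / "cohort.tsv"
        tiny_df.to_csv(path, sep="\t", index=False)
        cohort, report = read_cohort(path)
        assert len(cohort) == 2
        assert report.n_rejected == 1
        assert "event" in report.rejects["reason"].iloc[0]

    def test_header_only(self, tiny_df, tmp_path):
        path = tmp_path / "cohort.tsv"
        tiny_df.iloc[0:0].to_csv(path, sep="\t", index=False)
        cohort, report = read_cohort(path)
        assert len(cohort) == 0
        assert report.n_read == 0

    def test_missing_mandatory_column(self, tiny_df, tmp_path):
        path = tmp_path / "cohort.tsv"
        tiny_df.drop(columns=["interval_time"]).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="interval_time"):
            read_cohort(path)

    def test_unmapped_category_rejected_per_row(self, tiny_df, tmp_path):
        tiny_df.loc[0, "t_pbc"] = "Tx"
        path = tmp_path / "cohort.tsv"
        tiny_df.to_csv(path, sep="\t", index=False)
        cohort, report = read_cohort(path)
        assert len(cohort) == 2
        assert "t_pbc" in report.rejects["reason"].iloc[0]

    def test_dialect_mapping(self, tiny_df, tmp_path):
        renamed = tiny_df.rename(columns={"event": "cod"})
        renamed["cod"] = renamed["cod"].map({1: "breast"})
        path = tmp_path / "cohort.csv"
        renamed.to_csv(path, index=False)
        dialect = {
            "sep": ",",
            "columns": {"cod": "event"},
            "codes": {"event": {"breast": 1}},
        }
        cohort, report = read_cohort(path, dialect)
        assert len(cohort) == 3
        assert (cohort.df["event"] == 1).all()

    def test_round_trip(self, tiny_df, tmp_path):
        p1 = tmp_path / "a.tsv"
        p2 = tmp_path / "b.tsv"
        tiny_df.to_csv(p1, sep="\t", index=False)
        cohort, _ = read_cohort(p1)
        cohort.write(p2)
        again, _ = read_cohort(p2)
        pd.testing.assert_frame_equal(cohort.df, again.df)

    def test_duplicate_patient_id_rejected(self, tiny_df):
        tiny_df.loc[1, "patient_id"] = tiny_df.loc[0, "patient_id"]
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(tiny_df)


class TestEligibility:
    def test_six_month_rule(self):
        df = make_cohort_df(2)
        df.loc[0, "interval_time"] = 0.3
        kept, report = apply_eligibility_filters(Cohort(df))
        assert len(kept) == 1
        assert report.counts["interval_time < 6 months"] == 1

    def test_three_month_followup_rule(self):
        df = make_cohort_df(2)
        df.loc[0, "followup_time"] = 0.1
        kept, report = apply_eligibility_filters(Cohort(df))
        assert len(kept) == 1
        assert report.counts["followup_time < 3 months"] == 1

    def test_typical_record_retained(self):
        df = make_cohort_df(1, interval_time=[5.0], followup_time=[2.0],
                            age_pbc=[58.0], age_cbc=[63.0])
        kept, _ = apply_eligibility_filters(Cohort(df))
        assert len(kept) == 1

    def test_age_and_metastasis_rules(self):
        df = make_cohort_df(3)
        df.loc[0, "age_pbc"] = 17.0
        df.loc[0, "age_cbc"] = 25.0
        df.loc[1, "distant_met"] = True
        kept, report = apply_eligibility_filters(Cohort(df))
        assert len(kept) == 1
        assert report.counts["age_pbc outside [18, 97]"] == 1
        assert report.counts["distant metastasis at diagnosis"] == 1

    def test_idempotent(self):
        df = make_cohort_df(5)
        df.loc[0, "interval_time"] = 0.3
        once, _ = apply_eligibility_filters(Cohort(df))
        twice, report2 = apply_eligibility_filters(once)
        pd.testing.assert_frame_equal(once.df, twice.df)
        assert all(v == 0 for v in report2.counts.values())


class TestSummarize:
    def test_printed_interval_percentages(self):
        # marginal counts 7551 / 5753 of 13304
        iv = np.concatenate([np.full(7551, 3.0), np.full(5753, 9.0)])
        df = pd.DataFrame(
            {"patient_id": [str(i) for i in range(13304)], "interval_time": iv}
        )
        out = summarize_cohort(
            Cohort(df), "interval_time",
            bins=[("<=7", 0.0, 7.0), (">7", 7.0, 30.0)],
        )
        assert out.loc[out.group == ">7", "count"].item() == 5753
        assert out.loc[out.group == ">7", "percent"].item() == 43.24
        assert out.loc[out.group == "<=7", "percent"].item() == 56.76

    def test_printed_age_percentage(self):
        ages = np.concatenate([np.full(1493, 45.0), np.full(13304 - 1493, 70.0)])
        df = pd.DataFrame(
            {"patient_id": [str(i) for i in range(13304)], "age_cbc": ages}
        )
        out = summarize_cohort(
            Cohort(df), "age_cbc", bins=[("41-50", 40.0, 50.0), (">60", 60.0, 120.0)]
        )
        assert out.loc[out.group == "41-50", "percent"].item() == 11.22

    def test_single_group_is_100(self, tiny_df):
        out = summarize_cohort(Cohort(tiny_df), "race")
        assert out["percent"].item() == 100.00

    def test_partition_sums_to_100(self, sim_cohort):
        _, cohort, _ = sim_cohort
        out = summarize_cohort(cohort, "t_pbc")
        assert abs(out["percent"].sum() - 100.0) <= 0.05

    def test_unknown_variable(self, tiny_df):
        with pytest.raises(KeyError):
            summarize_cohort(Cohort(tiny_df), "nope")

    def test_denominator_excludes_missing(self):
        df = make_cohort_df(4)
        df.loc[0, "er_pbc"] = np.nan
        out = summarize_cohort(Cohort(df), "er_pbc")
        assert out["count"].sum() == 3
        assert abs(out["percent"].sum() - 100.0) <= 0.05
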
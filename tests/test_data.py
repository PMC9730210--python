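import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from esmstress import (
    ESMDataset,
    IntegrityError,
    NoAnalyzableDataError,
    SchemaError,
    apply_compliance_filter,
    compliance_percentage,
    descriptive_table,
    derive_prompts,
    read_esm_long,
    sample_totals,
    write_esm_long,
)
from conftest import HEADER, make_csv, prompt_row


class TestReadWrite:
    def test_fixture_round_trip(self, tiny_dataset, tmp_path):
        assert tiny_dataset.n_persons == 3
        assert tiny_dataset.n_prompts == 3 * 2 * 3
        out = tmp_path / "rt.csv"
        write_esm_long(tiny_dataset, out)
        back = read_esm_long(out)
        pd.testing.assert_frame_equal(
            back.prompts.reset_index(drop=True),
            tiny_dataset.prompts.reset_index(drop=True),
            check_dtype=False,
        )

    def test_out_of_range_value_flagged_not_dropped(self):
        ds = read_esm_long(make_csv([
            prompt_row(beep=1, pa=(9, 4, 4)),
            prompt_row(beep=2),
        ]))
        assert ds.n_prompts == 2  # row retained
        assert len(ds.issues) == 1
        assert ds.issues.iloc[0]["column"] == "pa_cheerful"
        assert ds.issues.iloc[0]["value"] == 9

    def test_missing_column_is_schema_error_naming_it(self):
        header = HEADER.replace("event_pleasantness,", "")
        row = prompt_row().split(",")
        del row[11]
        with pytest.raises(SchemaError, match="event_pleasantness"):
            read_esm_long(io.StringIO(header + "\n" + ",".join(row) + "\n"))

    def test_duplicate_key_is_integrity_error(self):
        with pytest.raises(IntegrityError):
            read_esm_long(make_csv([prompt_row(beep=1), prompt_row(beep=1)]))

    def test_varying_person_field_rejected(self):
        with pytest.raises(SchemaError):
            read_esm_long(make_csv([
                prompt_row(beep=1, group="control"),
                prompt_row(beep=2, group="patient"),
            ]))

    def test_missingness_preserved(self):
        ds = read_esm_long(make_csv([prompt_row(beep=1, delay=None, pa=(None,) * 3)]))
        assert ds.prompts["response_delay_min"].isna().all()
        assert ds.prompts["pa_cheerful"].isna().all()


class TestComplianceFilter:
    def _ds(self, rows):
        return read_esm_long(make_csv(rows))

    def test_compliant_person_untouched(self):
        rows = [prompt_row(day=d, beep=b, delay=10)
                for d in range(1, 7) for b in range(1, 11)]
        ds = self._ds(rows)
        out, logs = apply_compliance_filter(ds)
        assert out.n_prompts == 60
        assert sum(l.n_prompts_removed for l in logs) == 0

    def test_person_below_min_prompts_removed_at_stage_two(self):
        rows = [prompt_row(pid="few", day=1 + b // 10, beep=1 + b % 10, delay=5)
                for b in range(19)]
        rows += [prompt_row(pid="many", group="patient", day=d, beep=b, delay=5)
                 for d in range(1, 4) for b in range(1, 11)]
        out, logs = apply_compliance_filter(self._ds(rows))
        assert set(out.persons["person_id"]) == {"many"}
        assert logs[1].n_persons_removed == 1
        assert logs[1].n_prompts_removed == 19

    def test_removed_counts_match_row_scan(self):
        rng = np.random.default_rng(3)
        rows = []
        for p in range(6):
            for d in range(1, 4):
                for b in range(1, 11):
                    delay = None if rng.random() < 0.2 else round(float(rng.uniform(0, 30)), 1)
                    rows.append(prompt_row(pid=f"p{p}", day=d, beep=b, delay=delay))
        ds = self._ds(rows)
        out, logs = apply_compliance_filter(ds, max_delay=15, min_prompts=12)

        # independent row scan
        df = ds.prompts
        ok = df["response_delay_min"].notna() & (df["response_delay_min"] <= 15)
        surv = df[ok].groupby("person_id").size()
        keep_persons = set(surv[surv >= 12].index)
        expect_stage2 = int(surv[~surv.index.isin(keep_persons)].sum())
        assert logs[0].n_prompts_removed == int((~ok).sum())
        assert logs[1].n_prompts_removed == expect_stage2
        assert out.n_prompts == int(surv[surv.index.isin(keep_persons)].sum())

    def test_idempotent_and_row_conserving(self, small_sim):
        ds, _ = small_sim
        out, logs = apply_compliance_filter(ds)
        assert ds.n_prompts == out.n_prompts + sum(l.n_prompts_removed for l in logs)
        again, logs2 = apply_compliance_filter(out)
        assert again.n_prompts == out.n_prompts
        assert sum(l.n_prompts_removed for l in logs2) == 0
        assert sum(l.n_persons_removed for l in logs2) == 0

    def test_all_removed_raises(self):
        ds = self._ds([prompt_row(beep=b, delay=30) for b in range(1, 5)])
        with pytest.raises(NoAnalyzableDataError):
            apply_compliance_filter(ds)


class TestCompliancePercentage:
    @pytest.mark.parametrize("answered,scheduled,expect", [
        (45, 60, 75), (49, 60, 82), (47, 60, 78), (60, 60, 100), (0, 60, 0),
    ])
    def test_values(self, answered, scheduled, expect):
        assert compliance_percentage(answered, scheduled) == expect

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            compliance_percentage(1, 0)
        with pytest.raises(ValueError):
            compliance_percentage(5, 4)

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_monotone_in_answered(self, scheduled, data):
        a = data.draw(st.integers(0, scheduled - 1))
        assert (compliance_percentage(a, scheduled)
                <= compliance_percentage(a + 1, scheduled))


def test_sample_totals_sums_group_counts():
    assert sample_totals({"a": 2, "b": 3}) == 5
    with pytest.raises(ValueError):
        sample_totals({"a": -1})


class TestDescriptives:
    def _persons_ds(self, spec):
        """spec: list of (pid, group, age, gender); one answered prompt each x2."""
        rows = []
        for pid, g, age, gender in spec:
            for b in (1, 2):
                rows.append(prompt_row(pid=pid, group=g, age=age, gender=gender,
                                       beep=b, delay=5))
        return read_esm_long(make_csv(rows))

    def test_identical_groups_give_zero_f(self):
        spec = [(f"{g}{i}", g, age, "female")
                for g in ("control", "at_risk", "patient")
                for i, age in enumerate((30, 40, 50))]
        res = descriptive_table(self._persons_ds(spec))
        age_test = res["tests"].set_index("characteristic").loc["Age"]
        assert age_test["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert not res["contrasts"].query("characteristic == 'Age'")["significant"].any()

    def test_anova_matches_hand_computation(self):
        # groups (31,32,33) and (34,35,36): MSB = 13.5, MSW = 1 -> F = 13.5
        spec = ([(f"c{i}", "control", a, "female") for i, a in enumerate((31, 32, 33))]
                + [(f"p{i}", "patient", a, "female") for i, a in enumerate((34, 35, 36))])
        res = descriptive_table(self._persons_ds(spec))
        t = res["tests"].set_index("characteristic").loc["Age"]
        assert t["statistic"] == pytest.approx(13.5, rel=1e-12)
        assert (t["df1"], t["df2"]) == (1, 4)

    def test_chi_square_matches_hand_computation(self):
        # 2x2 gender table (10,10 / 20,0): Pearson chi2 = 40*200^2/(20*20*30*10)
        spec = ([(f"c{i}", "control", 30, "male") for i in range(10)]
                + [(f"c{i + 10}", "control", 30, "female") for i in range(10)]
                + [(f"p{i}", "patient", 30, "male") for i in range(20)])
        res = descriptive_table(self._persons_ds(spec))
        chi = res["tests"].set_index("characteristic").loc["Gender"]
        assert chi["statistic"] == pytest.approx(40 * 200**2 / (20 * 20 * 30 * 10), rel=1e-12)

    def test_tiny_group_skips_test_with_warning(self):
        spec = [("a", "control", 30, "female"), ("b", "control", 40, "female"),
                ("c", "patient", 50, "male")]
        with pytest.warns(UserWarning, match="n < 2"):
            res = descriptive_table(self._persons_ds(spec))
        assert "Age" not in set(res["tests"]["characteristic"])

    def test_includes_affect_and_stress_rows_when_derived_given(self, small_sim):
        ds, _ = small_sim
        filtered, _ = apply_compliance_filter(ds)
        derived = derive_prompts(filtered)
        res = descriptive_table(filtered, derived)
        labels = set(res["table"]["characteristic"])
        assert {"Positive affect (raw)", "Stressful days per person",
                "Time of first stressor (hour of day)",
                "Unpleasantness of first stressor (recoded 1-7)",
                "Unpleasantness of first stressor (|bipolar| 1-3)"} <= labels
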
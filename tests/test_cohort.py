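import numpy as np
import pytest

from conftest import binary, cont, genotype, make_cohort
from trajpc import (
    VariableSpec,
    complete_case_filter,
    read_cohort,
    split_cohort,
    write_cohort,
)


def _write(tmp_path, rows, variables, timepoints):
    csv = tmp_path / "cohort.csv"
    meta = tmp_path / "meta.json"
    import json

    csv.write_text("patient_id,timepoint,variable,value\n" + "\n".join(rows) + "\n")
    meta.write_text(
        json.dumps({"timepoints": timepoints, "variables": [v.to_dict() for v in variables]})
    )
    return csv, meta


class TestVariableSpec:
    def test_continuous_requires_direction(self):
        with pytest.raises(ValueError, match="direction"):
            VariableSpec("x", kind="continuous")

    def test_direction_forbidden_off_continuous(self):
        with pytest.raises(ValueError):
            VariableSpec("g", kind="binary", direction=+1)

    def test_genotype_requires_classes(self):
        with pytest.raises(ValueError, match="classes"):
            VariableSpec("g", kind="genotype", static=True)


class TestReadWrite:
    def test_dense_round_trip_bit_exact(self, tmp_path):
        vals = np.zeros((2, 3, 2))
        vals[:, 0, :] = [[0.1, 0.30000000000000004], [1e-17, -2.5]]
        vals[:, 1, :] = [[1, 1], [0, 0]]  # binary
        vals[:, 2, :] = [[2, 2], [1, 1]]  # genotype class indices
        cohort = make_cohort(vals, [cont("a"), binary("sex"), genotype("g1")])
        write_cohort(cohort, tmp_path / "c.csv", tmp_path / "m.json")
        back = read_cohort(tmp_path / "c.csv", tmp_path / "m.json")
        assert back.patient_ids == cohort.patient_ids
        assert np.array_equal(back.values, cohort.values)
        assert not back.mask.any()
        assert back.genotype_label(2, 0) == "TT"

    def test_omitted_row_marks_missing(self, tmp_path):
        rows = ["p0,bl,a,1.0", "p0,y1,a,2.0", "p1,bl,a,3.0"]  # p1 lacks y1
        csv, meta = _write(tmp_path, rows, [cont("a")], ["bl", "y1"])
        cohort = read_cohort(csv, meta)
        assert not cohort.mask[0].any()
        assert cohort.mask[1, 0, 1]

    def test_duplicate_rows_rejected(self, tmp_path):
        rows = ["p0,bl,a,1.0", "p0,bl,a,2.0"]
        csv, meta = _write(tmp_path, rows, [cont("a")], ["bl"])
        with pytest.raises(ValueError, match="duplicate"):
            read_cohort(csv, meta)

    def test_unknown_variable_rejected(self, tmp_path):
        csv, meta = _write(tmp_path, ["p0,bl,zzz,1.0"], [cont("a")], ["bl"])
        with pytest.raises(ValueError, match="not declared"):
            read_cohort(csv, meta)

    def test_non_numeric_continuous_rejected(self, tmp_path):
        csv, meta = _write(tmp_path, ["p0,bl,a,high"], [cont("a")], ["bl"])
        with pytest.raises(ValueError, match="non-numeric"):
            read_cohort(csv, meta)

    def test_genotype_label_outside_classes_rejected(self, tmp_path):
        csv, meta = _write(tmp_path, ["p0,bl,g1,AG"], [genotype("g1")], ["bl"])
        with pytest.raises(ValueError, match="genotype"):
            read_cohort(csv, meta)

    def test_static_measured_once_is_broadcast(self, tmp_path):
        rows = ["p0,bl,age,61.5", "p0,bl,a,1.0", "p0,y1,a,2.0"]
        csv, meta = _write(tmp_path, rows, [cont("age", static=True), cont("a")], ["bl", "y1"])
        cohort = read_cohort(csv, meta)
        assert not cohort.mask[0, 0].any()
        assert np.array_equal(cohort.values[0, 0], [61.5, 61.5])

    def test_static_variable_must_not_vary(self):
        vals = np.array([[[1.0, 2.0]]])
        with pytest.raises(ValueError, match="static"):
            make_cohort(vals, [cont("age", static=True)])


class TestCompleteCase:
    def test_patient_with_missing_cell_dropped(self, two_var_cohort):
        mask = np.zeros_like(two_var_cohort.values, dtype=bool)
        mask[1, 0, 1] = True
        cohort = make_cohort(
            two_var_cohort.values, two_var_cohort.variables, mask=mask
        )
        kept = complete_case_filter(cohort)
        assert kept.patient_ids == ["p0", "p2"]

    def test_no_missing_is_identity(self, two_var_cohort):
        kept = complete_case_filter(two_var_cohort)
        assert kept.patient_ids == two_var_cohort.patient_ids
        assert np.array_equal(kept.values, two_var_cohort.values)

    def test_all_removed_raises(self, two_var_cohort):
        mask = np.ones_like(two_var_cohort.values, dtype=bool)
        cohort = make_cohort(two_var_cohort.values, two_var_cohort.variables, mask=mask)
        with pytest.raises(ValueError, match="every patient"):
            complete_case_filter(cohort)

    def test_enrollment_attrition_leaves_complete_cases(self, rng):
        """430 enrollees with 236 incomplete records reduce to 194 patients."""
        vals = rng.normal(size=(430, 2, 5))
        mask = np.zeros_like(vals, dtype=bool)
        dropped = rng.choice(430, size=236, replace=False)
        for i in dropped:
            mask[i, rng.integers(2), rng.integers(5)] = True
        cohort = make_cohort(vals, [cont("a"), cont("b")], mask=mask)
        assert complete_case_filter(cohort).n_patients == 194


class TestSplit:
    def test_twenty_percent_of_194_is_39(self, rng):
        cohort = make_cohort(rng.normal(size=(194, 1, 2)), [cont("a")])
        split = split_cohort(cohort, 0.2, seed=7)
        assert split.test.n_patients == 39
        assert split.train.n_patients == 155

    def test_round_half_up(self, rng):
        cohort = make_cohort(rng.normal(size=(10, 1, 2)), [cont("a")])
        assert split_cohort(cohort, 0.25, seed=0).test.n_patients == 3  # 2.5 -> 3

    def test_same_seed_same_split(self, rng):
        cohort = make_cohort(rng.normal(size=(10, 1, 2)), [cont("a")])
        s1 = split_cohort(cohort, 0.5, seed=11)
        s2 = split_cohort(cohort, 0.5, seed=11)
        assert s1.test.patient_ids == s2.test.patient_ids
        assert s1.train.patient_ids == s2.train.patient_ids

    def test_degenerate_split_raises(self, rng):
        cohort = make_cohort(rng.normal(size=(2, 1, 2)), [cont("a")])
        with pytest.raises(ValueError, match="degenerate"):
            split_cohort(cohort, 0.9, seed=0)  # empty train

    def test_partition_properties_over_seeds(self, rng):
        cohort = make_cohort(rng.normal(size=(10, 1, 2)), [cont("a")])
        for seed in range(100):
            split = split_cohort(cohort, 0.3, seed=seed)
            train, test = set(split.train.patient_ids), set(split.test.patient_ids)
            assert train | test == set(cohort.patient_ids)
            assert not train & test
            assert len(test) == 3
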
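import numpy as np
import pandas as pd
import pytest

from ecselect.cq import (
    CqMatrix,
    PlateCalibration,
    ReplicateSet,
    apply_iac_calibration,
    calibrations_from_replicates,
    collapse_replicates,
    plates_from_replicates,
    read_cq_table,
    summarize_assays,
    write_cq_table,
)
from ecselect.errors import InputError

from conftest import matrix_from_rows, random_matrix, two_group_sheet


WIDE = "assay,s1,s2\nmiR-16,15.4,16.1\nmiR-425,20.2,Undetermined\nU6,21.0,21.5\n"
LONG = (
    "sample,assay,cq\n"
    "s2,U6,21.5\ns1,miR-16,15.4\ns2,miR-425,Undetermined\n"
    "s1,U6,21.0\ns2,miR-16,16.1\ns1,miR-425,20.2\n"
)


class TestReadWrite:
    def test_wide_maps_undetermined_to_not_detected(self, tmp_path):
        p = tmp_path / "wide.csv"
        p.write_text(WIDE)
        m = read_cq_table(str(p))
        assert m.assay_ids == ["miR-16", "miR-425", "U6"]
        assert not m.detected.loc["miR-425", "s2"]
        assert m.cq.loc["miR-16", "s2"] == 16.1

    def test_long_shuffled_equals_wide(self, tmp_path):
        pw, pl = tmp_path / "w.csv", tmp_path / "l.csv"
        pw.write_text(WIDE)
        pl.write_text(LONG)
        assert read_cq_table(str(pl)).equals(read_cq_table(str(pw)))

    def test_non_numeric_cq_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("assay,s1\nmiR-16,abc\n")
        with pytest.raises(InputError, match=r":2"):
            read_cq_table(str(p))

    def test_duplicate_assay_rows_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("assay,s1\nmiR-16,15.0\nmiR-16,15.1\n")
        with pytest.raises(InputError, match="duplicate"):
            read_cq_table(str(p))

    @pytest.mark.parametrize("layout", ["wide", "long"])
    def test_round_trip_identity(self, tmp_path, rng, layout):
        m = random_matrix(rng, 5, 4)
        cq = m.cq.copy()
        cq.iloc[1, 2] = np.nan  # an undetected cell must survive the trip
        m = CqMatrix(cq)
        p = tmp_path / "out.csv"
        write_cq_table(m, str(p), layout=layout)
        assert read_cq_table(str(p), layout=layout).equals(m)


class TestCqMatrixInvariants:
    def test_out_of_range_rejected(self):
        with pytest.raises(InputError, match="out of range"):
            matrix_from_rows({"a": {"s1": 41.0}})

    def test_duplicate_ids_rejected(self):
        cq = pd.DataFrame([[20.0], [21.0]], index=["a", "a"], columns=["s1"])
        with pytest.raises(InputError, match="duplicate assay"):
            CqMatrix(cq)


class TestCollapseReplicates:
    def test_identical_replicates_pass(self):
        m, qc = collapse_replicates([ReplicateSet("s1", "a", (20.0, 20.0, 20.0))])
        assert m.cq.loc["a", "s1"] == 20.0
        assert qc["passed"].all() and qc["sd"].iloc[0] == 0.0

    def test_discordant_triplicate_flagged_and_excluded(self):
        # sample SD of (20, 20, 21) = 0.577 > 0.28
        m, qc = collapse_replicates([ReplicateSet("s1", "a", (20.0, 20.0, 21.0))])
        assert qc["sd"].iloc[0] == pytest.approx(0.5774, abs=1e-4)
        assert not qc["passed"].iloc[0]
        assert not m.detected.loc["a", "s1"]

    def test_tight_duplicate_retained(self):
        # sample SD of (15.40, 15.52) = 0.085 <= 0.28
        m, qc = collapse_replicates([ReplicateSet("s1", "a", (15.40, 15.52))])
        assert qc["sd"].iloc[0] == pytest.approx(0.0849, abs=1e-4)
        assert m.cq.loc["a", "s1"] == pytest.approx(15.46)

    def test_empty_replicate_set_is_error(self):
        with pytest.raises(InputError, match="empty replicate set"):
            ReplicateSet("s1", "a", ())

    def test_no_flagged_set_survives(self, rng):
        reps = []
        for i in range(40):
            vals = rng.uniform(18, 25) + rng.normal(0, rng.uniform(0.01, 0.5), size=3)
            reps.append(ReplicateSet(f"s{i}", "a", tuple(vals)))
        m, qc = collapse_replicates(reps)
        flagged = qc.loc[~qc["passed"], "sample"]
        assert flagged.map(lambda s: not m.detected.loc["a", s]).all()
        assert (qc.loc[qc["passed"], "sd"] <= 0.28).all()


class TestIacCalibration:
    def _reps(self):
        return [
            ReplicateSet("IAC", "miR-16", (18.1, 18.3), plate_id="p1"),
            ReplicateSet("IAC", "miR-16", (18.7, 18.9), plate_id="p2"),
            ReplicateSet("s1", "miR-16", (20.0,), plate_id="p1"),
            ReplicateSet("s2", "miR-16", (21.0,), plate_id="p1"),
            ReplicateSet("s3", "miR-16", (20.5,), plate_id="p2"),
        ]

    def test_two_plate_offsets(self):
        cals = calibrations_from_replicates(self._reps())
        offsets = {c.plate_id: c.offset for c in cals}
        assert offsets == pytest.approx({"p1": -0.3, "p2": 0.3})
        # weighted offsets sum to zero
        assert sum(c.offset * c.n_wells for c in cals) == pytest.approx(0.0)

    def test_calibration_applied_and_iac_dropped(self):
        reps = self._reps()
        m, _ = collapse_replicates(reps)
        cals = calibrations_from_replicates(reps)
        out = apply_iac_calibration(m, cals, plates_from_replicates(reps))
        assert "IAC" not in out.sample_ids
        assert out.cq.loc["miR-16", "s1"] == pytest.approx(20.3)
        assert out.cq.loc["miR-16", "s3"] == pytest.approx(20.2)

    def test_within_plate_differences_unchanged(self):
        reps = self._reps()
        m, _ = collapse_replicates(reps)
        cals = calibrations_from_replicates(reps)
        out = apply_iac_calibration(m, cals, plates_from_replicates(reps))
        before = m.cq.loc["miR-16", "s2"] - m.cq.loc["miR-16", "s1"]
        after = out.cq.loc["miR-16", "s2"] - out.cq.loc["miR-16", "s1"]
        assert after == pytest.approx(before)

    def test_single_plate_is_identity(self):
        reps = [
            ReplicateSet("IAC", "miR-16", (18.2,), plate_id="p1"),
            ReplicateSet("s1", "miR-16", (20.0,), plate_id="p1"),
        ]
        m, _ = collapse_replicates(reps)
        cals = calibrations_from_replicates(reps)
        assert cals[0].offset == pytest.approx(0.0)
        out = apply_iac_calibration(m, cals, plates_from_replicates(reps))
        assert out.cq.loc["miR-16", "s1"] == pytest.approx(20.0)

    def test_missing_plate_calibration_is_error(self):
        m, _ = collapse_replicates([ReplicateSet("s1", "a", (20.0,), plate_id="p9")])
        cal = PlateCalibration("p1", "a", 18.2, 18.2)
        with pytest.raises(InputError, match="lacks an IAC"):
            apply_iac_calibration(m, [cal], {"s1": "p9"})


class TestSummaries:
    def test_range_is_max_minus_min(self, rng):
        m = random_matrix(rng, 6, 10)
        table = summarize_assays(m)
        for assay in m.assay_ids:
            row = table.loc[(assay, "all")]
            assert row["range"] == pytest.approx(row["max"] - row["min"], abs=2e-3)
            assert row["range"] >= 0

    def test_constant_assay(self):
        m = matrix_from_rows({"a": {"s1": 20.0, "s2": 20.0, "s3": 20.0}})
        row = summarize_assays(m).loc[("a", "all")]
        assert row["sd"] == 0.0 and row["range"] == 0.0

    def test_sd_invariant_under_constant_shift(self, rng):
        m = random_matrix(rng, 3, 8)
        shifted = CqMatrix(m.cq + 2.5)
        a = summarize_assays(m)["sd"]
        b = summarize_assays(shifted)["sd"]
        assert np.allclose(a, b)

    def test_per_group_rows(self, rng):
        m = random_matrix(rng, 2, 6)
        m = CqMatrix(m.cq.set_axis(
            [f"cancer_{i}" for i in range(3)] + [f"control_{i}" for i in range(3)],
            axis=1,
        ))
        sheet = two_group_sheet(3, 3)
        table = summarize_assays(m, sheet)
        assert set(table.index.get_level_values("scope")) == {"all", "cancer", "control"}
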
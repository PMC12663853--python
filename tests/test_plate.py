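import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvatlas import (
    InjectionSchedule,
    KineticTrace,
    WellMeta,
    load_assay_config,
    read_plate_export,
    segment_phases,
    write_plate_csv,
)
from cvatlas.errors import ScheduleMismatchError, SchemaError, UnknownTissueError
from cvatlas.plate import PHASES


def make_meta(well="A1", tissue="Liver", animal="YM01", rep=1):
    return WellMeta(
        well_id=well, tissue=tissue, animal_id=animal, sex="male",
        age_group="young", protein_ug=8.0, replicate_index=rep,
    )


def trace_frame(n_wells=1, n_meas=12):
    rows = []
    for w in range(n_wells):
        for i in range(1, n_meas + 1):
            rows.append(
                {"well_id": f"W{w:02d}", "tissue": "Liver", "animal_id": f"A{w:02d}",
                 "sex": "male", "age_group": "young", "protein_ug": 8.0,
                 "replicate_index": 1, "measurement_index": i,
                 "ar": float(10 * w + i)}
            )
    return pd.DataFrame(rows)


class TestSchedule:
    def test_default_is_four_phases_of_three(self):
        s = InjectionSchedule()
        assert s.phase_names == PHASES
        assert s.total_measurements == 12
        assert [sl.stop - sl.start for sl in s.phase_slices().values()] == [3, 3, 3, 3]

    def test_int_broadcasts_and_zero_rejected(self):
        assert InjectionSchedule(1).total_measurements == 4
        with pytest.raises(ValueError):
            InjectionSchedule((3, 3, 0, 3))

    def test_phase_of_positional(self):
        s = InjectionSchedule()
        assert s.phase_of(0) == "baseline"
        assert s.phase_of(5) == "rot_aa"
        assert s.phase_of(11) == "oligomycin"


class TestSegmentation:
    def test_positional_partition(self):
        ar = [5.0, 5.1, 4.9, 4.0, 4.1, 3.9, 11.0, 12.0, 10.0, 2.0, 3.0, 1.0]
        seg = segment_phases(KineticTrace(make_meta(), ar), InjectionSchedule())
        assert list(seg["baseline"]) == [5.0, 5.1, 4.9]
        assert list(seg["oligomycin"]) == [2.0, 3.0, 1.0]

    def test_single_measurement_per_phase(self):
        seg = segment_phases(
            KineticTrace(make_meta(), [1.0, 2.0, 3.0, 4.0]), InjectionSchedule(1)
        )
        assert {k: list(v) for k, v in seg.items()} == {
            "baseline": [1.0], "rot_aa": [2.0], "atp_fccp": [3.0], "oligomycin": [4.0]
        }

    def test_length_mismatch_raises(self):
        with pytest.raises(ScheduleMismatchError):
            segment_phases(
                KineticTrace(make_meta(), list(range(11))), InjectionSchedule()
            )

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 4), min_size=4, max_size=4), st.data())
    def test_partition_is_bijection(self, counts, data):
        """Concatenating phase blocks in order reproduces the trace exactly."""
        schedule = InjectionSchedule(tuple(counts))
        ar = data.draw(
            st.lists(
                st.floats(-100, 100, allow_nan=False),
                min_size=schedule.total_measurements,
                max_size=schedule.total_measurements,
            )
        )
        seg = segment_phases(KineticTrace(make_meta(), ar), schedule)
        concat = np.concatenate([seg[p] for p in PHASES])
        assert list(concat) == list(KineticTrace(make_meta(), ar).ar_values)
        assert sum(len(v) for v in seg.values()) == schedule.total_measurements


class TestPlateIO:
    def test_single_well_long_format(self, tmp_path):
        path = tmp_path / "plate.csv"
        trace_frame(1, 12).to_csv(path, index=False)
        traces = read_plate_export(path, InjectionSchedule())
        assert len(traces) == 1
        seg = segment_phases(traces[0], InjectionSchedule())
        assert all(len(v) == 3 for v in seg.values())

    def test_missing_metadata_column_is_schema_error(self, tmp_path):
        path = tmp_path / "plate.csv"
        trace_frame().drop(columns=["tissue"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="tissue"):
            read_plate_export(path, InjectionSchedule())

    def test_96_wells_by_12_measurements(self, tmp_path):
        path = tmp_path / "plate.csv"
        trace_frame(96, 12).to_csv(path, index=False)
        traces = read_plate_export(path, InjectionSchedule())
        assert len(traces) == 96
        assert sum(len(t.ar_values) for t in traces) == 1152

    def test_wrong_measurement_count_names_well(self, tmp_path):
        df = pd.concat([trace_frame(1, 12), trace_frame(1, 11)], ignore_index=True)
        df.loc[12:, "well_id"] = "BAD"
        path = tmp_path / "plate.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ScheduleMismatchError, match="BAD"):
            read_plate_export(path, InjectionSchedule())

    def test_wide_dialect(self, tmp_path):
        row = {"well_id": "A1", "tissue": "Liver", "animal_id": "A00",
               "sex": "male", "age_group": "young", "protein_ug": 8.0,
               "replicate_index": 1}
        row.update({f"ar_{i}": float(i) for i in range(1, 13)})
        path = tmp_path / "wide.csv"
        pd.DataFrame([row]).to_csv(path, index=False)
        (trace,) = read_plate_export(path, InjectionSchedule())
        assert trace.ar_values == tuple(float(i) for i in range(1, 13))

    def test_round_trip_is_exact(self, tmp_path, zero_noise_atlas):
        traces = zero_noise_atlas[0][:20]
        path = tmp_path / "rt.csv"
        write_plate_csv(traces, path)
        back = read_plate_export(path, InjectionSchedule())
        assert len(back) == len(traces)
        by_id = {t.meta.well_id: t for t in back}
        for t in traces:
            assert by_id[t.meta.well_id].ar_values == t.ar_values
            assert by_id[t.meta.well_id].meta == t.meta


class TestAssayConfig:
    def test_printed_defaults(self):
        cfg = load_assay_config(None)
        assert (cfg.rotenone_um, cfg.antimycin_a_um) == (4.0, 4.0)
        assert (cfg.atp_mm, cfg.fccp_mm) == (20.0, 7.87)
        assert (cfg.oligomycin_um, cfg.ouabain_um) == (10.0, 1.0)
        assert cfg.protein_ug_by_tissue["Heart ventricle"] == 2
        assert cfg.protein_ug_by_tissue["gWAT"] == 15
        assert len(cfg.protein_ug_by_tissue) == 33

    def test_override_one_reagent(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("reagents:\n  oligomycin_um: 5\n")
        cfg = load_assay_config(p)
        assert cfg.oligomycin_um == 5
        assert cfg.atp_mm == 20.0

    def test_unknown_tissue_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("protein_ug_by_tissue:\n  Spleeen: 8\n")
        with pytest.raises(UnknownTissueError, match="Spleeen"):
            load_assay_config(p)
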
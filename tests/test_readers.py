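import numpy as np
import pandas as pd
import pytest

from platecurve.model import PlateShape
from platecurve.readers import (
    FormatError,
    detect_format,
    join_experiment,
    parse_hms,
    read_design_plater,
    read_measures_bioscreen,
    read_measures_long_csv,
    read_measures_wide_csv,
)
from platecurve.synth import SimConfig, emit_fixture_files, simulate_experiment


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


LONG = "well,runtime,measure\nA1,0,0.1\nA1,900,0.2\nA1,1800,0.3\nA2,0,0.15\nA2,900,0.2\nA2,1800,0.4\n"
WIDE = "time,A01,A02\n0,0.1,0.2\n900,0.2,\n1800,0.3,0.5\n"
BIOSCREEN = "Time,1,2,101\n00:00:00,0.1,0.2,0.3\n00:15:00,0.2,0.3,0.4\n"
PLATER = (
    "strain,1,2,3,4,5,6,7,8,9,10,11,12\n"
    + "\n".join(f"{r}," + ",".join(["BY"] * 12) for r in "ABCDEFGH")
    + "\n"
)
GENERIC_DESIGN = "well,strain,dose\nA01,BY,0\nA02,mut,10\n"


# ---------------------------------------------------------------------------
# Detection


@pytest.mark.parametrize(
    "name, text, expected",
    [
        ("a.csv", LONG, "long_csv"),
        ("b.csv", WIDE, "wide_csv"),
        ("c.csv", BIOSCREEN, "bioscreen"),
        ("d.csv", PLATER, "plater_design"),
        ("e.csv", GENERIC_DESIGN, "generic_design_csv"),
    ],
)
def test_each_dialect_is_claimed_by_exactly_one_reader(tmp_path, name, text, expected):
    assert detect_format(_write(tmp_path, name, text)) == expected


def test_detection_is_content_based_not_filename_based(tmp_path):
    # a bioscreen file masquerading under a design-like name
    p = _write(tmp_path, "plate_design.csv", BIOSCREEN)
    assert detect_format(p) == "bioscreen"


def test_unrecognized_format_echoes_the_first_line(tmp_path):
    p = _write(tmp_path, "x.csv", "utter,nonsense\n1,2\n")
    with pytest.raises(FormatError, match="utter,nonsense"):
        detect_format(p)


def test_semicolon_delimited_and_bom_inputs_are_accepted(tmp_path):
    text = "﻿well;runtime;measure\nA1;0;0.1\nA1;900;0.2\n"
    p = _write(tmp_path, "semi.csv", text)
    assert detect_format(p) == "long_csv"
    tm = read_measures_long_csv(p)
    assert len(tm) == 2


# ---------------------------------------------------------------------------
# Long CSV


def test_long_csv_defaults_and_normalization(tmp_path):
    tm = read_measures_long_csv(_write(tmp_path, "run7.csv", LONG))
    assert len(tm) == 6
    assert set(tm.data["run"]) == {"run7"}  # file stem
    assert set(tm.data["plate"]) == {"1"}
    assert set(tm.data["well"]) == {"A01", "A02"}  # labels canonicalized


def test_long_csv_measure_type_keeps_keys_unique(tmp_path):
    text = (
        "well,runtime,measure,measure_type\n"
        "A1,0,0.1,OD595\nA1,0,7.0,lum\nA1,900,0.2,OD595\n"
    )
    tm = read_measures_long_csv(_write(tmp_path, "m.csv", text))
    assert len(tm) == 3


def test_long_csv_duplicate_keys_error(tmp_path):
    text = "well,runtime,measure\nA1,0,0.1\nA1,0,0.2\n"
    with pytest.raises(ValueError, match="duplicate"):
        read_measures_long_csv(_write(tmp_path, "m.csv", text))


def test_long_csv_non_numeric_measure_is_row_addressed(tmp_path):
    text = "well,runtime,measure\nA1,0,0.1\nA1,900,oops\n"
    with pytest.raises(FormatError, match="line 3"):
        read_measures_long_csv(_write(tmp_path, "m.csv", text))


# ---------------------------------------------------------------------------
# Wide CSV


def test_wide_csv_melts_and_drops_blank_cells(tmp_path):
    tm = read_measures_wide_csv(_write(tmp_path, "w.csv", WIDE))
    assert len(tm) == 5  # one blank cell dropped
    t, y = tm.well_series("w", "1", "A02")
    np.testing.assert_allclose(t, [0.0, 1800.0])
    np.testing.assert_allclose(y, [0.2, 0.5])


def test_wide_csv_repeated_well_header_errors(tmp_path):
    text = "time,A01,a1\n0,0.1,0.2\n"
    with pytest.raises(FormatError, match="repeated"):
        read_measures_wide_csv(_write(tmp_path, "w.csv", text))


def test_wide_csv_hms_times_convert_to_requested_unit(tmp_path):
    text = "time,A01\n00:00:00,0.1\n00:15:00,0.2\n"
    tm = read_measures_wide_csv(_write(tmp_path, "w.csv", text), unit="minutes")
    np.testing.assert_allclose(tm.data["runtime"], [0.0, 15.0])


def test_parse_hms():
    assert parse_hms("00:15:00") == 900.0
    assert parse_hms("2:00:30") == 7230.0
    with pytest.raises(FormatError):
        parse_hms("15:99")


# ---------------------------------------------------------------------------
# Bioscreen


def test_bioscreen_splits_wells_into_two_plates(tmp_path):
    tm = read_measures_bioscreen(_write(tmp_path, "b.csv", BIOSCREEN), unit="minutes")
    assert len(tm) == 6
    assert set(zip(tm.data["plate"], tm.data["well"])) == {
        ("1", "1"), ("1", "2"), ("2", "1"),
    }
    np.testing.assert_allclose(sorted(tm.data["runtime"].unique()), [0.0, 15.0])


def test_bioscreen_well_over_200_errors(tmp_path):
    text = "Time,201\n00:00:00,0.1\n"
    with pytest.raises(FormatError, match="201"):
        read_measures_bioscreen(_write(tmp_path, "b.csv", text))


# ---------------------------------------------------------------------------
# plater designs


def test_plater_single_block(tmp_path):
    d = read_design_plater(_write(tmp_path, "d.csv", PLATER))
    assert len(d) == 96
    assert set(d.columns) == {"well", "strain"}
    assert (d["strain"] == "BY").all()


def test_plater_two_blocks_and_missing_cells(tmp_path):
    text = (
        "drug,1,2\nA,d1,d2\nB,d1,d2\n"
        "\n"
        "dose_uM,1,2\nA,50,25\nB,50,\n"
    )
    d = read_design_plater(_write(tmp_path, "d.csv", text))
    assert set(d.columns) == {"well", "drug", "dose_uM"}
    assert d.set_index("well").loc["B01", "drug"] == "d1"
    assert pd.isna(d.set_index("well").loc["B02", "dose_uM"])


def test_plater_ragged_block_errors(tmp_path):
    text = "v,1,2\nA,x,y,z\n"
    with pytest.raises(FormatError, match="ragged"):
        read_design_plater(_write(tmp_path, "d.csv", text))


def test_plater_shape_mismatch_between_blocks_errors(tmp_path):
    text = "v,1,2\nA,x,y\n\nw,1,2,3\nA,x,y,z\n"
    with pytest.raises(FormatError, match="shape"):
        read_design_plater(_write(tmp_path, "d.csv", text))


# ---------------------------------------------------------------------------
# Joining heuristics


def _two_run_files(tmp_path):
    m1 = _write(tmp_path, "run1.csv", LONG)
    m2 = _write(tmp_path, "run2.csv", LONG.replace("0.1", "0.9"))
    d1 = _write(tmp_path, "run1_design.csv", GENERIC_DESIGN)
    d2 = _write(tmp_path, "run2_design.csv", GENERIC_DESIGN.replace("BY", "YB"))
    return m1, m2, d1, d2


def test_two_files_one_design_single_run(tmp_path):
    m1, _, d1, _ = _two_run_files(tmp_path)
    tm = join_experiment([m1, d1])
    assert set(tm.data["run"]) == {"run1"}
    assert tm.design_columns == ["dose", "strain"]
    assert len(tm) == 6  # join adds columns, never rows


def test_many_measures_one_design_joins_onto_each(tmp_path):
    m1, m2, d1, _ = _two_run_files(tmp_path)
    tm = join_experiment([m1, m2, d1])
    assert set(tm.data["run"]) == {"run1", "run2"}
    for run in ("run1", "run2"):
        sub = tm.data[tm.data["run"] == run]
        assert sub.loc[sub["well"] == "A01", "strain"].iloc[0] == "BY"


def test_designs_match_measures_by_stem_prefix(tmp_path):
    m1, m2, d1, d2 = _two_run_files(tmp_path)
    tm = join_experiment([m1, d1, m2, d2])
    s1 = tm.data[(tm.data["run"] == "run1") & (tm.data["well"] == "A01")]["strain"].iloc[0]
    s2 = tm.data[(tm.data["run"] == "run2") & (tm.data["well"] == "A01")]["strain"].iloc[0]
    assert (s1, s2) == ("BY", "YB")


def test_unmatched_design_warns_and_is_ignored(tmp_path):
    m1, _, d1, _ = _two_run_files(tmp_path)
    stray = _write(tmp_path, "elsewhere_design.csv", GENERIC_DESIGN)
    m3 = _write(tmp_path, "zzz.csv", LONG)
    with pytest.warns(UserWarning, match="matched no measures"):
        tm = join_experiment([m1, m3, d1, stray])
    assert set(tm.data["run"]) == {"run1", "zzz"}


def test_design_wells_absent_from_measures_warn_and_drop(tmp_path):
    m1 = _write(tmp_path, "run1.csv", LONG)
    d = _write(tmp_path, "run1_design.csv", GENERIC_DESIGN + "H08,ghost,1\n")
    with pytest.warns(UserWarning, match="absent"):
        tm = join_experiment([m1, d])
    assert len(tm) == 6
    assert "ghost" not in set(tm.data["strain"])


def test_measures_wells_without_design_get_missing_values(tmp_path):
    m1 = _write(tmp_path, "run1.csv", LONG)
    d = _write(tmp_path, "run1_design.csv", "well,strain\nA01,BY\n")
    tm = join_experiment([m1, d])
    sub = tm.data[tm.data["well"] == "A02"]
    assert sub["strain"].isna().all()


def test_no_measures_file_is_fatal(tmp_path):
    d = _write(tmp_path, "d.csv", GENERIC_DESIGN)
    with pytest.raises(FormatError, match="no measures"):
        join_experiment([d])


# ---------------------------------------------------------------------------
# Cross-dialect equivalence on synthetic fixtures


def _normalized(tm):
    df = tm.data.copy()
    for c in ("strain", "drug", "dose_uM"):
        if c in df.columns:
            df[c] = df[c].astype(str).str.replace(r"\.0$", "", regex=True)
    key = ["run", "plate", "well", "runtime"]
    return df.sort_values(key).reset_index(drop=True)


def test_every_dialect_round_trips_to_the_same_tidy_table(tmp_path):
    sim = simulate_experiment(SimConfig(seed=3, n_cycles=10, noise_sd=0.01))
    tables = {}
    for dialect in ("long_csv", "wide_csv"):
        d = tmp_path / dialect
        files = emit_fixture_files(sim, dialect, d)
        tables[dialect] = join_experiment([str(f) for f in files])
    ref = _normalized(tables["long_csv"])
    for dialect, tm in tables.items():
        got = _normalized(tm)
        pd.testing.assert_frame_equal(
            got[["run", "plate", "well", "runtime", "measure"]],
            ref[["run", "plate", "well", "runtime", "measure"]],
        )
        pd.testing.assert_frame_equal(got[["strain", "drug"]], ref[["strain", "drug"]])


def test_bioscreen_fixture_round_trips(tmp_path):
    cfg = SimConfig(seed=5, n_cycles=8, shape=PlateShape(n_numeric_wells=100),
                    noise_sd=0.005)
    sim = simulate_experiment(cfg)
    files = emit_fixture_files(sim, "bioscreen", tmp_path)
    assert detect_format(files[0]) == "bioscreen"
    tm = join_experiment([str(f) for f in files])
    ref = _normalized(sim.measures)
    got = _normalized(tm)
    pd.testing.assert_frame_equal(
        got[["run", "plate", "well", "runtime", "measure"]],
        ref[["run", "plate", "well", "runtime", "measure"]],
    )
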
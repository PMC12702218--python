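"""Domain types, isolation-window arithmetic and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harmolib import io
from harmolib.errors import ConfigError, FormatError, IntegrityError, OutOfRangeError
from harmolib.evaluation import random_library
from harmolib.model import (
    ChromatogramSet,
    ChromatogramTrace,
    IsolationScheme,
    PipelineConfig,
    QuantTable,
)
from tests.conftest import make_meta


class TestIsolationWindows:
    def test_staggered_interior_precursor_hits_two_windows(self, wide_scheme):
        idx = wide_scheme.windows_for_precursor(417.0)
        bounds = {wide_scheme.windows[i] for i in idx}
        assert bounds == {(416.0, 432.0), (408.0, 424.0)}

    def test_half_open_boundary_belongs_to_higher_window(self):
        scheme = IsolationScheme(400.0, 1000.0, 16.0, staggered=False)
        idx = scheme.windows_for_precursor(416.0)
        assert {scheme.windows[i] for i in idx} == {(416.0, 432.0)}

    def test_out_of_range_precursor_rejected(self, wide_scheme):
        with pytest.raises(OutOfRangeError):
            wide_scheme.windows_for_precursor(399.0)
        with pytest.raises(OutOfRangeError):
            wide_scheme.demux_index(1000.0)

    @given(
        start=st.floats(300, 500),
        width=st.floats(2, 30),
        staggered=st.booleans(),
        frac=st.floats(0.0, 1.0, exclude_max=True),
    )
    @settings(max_examples=200, deadline=None)
    def test_window_lookup_matches_brute_force(self, start, width, staggered, frac):
        scheme = IsolationScheme(start, start + 37 * width, width, staggered)
        mz = min(
            start + frac * (scheme.end_mz - start),
            np.nextafter(scheme.end_mz, -np.inf),
        )
        got = scheme.windows_for_precursor(mz)
        expected = {
            i for i, (a, b) in enumerate(scheme.windows) if a <= mz < b
        }
        assert got == expected
        interior = start + width / 2 <= mz < scheme.end_mz - width / 2
        if staggered and interior:
            assert len(got) == 2
        assert 1 <= len(got) <= 2


class TestLibraryIO:
    def test_round_trip_preserves_all_fields(self, tmp_path, rng):
        lib = random_library(rng, 40, matrix_id="urine")
        for e in lib.entries[:5]:
            for f in e.fragments[:2]:
                f.quant_flag = "quant"
        path = tmp_path / "lib.tsv"
        io.write_library(lib, path)
        back = io.read_library(path)
        assert back.matrix_id == lib.matrix_id
        assert back.entries == lib.entries

    def test_round_trip_large_library(self, tmp_path):
        rng = np.random.default_rng(5)
        lib = random_library(rng, 400, matrix_id="serum")
        path = tmp_path / "big.tsv"
        io.write_library(lib, path)
        assert io.read_library(path).entries == lib.entries

    def test_single_precursor_parse(self, tmp_path, rng):
        lib = random_library(rng, 1)
        n_frag = len(lib.entries[0].fragments)
        path = tmp_path / "one.tsv"
        io.write_library(lib, path)
        back = io.read_library(path)
        assert len(back.entries) == 1
        assert len(back.entries[0].fragments) == n_frag

    def test_header_only_file_yields_empty_library(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("\t".join(io.LIBRARY_COLUMNS) + "\n")
        assert len(io.read_library(path).entries) == 0

    def test_missing_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        cols = [c for c in io.LIBRARY_COLUMNS if c != "fragment_mz"]
        path.write_text("\t".join(cols) + "\n")
        with pytest.raises(FormatError, match="fragment_mz"):
            io.read_library(path)

    def test_malformed_row_names_line_and_column(self, tmp_path, rng):
        lib = random_library(rng, 1)
        path = tmp_path / "rowbad.tsv"
        io.write_library(lib, path)
        lines = path.read_text().splitlines()
        fields = lines[1].split("\t")
        fields[io.LIBRARY_COLUMNS.index("fragment_mz")] = ""
        lines[1] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(FormatError, match=r"line 2.*fragment_mz"):
            io.read_library(path)

    def test_conflicting_duplicate_scores_rejected(self, tmp_path, rng):
        lib = random_library(rng, 1)
        path = tmp_path / "dup.tsv"
        io.write_library(lib, path)
        lines = path.read_text().splitlines()
        fields = lines[2].split("\t")
        fields[io.LIBRARY_COLUMNS.index("score")] = "99.9"
        lines[2] = "\t".join(fields)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(IntegrityError, match="conflicting scores"):
            io.read_library(path)


class TestChromatogramAndQuantIO:
    def test_chromatogram_round_trip(self, tmp_path):
        traces = [
            ChromatogramTrace(
                run_id="r1",
                matrix_id="urine",
                peptide="PEPTIDEK",
                precursor_charge=2,
                fragment_key=("y", o, 1),
                times=np.array([0.0, 0.5, 1.0, 1.5]),
                intensities=np.array([0.0, 5.25, 9.125, 1.0]),
            )
            for o in (3, 4)
        ]
        chroms = ChromatogramSet(traces)
        path = tmp_path / "chroms.csv"
        io.write_chromatograms(chroms, path)
        back = io.read_chromatograms(path)
        assert len(back) == 2
        t = back.precursor_traces("r1", "PEPTIDEK", 2)[("y", 4, 1)]
        np.testing.assert_array_equal(t.times, traces[1].times)
        np.testing.assert_array_equal(t.intensities, traces[1].intensities)

    def test_quant_table_round_trip_keeps_missing_values(self, tmp_path):
        import pandas as pd

        values = pd.DataFrame(
            {"r1": [1.5, np.nan], "r2": [2.0, 3.0]}, index=["pepA", "pepB"]
        )
        meta = make_meta(["r1", "r2"], ["urine", "serum"], ["h", "d"])
        table = QuantTable(values=values, meta=meta)
        io.write_quant_table(table, tmp_path / "q.tsv", tmp_path / "m.csv")
        back = io.read_quant_table(tmp_path / "q.tsv", tmp_path / "m.csv")
        assert back.scale == "linear"
        assert back.row_kind == "peptide"
        pd.testing.assert_frame_equal(back.values, values)
        assert np.isnan(back.values.loc["pepB", "r1"])


class TestPipelineConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fdr_alpha": 0.0},
            {"fdr_alpha": 1.5},
            {"ppm_tolerance": -1.0},
            {"min_quant_ions": 6, "max_quant_ions": 5},
            {"cofragmentation_rule": "other"},
            {"correlation_aggregation": "median"},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            PipelineConfig(**kwargs)

    def test_scheme_round_trip(self, tmp_path, wide_scheme):
        io.write_scheme(wide_scheme, tmp_path / "s.json")
        assert io.read_scheme(tmp_path / "s.json") == wide_scheme
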
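"""Peak integration, log2 normalization and protein roll-up."""

import math

import numpy as np
import pandas as pd
import pytest

from harmolib.errors import BoundaryError, ConfigError, NormalizationError
from harmolib.model import ChromatogramTrace, FragmentIon, LibraryEntry, QuantTable
from harmolib.quantify import (
    PeakBoundary,
    integrate_peptide,
    normalize_log2,
    rollup_protein,
)
from tests.conftest import make_meta


def _gauss_trace(key, amp=100.0, sigma=5.0, apex=100.0, dt=0.5, span=4.0):
    times = np.arange(apex - span * sigma, apex + span * sigma + dt / 2, dt)
    return ChromatogramTrace(
        run_id="r1",
        matrix_id="urine",
        peptide="AAAAAAK",
        precursor_charge=2,
        fragment_key=key,
        times=times,
        intensities=amp * np.exp(-0.5 * ((times - apex) / sigma) ** 2),
    )


def _entry(n_quant=1, n_total=None):
    n_total = n_total or n_quant
    frags = [
        FragmentIon(
            "y", i + 2, 1, 400.0 + i, 1.0,
            quant_flag="quant" if i < n_quant else "detection_only",
        )
        for i in range(n_total)
    ]
    return LibraryEntry(
        peptide="AAAAAAK",
        precursor_charge=2,
        precursor_mz=500.0,
        score=5.0,
        is_decoy=False,
        matrix_id="urine",
        rt=100.0,
        fragments=frags,
    )


BOUNDARY = PeakBoundary("AAAAAAK", "r1", 100.0 - 18.0, 100.0 + 18.0)


class TestIntegration:
    def test_gaussian_area_matches_closed_form(self):
        traces = {("y", 2, 1): _gauss_trace(("y", 2, 1))}
        area = integrate_peptide(traces, _entry(1), BOUNDARY)
        expected = 100.0 * 5.0 * math.sqrt(2 * math.pi)
        # +-3 sigma boundary carries 99.73% of the mass
        assert area == pytest.approx(expected, rel=0.01)

    def test_two_identical_quant_ions_double_the_area(self):
        one = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1))}, _entry(1), BOUNDARY
        )
        two = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1)),
             ("y", 3, 1): _gauss_trace(("y", 3, 1))},
            _entry(2),
            BOUNDARY,
        )
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_linear_in_amplitude_and_grid_invariant(self):
        a1 = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1), amp=50.0)}, _entry(1), BOUNDARY
        )
        a2 = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1), amp=200.0)}, _entry(1), BOUNDARY
        )
        assert a2 == pytest.approx(4 * a1, rel=1e-9)
        fine = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1), dt=0.05)}, _entry(1), BOUNDARY
        )
        coarse = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1), dt=1.0)}, _entry(1), BOUNDARY
        )
        assert coarse == pytest.approx(fine, rel=0.01)

    def test_all_zero_traces_integrate_to_zero(self):
        traces = {("y", 2, 1): _gauss_trace(("y", 2, 1), amp=0.0)}
        assert integrate_peptide(traces, _entry(1), BOUNDARY) == 0.0

    def test_no_quant_ions_is_missing_not_zero(self):
        entry = _entry(0, 3)
        traces = {("y", 2, 1): _gauss_trace(("y", 2, 1))}
        assert integrate_peptide(traces, entry, BOUNDARY) is None

    def test_missing_trace_contributes_zero(self):
        entry = _entry(2)
        one = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1))}, entry, BOUNDARY
        )
        both = integrate_peptide(
            {("y", 2, 1): _gauss_trace(("y", 2, 1)),
             ("y", 3, 1): _gauss_trace(("y", 3, 1))},
            entry,
            BOUNDARY,
        )
        assert one == pytest.approx(both / 2)

    def test_boundary_outside_trace_range_rejected(self):
        traces = {("y", 2, 1): _gauss_trace(("y", 2, 1))}
        far = PeakBoundary("AAAAAAK", "r1", 500.0, 536.0)
        with pytest.raises(BoundaryError):
            integrate_peptide(traces, _entry(1), far)
        with pytest.raises(BoundaryError):
            PeakBoundary("AAAAAAK", "r1", 100.0, 90.0)


def _table(values: dict, matrices=None, groups=None, subjects=None):
    df = pd.DataFrame(values)
    runs = list(df.columns)
    meta = make_meta(
        runs,
        matrices or ["urine"] * len(runs),
        groups,
        subjects,
    )
    return QuantTable(values=df, meta=meta)


class TestNormalization:
    def test_scaled_run_becomes_identical(self):
        t = _table({"a": [1.0, 4.0, 16.0], "b": [2.0, 8.0, 32.0]})
        norm = normalize_log2(t)
        np.testing.assert_allclose(norm.values["a"], norm.values["b"])
        assert norm.scale == "log2"

    def test_centered_table_is_a_fixed_point(self):
        t = _table({"a": [2.0, 8.0], "b": [4.0, 4.0]})
        norm = normalize_log2(t)
        # complete-case run means are equal afterwards
        assert norm.values["a"].mean() == pytest.approx(
            norm.values["b"].mean(), abs=1e-9
        )
        again_linear = QuantTable(values=2.0**norm.values, meta=t.meta)
        twice = normalize_log2(again_linear)
        pd.testing.assert_frame_equal(twice.values, norm.values)

    def test_rank_order_preserved_within_run(self):
        rng = np.random.default_rng(8)
        vals = pd.DataFrame(
            rng.lognormal(3, 1, size=(30, 4)), columns=list("abcd")
        )
        t = _table({c: vals[c] for c in vals.columns})
        norm = normalize_log2(t)
        for c in vals.columns:
            assert (
                norm.values[c].rank() == t.values[c].rank()
            ).all()

    def test_missing_values_stay_missing(self):
        t = _table({"a": [1.0, np.nan, 4.0], "b": [2.0, 3.0, 8.0]})
        norm = normalize_log2(t)
        assert np.isnan(norm.values.loc[1, "a"])
        assert norm.values.notna().sum().sum() == 5

    def test_no_complete_cases_rejected(self):
        t = _table({"a": [1.0, np.nan], "b": [np.nan, 3.0]})
        with pytest.raises(NormalizationError):
            normalize_log2(t)


class TestRollup:
    def test_unique_peptides_sum(self):
        t = _table({"r1": [10.0, 20.0, 30.0]})
        t.values.index = ["p1", "p2", "p3"]
        prot = rollup_protein(t, {"p1": "A", "p2": "A", "p3": "A"})
        assert prot.values.loc["A", "r1"] == 60.0
        assert prot.row_kind == "protein"

    def test_shared_peptide_contributes_to_neither_protein(self):
        t = _table({"r1": [10.0, 5.0]})
        t.values.index = ["unique", "shared"]
        prot = rollup_protein(
            t, {"unique": "A", "shared": ["A", "B"]}
        )
        assert prot.values.loc["A", "r1"] == 10.0
        assert "B" not in prot.values.index

    def test_total_protein_signal_bounded_by_peptide_signal(self):
        rng = np.random.default_rng(21)
        vals = pd.DataFrame(rng.lognormal(2, 1, (20, 3)), columns=list("xyz"))
        t = _table({c: vals[c] for c in vals.columns})
        t.values.index = [f"pep{i}" for i in range(20)]
        pmap = {f"pep{i}": f"P{i % 4}" if i % 5 else ["P0", "P1"] for i in range(20)}
        prot = rollup_protein(t, pmap)
        assert (prot.values.sum() <= t.values.sum() + 1e-9).all()

    def test_empty_map_rejected(self):
        t = _table({"r1": [1.0]})
        with pytest.raises(ConfigError):
            rollup_protein(t, {})
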
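"""Interference screening, peak-shape scoring and quant-ion selection."""

import numpy as np
import pytest

from harmolib.errors import InsufficientTracesError
from harmolib.evaluation import (
    brute_force_flags,
    implementation_flags,
    random_library,
)
from harmolib.model import (
    ChromatogramTrace,
    FragmentIon,
    LibraryEntry,
    PipelineConfig,
    SpectralLibrary,
)
from harmolib.transitions import (
    find_cofragmenting,
    peak_shape_correlation,
    select_quant_ions,
)


def _entry(pep, prec_mz, rt, frag_mzs, matrix="urine", charge=2):
    return LibraryEntry(
        peptide=pep,
        precursor_charge=charge,
        precursor_mz=prec_mz,
        score=5.0,
        is_decoy=False,
        matrix_id=matrix,
        rt=rt,
        fragments=[
            FragmentIon("y", i + 2, 1, mz, 1.0) for i, mz in enumerate(frag_mzs)
        ],
    )


class TestFindCofragmenting:
    def test_lone_analyte_has_no_flags(self, cfg):
        analyte = _entry("AAAAAAK", 500.25, 1000.0, [700.35, 800.4])
        lib = SpectralLibrary("urine", [analyte])
        reports = find_cofragmenting(analyte, lib, cfg.wide_scheme, cfg)
        assert not any(r.flagged for r in reports.values())

    def test_constructed_interferer_is_flagged_with_details(self, cfg):
        analyte = _entry("AAAAAAK", 500.25, 1000.0, [700.350, 800.4])
        interferer = _entry("CCCCCCK", 505.10, 1010.0, [700.352, 900.0])
        lib = SpectralLibrary("urine", [analyte, interferer])
        reports = find_cofragmenting(analyte, lib, cfg.wide_scheme, cfg)
        rep = reports[("y", 2, 1)]  # the 700.350 fragment
        assert rep.flagged
        (hit,) = rep.interferers
        assert hit.peptide == "CCCCCCK"
        assert hit.ppm_distance == pytest.approx(2.857, abs=0.01)
        assert hit.delta_rt == pytest.approx(10.0)
        assert not reports[("y", 3, 1)].flagged

    def test_late_eluting_interferer_not_flagged(self, cfg):
        analyte = _entry("AAAAAAK", 500.25, 1000.0, [700.350])
        interferer = _entry("CCCCCCK", 505.10, 1120.0, [700.352])
        lib = SpectralLibrary("urine", [analyte, interferer])
        reports = find_cofragmenting(analyte, lib, cfg.wide_scheme, cfg)
        assert not reports[("y", 2, 1)].flagged

    @pytest.mark.parametrize("rule", ["union", "demultiplexed"])
    def test_matches_brute_force_on_random_libraries(self, rule):
        rng = np.random.default_rng(99)
        cfg = PipelineConfig(cofragmentation_rule=rule)
        for _ in range(3):
            lib = random_library(rng, 120)
            assert implementation_flags(
                lib, cfg.wide_scheme, cfg
            ) == brute_force_flags(lib, cfg.wide_scheme, cfg)

    def test_union_rule_flags_superset_of_demultiplexed(self):
        rng = np.random.default_rng(17)
        lib = random_library(rng, 200)
        cfg_u = PipelineConfig(cofragmentation_rule="union")
        cfg_d = PipelineConfig(cofragmentation_rule="demultiplexed")
        union = implementation_flags(lib, cfg_u.wide_scheme, cfg_u)
        demux = implementation_flags(lib, cfg_d.wide_scheme, cfg_d)
        assert demux <= union


def _trace(key, apex, amp=100.0, sigma=5.0, t0=950.0, t1=1050.0):
    times = np.arange(t0, t1, 0.5)
    return ChromatogramTrace(
        run_id="r1",
        matrix_id="urine",
        peptide="AAAAAAK",
        precursor_charge=2,
        fragment_key=key,
        times=times,
        intensities=amp * np.exp(-0.5 * ((times - apex) / sigma) ** 2),
    )


class TestPeakShapeCorrelation:
    def test_identical_gaussians_correlate_perfectly(self):
        traces = {("y", o, 1): _trace(("y", o, 1), 1000.0) for o in range(2, 6)}
        corr = peak_shape_correlation(traces)
        assert all(c == pytest.approx(1.0, abs=1e-9) for c in corr.values())

    def test_shifted_apex_scores_strictly_lowest(self):
        traces = {("y", o, 1): _trace(("y", o, 1), 1000.0) for o in range(2, 5)}
        traces[("y", 9, 1)] = _trace(("y", 9, 1), 1015.0)  # 3 sigma shift
        corr = peak_shape_correlation(traces)
        shifted = corr.pop(("y", 9, 1))
        assert shifted < min(corr.values())

    def test_zero_variance_trace_gets_zero(self):
        traces = {("y", o, 1): _trace(("y", o, 1), 1000.0) for o in (2, 3)}
        flat = _trace(("y", 8, 1), 1000.0, amp=0.0)
        traces[("y", 8, 1)] = flat
        corr = peak_shape_correlation(traces)
        assert corr[("y", 8, 1)] == 0.0

    def test_fewer_than_two_traces_rejected(self):
        with pytest.raises(InsufficientTracesError):
            peak_shape_correlation({("y", 2, 1): _trace(("y", 2, 1), 1000.0)})


class TestSelectQuantIons:
    def _fragments(self, n, intensity=1.0):
        return [
            FragmentIon("y", i + 2, 1, 300.0 + 50 * i, intensity)
            for i in range(n)
        ]

    def test_eight_clean_ions_yield_exactly_five(self, cfg):
        frags = self._fragments(8)
        scores = {"urine": {f.key: 0.9 + 0.01 * i for i, f in enumerate(frags)}}
        quant, detection, ok = select_quant_ions(frags, scores, {}, cfg)
        assert ok and len(quant) == 5
        assert set(quant) | set(detection) == {f.key for f in frags}
        assert not set(quant) & set(detection)
        # highest-correlation ions selected
        assert quant == [f.key for f in frags[::-1][:5]]

    def test_two_clean_ions_make_peptide_unquantifiable(self, cfg):
        frags = self._fragments(6)
        flagged = {f.key: True for f in frags[2:]}
        quant, detection, ok = select_quant_ions(
            frags, {"urine": {f.key: 0.9 for f in frags}}, flagged, cfg
        )
        assert not ok
        assert quant == []
        assert set(detection) == {f.key for f in frags}

    def test_full_tie_breaks_by_ascending_mz(self, cfg):
        frags = self._fragments(4)
        scores = {"urine": {f.key: 0.5 for f in frags}}
        quant, _, ok = select_quant_ions(frags, scores, {}, cfg)
        assert ok
        mzs = {f.key: f.mz for f in frags}
        assert [mzs[k] for k in quant] == sorted(mzs[k] for k in quant)

    def test_min_aggregation_uses_worst_matrix(self, cfg):
        frags = self._fragments(3)
        scores = {
            "urine": {f.key: 0.9 for f in frags},
            "serum": {frags[0].key: 0.1, frags[1].key: 0.8, frags[2].key: 0.85},
        }
        quant, _, ok = select_quant_ions(frags, scores, {}, cfg)
        assert ok
        assert quant[-1] == frags[0].key  # dragged down by its worst matrix
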
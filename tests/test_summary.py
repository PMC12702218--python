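"""Catalog summaries: top biofluids, overlaps, deltas, fold changes, t test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from harmolib.errors import HarmolibError
from harmolib.model import QuantTable
from harmolib.summary import (
    compute_deltas,
    fold_change_table,
    group_ttest_table,
    overlap_partition,
    protein_summary,
    top_biofluids,
    two_group_ttest,
)
from tests.conftest import make_meta


class TestTopBiofluids:
    def test_half_of_peak_is_inclusive(self):
        means = {"urine": 100.0, "plasma": 50.0, "serum": 49.9}
        assert top_biofluids(means) == {"urine", "plasma"}

    def test_equal_means_include_every_fluid(self):
        assert top_biofluids({"u": 7.0, "p": 7.0, "s": 7.0}) == {"u", "p", "s"}

    def test_single_quantified_fluid(self):
        assert top_biofluids({"u": 3.0, "p": float("nan")}) == {"u"}

    def test_all_missing_rejected(self):
        with pytest.raises(HarmolibError):
            top_biofluids({"u": float("nan")})

    @given(
        scale=st.floats(1e-3, 1e6),
        vals=st.lists(st.floats(0.1, 1e6), min_size=1, max_size=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_to_uniform_positive_scaling(self, scale, vals):
        means = {f"f{i}": v for i, v in enumerate(vals)}
        scaled = {k: v * scale for k, v in means.items()}
        assert top_biofluids(means) == top_biofluids(scaled)


class TestOverlapPartition:
    def test_hand_enumerated_three_set_example(self):
        part = overlap_partition(
            {"U": {"a", "b", "c"}, "P": {"b", "c", "d"}, "S": {"c", "d", "e"}}
        )
        assert part[("U",)] == 1
        assert part[("P",)] == 0
        assert part[("S",)] == 1
        assert part[("P", "U")] == 1
        assert part[("S", "U")] == 0
        assert part[("P", "S")] == 1
        assert part[("P", "S", "U")] == 1

    def test_identical_sets_fill_only_the_triple_region(self):
        s = set(range(17))
        part = overlap_partition({"U": set(s), "P": set(s), "S": set(s)})
        assert part[("P", "S", "U")] == 17
        assert sum(part.values()) == 17

    def test_disjoint_sets_fill_only_unique_regions(self):
        part = overlap_partition({"U": {1}, "P": {2, 3}, "S": {4, 5, 6}})
        assert (part[("U",)], part[("P",)], part[("S",)]) == (1, 2, 3)
        assert sum(part.values()) == 6

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_regions_partition_the_union(self, data):
        ints = st.sets(st.integers(0, 40), max_size=25)
        sets = {k: data.draw(ints) for k in ("U", "P", "S")}
        part = overlap_partition(sets)
        assert sum(part.values()) == len(set.union(*sets.values()))


def _paired_table(a_vals, b_vals, scale="log2"):
    runs = ["uA", "uB", "sA", "sB"]
    df = pd.DataFrame(
        {"uA": a_vals[0], "uB": a_vals[1], "sA": b_vals[0], "sB": b_vals[1]},
        index=[f"prot{i}" for i in range(len(a_vals[0]))],
    )
    meta = make_meta(runs, ["urine", "urine", "serum", "serum"],
                     subjects=["A", "B", "A", "B"])
    return QuantTable(values=df, meta=meta, scale=scale, row_kind="protein")


class TestFoldChangesAndDeltas:
    def test_identical_fluid_columns_give_zero_fold_change(self):
        t = _paired_table(([1.0, 2.0], [3.0, 4.0]), ([1.0, 2.0], [3.0, 4.0]))
        fc = fold_change_table(t, "urine", "serum")
        assert np.allclose(fc["delta_log2"], 0.0)

    def test_four_fold_linear_ratio_gives_delta_two(self):
        urine = ([10.0], [12.0])
        serum = ([8.0], [10.0])  # log2 units: urine - serum = 2 per subject
        t = _paired_table(urine, serum)
        fc = fold_change_table(t, "urine", "serum")
        assert fc.loc["prot0", "delta_log2"] == pytest.approx(2.0)

    def test_rows_missing_in_either_fluid_are_omitted(self):
        t = _paired_table(
            ([1.0, 5.0], [2.0, 6.0]), ([1.0, np.nan], [2.0, np.nan])
        )
        fc = fold_change_table(t, "urine", "serum")
        assert list(fc.index) == ["prot0"]

    def test_identical_paired_values_give_zero_deltas(self):
        t = _paired_table(([4.0, 7.0], [5.0, 8.0]), ([4.0, 7.0], [5.0, 8.0]))
        deltas = compute_deltas(t)
        assert (deltas["delta"] == 0.0).all()

    def test_single_pair_arithmetic(self):
        t = _paired_table(([8.0], [8.0]), ([3.0], [3.0]))
        deltas = compute_deltas(t)
        assert set(deltas["delta"]) == {5.0}

    def test_row_count_matches_brute_force(self):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(2, 1, size=(6, 6))
        vals[rng.random((6, 6)) < 0.3] = np.nan
        runs = [f"{m}_{s}" for m in ("u", "p", "s") for s in ("A", "B")]
        df = pd.DataFrame(vals, columns=runs,
                          index=[f"prot{i}" for i in range(6)])
        meta = make_meta(runs, ["u", "u", "p", "p", "s", "s"],
                         subjects=["A", "B"] * 3)
        t = QuantTable(values=df, meta=meta, row_kind="protein")
        deltas = compute_deltas(t)
        expected = 0
        fluids = ["p", "s", "u"]
        for i in range(6):
            for fa, fb in [("p", "s"), ("p", "u"), ("s", "u")]:
                for s in ("A", "B"):
                    va = df.loc[f"prot{i}", f"{fa}_{s}"]
                    vb = df.loc[f"prot{i}", f"{fb}_{s}"]
                    if not (np.isnan(va) or np.isnan(vb)):
                        expected += 1
        assert len(deltas) == expected


class TestTwoGroupTTest:
    def test_identical_groups_give_t_zero_p_one(self):
        assert two_group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_hand_computed_case(self):
        t, p = two_group_ttest([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert t == pytest.approx(-1.224745, abs=1e-5)
        ref = 2 * stats.t.sf(abs(t), 4)
        assert p == pytest.approx(ref, abs=1e-12)
        assert p == pytest.approx(0.288, abs=1e-3)

    def test_group_swap_negates_t_and_preserves_p(self):
        t1, p1 = two_group_ttest([1.0, 5.0, 2.0], [4.0, 4.5, 6.0])
        t2, p2 = two_group_ttest([4.0, 4.5, 6.0], [1.0, 5.0, 2.0])
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_matches_reference_implementation_on_random_inputs(self):
        rng = np.random.default_rng(6)
        for _ in range(1000):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(loc=rng.normal(), size=rng.integers(2, 12))
            t, p = two_group_ttest(a, b)
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert t == pytest.approx(ref.statistic, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_degenerate_variance_conventions(self):
        with pytest.warns(UserWarning):
            t, p = two_group_ttest([1.0, 1.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0
        with pytest.raises(HarmolibError):
            two_group_ttest([1.0], [2.0, 3.0])


class TestTables:
    def test_protein_summary_marks_top_fluids(self):
        t = _paired_table(([100.0, 10.0], [100.0, 10.0]),
                          ([49.0, 10.0], [49.0, 10.0]), scale="linear")
        psum = protein_summary(t).set_index("row_id")
        assert psum.loc["prot0", "top_fluids"] == "urine"
        assert psum.loc["prot1", "top_fluids"] == "serum;urine"

    def test_group_ttest_table_runs_per_row(self):
        runs = [f"r{i}" for i in range(6)]
        df = pd.DataFrame(
            np.arange(12, dtype=float).reshape(2, 6), columns=runs,
            index=["p1", "p2"],
        )
        meta = make_meta(runs, ["u"] * 6, groups=["h", "h", "h", "d", "d", "d"])
        t = QuantTable(values=df, meta=meta, scale="log2")
        out = group_ttest_table(t)
        assert len(out) == 2
        assert (out["p_value"] <= 1.0).all()
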
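"""Biofluid-comparison summaries (the catalog back end).

Per-protein biofluid means and "top" biofluids (within 50% of the most
intense fluid), detection-overlap partitions, paired between-fluid fold
changes and absolute deltas, and the pooled two-group t test used for the
targeted disease-versus-healthy comparison.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import HarmolibError
from .model import QuantTable

log = logging.getLogger(__name__)


def top_biofluids(means: dict[str, float], threshold: float = 0.5) -> set[str]:
    """Fluids whose mean signal is within ``threshold`` (default 50%) of the
    most intense fluid's signal, comparison inclusive. Missing fluids are
    excluded; always contains the argmax fluid."""
    present = {f: v for f, v in means.items() if v is not None and not np.isnan(v)}
    if not present:
        raise HarmolibError("all per-fluid means are missing")
    peak = max(present.values())
    return {f for f, v in present.items() if v >= threshold * peak}


def overlap_partition(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Counts for the 7 exclusive regions of a three-set overlap.

    Keys are sorted tuples of fluid labels; values sum to the size of the
    union.
    """
    if len(sets) != 3:
        raise HarmolibError(f"overlap_partition expects 3 sets, got {len(sets)}")
    labels = sorted(sets)
    out: dict[tuple[str, ...], int] = {}
    for r in (1, 2, 3):
        for combo in combinations(labels, r):
            inside = set.intersection(*(sets[l] for l in combo))
            outside = set.union(
                *(sets[l] for l in labels if l not in combo), set()
            )
            out[combo] = len(inside - outside)
    return out


def _per_subject_means(table: QuantTable, fluid: str) -> pd.DataFrame:
    """Rows x subjects mean intensity for one fluid (NaN-aware)."""
    meta = table.meta
    runs = [r for r in table.values.columns if meta.loc[r, "matrix_id"] == fluid]
    if not runs or "subject" not in meta.columns:
        raise HarmolibError(
            f"fluid {fluid!r} has no runs or metadata lacks a subject column"
        )
    subjects = meta.loc[runs, "subject"]
    return table.values[runs].T.groupby(subjects.values).mean().T


def fold_change_table(
    table: QuantTable, fluid_a: str, fluid_b: str
) -> pd.DataFrame:
    """Per-protein mean paired log2 difference (fluid_a - fluid_b).

    ``table`` must be log2-scale with subject-paired runs; rows missing in
    either fluid for every subject are omitted.
    """
    if table.scale != "log2":
        raise HarmolibError("fold changes are computed on a log2-scale table")
    a = _per_subject_means(table, fluid_a)
    b = _per_subject_means(table, fluid_b)
    shared = [s for s in a.columns if s in set(b.columns)]
    diffs = a[shared] - b[shared]
    mean_diff = diffs.mean(axis=1, skipna=True)
    n_pairs = diffs.notna().sum(axis=1)
    out = pd.DataFrame(
        {"delta_log2": mean_diff, "n_pairs": n_pairs}
    )[n_pairs > 0]
    if out.empty:
        warnings.warn(
            f"no rows quantified in both {fluid_a} and {fluid_b}", stacklevel=2
        )
    return out


def compute_deltas(table: QuantTable) -> pd.DataFrame:
    """Absolute per-subject between-fluid intensity differences.

    One row per (protein, fluid pair, subject) with both values present:
    columns row_id, fluid_a, fluid_b, subject, delta.
    """
    fluids = sorted(set(table.meta["matrix_id"]))
    per_fluid = {f: _per_subject_means(table, f) for f in fluids}
    rows = []
    for fa, fb in combinations(fluids, 2):
        a, b = per_fluid[fa], per_fluid[fb]
        shared = [s for s in a.columns if s in set(b.columns)]
        for rid in table.values.index:
            for s in shared:
                va, vb = a.loc[rid, s], b.loc[rid, s]
                if np.isnan(va) or np.isnan(vb):
                    continue
                rows.append(
                    {
                        "row_id": rid,
                        "fluid_a": fa,
                        "fluid_b": fb,
                        "subject": s,
                        "delta": abs(va - vb),
                    }
                )
    return pd.DataFrame(rows, columns=["row_id", "fluid_a", "fluid_b",
                                       "subject", "delta"])


def two_group_ttest(a, b) -> tuple[float, float]:
    """Two-sided pooled-variance Student t test.

    Returns (t, p) with df = n_a + n_b - 2. Degenerate inputs follow fixed
    conventions: zero pooled variance with equal means gives (0, 1); with
    unequal means, (+/-inf, 0) and a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise HarmolibError("each group needs n >= 2")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    diff = a.mean() - b.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return float(np.sign(diff) * np.inf), 0.0
    t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def protein_summary(table: QuantTable, threshold: float = 0.5) -> pd.DataFrame:
    """Per-protein catalog row: per-fluid mean intensity and top fluids.

    Means are taken on the table's own scale; the top-fluid rule is applied
    to linear means (log2 tables are exponentiated first), reading "signal"
    as linear intensity.
    """
    fluids = sorted(set(table.meta["matrix_id"]))
    rows = []
    for rid in table.values.index:
        rec = {"row_id": rid}
        means = {}
        for f in fluids:
            runs = table.runs_for_matrix(f)
            v = table.values.loc[rid, runs].astype(float).mean(skipna=True)
            rec[f"mean_{f}"] = v
            means[f] = 2.0**v if table.scale == "log2" else v
        try:
            tops = top_biofluids(means, threshold)
        except HarmolibError:
            tops = set()
        rec["top_fluids"] = ";".join(sorted(tops))
        rows.append(rec)
    return pd.DataFrame(rows)


def group_ttest_table(
    table: QuantTable, group_column: str = "group"
) -> pd.DataFrame:
    """Per-row two-group pooled t test between the two metadata groups."""
    groups = sorted(set(table.meta[group_column].dropna()))
    if len(groups) != 2:
        raise HarmolibError(f"expected exactly 2 groups, got {groups}")
    ga = [r for r in table.values.columns
          if table.meta.loc[r, group_column] == groups[0]]
    gb = [r for r in table.values.columns
          if table.meta.loc[r, group_column] == groups[1]]
    rows = []
    for rid in table.values.index:
        va = table.values.loc[rid, ga].dropna().to_numpy(dtype=float)
        vb = table.values.loc[rid, gb].dropna().to_numpy(dtype=float)
        if va.size < 2 or vb.size < 2:
            continue
        t, p = two_group_ttest(va, vb)
        rows.append({"row_id": rid, "group_a": groups[0], "group_b": groups[1],
                     "t": t, "p_value": p})
    return pd.DataFrame(rows, columns=["row_id", "group_a", "group_b",
                                       "t", "p_value"])
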
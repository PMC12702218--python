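"""Peptide and protein quantification from quant-flagged transitions.

Peptide intensity in a run is the summed trapezoidal area of its
quantitative fragment traces inside a fixed boundary around the expected
retention time. Run-level systematic scale is removed by normalizing each
run to the average log2 intensity over complete-case rows, and protein
quantities are the sum of their *unique* peptides (peptides mapping to more
than one protein are discarded).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BoundaryError, ConfigError, NormalizationError
from .model import (
    QUANT,
    ChromatogramSet,
    ChromatogramTrace,
    FragmentKey,
    LibraryEntry,
    QuantTable,
)

log = logging.getLogger(__name__)


@dataclass
class PeakBoundary:
    peptide: str
    run_id: str
    start: float
    end: float

    def __post_init__(self):
        if self.start >= self.end:
            raise BoundaryError(
                f"boundary start {self.start} must precede end {self.end}"
            )


def _trapz_within(trace: ChromatogramTrace, start: float, end: float) -> float:
    t, y = trace.times, trace.intensities
    if end < t[0] or start > t[-1]:
        raise BoundaryError(
            f"boundary [{start}, {end}] outside trace range [{t[0]}, {t[-1]}]"
        )
    lo, hi = max(start, t[0]), min(end, t[-1])
    inner = (t > lo) & (t < hi)
    tt = np.concatenate([[lo], t[inner], [hi]])
    yy = np.concatenate(
        [[np.interp(lo, t, y)], y[inner], [np.interp(hi, t, y)]]
    )
    return float(np.trapezoid(yy, tt))


def integrate_peptide(
    traces: dict[FragmentKey, ChromatogramTrace],
    entry: LibraryEntry,
    boundary: PeakBoundary,
) -> float | None:
    """Linear peptide intensity: summed quant-ion areas within the boundary.

    A quant ion without a trace contributes 0 (logged); a peptide with no
    quant-flagged ions yields None (missing, never zero).
    """
    quant_keys = [f.key for f in entry.fragments if f.quant_flag == QUANT]
    if not quant_keys:
        return None
    total = 0.0
    for key in quant_keys:
        tr = traces.get(key)
        if tr is None:
            log.debug(
                "no trace for quant ion %s of %s in %s",
                key, entry.peptide, boundary.run_id,
            )
            continue
        total += _trapz_within(tr, boundary.start, boundary.end)
    return total


def default_boundary(
    entry: LibraryEntry, run_id: str, peak_sigma: float
) -> PeakBoundary:
    """Expected RT +/- 3 peak sigmas."""
    return PeakBoundary(
        peptide=entry.peptide,
        run_id=run_id,
        start=entry.rt - 3.0 * peak_sigma,
        end=entry.rt + 3.0 * peak_sigma,
    )


def build_quant_table(
    harmonized: dict[str, "SpectralLibrary"],
    chroms: ChromatogramSet,
    meta: pd.DataFrame,
    peak_sigma: float,
) -> QuantTable:
    """Peptide x run linear intensity table over all matrices' runs.

    Each run is quantified against its own matrix's harmonized library;
    missing traces or out-of-boundary peaks leave NaN.
    """
    run_ids = [r for r in meta.index if r in set(t.run_id for t in chroms.traces)]
    peptides = sorted(
        {e.peptide for lib in harmonized.values() for e in lib.entries}
    )
    values = pd.DataFrame(np.nan, index=peptides, columns=run_ids)
    for run_id in run_ids:
        matrix_id = meta.loc[run_id, "matrix_id"]
        lib = harmonized.get(matrix_id)
        if lib is None:
            continue
        for e in lib.entries:
            traces = chroms.precursor_traces(run_id, e.peptide, e.precursor_charge)
            if not traces:
                continue
            try:
                v = integrate_peptide(
                    traces, e, default_boundary(e, run_id, peak_sigma)
                )
            except BoundaryError:
                continue
            if v is not None:
                values.loc[e.peptide, run_id] = v
    return QuantTable(values=values, meta=meta.loc[run_ids], scale="linear",
                      row_kind="peptide")


def normalize_log2(table: QuantTable) -> QuantTable:
    """Normalize run intensities to the average log2 intensity.

    x'(i,j) = log2 x(i,j) - m(j) + M, where m(j) is run j's mean log2
    intensity over rows quantified in every run and M is the grand mean of
    the m(j). After normalization every run's complete-case mean is equal.
    """
    if table.scale != "linear":
        raise ConfigError("normalize_log2 expects a linear-scale table")
    vals = table.values.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        logv = np.log2(vals)
    complete = ~np.isnan(vals).any(axis=1)
    if not complete.any():
        raise NormalizationError("no complete-case rows to anchor normalization")
    m = logv[complete].mean(axis=0)
    grand = m.mean()
    out = pd.DataFrame(
        logv - m[None, :] + grand,
        index=table.values.index,
        columns=table.values.columns,
    )
    return QuantTable(values=out, meta=table.meta, scale="log2",
                      row_kind=table.row_kind)


def rollup_protein(table: QuantTable, protein_map: dict[str, object]) -> QuantTable:
    """Sum unique peptides into proteins (linear scale).

    ``protein_map`` maps peptide -> accession or collection of accessions;
    peptides mapping to more than one protein are excluded entirely. A
    protein appears only if at least one unique peptide is quantified; runs
    where none of its peptides were quantified stay NaN.
    """
    if not protein_map:
        raise ConfigError("protein map is empty")
    if table.scale != "linear":
        raise ConfigError("protein roll-up operates on linear intensities")
    unique: dict[str, str] = {}
    for pep, acc in protein_map.items():
        accs = {acc} if isinstance(acc, str) else set(acc)
        if len(accs) == 1:
            unique[pep] = next(iter(accs))
    groups: dict[str, list[str]] = {}
    for pep in table.values.index:
        acc = unique.get(pep)
        if acc is not None:
            groups.setdefault(acc, []).append(pep)
    rows = {}
    for acc in sorted(groups):
        sub = table.values.loc[groups[acc]]
        summed = sub.sum(axis=0, min_count=1)  # all-NaN run stays NaN
        if summed.notna().any():
            rows[acc] = summed
    values = pd.DataFrame(rows).T
    values = values.reindex(columns=table.values.columns)
    return QuantTable(values=values, meta=table.meta, scale="linear",
                      row_kind="protein")
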
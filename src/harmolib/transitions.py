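"""Quantitative transition selection under wide-window co-isolation.

The chromatogram libraries are built with narrow windows, but quantification
happens in wide-window runs, where co-eluting precursors sharing an isolation
window can contribute fragment signal within the mass tolerance of an
analyte's transition. This module re-evaluates every library precursor under
the wide-window scheme to flag such at-risk fragments, scores the remaining
candidates by how well their peak shape tracks the precursor's summed
elution profile in every biofluid, and picks the harmonized quantitative-ion
set (up to ``max_quant_ions``, requiring at least ``min_quant_ions``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, InsufficientTracesError, OutOfRangeError
from .model import (
    DETECTION_ONLY,
    QUANT,
    ChromatogramTrace,
    FragmentKey,
    IsolationScheme,
    LibraryEntry,
    PipelineConfig,
    SpectralLibrary,
)


@dataclass
class Interferer:
    peptide: str
    charge: int
    fragment_key: FragmentKey
    window_index: int
    ppm_distance: float
    delta_rt: float


@dataclass
class InterferenceReport:
    analyte: tuple[str, int]
    fragment_key: FragmentKey
    interferers: list[Interferer] = field(default_factory=list)

    @property
    def flagged(self) -> bool:
        return bool(self.interferers)


def _shared_window(
    scheme: IsolationScheme, mz_a: float, mz_b: float, rule: str
) -> int | None:
    """Lowest shared window index under the given co-fragmentation rule, or
    None. "union" shares any staggered window; "demultiplexed" requires the
    same half-width effective window."""
    try:
        if rule == "demultiplexed":
            ia, ib = scheme.demux_index(mz_a), scheme.demux_index(mz_b)
            return ia if ia == ib else None
        wa = scheme.windows_for_precursor(mz_a)
        wb = scheme.windows_for_precursor(mz_b)
        shared = wa & wb
        return min(shared) if shared else None
    except OutOfRangeError:
        return None


def find_cofragmenting(
    analyte: LibraryEntry,
    library: SpectralLibrary,
    scheme: IsolationScheme,
    cfg: PipelineConfig,
) -> dict[FragmentKey, InterferenceReport]:
    """Interference report for every fragment of one analyte.

    Fragment f is flagged iff some other target precursor (i) shares a wide
    window with the analyte under ``cfg.cofragmentation_rule``, (ii) elutes
    within ``cfg.coelution_tolerance`` seconds, and (iii) has a fragment
    within ``cfg.ppm_tolerance`` of f's m/z (ppm relative to f).
    """
    if scheme is None:
        raise ConfigError("an isolation scheme is required")
    reports = {
        f.key: InterferenceReport(
            analyte=(analyte.peptide, analyte.precursor_charge), fragment_key=f.key
        )
        for f in analyte.fragments
    }
    a_mz = np.array([f.mz for f in analyte.fragments])
    a_keys = [f.key for f in analyte.fragments]
    for e in library.entries:
        if e.is_decoy:
            continue
        if (e.peptide, e.precursor_charge) == (
            analyte.peptide,
            analyte.precursor_charge,
        ):
            continue
        drt = e.rt - analyte.rt
        if abs(drt) > cfg.coelution_tolerance:
            continue
        win = _shared_window(
            scheme, analyte.precursor_mz, e.precursor_mz, cfg.cofragmentation_rule
        )
        if win is None:
            continue
        for ef in e.fragments:
            ppm = np.abs(ef.mz - a_mz) / a_mz * 1e6
            for j in np.nonzero(ppm <= cfg.ppm_tolerance)[0]:
                reports[a_keys[j]].interferers.append(
                    Interferer(
                        peptide=e.peptide,
                        charge=e.precursor_charge,
                        fragment_key=ef.key,
                        window_index=win,
                        ppm_distance=float(ppm[j]),
                        delta_rt=float(drt),
                    )
                )
    return reports


def find_cofragmenting_library(
    library: SpectralLibrary, scheme: IsolationScheme, cfg: PipelineConfig
) -> dict[tuple[str, int], dict[FragmentKey, InterferenceReport]]:
    """Reports for every target precursor of one library.

    Entries are pre-sorted by RT so only precursors inside the co-elution
    tolerance are compared; the per-pair window and ppm checks match
    :func:`find_cofragmenting` exactly.
    """
    targets = [e for e in library.entries if not e.is_decoy]
    order = np.argsort([e.rt for e in targets], kind="stable")
    sorted_entries = [targets[i] for i in order]
    rts = np.array([e.rt for e in sorted_entries])
    frag_mz = [np.array([f.mz for f in e.fragments]) for e in sorted_entries]
    frag_keys = [[f.key for f in e.fragments] for e in sorted_entries]

    out = {
        (e.peptide, e.precursor_charge): {
            f.key: InterferenceReport(
                analyte=(e.peptide, e.precursor_charge), fragment_key=f.key
            )
            for f in e.fragments
        }
        for e in sorted_entries
    }
    n = len(sorted_entries)
    for i in range(n):
        a = sorted_entries[i]
        lo = int(np.searchsorted(rts, a.rt - cfg.coelution_tolerance, side="left"))
        hi = int(np.searchsorted(rts, a.rt + cfg.coelution_tolerance, side="right"))
        a_reports = out[(a.peptide, a.precursor_charge)]
        for j in range(lo, hi):
            if j == i:
                continue
            e = sorted_entries[j]
            win = _shared_window(
                scheme, a.precursor_mz, e.precursor_mz, cfg.cofragmentation_rule
            )
            if win is None:
                continue
            drt = float(e.rt - a.rt)
            ppm = (
                np.abs(frag_mz[j][:, None] - frag_mz[i][None, :])
                / frag_mz[i][None, :]
                * 1e6
            )
            for fj, fi in zip(*np.nonzero(ppm <= cfg.ppm_tolerance)):
                a_reports[frag_keys[i][fi]].interferers.append(
                    Interferer(
                        peptide=e.peptide,
                        charge=e.precursor_charge,
                        fragment_key=frag_keys[j][fj],
                        window_index=win,
                        ppm_distance=float(ppm[fj, fi]),
                        delta_rt=drt,
                    )
                )
    return out


def peak_shape_correlation(
    traces: dict[FragmentKey, ChromatogramTrace] | list[ChromatogramTrace],
    grid_step: float = 0.5,
) -> dict[FragmentKey, float]:
    """Per-fragment Pearson correlation with the precursor's elution shape.

    All fragment traces are resampled to one uniform grid spanning the union
    of their time ranges (0 outside a trace's own range); each fragment is
    correlated against the *leave-one-out* reference (sum of the others), so
    a dominant interfered ion cannot validate itself. Zero-variance traces
    score 0.
    """
    if isinstance(traces, dict):
        items = list(traces.items())
    else:
        items = [(t.fragment_key, t) for t in traces]
    if len(items) < 2:
        raise InsufficientTracesError(
            f"peak-shape scoring needs >= 2 fragment traces, got {len(items)}"
        )
    t0 = min(t.times[0] for _, t in items)
    t1 = max(t.times[-1] for _, t in items)
    grid = np.arange(t0, t1 + grid_step / 2, grid_step)
    mat = np.vstack(
        [np.interp(grid, t.times, t.intensities, left=0.0, right=0.0) for _, t in items]
    )
    total = mat.sum(axis=0)
    out = {}
    for row, (key, _) in zip(mat, items):
        ref = total - row
        if np.std(row) == 0.0 or np.std(ref) == 0.0:
            out[key] = 0.0
        else:
            out[key] = float(np.corrcoef(row, ref)[0, 1])
    return out


@dataclass
class FragmentQuantScore:
    fragment_key: FragmentKey
    per_matrix: dict[str, float]
    aggregate: float
    interference_flagged: bool


def aggregate_correlations(per_matrix: dict[str, float], how: str) -> float:
    vals = list(per_matrix.values())
    if not vals:
        return float("-inf")
    return float(min(vals)) if how == "min" else float(np.mean(vals))


def select_quant_ions(
    fragments,
    per_matrix_scores: dict[str, dict[FragmentKey, float]],
    flagged_any: dict[FragmentKey, bool],
    cfg: PipelineConfig,
) -> tuple[list[FragmentKey], list[FragmentKey], bool]:
    """Choose the harmonized quantitative-ion set for one peptide.

    Candidates are fragments flagged in *no* matrix; they are ranked by the
    aggregated cross-matrix correlation (descending), ties broken by library
    intensity (descending) then fragment m/z (ascending). The top
    ``max_quant_ions`` become quantitative; if fewer than ``min_quant_ions``
    candidates exist the peptide is not quantifiable and every ion is
    detection-only.

    Returns (quant keys, detection-only keys, peptide_quantifiable).
    """
    scored = []
    for f in fragments:
        per_matrix = {
            m: s[f.key] for m, s in per_matrix_scores.items() if f.key in s
        }
        scored.append(
            FragmentQuantScore(
                fragment_key=f.key,
                per_matrix=per_matrix,
                aggregate=aggregate_correlations(
                    per_matrix, cfg.correlation_aggregation
                ),
                interference_flagged=bool(flagged_any.get(f.key, False)),
            )
        )
    frag_by_key = {f.key: f for f in fragments}
    candidates = [s for s in scored if not s.interference_flagged]
    candidates.sort(
        key=lambda s: (
            -s.aggregate,
            -frag_by_key[s.fragment_key].library_intensity,
            frag_by_key[s.fragment_key].mz,
        )
    )
    if len(candidates) < cfg.min_quant_ions:
        return [], [f.key for f in fragments], False
    quant = [s.fragment_key for s in candidates[: cfg.max_quant_ions]]
    quant_set = set(quant)
    detection = [f.key for f in fragments if f.key not in quant_set]
    return quant, detection, True


def apply_quant_flags(entry: LibraryEntry, quant_keys) -> None:
    """Stamp quant/detection-only flags onto an entry's fragments in place."""
    quant_set = set(quant_keys)
    for f in entry.fragments:
        f.quant_flag = QUANT if f.key in quant_set else DETECTION_ONLY
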
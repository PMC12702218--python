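"""Core domain types shared by every pipeline stage.

The central objects are the spectral library (one per biofluid matrix), the
precursor isolation scheme of the wide-window acquisition, fragment-level
chromatogram traces, and the peptide/protein-by-run quantitative table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, IntegrityError, OutOfRangeError

QUANT = "quant"
DETECTION_ONLY = "detection_only"
UNSET = "unset"

OBSERVED = "observed"
IMPUTED = "imputed"

#: (ion_series, ordinal, fragment_charge) — the identity of a transition's
#: product ion, independent of its m/z value.
FragmentKey = tuple[str, int, int]


@dataclass
class FragmentIon:
    """One product ion of a library precursor."""

    ion_series: str  # "y" or "b"
    ordinal: int
    charge: int
    mz: float
    library_intensity: float
    quant_flag: str = UNSET

    def __post_init__(self):
        if self.ion_series not in ("y", "b"):
            raise IntegrityError(f"ion_series must be y or b, got {self.ion_series!r}")
        if self.ordinal < 1 or self.charge < 1:
            raise IntegrityError("fragment ordinal and charge must be positive")
        if self.mz <= 0:
            raise IntegrityError(f"fragment m/z must be > 0, got {self.mz}")
        if self.library_intensity < 0:
            raise IntegrityError("library_intensity must be >= 0")
        if self.quant_flag not in (QUANT, DETECTION_ONLY, UNSET):
            raise IntegrityError(f"bad quant_flag {self.quant_flag!r}")

    @property
    def key(self) -> FragmentKey:
        return (self.ion_series, self.ordinal, self.charge)


@dataclass
class LibraryEntry:
    """One peptide precursor in one matrix's library."""

    peptide: str
    precursor_charge: int
    precursor_mz: float
    score: float
    is_decoy: bool
    matrix_id: str
    rt: float  # seconds
    fragments: list[FragmentIon]
    rt_origin: str = OBSERVED

    def __post_init__(self):
        if not self.fragments:
            raise IntegrityError(
                f"entry {self.peptide}/{self.precursor_charge} has no fragments"
            )
        if self.rt < 0:
            raise IntegrityError("retention time must be >= 0 s")
        if self.rt_origin not in (OBSERVED, IMPUTED):
            raise IntegrityError(f"bad rt_origin {self.rt_origin!r}")

    def fragment(self, key: FragmentKey) -> FragmentIon | None:
        for f in self.fragments:
            if f.key == key:
                return f
        return None

    def copy(self) -> "LibraryEntry":
        return replace(self, fragments=[replace(f) for f in self.fragments])


@dataclass
class SpectralLibrary:
    """A scored transition library for one biofluid matrix.

    Before FDR filtering it holds both target and decoy precursors; the
    (peptide, precursor_charge) pair is unique within one library.
    """

    matrix_id: str
    entries: list[LibraryEntry] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.matrix_id != self.matrix_id:
                raise IntegrityError(
                    f"entry matrix {e.matrix_id!r} != library matrix {self.matrix_id!r}"
                )
            k = (e.peptide, e.precursor_charge)
            if k in seen:
                raise IntegrityError(f"duplicate precursor {k} in {self.matrix_id}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.entries)

    def targets(self) -> list[LibraryEntry]:
        return [e for e in self.entries if not e.is_decoy]

    def by_precursor(self) -> dict[tuple[str, int], LibraryEntry]:
        return {(e.peptide, e.precursor_charge): e for e in self.entries}

    def target_peptides(self) -> set[str]:
        return {e.peptide for e in self.entries if not e.is_decoy}


@dataclass
class IsolationScheme:
    """Ordered precursor isolation windows, optionally staggered.

    Windows are half-open ``[start, start + width)``; when staggered, a second
    interleaved cycle offset by ``width / 2`` covers the same m/z range, so
    every interior precursor is co-isolated by exactly two windows.
    """

    start_mz: float
    end_mz: float
    window_width: float
    staggered: bool = False

    def __post_init__(self):
        if self.window_width <= 0:
            raise ConfigError("window_width must be > 0")
        if self.end_mz <= self.start_mz:
            raise ConfigError("end_mz must exceed start_mz")

    @property
    def mz_range(self) -> tuple[float, float]:
        return (self.start_mz, self.end_mz)

    @property
    def windows(self) -> list[tuple[float, float]]:
        """All windows as (start, end), primary cycle first, then the
        staggered cycle (whose edge windows extend past mz_range)."""
        w = self.window_width
        out = []
        s = self.start_mz
        while s < self.end_mz:
            out.append((s, s + w))
            s += w
        if self.staggered:
            s = self.start_mz - w / 2.0
            while s < self.end_mz:
                out.append((s, s + w))
                s += w
        return out

    def windows_for_precursor(self, mz: float) -> set[int]:
        """Indices of every window that isolates ``mz`` (half-open bounds)."""
        if not (self.start_mz <= mz < self.end_mz):
            raise OutOfRangeError(
                f"m/z {mz} outside scheme range [{self.start_mz}, {self.end_mz})"
            )
        return {i for i, (a, b) in enumerate(self.windows) if a <= mz < b}

    def demux_index(self, mz: float) -> int:
        """Half-width effective window index after demultiplexing a staggered
        scheme. For a non-staggered scheme this is the plain window index."""
        if not (self.start_mz <= mz < self.end_mz):
            raise OutOfRangeError(
                f"m/z {mz} outside scheme range [{self.start_mz}, {self.end_mz})"
            )
        eff = self.window_width / 2.0 if self.staggered else self.window_width
        return int((mz - self.start_mz) // eff)


def windows_for_precursor(scheme: IsolationScheme, mz: float) -> set[int]:
    return scheme.windows_for_precursor(mz)


@dataclass
class ChromatogramTrace:
    """Extracted fragment-ion chromatogram for one precursor in one run."""

    run_id: str
    matrix_id: str
    peptide: str
    precursor_charge: int
    fragment_key: FragmentKey
    times: np.ndarray  # seconds, strictly ascending
    intensities: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape or self.times.size < 3:
            raise IntegrityError("trace needs >= 3 aligned (time, intensity) points")
        if np.any(np.diff(self.times) <= 0):
            raise IntegrityError("trace times must be strictly ascending")
        if np.any(self.intensities < 0):
            raise IntegrityError("trace intensities must be non-negative")


class ChromatogramSet:
    """Indexed collection of traces: by run and by (peptide, charge)."""

    def __init__(self, traces: list[ChromatogramTrace] | None = None):
        self.traces: list[ChromatogramTrace] = []
        self._index: dict[tuple[str, str, int], dict[FragmentKey, ChromatogramTrace]] = {}
        for t in traces or []:
            self.add(t)

    def add(self, trace: ChromatogramTrace) -> None:
        self.traces.append(trace)
        key = (trace.run_id, trace.peptide, trace.precursor_charge)
        self._index.setdefault(key, {})[trace.fragment_key] = trace

    def __len__(self) -> int:
        return len(self.traces)

    def run_ids(self) -> list[str]:
        return sorted({t.run_id for t in self.traces})

    def runs_for_matrix(self, matrix_id: str) -> list[str]:
        return sorted({t.run_id for t in self.traces if t.matrix_id == matrix_id})

    def precursor_traces(
        self, run_id: str, peptide: str, charge: int
    ) -> dict[FragmentKey, ChromatogramTrace]:
        return self._index.get((run_id, peptide, charge), {})


@dataclass
class QuantTable:
    """Peptides (or proteins) x runs intensity matrix with run metadata.

    Missing values are explicit NaN, never zero. ``meta`` is indexed by
    run_id with columns matrix_id, group and (optionally) subject.
    """

    values: pd.DataFrame  # rows x runs
    meta: pd.DataFrame
    scale: str = "linear"  # "linear" | "log2"
    row_kind: str = "peptide"  # "peptide" | "protein"

    def __post_init__(self):
        if self.scale not in ("linear", "log2"):
            raise ConfigError(f"bad scale {self.scale!r}")
        if self.row_kind not in ("peptide", "protein"):
            raise ConfigError(f"bad row_kind {self.row_kind!r}")
        missing = [c for c in self.values.columns if c not in self.meta.index]
        if missing:
            raise IntegrityError(f"runs without metadata: {missing}")
        if self.scale == "linear":
            arr = self.values.to_numpy(dtype=float)
            if np.nanmin(arr, initial=0.0) < 0:
                raise IntegrityError("negative linear intensities")

    def runs_for_matrix(self, matrix_id: str) -> list[str]:
        m = self.meta
        return [r for r in self.values.columns if m.loc[r, "matrix_id"] == matrix_id]


@dataclass
class PipelineConfig:
    """Workflow constants.

    Defaults mirror the study design this workflow reproduces: a global 1%
    peptide FDR, 10 ppm mass tolerances, five quantitative ions with a
    minimum of three, and a 16 m/z staggered wide-window scheme.
    """

    fdr_alpha: float = 0.01
    ppm_tolerance: float = 10.0
    max_quant_ions: int = 5
    min_quant_ions: int = 3
    coelution_tolerance: float = 30.0  # seconds
    wide_scheme: IsolationScheme = field(
        default_factory=lambda: IsolationScheme(400.0, 1000.0, 16.0, staggered=True)
    )
    cofragmentation_rule: str = "union"  # "union" | "demultiplexed"
    correlation_aggregation: str = "min"  # "min" | "mean"
    peak_sigma: float = 6.0  # seconds; integration half-window is 3 sigma
    rng_seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.fdr_alpha < 1:
            raise ConfigError(f"fdr_alpha must be in (0, 1), got {self.fdr_alpha}")
        if self.ppm_tolerance <= 0:
            raise ConfigError("ppm_tolerance must be > 0")
        if self.min_quant_ions > self.max_quant_ions:
            raise ConfigError(
                f"min_quant_ions ({self.min_quant_ions}) exceeds "
                f"max_quant_ions ({self.max_quant_ions})"
            )
        if self.coelution_tolerance <= 0:
            raise ConfigError("coelution_tolerance must be > 0")
        if self.cofragmentation_rule not in ("union", "demultiplexed"):
            raise ConfigError(
                f"cofragmentation_rule must be union or demultiplexed, "
                f"got {self.cofragmentation_rule!r}"
            )
        if self.correlation_aggregation not in ("min", "mean"):
            raise ConfigError("correlation_aggregation must be min or mean")
        if self.peak_sigma <= 0:
            raise ConfigError("peak_sigma must be > 0")
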
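"""Readers and writers for the pipeline's on-disk formats.

* library TSV: flat transition list, one fragment per row, header mandatory
* chromatogram CSV: long format, one (time, intensity) sample per row
* isolation scheme JSON
* quant report TSV with a run-metadata sidecar CSV
* pipeline config TOML/JSON

Floats are serialized with Python's shortest round-trip repr so that
``read(write(x)) == x`` bit for bit.
"""

from __future__ import annotations

import csv
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError, IntegrityError
from .model import (
    ChromatogramSet,
    ChromatogramTrace,
    FragmentIon,
    IsolationScheme,
    LibraryEntry,
    PipelineConfig,
    QuantTable,
    SpectralLibrary,
)

LIBRARY_COLUMNS = [
    "matrix_id",
    "peptide",
    "precursor_charge",
    "precursor_mz",
    "score",
    "is_decoy",
    "rt_seconds",
    "rt_origin",
    "ion_series",
    "fragment_ordinal",
    "fragment_charge",
    "fragment_mz",
    "library_intensity",
    "quant_flag",
]

CHROMATOGRAM_COLUMNS = [
    "run_id",
    "matrix_id",
    "peptide",
    "precursor_charge",
    "ion_series",
    "fragment_ordinal",
    "fragment_charge",
    "time_sec",
    "intensity",
]

_INT_LIB_COLS = {"precursor_charge", "fragment_ordinal", "fragment_charge"}
_FLOAT_LIB_COLS = {"precursor_mz", "score", "rt_seconds", "fragment_mz", "library_intensity"}


def _parse_cell(line_no: int, column: str, raw: str):
    raw = raw.strip()
    if raw == "":
        raise FormatError(f"line {line_no}: missing value in column {column!r}")
    try:
        if column in _INT_LIB_COLS:
            return int(raw)
        if column in _FLOAT_LIB_COLS:
            return float(raw)
        if column == "is_decoy":
            if raw not in ("0", "1"):
                raise ValueError
            return raw == "1"
    except ValueError:
        raise FormatError(
            f"line {line_no}: cannot parse {raw!r} in column {column!r}"
        ) from None
    return raw


def read_library(path: str | Path) -> SpectralLibrary:
    """Parse a transition-list TSV into a :class:`SpectralLibrary`.

    Fragment rows are grouped under their (peptide, precursor_charge)
    precursor; precursor-level fields must agree across a group.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header required") from None
        missing = [c for c in LIBRARY_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing mandatory column(s) {missing}")
        col = {c: header.index(c) for c in LIBRARY_COLUMNS}

        groups: dict[tuple[str, int], dict] = {}
        matrix_ids = set()
        for line_no, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) < len(header):
                raise FormatError(f"line {line_no}: expected {len(header)} fields")
            rec = {c: _parse_cell(line_no, c, row[col[c]]) for c in LIBRARY_COLUMNS}
            matrix_ids.add(rec["matrix_id"])
            key = (rec["peptide"], rec["precursor_charge"])
            frag = FragmentIon(
                ion_series=rec["ion_series"],
                ordinal=rec["fragment_ordinal"],
                charge=rec["fragment_charge"],
                mz=rec["fragment_mz"],
                library_intensity=rec["library_intensity"],
                quant_flag=rec["quant_flag"],
            )
            if key not in groups:
                groups[key] = {
                    "precursor_mz": rec["precursor_mz"],
                    "score": rec["score"],
                    "is_decoy": rec["is_decoy"],
                    "matrix_id": rec["matrix_id"],
                    "rt": rec["rt_seconds"],
                    "rt_origin": rec["rt_origin"],
                    "fragments": [frag],
                }
            else:
                g = groups[key]
                if g["score"] != rec["score"]:
                    raise IntegrityError(
                        f"line {line_no}: precursor {key} has conflicting scores "
                        f"{g['score']} vs {rec['score']}"
                    )
                g["fragments"].append(frag)

    if len(matrix_ids) > 1:
        raise IntegrityError(f"{path}: multiple matrix_ids in one library: {matrix_ids}")
    matrix_id = matrix_ids.pop() if matrix_ids else path.stem
    entries = [
        LibraryEntry(
            peptide=pep,
            precursor_charge=z,
            precursor_mz=g["precursor_mz"],
            score=g["score"],
            is_decoy=g["is_decoy"],
            matrix_id=matrix_id,
            rt=g["rt"],
            rt_origin=g["rt_origin"],
            fragments=g["fragments"],
        )
        for (pep, z), g in groups.items()
    ]
    return SpectralLibrary(matrix_id=matrix_id, entries=entries, provenance=str(path))


def write_library(lib: SpectralLibrary, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(LIBRARY_COLUMNS)
        for e in lib.entries:
            for f in e.fragments:
                w.writerow(
                    [
                        e.matrix_id,
                        e.peptide,
                        int(e.precursor_charge),
                        repr(float(e.precursor_mz)),
                        repr(float(e.score)),
                        int(e.is_decoy),
                        repr(float(e.rt)),
                        e.rt_origin,
                        f.ion_series,
                        int(f.ordinal),
                        int(f.charge),
                        repr(float(f.mz)),
                        repr(float(f.library_intensity)),
                        f.quant_flag,
                    ]
                )


def read_chromatograms(path: str | Path) -> ChromatogramSet:
    """Read one long-format CSV, or every ``*.csv`` in a directory."""
    path = Path(path)
    files = sorted(path.glob("*.csv")) if path.is_dir() else [path]
    chroms = ChromatogramSet()
    for f in files:
        df = pd.read_csv(f)
        missing = [c for c in CHROMATOGRAM_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{f}: missing mandatory column(s) {missing}")
        keys = ["run_id", "matrix_id", "peptide", "precursor_charge",
                "ion_series", "fragment_ordinal", "fragment_charge"]
        for vals, sub in df.groupby(keys, sort=False):
            run, mat, pep, z, series, ordinal, fz = vals
            chroms.add(
                ChromatogramTrace(
                    run_id=str(run),
                    matrix_id=str(mat),
                    peptide=str(pep),
                    precursor_charge=int(z),
                    fragment_key=(str(series), int(ordinal), int(fz)),
                    times=sub["time_sec"].to_numpy(dtype=float),
                    intensities=sub["intensity"].to_numpy(dtype=float),
                )
            )
    return chroms


def write_chromatograms(chroms: ChromatogramSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CHROMATOGRAM_COLUMNS)
        for t in chroms.traces:
            series, ordinal, fz = t.fragment_key
            for time, inten in zip(t.times, t.intensities):
                w.writerow(
                    [t.run_id, t.matrix_id, t.peptide, t.precursor_charge,
                     series, ordinal, fz, repr(float(time)), repr(float(inten))]
                )


def read_scheme(path: str | Path) -> IsolationScheme:
    with Path(path).open() as fh:
        d = json.load(fh)
    try:
        return IsolationScheme(
            start_mz=float(d["start_mz"]),
            end_mz=float(d["end_mz"]),
            window_width=float(d["window_width"]),
            staggered=bool(d["staggered"]),
        )
    except KeyError as e:
        raise FormatError(f"{path}: isolation scheme missing key {e}") from None


def write_scheme(scheme: IsolationScheme, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(
            {
                "start_mz": scheme.start_mz,
                "end_mz": scheme.end_mz,
                "window_width": scheme.window_width,
                "staggered": scheme.staggered,
            },
            fh,
            indent=2,
        )
        fh.write("\n")


def read_quant_table(path: str | Path, meta_path: str | Path) -> QuantTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    for c in ("row_id", "row_type"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {c!r}")
    kinds = set(df["row_type"])
    if len(kinds) > 1:
        raise IntegrityError(f"{path}: mixed row types {kinds}")
    row_kind = kinds.pop() if kinds else "peptide"
    values = df.set_index("row_id").drop(columns=["row_type"]).astype(float)
    values.index.name = None
    scale = "linear"
    scale_path = path.with_suffix(path.suffix + ".scale")
    if scale_path.exists():
        scale = scale_path.read_text().strip()
    meta = pd.read_csv(meta_path, dtype=str).set_index("run_id")
    return QuantTable(values=values, meta=meta, scale=scale, row_kind=row_kind)


def write_quant_table(table: QuantTable, path: str | Path, meta_path: str | Path) -> None:
    path = Path(path)
    df = table.values.copy()
    df.insert(0, "row_type", table.row_kind)
    df.index.name = "row_id"
    out = df.reset_index()
    num_cols = [c for c in out.columns if c not in ("row_id", "row_type")]
    out[num_cols] = out[num_cols].map(lambda v: "" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)
    path.with_suffix(path.suffix + ".scale").write_text(table.scale + "\n")
    table.meta.reset_index().to_csv(meta_path, index=False)


def _scheme_from_mapping(d: dict) -> IsolationScheme:
    try:
        return IsolationScheme(
            start_mz=float(d["start_mz"]),
            end_mz=float(d["end_mz"]),
            window_width=float(d["window_width"]),
            staggered=bool(d.get("staggered", False)),
        )
    except KeyError as e:
        raise ConfigError(f"wide_scheme missing key {e}") from None


def config_from_mapping(d: dict) -> PipelineConfig:
    """Build a validated :class:`PipelineConfig` from a parsed TOML/JSON dict
    (the ``[pipeline]`` table; unknown keys are rejected)."""
    d = dict(d)
    scheme = d.pop("wide_scheme", None)
    kwargs = {}
    valid = set(PipelineConfig.__dataclass_fields__)
    for k, v in d.items():
        if k not in valid:
            raise ConfigError(f"unknown config key {k!r}")
        kwargs[k] = v
    if scheme is not None:
        kwargs["wide_scheme"] = _scheme_from_mapping(scheme)
    return PipelineConfig(**kwargs)


def read_config(path: str | Path) -> dict:
    """Load a TOML or JSON config file into a plain dict."""
    path = Path(path)
    if path.suffix == ".json":
        with path.open() as fh:
            return json.load(fh)
    with path.open("rb") as fh:
        return tomllib.load(fh)
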
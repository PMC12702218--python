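"""End-to-end orchestration: simulate -> fdr -> align -> select-ions ->
harmonize -> quantify -> summarize, with a reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, synthetic
from .errors import HarmolibError, NormalizationError
from .fdr import compute_qvalues, global_filter, pick_best_evidence
from .harmonize import build_harmonized_libraries, harmonization_report
from .model import ChromatogramSet, PipelineConfig, QuantTable, SpectralLibrary
from .quantify import build_quant_table, normalize_log2, rollup_protein
from .rt_alignment import fit_all_warps, impute_missing_rts
from .summary import (
    compute_deltas,
    fold_change_table,
    group_ttest_table,
    overlap_partition,
    protein_summary,
)
from .transitions import (
    aggregate_correlations,
    find_cofragmenting_library,
    peak_shape_correlation,
    select_quant_ions,
)

log = logging.getLogger(__name__)

__version__ = "0.1.0"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(path: Path, manifest: dict) -> None:
    tmp = path.with_suffix(".tmp")
    with tmp.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    os.replace(tmp, path)


def select_ions_for_accepted(
    libraries: dict[str, SpectralLibrary],
    chroms: ChromatogramSet,
    accepted: set[str],
    best_matrix: dict[str, str],
    cfg: PipelineConfig,
):
    """Interference screening plus cross-matrix peak-shape scoring for every
    accepted peptide; returns peptide -> (quant, detection, quantifiable)."""
    reports_by_matrix = {
        m: find_cofragmenting_library(lib, cfg.wide_scheme, cfg)
        for m, lib in libraries.items()
    }
    decisions = {}
    for pep in sorted(accepted):
        template = None
        flagged_any: dict = {}
        per_matrix_scores: dict[str, dict] = {}
        for m, lib in libraries.items():
            entry = None
            for e in lib.entries:
                if e.peptide == pep and not e.is_decoy:
                    entry = e
                    break
            if entry is None:
                continue
            if m == best_matrix.get(pep) or template is None:
                template = entry
            for key, rep in reports_by_matrix[m][(pep, entry.precursor_charge)].items():
                flagged_any[key] = flagged_any.get(key, False) or rep.flagged
            # average the per-run correlations within this matrix
            per_run = []
            for run_id in chroms.runs_for_matrix(m):
                traces = chroms.precursor_traces(run_id, pep, entry.precursor_charge)
                if len(traces) >= 2:
                    per_run.append(peak_shape_correlation(traces))
            if per_run:
                keys = set().union(*(set(d) for d in per_run))
                per_matrix_scores[m] = {
                    k: float(np.mean([d[k] for d in per_run if k in d]))
                    for k in keys
                }
        if template is None:
            continue
        decisions[pep] = select_quant_ions(
            template.fragments, per_matrix_scores, flagged_any, cfg
        )
    return decisions


def run_pipeline(
    cfg: PipelineConfig,
    outdir: str | Path,
    libraries: dict[str, SpectralLibrary] | None = None,
    chroms: ChromatogramSet | None = None,
    meta: pd.DataFrame | None = None,
    simulate: bool = False,
    sim_config: synthetic.SimulationConfig | None = None,
    seed: int | None = None,
) -> dict:
    """Run every stage and write all outputs under ``outdir``.

    Returns the run manifest (also written to ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}
    t_start = time.time()

    def record(stage: str, **info):
        stages[stage] = {k: v for k, v in info.items()}
        log.info("stage %-12s %s", stage, info)

    truth = None
    if simulate:
        sim = sim_config or synthetic.demo_simulation_config()
        if seed is not None:
            sim.seed = seed
        libraries, chroms, truth = synthetic.simulate_experiment(sim)
        for m, lib in libraries.items():
            io.write_library(lib, outdir / f"library_{m}.tsv")
        io.write_chromatograms(chroms, outdir / "chromatograms.csv")
        truth.to_json(outdir / "ground_truth.json")
        meta = pd.DataFrame.from_dict(truth.run_meta, orient="index")
        meta.index.name = "run_id"
        meta.reset_index().to_csv(outdir / "meta.csv", index=False)
        record(
            "simulate",
            seed=sim.seed,
            peptides=sim.n_true_peptides + sim.n_false_targets,
            decoys=sim.n_decoys,
            runs=len(truth.run_meta),
            outputs=[f"library_{m}.tsv" for m in libraries]
            + ["chromatograms.csv", "ground_truth.json", "meta.csv"],
        )
    if libraries is None or chroms is None or meta is None:
        raise HarmolibError("libraries, chromatograms and metadata are required")

    # ---- global FDR ------------------------------------------------------
    scored = compute_qvalues(pick_best_evidence(libraries))
    accepted = global_filter(scored, cfg.fdr_alpha)
    best_matrix = {p.peptide: p.best_matrix for p in scored if not p.is_decoy}
    best_charge = {p.peptide: p.best_charge for p in scored if not p.is_decoy}
    qdf = pd.DataFrame(
        {
            "peptide": [p.peptide for p in scored],
            "best_matrix": [p.best_matrix for p in scored],
            "best_score": [p.best_score for p in scored],
            "is_decoy": [int(p.is_decoy) for p in scored],
            "q_value": [p.q_value for p in scored],
            "accepted": [int(p.peptide in accepted) for p in scored],
        }
    )
    qdf.to_csv(outdir / "qvalues.tsv", sep="\t", index=False)
    record("fdr", peptides_in=len(scored), accepted=len(accepted),
           alpha=cfg.fdr_alpha, outputs=["qvalues.tsv"])

    # ---- RT alignment ----------------------------------------------------
    warps = fit_all_warps(libraries)
    warps_json = {
        f"{a}->{b}": {
            "source_matrix": a,
            "target_matrix": b,
            "knots": w.knots.tolist(),
            "residual_sd": w.residual_sd,
            "n_anchors": w.n_anchors,
        }
        for (a, b), w in sorted(warps.items())
    }
    with (outdir / "warps.json").open("w") as fh:
        json.dump(warps_json, fh, indent=1)
        fh.write("\n")
    rt_assign = impute_missing_rts(accepted, libraries, warps, best_matrix)
    record("align", n_warps=len(warps), outputs=["warps.json"])

    # ---- transition selection -------------------------------------------
    decisions = select_ions_for_accepted(libraries, chroms, accepted,
                                         best_matrix, cfg)
    ion_rows = []
    for pep in sorted(decisions):
        quant, detection, ok = decisions[pep]
        for key in quant:
            ion_rows.append({"peptide": pep, "fragment": f"{key[0]}{key[1]}^{key[2]}",
                             "decision": "quant", "quantifiable": int(ok)})
        for key in detection:
            ion_rows.append({"peptide": pep, "fragment": f"{key[0]}{key[1]}^{key[2]}",
                             "decision": "detection_only", "quantifiable": int(ok)})
    pd.DataFrame(ion_rows, columns=["peptide", "fragment", "decision",
                                    "quantifiable"]).to_csv(
        outdir / "ionflags.tsv", sep="\t", index=False
    )
    n_quantifiable = sum(1 for d in decisions.values() if d[2])
    record("select_ions", peptides=len(decisions),
           quantifiable=n_quantifiable, outputs=["ionflags.tsv"])

    # ---- harmonization ---------------------------------------------------
    harmonized = build_harmonized_libraries(
        libraries, accepted, best_matrix, best_charge, rt_assign, decisions, cfg
    )
    harm_files = []
    for m, lib in harmonized.items():
        f = f"harmonized_{m}.tsv"
        io.write_library(lib, outdir / f)
        harm_files.append(f)
    report = harmonization_report(libraries, harmonized)
    report.to_csv(outdir / "harmonization_report.tsv", sep="\t", index=False)
    record("harmonize", peptides=len(accepted),
           outputs=harm_files + ["harmonization_report.tsv"])

    # ---- quantification --------------------------------------------------
    pep_table = build_quant_table(harmonized, chroms, meta, cfg.peak_sigma)
    io.write_quant_table(pep_table, outdir / "quant_peptides.tsv",
                         outdir / "quant_meta.csv")
    try:
        norm = normalize_log2(pep_table)
        io.write_quant_table(norm, outdir / "quant_peptides_log2.tsv",
                             outdir / "quant_meta.csv")
    except NormalizationError:
        log.warning("no complete-case peptides; log2 report skipped")
    protein_map = truth.protein_map if truth is not None else None
    prot_linear = None
    if protein_map:
        prot_linear = rollup_protein(pep_table, protein_map)
        io.write_quant_table(prot_linear, outdir / "quant_proteins.tsv",
                             outdir / "quant_meta.csv")
    record("quantify", peptides=len(pep_table.values),
           proteins=0 if prot_linear is None else len(prot_linear.values),
           outputs=["quant_peptides.tsv", "quant_peptides_log2.tsv"]
           + (["quant_proteins.tsv"] if prot_linear is not None else []))

    # ---- biofluid summaries ---------------------------------------------
    summary_table = prot_linear if prot_linear is not None else pep_table
    outputs = []
    psum = protein_summary(summary_table)
    psum.to_csv(outdir / "catalog_summary.tsv", sep="\t", index=False)
    outputs.append("catalog_summary.tsv")
    fluids = sorted(set(meta["matrix_id"]))
    detected = {
        f: set(
            summary_table.values.index[
                summary_table.values[summary_table.runs_for_matrix(f)]
                .notna()
                .any(axis=1)
            ]
        )
        for f in fluids
    }
    if len(fluids) == 3:
        venn = overlap_partition(detected)
        pd.DataFrame(
            [{"region": "+".join(k), "count": v} for k, v in sorted(venn.items())]
        ).to_csv(outdir / "venn.tsv", sep="\t", index=False)
        outputs.append("venn.tsv")
    try:
        if "subject" in meta.columns:
            norm_summary = normalize_log2(summary_table)
            fc_frames = []
            for fa, fb in [(a, b) for i, a in enumerate(fluids) for b in fluids[i + 1:]]:
                fc = fold_change_table(norm_summary, fa, fb)
                fc.insert(0, "fluid_b", fb)
                fc.insert(0, "fluid_a", fa)
                fc_frames.append(fc.reset_index(names="row_id"))
            pd.concat(fc_frames, ignore_index=True).to_csv(
                outdir / "foldchange.tsv", sep="\t", index=False
            )
            compute_deltas(summary_table).to_csv(outdir / "deltas.csv", index=False)
            outputs += ["foldchange.tsv", "deltas.csv"]
        if "group" in meta.columns and meta["group"].nunique() == 2:
            tt = group_ttest_table(normalize_log2(summary_table))
            tt.to_csv(outdir / "group_ttest.tsv", sep="\t", index=False)
            outputs.append("group_ttest.tsv")
    except NormalizationError:
        log.warning("no complete-case rows; fold-change and group summaries skipped")
    record("summarize", proteins=len(summary_table.values), outputs=outputs)

    manifest = {
        "tool": "harmolib",
        "version": __version__,
        "seed": seed if seed is not None else cfg.rng_seed,
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "wide_scheme"},
            "wide_scheme": asdict(cfg.wide_scheme),
        },
        "stages": stages,
        "input_digests": {
            f.name: _sha256(f)
            for f in sorted(outdir.glob("library_*.tsv"))
        },
    }
    _write_manifest(outdir / "manifest.json", manifest)
    log.info("pipeline finished in %.1f s", time.time() - t_start)
    return manifest
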
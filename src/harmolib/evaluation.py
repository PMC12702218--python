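"""Simulation studies that measure how well the workflow recovers known
ground truth: FDR calibration, warp recovery, interference-screening
accuracy against brute force, and quantification error with and without
harmonized ion selection."""

from __future__ import annotations

import numpy as np

from . import _mass
from .fdr import global_filter, qvalues_from_scores
from .harmonize import build_harmonized_libraries
from .model import (
    QUANT,
    FragmentIon,
    IsolationScheme,
    LibraryEntry,
    PipelineConfig,
    SpectralLibrary,
)
from .quantify import default_boundary, integrate_peptide
from .rt_alignment import fit_kde_warp
from .synthetic import (
    SimulationConfig,
    expected_peak_area,
    make_peptide,
    simulate_experiment,
    simulate_scores,
)
from .transitions import find_cofragmenting_library


# ---------------------------------------------------------------------------
# FDR calibration


def fdr_calibration_study(
    seed: int,
    n_seeds: int = 20,
    n_targets: int = 20_000,
    true_fraction: float = 0.3,
    n_decoys: int = 20_000,
    n_matrices: int = 3,
    alpha: float = 0.01,
) -> dict:
    """Empirical false-discovery proportion of the global filter.

    Each replicate simulates per-matrix scores for a shared peptide
    population (targets 30% true by default, plus decoys), takes the
    best score over matrices, computes q-values and filters at ``alpha``.
    Returns the mean FDP over replicates.
    """
    rng = np.random.default_rng(seed)
    fdps = []
    for _ in range(n_seeds):
        per_matrix = [
            simulate_scores(n_targets, true_fraction, n_decoys, rng)
            for _ in range(n_matrices)
        ]
        scores = np.max([s for s, _, _ in per_matrix], axis=0)
        is_decoy = per_matrix[0][1]
        is_true = per_matrix[0][2]
        q = qvalues_from_scores(scores, is_decoy)
        accepted = (~is_decoy) & (q <= alpha)
        n_acc = int(accepted.sum())
        fdps.append(float((accepted & ~is_true).sum() / n_acc) if n_acc else 0.0)
    return {
        "mean_fdp": float(np.mean(fdps)),
        "fdps": fdps,
        "n_targets": n_targets,
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# RT warp recovery


def true_warp(s):
    """The reference nonlinear warp used for recovery studies."""
    s = np.asarray(s, dtype=float)
    return 0.95 * s + 120.0 + 30.0 * np.sin(s / 1500.0)


def warp_recovery_study(
    seed: int,
    n_anchors: int = 2000,
    noise_sd: float = 10.0,
    outlier_fraction: float = 0.1,
    gradient: float = 5400.0,
    holdout_fraction: float = 0.3,
) -> dict:
    """Fit the KDE warp on noisy, outlier-contaminated anchors and measure
    the held-out median absolute error against the noise-free warp."""
    rng = np.random.default_rng(seed)
    src = rng.uniform(0.0, gradient, n_anchors)
    tgt = true_warp(src) + rng.normal(0.0, noise_sd, n_anchors)
    n_out = int(round(outlier_fraction * n_anchors))
    idx = rng.choice(n_anchors, n_out, replace=False)
    tgt[idx] = rng.uniform(tgt.min(), tgt.max(), n_out)
    n_hold = int(round(holdout_fraction * n_anchors))
    hold = np.zeros(n_anchors, dtype=bool)
    hold[rng.choice(n_anchors, n_hold, replace=False)] = True
    warp = fit_kde_warp(np.column_stack([src[~hold], tgt[~hold]]))
    err = np.abs(warp.predict(src[hold]) - true_warp(src[hold]))
    return {
        "median_abs_error_s": float(np.median(err)),
        "residual_sd_s": warp.residual_sd,
        "n_anchors": n_anchors,
    }


# ---------------------------------------------------------------------------
# interference screening vs brute force


def random_library(
    rng: np.random.Generator,
    n_entries: int,
    matrix_id: str = "m",
    gradient: float = 2000.0,
    mz_range: tuple[float, float] = (400.0, 1000.0),
    n_fragments: int = 6,
) -> SpectralLibrary:
    """A random target-only library for screening studies: tryptic-like
    peptides with true mass ladders, uniform RTs, 2+ precursors inside the
    acquisition range."""
    entries = []
    seen = set()
    while len(entries) < n_entries:
        pep, ladder = make_peptide(rng, min_len=7, max_len=18)
        if pep in seen:
            continue
        mz = _mass.precursor_mz(pep, 2)
        if not mz_range[0] + 0.5 <= mz < mz_range[1] - 0.5:
            continue
        seen.add(pep)
        frags = [
            FragmentIon(s, o, z, f_mz, float(rng.gamma(2.0, 1.0)))
            for s, o, z, f_mz in ladder
            if o >= 2 and 200.0 <= f_mz <= 1800.0
        ][:n_fragments]
        if len(frags) < 2:
            continue
        entries.append(
            LibraryEntry(
                peptide=pep,
                precursor_charge=2,
                precursor_mz=mz,
                score=float(rng.normal()),
                is_decoy=False,
                matrix_id=matrix_id,
                rt=float(rng.uniform(0.0, gradient)),
                fragments=frags,
            )
        )
    return SpectralLibrary(matrix_id=matrix_id, entries=entries)


def brute_force_flags(
    library: SpectralLibrary, scheme: IsolationScheme, cfg: PipelineConfig
) -> set[tuple[str, int, tuple]]:
    """Naive all-pairs enumeration of flagged (peptide, charge, fragment_key)
    triples — the independent oracle for the indexed implementation."""
    targets = [e for e in library.entries if not e.is_decoy]
    flagged = set()
    for a in targets:
        for e in targets:
            if (e.peptide, e.precursor_charge) == (a.peptide, a.precursor_charge):
                continue
            if abs(e.rt - a.rt) > cfg.coelution_tolerance:
                continue
            if cfg.cofragmentation_rule == "demultiplexed":
                if scheme.demux_index(a.precursor_mz) != scheme.demux_index(
                    e.precursor_mz
                ):
                    continue
            else:
                if not (
                    scheme.windows_for_precursor(a.precursor_mz)
                    & scheme.windows_for_precursor(e.precursor_mz)
                ):
                    continue
            for fa in a.fragments:
                for fe in e.fragments:
                    if abs(fe.mz - fa.mz) / fa.mz * 1e6 <= cfg.ppm_tolerance:
                        flagged.add((a.peptide, a.precursor_charge, fa.key))
    return flagged


def implementation_flags(
    library: SpectralLibrary, scheme: IsolationScheme, cfg: PipelineConfig
) -> set[tuple[str, int, tuple]]:
    reports = find_cofragmenting_library(library, scheme, cfg)
    return {
        (pep, z, key)
        for (pep, z), per_frag in reports.items()
        for key, rep in per_frag.items()
        if rep.flagged
    }


def interference_equivalence_study(
    seed: int,
    n_libraries: int = 50,
    max_entries: int = 500,
    min_entries: int = 50,
) -> dict:
    """Exact set equality of the screening implementation against brute
    force, over random libraries and both co-fragmentation rules."""
    rng = np.random.default_rng(seed)
    cfg = PipelineConfig()
    mismatches = 0
    compared = 0
    for _ in range(n_libraries):
        n = int(rng.integers(min_entries, max_entries + 1))
        lib = random_library(rng, n)
        for rule in ("union", "demultiplexed"):
            cfg.cofragmentation_rule = rule
            compared += 1
            if implementation_flags(lib, cfg.wide_scheme, cfg) != brute_force_flags(
                lib, cfg.wide_scheme, cfg
            ):
                mismatches += 1
    return {"n_compared": compared, "n_mismatch": mismatches}


# ---------------------------------------------------------------------------
# quantification accuracy with and without harmonized ion selection


def _pipeline_objects(sim: SimulationConfig):
    """Run the in-memory pipeline stages on one simulated experiment."""
    from .fdr import compute_qvalues, pick_best_evidence
    from .pipeline import select_ions_for_accepted
    from .rt_alignment import fit_all_warps, impute_missing_rts

    cfg = PipelineConfig()
    libraries, chroms, truth = simulate_experiment(sim)
    scored = compute_qvalues(pick_best_evidence(libraries))
    accepted = global_filter(scored, cfg.fdr_alpha)
    best_matrix = {p.peptide: p.best_matrix for p in scored if not p.is_decoy}
    best_charge = {p.peptide: p.best_charge for p in scored if not p.is_decoy}
    warps = fit_all_warps(libraries)
    rt_assign = impute_missing_rts(accepted, libraries, warps, best_matrix)
    decisions = select_ions_for_accepted(libraries, chroms, accepted,
                                         best_matrix, cfg)
    harmonized = build_harmonized_libraries(
        libraries, accepted, best_matrix, best_charge, rt_assign, decisions, cfg
    )
    return cfg, libraries, chroms, truth, accepted, decisions, harmonized


def interference_quant_study(seed: int, n_seeds: int = 10) -> dict:
    """Median |log2 error| of peptide quantities for the injected-interference
    analytes: harmonized quant ions versus naive top-5-by-intensity ions.

    The error reference is the noise-free Gaussian peak area the generating
    amounts imply for the same ion subset, so interference contamination is
    the only systematic discrepancy.
    """
    harm_errs, naive_errs = [], []
    sens_hit = sens_total = 0
    clean_flagged = clean_total = 0
    for k in range(n_seeds):
        sim = SimulationConfig(seed=seed + k)
        cfg, libraries, chroms, truth, accepted, decisions, harmonized = (
            _pipeline_objects(sim)
        )
        interfered = {(a, key) for a, key, _ in truth.interference_pairs}
        for a_pep, key, _ in truth.interference_pairs:
            sens_total += 1
            dec = decisions.get(a_pep)
            if dec is not None and key not in set(dec[0]):
                sens_hit += 1  # excluded from the quant set
        # flag rate among fragments that carry no injected interference
        reports = {
            m: find_cofragmenting_library(lib, cfg.wide_scheme, cfg)
            for m, lib in libraries.items()
        }
        for m, per_entry in reports.items():
            for (pep, z), per_frag in per_entry.items():
                if pep not in truth.true_peptides:
                    continue
                for key, rep in per_frag.items():
                    if (pep, key) in interfered:
                        continue
                    clean_total += 1
                    if rep.flagged:
                        clean_flagged += 1

        for a_pep, key, _ in truth.interference_pairs:
            if a_pep not in accepted or not decisions.get(a_pep, (None, None, False))[2]:
                continue
            for m, lib in libraries.items():
                entry = lib.by_precursor().get((a_pep, 2))
                if entry is None or entry.is_decoy or a_pep not in truth.matrix_rt[m]:
                    continue
                harm_entry = next(
                    e for e in harmonized[m].entries if e.peptide == a_pep
                )
                quant_keys = [
                    f.key for f in harm_entry.fragments if f.quant_flag == QUANT
                ]
                naive_keys = [
                    f.key
                    for f in sorted(
                        harm_entry.fragments,
                        key=lambda f: -f.library_intensity,
                    )[:5]
                ]
                intens = {f.key: f.library_intensity for f in entry.fragments}
                for run_id, info in truth.run_meta.items():
                    if info["matrix_id"] != m:
                        continue
                    traces = chroms.precursor_traces(run_id, a_pep, 2)
                    if not traces:
                        continue
                    amount = truth.peptide_amount[run_id].get(a_pep)
                    if amount is None:
                        continue
                    for keys, errs in ((quant_keys, harm_errs),
                                       (naive_keys, naive_errs)):
                        sub = entry.copy()
                        for f in sub.fragments:
                            f.quant_flag = QUANT if f.key in set(keys) else "detection_only"
                        est = integrate_peptide(
                            traces, sub,
                            default_boundary(harm_entry, run_id, sim.peak_sigma),
                        )
                        pred = expected_peak_area(
                            amount,
                            [intens[kk] for kk in keys if kk in intens],
                            sim.peak_sigma,
                        )
                        if est and est > 0 and pred > 0:
                            errs.append(abs(np.log2(est / pred)))
    return {
        "harmonized_median_abs_log2_error": float(np.median(harm_errs)),
        "naive_top5_median_abs_log2_error": float(np.median(naive_errs)),
        "interference_exclusion_sensitivity": sens_hit / sens_total,
        "clean_fragment_flag_rate": clean_flagged / max(clean_total, 1),
        "n_seeds": n_seeds,
        "n_measurements": len(harm_errs),
    }


def fold_change_recovery_study(seed: int, n_seeds: int = 5) -> dict:
    """Recovery of the spiked two-fold protein changes after harmonized
    quantification, normalization and unique-peptide roll-up."""
    from .quantify import build_quant_table, normalize_log2, rollup_protein

    import pandas as pd

    errs = []
    for k in range(n_seeds):
        sim = SimulationConfig(seed=seed + 1000 + k)
        cfg, libraries, chroms, truth, accepted, decisions, harmonized = (
            _pipeline_objects(sim)
        )
        meta = pd.DataFrame.from_dict(truth.run_meta, orient="index")
        meta.index.name = "run_id"
        pep_table = build_quant_table(harmonized, chroms, meta, cfg.peak_sigma)
        prot = rollup_protein(pep_table, truth.protein_map)
        norm = normalize_log2(prot)
        groups = meta["group"]
        healthy = [r for r in norm.values.columns if groups[r] == "healthy"]
        disease = [r for r in norm.values.columns if groups[r] == "disease"]
        for acc, fc in truth.diff_proteins.items():
            if acc not in norm.values.index:
                continue
            d = (
                norm.values.loc[acc, disease].mean()
                - norm.values.loc[acc, healthy].mean()
            )
            if not np.isnan(d):
                errs.append(abs(float(d) - np.log2(fc)))
    return {
        "median_abs_error_log2": float(np.median(errs)),
        "n_proteins": len(errs),
        "n_seeds": n_seeds,
    }
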
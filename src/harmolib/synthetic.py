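"""Synthetic multi-biofluid DIA experiments with known ground truth.

The generator emulates the measurement design this workflow targets: three
biofluid matrices ("urine", "plasma", "serum"), each with its own chromatogram
library (targets plus decoys, scores drawn from a two-component mixture),
matrix-specific monotone retention-time warps, per-matrix detection
probabilities, Gaussian elution profiles with multiplicative noise, injected
co-isolating interferers, and known protein abundances with group fold
changes. Every random draw flows from one seed, so outputs are reproducible
byte for byte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import _mass
from .errors import ConfigError
from .model import (
    ChromatogramSet,
    ChromatogramTrace,
    FragmentIon,
    IsolationScheme,
    LibraryEntry,
    PipelineConfig,
    SpectralLibrary,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_MZ_MIN, _MZ_MAX = 200.0, 1800.0  # fragment m/z acceptance band


def make_peptide(rng: np.random.Generator, min_len: int = 7, max_len: int = 25):
    """Random tryptic-like peptide (length 7-25, C-terminal K/R) and its
    singly-charged y/b fragment ladder.

    Cysteines carry the fixed carbamidomethyl modification; fragment m/z come
    from the monoisotopic residue-mass table so downstream ppm-tolerance logic
    sees realistic mass coincidences.
    """
    n = int(rng.integers(min_len, max_len + 1))
    body = rng.choice(list(AMINO_ACIDS), size=n - 1)
    last = rng.choice(["K", "R"])
    residues = [*body, last]
    pep = "".join(_mass.CYS_CAM if aa == "C" else aa for aa in residues)
    return pep, _mass.fragment_ladder(pep)


# ---------------------------------------------------------------------------
# retention-time warps: affine + low-amplitude sinusoid, strictly monotone


def warp_time(params: dict, t):
    """slope * t + offset + amp * sin(t / period); monotone when
    slope > amp / period."""
    t = np.asarray(t, dtype=float)
    return params["slope"] * t + params["offset"] + params["amp"] * np.sin(
        t / params["period"]
    )


def inverse_warp(params: dict, y: float, t_max: float = 1e6) -> float:
    return brentq(lambda t: warp_time(params, t) - y, -t_max, t_max)


_DEFAULT_WARPS = {
    "urine": {"slope": 1.0, "offset": 0.0, "amp": 0.0, "period": 1800.0},
    "plasma": {"slope": 0.97, "offset": 60.0, "amp": 20.0, "period": 1800.0},
    "serum": {"slope": 1.03, "offset": -40.0, "amp": 15.0, "period": 1500.0},
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment.

    Defaults describe the emulated study conditions: a 90-minute gradient,
    three biofluids with unequal detection probabilities, well-separated
    target score mixtures, 6-second Gaussian peaks, 5% multiplicative noise,
    and two-fold protein changes in the "disease" group.
    """

    n_true_peptides: int = 150
    n_false_targets: int = 100
    n_decoys: int = 250
    matrices: tuple[str, ...] = ("urine", "plasma", "serum")
    detection_probability: dict[str, float] | float = field(
        default_factory=lambda: {"urine": 0.95, "plasma": 0.8, "serum": 0.8}
    )
    true_score_mean: float = 4.5
    true_score_sd: float = 1.0
    null_score_mean: float = 0.0
    null_score_sd: float = 1.0
    gradient_length: float = 5400.0  # seconds
    warp_params: dict[str, dict] = field(
        default_factory=lambda: {m: dict(p) for m, p in _DEFAULT_WARPS.items()}
    )
    rt_jitter_sd: float = 3.0  # seconds, library RT jitter about the warp
    peak_sigma: float = 6.0  # seconds
    trace_dt: float = 1.0  # seconds between chromatogram samples
    apex_jitter_sd: float = 2.0  # per-run apex shift, seconds
    noise_sd: float = 0.05  # multiplicative, fraction of amplitude
    n_fragments: int = 8
    matrix_intensity_jitter: float = 0.1  # log-normal sd across matrices
    run_intensity_jitter: float = 0.1  # log-normal sd across runs
    n_interference_pairs: int = 12
    interference_strength: float = 2.0  # interferer amount / analyte amount
    interference_rt_offset: tuple[float, float] = (5.0, 15.0)  # |dRT| range, s
    runs_per_matrix: int = 6
    peptides_per_protein: int = 3
    n_diff_proteins: int = 5  # with 3 peptides/protein: ~10% of true peptides
    fold_change: float = 2.0  # disease / healthy, linear
    mz_min: float = 400.0
    mz_max: float = 1000.0  # precursors kept inside the wide-window range
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.detection_probability, (int, float)):
            self.detection_probability = {
                m: float(self.detection_probability) for m in self.matrices
            }
        for m in self.matrices:
            p = self.detection_probability.get(m)
            if p is None or not 0 < p <= 1:
                raise ConfigError(f"detection_probability for {m!r} must be in (0, 1]")
            w = self.warp_params.get(m)
            if w is None:
                raise ConfigError(f"no warp parameters for matrix {m!r}")
            if w["slope"] <= abs(w["amp"]) / w["period"]:
                raise ConfigError(f"warp for {m!r} is not monotone")
        if self.n_interference_pairs > self.n_true_peptides:
            raise ConfigError("n_interference_pairs exceeds n_true_peptides")
        if self.n_interference_pairs > self.n_false_targets:
            raise ConfigError("n_interference_pairs exceeds n_false_targets")
        if self.runs_per_matrix < 2:
            raise ConfigError("runs_per_matrix must be >= 2")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    true_peptides: set[str]
    false_targets: set[str]
    decoys: set[str]
    warp_params: dict[str, dict]
    reference_rt: dict[str, float]  # peptide -> gradient-reference RT
    matrix_rt: dict[str, dict[str, float]]  # matrix -> peptide -> library RT
    interference_pairs: list[tuple[str, tuple[str, int, int], str]]
    protein_map: dict[str, str]  # true peptide -> protein accession
    protein_abundance: dict[str, dict[str, float]]  # matrix -> protein -> base
    diff_proteins: dict[str, float]  # protein -> disease/healthy fold change
    run_meta: dict[str, dict]  # run_id -> {matrix_id, subject, group}
    peptide_amount: dict[str, dict[str, float]]  # run_id -> peptide -> amount

    def to_json(self, path: str | Path) -> None:
        d = {
            "true_peptides": sorted(self.true_peptides),
            "false_targets": sorted(self.false_targets),
            "decoys": sorted(self.decoys),
            "warp_params": self.warp_params,
            "reference_rt": self.reference_rt,
            "matrix_rt": self.matrix_rt,
            "interference_pairs": [
                [a, list(k), b] for a, k, b in self.interference_pairs
            ],
            "protein_map": self.protein_map,
            "protein_abundance": self.protein_abundance,
            "diff_proteins": self.diff_proteins,
            "run_meta": self.run_meta,
            "peptide_amount": self.peptide_amount,
        }
        with Path(path).open("w") as fh:
            json.dump(d, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with Path(path).open() as fh:
            d = json.load(fh)
        return cls(
            true_peptides=set(d["true_peptides"]),
            false_targets=set(d["false_targets"]),
            decoys=set(d["decoys"]),
            warp_params=d["warp_params"],
            reference_rt=d["reference_rt"],
            matrix_rt=d["matrix_rt"],
            interference_pairs=[
                (a, (k[0], int(k[1]), int(k[2])), b)
                for a, k, b in d["interference_pairs"]
            ],
            protein_map=d["protein_map"],
            protein_abundance=d["protein_abundance"],
            diff_proteins=d["diff_proteins"],
            run_meta=d["run_meta"],
            peptide_amount=d["peptide_amount"],
        )


def _draw_unique_peptides(rng, count, taken, mz_lo, mz_hi, charge=2):
    """Peptides whose 2+ precursor lands inside the acquisition range."""
    out = []
    while len(out) < count:
        pep, _ = make_peptide(rng)
        if pep in taken:
            continue
        mz = _mass.precursor_mz(pep, charge)
        if not mz_lo + 0.5 <= mz < mz_hi - 0.5:
            continue
        taken.add(pep)
        out.append(pep)
    return out


def _select_fragments(pep: str, rng, n_fragments: int) -> list[FragmentIon]:
    ladder = _mass.fragment_ladder(pep, charge=1)
    usable = [
        (s, o, z, mz)
        for s, o, z, mz in ladder
        if o >= 2 and _MZ_MIN <= mz <= _MZ_MAX
    ]
    # favour y ions, as real libraries do
    usable.sort(key=lambda f: (f[0] != "y", f[1]))
    chosen = usable[:n_fragments]
    intens = rng.gamma(shape=2.0, scale=1.0, size=len(chosen)) + 0.05
    return [
        FragmentIon(ion_series=s, ordinal=o, charge=z, mz=mz, library_intensity=float(v))
        for (s, o, z, mz), v in zip(chosen, intens)
    ]


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[dict[str, SpectralLibrary], ChromatogramSet, GroundTruth]:
    """Generate per-matrix libraries, per-run chromatograms and ground truth.

    Deterministic given ``cfg.seed``. Chromatograms are produced for true
    targets and injected interferers (the species downstream quantification
    can see); decoys and ordinary false targets exist only as library rows.
    """
    rng = np.random.default_rng(cfg.seed)
    taken: set[str] = set()
    true_peps = _draw_unique_peptides(
        rng, cfg.n_true_peptides, taken, cfg.mz_min, cfg.mz_max
    )
    false_peps = _draw_unique_peptides(
        rng, cfg.n_false_targets, taken, cfg.mz_min, cfg.mz_max
    )
    decoy_peps = _draw_unique_peptides(
        rng, cfg.n_decoys, taken, cfg.mz_min, cfg.mz_max
    )

    reference_rt = {
        p: float(rng.uniform(0.05, 0.95) * cfg.gradient_length)
        for p in true_peps + false_peps + decoy_peps
    }

    # peptide -> protein, and per-matrix protein abundances
    proteins = []
    protein_map = {}
    for i, pep in enumerate(true_peps):
        acc = f"PROT{i // cfg.peptides_per_protein + 1:04d}"
        protein_map[pep] = acc
        if not proteins or proteins[-1] != acc:
            proteins.append(acc)
    protein_abundance = {
        m: {acc: float(10 ** rng.uniform(4.0, 6.0)) for acc in proteins}
        for m in cfg.matrices
    }
    diff_proteins = {acc: cfg.fold_change for acc in proteins[: cfg.n_diff_proteins]}
    response = {p: float(rng.lognormal(0.0, 0.3)) for p in true_peps}

    # base fragment templates shared across matrices
    base_frags = {p: _select_fragments(p, rng, cfg.n_fragments) for p in true_peps}
    for p in false_peps + decoy_peps:
        base_frags[p] = _select_fragments(p, rng, cfg.n_fragments)

    # interference pairs: analyte = true peptide (diff-protein peptides first,
    # so group-comparison effects of interference are observable), interferer =
    # a false target re-positioned to co-isolate, co-elute and share a fragment
    # m/z within tolerance with the analyte's most intense fragment.
    diff_first = [p for p in true_peps if protein_map[p] in diff_proteins]
    others = [p for p in true_peps if protein_map[p] not in diff_proteins]
    analytes = (diff_first + others)[: cfg.n_interference_pairs]
    interferers = false_peps[: cfg.n_interference_pairs]
    interference_pairs = []
    interferer_override = {}  # interferer pep -> (precursor_mz, frag0_mz)
    for a_pep, i_pep in zip(analytes, interferers):
        a_frags = base_frags[a_pep]
        target_frag = max(a_frags, key=lambda f: f.library_intensity)
        a_mz = _mass.precursor_mz(a_pep, 2)
        d_mz = float(rng.uniform(1.0, 4.0) * rng.choice([-1.0, 1.0]))
        if not cfg.mz_min + 0.5 <= a_mz + d_mz < cfg.mz_max - 0.5:
            d_mz = -d_mz
        ppm = float(rng.uniform(-8.0, 8.0))
        interferer_override[i_pep] = (
            a_mz + d_mz,
            target_frag.mz * (1.0 + ppm * 1e-6),
        )
        interference_pairs.append((a_pep, target_frag.key, i_pep))
    interferer_set = set(interferers)
    analyte_of = {i: a for a, _, i in interference_pairs}

    # run design: one run per subject per matrix; first half healthy
    run_meta = {}
    half = cfg.runs_per_matrix // 2
    for m in cfg.matrices:
        for s in range(cfg.runs_per_matrix):
            run_id = f"{m}_s{s:02d}"
            run_meta[run_id] = {
                "matrix_id": m,
                "subject": f"s{s:02d}",
                "group": "healthy" if s < half else "disease",
            }

    libraries: dict[str, SpectralLibrary] = {}
    matrix_rt: dict[str, dict[str, float]] = {}
    detected: dict[str, set[str]] = {}
    for m in cfg.matrices:
        wp = cfg.warp_params[m]
        p_detect = cfg.detection_probability[m]
        entries = []
        rts: dict[str, float] = {}
        det: set[str] = set()
        for pep in true_peps:
            if rng.random() > p_detect:
                rng.normal()  # keep the stream aligned across matrices
                continue
            det.add(pep)
            rt = float(
                warp_time(wp, reference_rt[pep]) + rng.normal(0, cfg.rt_jitter_sd)
            )
            rt = max(rt, 0.0)
            rts[pep] = rt
            frags = [
                FragmentIon(
                    f.ion_series, f.ordinal, f.charge, f.mz,
                    f.library_intensity
                    * float(rng.lognormal(0.0, cfg.matrix_intensity_jitter)),
                )
                for f in base_frags[pep]
            ]
            entries.append(
                LibraryEntry(
                    peptide=pep,
                    precursor_charge=2,
                    precursor_mz=_mass.precursor_mz(pep, 2),
                    score=float(rng.normal(cfg.true_score_mean, cfg.true_score_sd)),
                    is_decoy=False,
                    matrix_id=m,
                    rt=rt,
                    fragments=frags,
                )
            )
        decoy_set = set(decoy_peps)
        for pep in false_peps + decoy_peps:
            is_decoy = pep in decoy_set
            if pep in interferer_override:
                prec_mz, frag0_mz = interferer_override[pep]
                a_rt = rts.get(analyte_of[pep])
                if a_rt is None:
                    base = warp_time(wp, reference_rt[pep])
                else:
                    lo, hi = cfg.interference_rt_offset
                    base = a_rt + float(
                        rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                    )
                rt = max(float(base), 0.0)
            else:
                prec_mz = _mass.precursor_mz(pep, 2)
                frag0_mz = None
                rt = max(
                    float(
                        warp_time(wp, reference_rt[pep])
                        + rng.normal(0, cfg.rt_jitter_sd)
                    ),
                    0.0,
                )
            rts[pep] = rt
            frags = []
            for j, f in enumerate(base_frags[pep]):
                mz = frag0_mz if (j == 0 and frag0_mz is not None) else f.mz
                frags.append(
                    FragmentIon(
                        f.ion_series, f.ordinal, f.charge, mz,
                        f.library_intensity
                        * float(rng.lognormal(0.0, cfg.matrix_intensity_jitter)),
                    )
                )
            entries.append(
                LibraryEntry(
                    peptide=pep,
                    precursor_charge=2,
                    precursor_mz=prec_mz,
                    score=float(rng.normal(cfg.null_score_mean, cfg.null_score_sd)),
                    is_decoy=is_decoy,
                    matrix_id=m,
                    rt=rt,
                    fragments=frags,
                )
            )
        libraries[m] = SpectralLibrary(matrix_id=m, entries=entries,
                                       provenance=f"simulated seed={cfg.seed}")
        matrix_rt[m] = rts
        detected[m] = det

    # ---- chromatograms ---------------------------------------------------
    chroms = ChromatogramSet()
    peptide_amount: dict[str, dict[str, float]] = {r: {} for r in run_meta}
    sigma = cfg.peak_sigma
    half_span = 4.0 * sigma

    def gauss(times, apex, amp):
        return amp * np.exp(-0.5 * ((times - apex) / sigma) ** 2)

    apex_of: dict[tuple[str, str], float] = {}  # (run, peptide) -> apex
    for m in cfg.matrices:
        lib = libraries[m].by_precursor()
        for s in range(cfg.runs_per_matrix):
            run_id = f"{m}_s{s:02d}"
            group = run_meta[run_id]["group"]
            quant_peps = [p for p in true_peps if p in detected[m]]
            quant_peps += [p for p in interferer_set if p in matrix_rt[m]]
            for pep in quant_peps:
                entry = lib[(pep, 2)]
                if pep in interferer_set:
                    a_acc = protein_map[analyte_of[pep]]
                    base = protein_abundance[m][a_acc] * cfg.interference_strength
                    amount = base * float(rng.lognormal(0.0, cfg.run_intensity_jitter))
                else:
                    acc = protein_map[pep]
                    base = protein_abundance[m][acc] * response[pep]
                    if group == "disease" and acc in diff_proteins:
                        base *= diff_proteins[acc]
                    amount = base * float(rng.lognormal(0.0, cfg.run_intensity_jitter))
                peptide_amount[run_id][pep] = amount
                apex = matrix_rt[m][pep] + float(rng.normal(0, cfg.apex_jitter_sd))
                apex_of[(run_id, pep)] = apex
                t0 = max(apex - half_span, 0.0)
                times = np.arange(t0, apex + half_span + cfg.trace_dt / 2, cfg.trace_dt)
                for f in entry.fragments:
                    prof = gauss(times, apex, amount * f.library_intensity)
                    noise = 1.0 + rng.normal(0.0, cfg.noise_sd, size=prof.size)
                    chroms.add(
                        ChromatogramTrace(
                            run_id=run_id,
                            matrix_id=m,
                            peptide=pep,
                            precursor_charge=2,
                            fragment_key=f.key,
                            times=times,
                            intensities=np.clip(prof * noise, 0.0, None),
                        )
                    )

    # add interferer signal onto the analyte's matching fragment trace
    for a_pep, fkey, i_pep in interference_pairs:
        for m in cfg.matrices:
            if a_pep not in detected[m] or i_pep not in matrix_rt[m]:
                continue
            i_entry = libraries[m].by_precursor()[(i_pep, 2)]
            i_amp_frac = i_entry.fragments[0].library_intensity
            for s in range(cfg.runs_per_matrix):
                run_id = f"{m}_s{s:02d}"
                tr = chroms.precursor_traces(run_id, a_pep, 2).get(fkey)
                if tr is None:
                    continue
                i_apex = apex_of[(run_id, i_pep)]
                i_amount = peptide_amount[run_id][i_pep]
                tr.intensities = tr.intensities + gauss(
                    tr.times, i_apex, i_amount * i_amp_frac
                )

    truth = GroundTruth(
        true_peptides=set(true_peps),
        false_targets=set(false_peps),
        decoys=set(decoy_peps),
        warp_params={m: dict(cfg.warp_params[m]) for m in cfg.matrices},
        reference_rt=reference_rt,
        matrix_rt=matrix_rt,
        interference_pairs=interference_pairs,
        protein_map=protein_map,
        protein_abundance=protein_abundance,
        diff_proteins=diff_proteins,
        run_meta=run_meta,
        peptide_amount=peptide_amount,
    )
    return libraries, chroms, truth


def expected_peak_area(amount: float, library_intensities, sigma: float) -> float:
    """Noise-free total area of a peptide's Gaussian fragment peaks for a
    given ion subset: amount * sum(intensity) * sigma * sqrt(2*pi)."""
    return amount * float(np.sum(library_intensities)) * sigma * math.sqrt(2 * math.pi)


def simulate_scores(
    n_targets: int,
    true_fraction: float,
    n_decoys: int,
    rng: np.random.Generator,
    true_mean: float = 3.5,
    true_sd: float = 1.0,
    null_mean: float = 0.0,
    null_sd: float = 1.0,
):
    """Lightweight score-only mixture for FDR-calibration studies.

    Returns (scores, is_decoy, is_true) arrays: targets are a mixture of
    true (high) and false (null) components; decoys are pure null.
    """
    n_true = int(round(n_targets * true_fraction))
    t_scores = np.concatenate(
        [
            rng.normal(true_mean, true_sd, n_true),
            rng.normal(null_mean, null_sd, n_targets - n_true),
        ]
    )
    d_scores = rng.normal(null_mean, null_sd, n_decoys)
    scores = np.concatenate([t_scores, d_scores])
    is_decoy = np.concatenate(
        [np.zeros(n_targets, dtype=bool), np.ones(n_decoys, dtype=bool)]
    )
    is_true = np.concatenate(
        [
            np.ones(n_true, dtype=bool),
            np.zeros(n_targets - n_true + n_decoys, dtype=bool),
        ]
    )
    return scores, is_decoy, is_true


def demo_simulation_config(seed: int = 1, **overrides) -> SimulationConfig:
    """Reduced-size configuration used by the packaged demo and smoke tests."""
    kwargs = dict(
        n_true_peptides=150,
        n_false_targets=80,
        n_decoys=230,
        n_interference_pairs=8,
        runs_per_matrix=4,
        n_diff_proteins=5,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
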
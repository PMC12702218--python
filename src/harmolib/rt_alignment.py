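"""Retention-time calibration between biofluid matrices.

Peptides identified in two matrices anchor a monotone warp between their RT
spaces. The warp is fitted by a kernel-density construction: source RTs are
binned on a uniform grid, the Gaussian-kernel density mode of the target RTs
in each bin gives that bin's calibration point, and isotonic regression over
the bin modes enforces monotonicity. Evaluation is linear interpolation
between the resulting knots, with linear extrapolation past the ends.
Peptides missing from a matrix get a match-between-runs RT imputed through
the warp from their best-scoring matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .errors import (
    DegenerateInputError,
    HarmolibError,
    InsufficientAnchorsError,
    UnimputableError,
)
from .model import IMPUTED, OBSERVED, SpectralLibrary


@dataclass
class RTWarp:
    """Piecewise-linear monotone map from one matrix's RT space to another's."""

    source_matrix: str
    target_matrix: str
    knots: np.ndarray  # (k, 2) ascending source RT -> target RT
    residual_sd: float  # seconds, MAD-based
    n_anchors: int = 0

    def __post_init__(self):
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[1] != 2 or len(self.knots) < 2:
            raise HarmolibError("warp needs >= 2 (source, target) knots")
        if np.any(np.diff(self.knots[:, 0]) <= 0):
            raise HarmolibError("warp knot sources must be strictly ascending")
        if np.any(np.diff(self.knots[:, 1]) < 0):
            raise HarmolibError("warp must be monotone non-decreasing")

    def predict(self, rt_source):
        """Warp source RT(s) to the target matrix (seconds)."""
        scalar = np.isscalar(rt_source)
        x = np.atleast_1d(np.asarray(rt_source, dtype=float))
        if np.any(x < 0):
            raise HarmolibError("retention times must be >= 0 s")
        xs, ys = self.knots[:, 0], self.knots[:, 1]
        y = np.interp(x, xs, ys)
        # linear extrapolation from the end segments
        lo = x < xs[0]
        hi = x > xs[-1]
        if np.any(lo):
            s = (ys[1] - ys[0]) / (xs[1] - xs[0])
            y[lo] = ys[0] + s * (x[lo] - xs[0])
        if np.any(hi):
            s = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            y[hi] = ys[-1] + s * (x[hi] - xs[-1])
        return float(y[0]) if scalar else y


def predict_rt(warp: RTWarp, rt_source):
    return warp.predict(rt_source)


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 1.0  # seconds; degenerate bin, kernel width floor
    return 0.9 * spread * n ** (-0.2)


def _kde_mode_index(y: np.ndarray, bandwidth: float) -> int:
    """Index of the Gaussian-kernel density mode, maximized over the sample
    points.

    Evaluating the density only at the observations keeps the mode on-sample
    and makes the estimate robust to a minority of outliers.
    """
    if y.size == 1:
        return 0
    diff = (y[:, None] - y[None, :]) / bandwidth
    dens = np.exp(-0.5 * diff**2).sum(axis=1)
    return int(np.argmax(dens))


def fit_kde_warp(
    anchor_pairs,
    bandwidth: float | str = "auto",
    n_bins: int = 64,
    min_bin_count: int = 1,
    source_matrix: str = "",
    target_matrix: str = "",
) -> RTWarp:
    """Fit a monotone RT warp from (source RT, target RT) anchor pairs.

    ``bandwidth`` is the Gaussian kernel width in seconds, or "auto" for
    Silverman's rule computed per bin.
    """
    pairs = np.asarray(list(anchor_pairs), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2:
        raise HarmolibError("anchor_pairs must be (rt_source, rt_target) pairs")
    n = len(pairs)
    if n < 20:
        raise InsufficientAnchorsError(
            f"need >= 20 anchor pairs to fit a warp, got {n}"
        )
    src, tgt = pairs[:, 0], pairs[:, 1]
    if np.ptp(src) <= 0 or np.ptp(tgt) <= 0:
        raise DegenerateInputError("anchors have zero retention-time variance")

    edges = np.linspace(src.min(), src.max(), n_bins + 1)
    idx = np.clip(np.digitize(src, edges) - 1, 0, n_bins - 1)

    # the knot is the anchor whose target RT maximizes the bin's kernel
    # density, so a perfect (e.g. identity) relation is reproduced exactly
    knot_x, knot_y, weights = [], [], []
    for b in range(n_bins):
        in_bin = idx == b
        y = tgt[in_bin]
        if y.size < min_bin_count or y.size == 0:
            continue
        bw = _silverman_bandwidth(y) if bandwidth == "auto" else float(bandwidth)
        k = _kde_mode_index(y, bw)
        knot_x.append(float(src[in_bin][k]))
        knot_y.append(float(y[k]))
        weights.append(y.size)
    if len(knot_x) < 2:
        raise DegenerateInputError("fewer than two populated RT bins")
    if np.any(np.diff(knot_x) <= 0):  # duplicate edge values across bins
        keep = np.concatenate([[True], np.diff(knot_x) > 0])
        knot_x = list(np.asarray(knot_x)[keep])
        knot_y = list(np.asarray(knot_y)[keep])
        weights = list(np.asarray(weights)[keep])

    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    fitted = iso.fit_transform(knot_x, knot_y, sample_weight=weights)

    warp = RTWarp(
        source_matrix=source_matrix,
        target_matrix=target_matrix,
        knots=np.column_stack([knot_x, fitted]),
        residual_sd=0.0,
        n_anchors=n,
    )
    resid = tgt - warp.predict(src)
    warp.residual_sd = float(1.4826 * np.median(np.abs(resid)))
    return warp


def anchor_pairs_between(
    lib_a: SpectralLibrary, lib_b: SpectralLibrary
) -> np.ndarray:
    """(RT_a, RT_b) for target peptides identified in both matrices, using
    each matrix's best-scoring charge state."""

    def best_rts(lib):
        out = {}
        for e in lib.targets():
            cur = out.get(e.peptide)
            if cur is None or e.score > cur[0]:
                out[e.peptide] = (e.score, e.rt)
        return {p: rt for p, (_, rt) in out.items()}

    ra, rb = best_rts(lib_a), best_rts(lib_b)
    shared = sorted(set(ra) & set(rb))
    return np.array([[ra[p], rb[p]] for p in shared], dtype=float)


def fit_all_warps(
    libraries: dict[str, SpectralLibrary],
    bandwidth: float | str = "auto",
    n_bins: int = 64,
    min_anchors: int = 20,
) -> dict[tuple[str, str], RTWarp]:
    """Warps for every ordered matrix pair sharing >= ``min_anchors``."""
    warps = {}
    mats = sorted(libraries)
    for a in mats:
        for b in mats:
            if a == b:
                continue
            pairs = anchor_pairs_between(libraries[a], libraries[b])
            if len(pairs) < min_anchors:
                continue
            warps[(a, b)] = fit_kde_warp(
                pairs, bandwidth=bandwidth, n_bins=n_bins,
                source_matrix=a, target_matrix=b,
            )
    return warps


def _predict_via(warps, src: str, dst: str, rt: float) -> float | None:
    """Predict through a direct warp, else compose through the intermediate
    matrix with the most shared anchors; None if no route exists."""
    direct = warps.get((src, dst))
    if direct is not None:
        return direct.predict(rt)
    candidates = []
    for (a, b), w1 in warps.items():
        if a != src:
            continue
        w2 = warps.get((b, dst))
        if w2 is not None:
            candidates.append((min(w1.n_anchors, w2.n_anchors), b, w1, w2))
    if not candidates:
        return None
    _, _, w1, w2 = max(candidates, key=lambda c: (c[0], c[1]))
    return w2.predict(w1.predict(rt))


def impute_missing_rts(
    accepted: set[str],
    libraries: dict[str, SpectralLibrary],
    warps: dict[tuple[str, str], RTWarp],
    best_matrix: dict[str, str],
) -> dict[str, dict[str, tuple[float, str]]]:
    """Per matrix, an RT (and origin flag) for every accepted peptide.

    A peptide observed in a matrix keeps its observed RT; otherwise the RT is
    warped over from its best-scoring matrix (match-between-runs).
    """
    observed: dict[str, dict[str, float]] = {}
    for m, lib in libraries.items():
        rts: dict[str, float] = {}
        best_score: dict[str, float] = {}
        for e in lib.targets():
            if e.peptide in accepted and (
                e.peptide not in rts or e.score > best_score[e.peptide]
            ):
                rts[e.peptide] = e.rt
                best_score[e.peptide] = e.score
        observed[m] = rts

    result: dict[str, dict[str, tuple[float, str]]] = {}
    failures: list[str] = []
    for m in libraries:
        assign: dict[str, tuple[float, str]] = {}
        for pep in accepted:
            if pep in observed[m]:
                assign[pep] = (observed[m][pep], OBSERVED)
                continue
            src = best_matrix.get(pep)
            if src is None or pep not in observed.get(src, {}):
                failures.append(pep)
                continue
            rt = _predict_via(warps, src, m, observed[src][pep])
            if rt is None:
                failures.append(pep)
                continue
            assign[pep] = (max(float(rt), 0.0), IMPUTED)
        result[m] = assign
    if failures:
        raise UnimputableError(
            f"no warp route for {len(set(failures))} peptide(s)", sorted(set(failures))
        )
    return result
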
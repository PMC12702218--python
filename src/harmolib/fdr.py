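"""Global peptide-level error control across biofluid libraries.

Each peptide keeps its single best-scoring occurrence over all matrices and
charge states ("picked" target-decoy competition); q-values come from the
conservative +1 estimator, and the global filter at the configured alpha
(default 1%) defines the shared peptide set of the harmonized libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import HarmolibError, IntegrityError
from .model import SpectralLibrary

log = logging.getLogger(__name__)


@dataclass
class ScoredPeptide:
    """Best evidence for one peptide across every library."""

    peptide: str
    best_matrix: str
    best_score: float
    is_decoy: bool
    best_charge: int = 0
    q_value: float = float("nan")


def pick_best_evidence(libraries) -> list[ScoredPeptide]:
    """Collapse libraries to one record per peptide: the maximal-score
    occurrence wins; exact score ties break to the lexicographically smallest
    matrix_id so the choice is deterministic."""
    if isinstance(libraries, dict):
        libraries = list(libraries.values())
    if not libraries:
        raise HarmolibError("at least one library required")
    best: dict[str, ScoredPeptide] = {}
    for lib in libraries:
        for e in lib.entries:
            cur = best.get(e.peptide)
            if cur is None:
                best[e.peptide] = ScoredPeptide(
                    peptide=e.peptide,
                    best_matrix=e.matrix_id,
                    best_score=e.score,
                    best_charge=e.precursor_charge,
                    is_decoy=e.is_decoy,
                )
                continue
            if cur.is_decoy != e.is_decoy:
                raise IntegrityError(
                    f"peptide {e.peptide!r} is target in one library and decoy "
                    f"in another"
                )
            if e.score > cur.best_score or (
                e.score == cur.best_score and e.matrix_id < cur.best_matrix
            ):
                cur.best_matrix = e.matrix_id
                cur.best_score = e.score
                cur.best_charge = e.precursor_charge
    return sorted(best.values(), key=lambda p: p.peptide)


def qvalues_from_scores(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """q-values for *target* scores under the +1 target-decoy estimator.

    FDR_hat(t) = (1 + #decoys >= t) / (#targets >= t), evaluated at every
    target score t; q(s) = min over thresholds t <= s of FDR_hat(t), capped
    at 1. Returns an array aligned with ``scores`` (decoy positions get the
    q-value of the threshold at their score).
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    t_scores = scores[~is_decoy]
    d_scores = scores[is_decoy]
    if t_scores.size == 0:
        raise HarmolibError("q-value estimation requires at least one target")
    if d_scores.size == 0:
        log.warning("no decoys present; FDR estimated from the +1 numerator only")

    order = np.argsort(-t_scores, kind="stable")  # descending
    sorted_t = t_scores[order]
    d_sorted = np.sort(d_scores)
    # counts at threshold = each sorted target score (ties share counts)
    n_t_ge = t_scores.size - np.searchsorted(sorted_t[::-1], sorted_t, side="left")
    n_d_ge = d_sorted.size - np.searchsorted(d_sorted, sorted_t, side="left")
    fdr = (1.0 + n_d_ge) / n_t_ge
    q_sorted = np.minimum(np.minimum.accumulate(fdr[::-1])[::-1], 1.0)

    out = np.empty_like(scores)
    t_out = np.empty(t_scores.size)
    t_out[order] = q_sorted  # invert the descending-sort permutation
    out[~is_decoy] = t_out
    if d_scores.size:
        # decoys take the q of the nearest target threshold at or below them
        asc_t = sorted_t[::-1]
        asc_q = q_sorted[::-1]
        idx = np.searchsorted(asc_t, d_scores, side="right") - 1
        dq = np.where(idx >= 0, asc_q[np.clip(idx, 0, None)], 1.0)
        out[is_decoy] = np.minimum(dq, 1.0)
    return out


def compute_qvalues(peptides: list[ScoredPeptide]) -> list[ScoredPeptide]:
    """Set ``q_value`` on every record in place (and return the list)."""
    scores = np.array([p.best_score for p in peptides])
    is_decoy = np.array([p.is_decoy for p in peptides])
    q = qvalues_from_scores(scores, is_decoy)
    for p, qv in zip(peptides, q):
        p.q_value = float(qv)
    return peptides


def global_filter(peptides: list[ScoredPeptide], alpha: float) -> set[str]:
    """Target peptides accepted at q <= alpha. Decoys are never returned."""
    accepted = {
        p.peptide for p in peptides if not p.is_decoy and p.q_value <= alpha
    }
    return accepted
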
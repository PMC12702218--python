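"""Assembly of the per-biofluid harmonized libraries.

After global FDR filtering, template selection, RT calibration and
quantitative-ion selection, each matrix receives a library with the *same*
peptide set, the *same* fragmentation template (copied from the peptide's
best-scoring matrix) and the *same* quant/detection-only ion flags; only the
retention times (observed or imputed) are matrix-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import IntegrityError
from .model import (
    DETECTION_ONLY,
    IMPUTED,
    QUANT,
    FragmentKey,
    LibraryEntry,
    SpectralLibrary,
)


@dataclass
class HarmonizedLibrary(SpectralLibrary):
    """A matrix's harmonized library plus the per-peptide template source."""

    template_source: dict[str, str] = field(default_factory=dict)


def build_harmonized_libraries(
    libraries: dict[str, SpectralLibrary],
    accepted: set[str],
    best_matrix: dict[str, str],
    best_charge: dict[str, int],
    rt_assignments: dict[str, dict[str, tuple[float, str]]],
    ion_decisions: dict[str, tuple[list[FragmentKey], list[FragmentKey], bool]],
    cfg,
) -> dict[str, HarmonizedLibrary]:
    """One :class:`HarmonizedLibrary` per matrix.

    ``ion_decisions`` maps peptide -> (quant keys, detection keys,
    quantifiable) as produced by transition selection. Output entries are
    ordered by (peptide, charge) so repeated runs are byte-identical.
    """
    out: dict[str, HarmonizedLibrary] = {}
    templates: dict[str, LibraryEntry] = {}
    for pep in accepted:
        src = best_matrix.get(pep)
        entry = None
        if src is not None:
            entry = libraries[src].by_precursor().get((pep, best_charge.get(pep, 0)))
            if entry is None:  # fall back to the best-scoring charge present
                cands = [
                    e for e in libraries[src].entries
                    if e.peptide == pep and not e.is_decoy
                ]
                entry = max(cands, key=lambda e: e.score, default=None)
        if entry is None or entry.is_decoy:
            raise IntegrityError(f"accepted peptide {pep!r} has no template entry")
        templates[pep] = entry

    for m in sorted(libraries):
        entries = []
        for pep in sorted(accepted):
            tmpl = templates[pep]
            quant_keys, _, quantifiable = ion_decisions.get(pep, ([], [], False))
            quant_set = set(quant_keys) if quantifiable else set()
            rt, origin = rt_assignments[m][pep]
            frags = [
                replace(f, quant_flag=QUANT if f.key in quant_set else DETECTION_ONLY)
                for f in tmpl.fragments
            ]
            entries.append(
                LibraryEntry(
                    peptide=pep,
                    precursor_charge=tmpl.precursor_charge,
                    precursor_mz=tmpl.precursor_mz,
                    score=tmpl.score,
                    is_decoy=False,
                    matrix_id=m,
                    rt=rt,
                    rt_origin=origin,
                    fragments=frags,
                )
            )
        out[m] = HarmonizedLibrary(
            matrix_id=m,
            entries=entries,
            provenance=f"harmonized from {sorted(libraries)}",
            template_source={p: best_matrix[p] for p in accepted},
        )
    return out


def harmonization_report(
    before: dict[str, SpectralLibrary],
    after: dict[str, HarmonizedLibrary],
) -> pd.DataFrame:
    """Per-matrix before/after summary of the harmonization step.

    Columns: target peptides before, peptides after, fraction of imputed
    RTs, fraction of non-quantifiable peptides, and the number of templates
    drawn from each matrix (identical across rows by construction).
    """
    matrices = sorted(before)
    columns = [
        "matrix_id", "peptides_before", "peptides_after",
        "fraction_imputed_rt", "fraction_non_quantifiable",
        *[f"templates_from_{m}" for m in matrices],
    ]
    if all(len(h.entries) == 0 for h in after.values()):
        return pd.DataFrame(columns=columns)
    rows = []
    for m in matrices:
        harm = after.get(m)
        n_after = len(harm.entries) if harm else 0
        n_imputed = sum(1 for e in harm.entries if e.rt_origin == IMPUTED) if harm else 0
        n_nonquant = (
            sum(
                1
                for e in harm.entries
                if not any(f.quant_flag == QUANT for f in e.fragments)
            )
            if harm
            else 0
        )
        row = {
            "matrix_id": m,
            "peptides_before": len(before[m].target_peptides()),
            "peptides_after": n_after,
            "fraction_imputed_rt": n_imputed / n_after if n_after else 0.0,
            "fraction_non_quantifiable": n_nonquant / n_after if n_after else 0.0,
        }
        if harm:
            src_counts = pd.Series(list(harm.template_source.values()))
            for src in matrices:
                row[f"templates_from_{src}"] = int((src_counts == src).sum())
        else:
            for src in matrices:
                row[f"templates_from_{src}"] = 0
        rows.append(row)
    return pd.DataFrame(rows)
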
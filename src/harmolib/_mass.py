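"""Monoisotopic peptide mass arithmetic.

Peptide strings use uppercase one-letter residues with modification masses in
brackets immediately after the modified residue, e.g. ``C[+57.02146]`` for
fixed carbamidomethyl cysteine. Only singly-modified residues are supported,
which covers the fixed-modification-only search space this workflow targets.
"""

from __future__ import annotations

import re

import numpy as np

# Monoisotopic residue masses (Da), unmodified.
RESIDUE_MASS = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER = 18.010565
PROTON = 1.007276

CARBAMIDOMETHYL = 57.02146
CYS_CAM = f"C[+{CARBAMIDOMETHYL:.5f}]"

_TOKEN = re.compile(r"([A-Z])(\[([+-]?\d+(?:\.\d+)?)\])?")


def parse_peptide(peptide: str) -> list[float]:
    """Return the per-residue monoisotopic masses of a bracketed sequence."""
    masses = []
    pos = 0
    for m in _TOKEN.finditer(peptide):
        if m.start() != pos:
            raise ValueError(f"unparsable peptide string at offset {pos}: {peptide!r}")
        aa = m.group(1)
        if aa not in RESIDUE_MASS:
            raise ValueError(f"unknown residue {aa!r} in {peptide!r}")
        mass = RESIDUE_MASS[aa]
        if m.group(3) is not None:
            mass += float(m.group(3))
        masses.append(mass)
        pos = m.end()
    if pos != len(peptide) or not masses:
        raise ValueError(f"unparsable peptide string: {peptide!r}")
    return masses


def strip_mods(peptide: str) -> str:
    """Bare residue sequence without bracketed modification masses."""
    return re.sub(r"\[[^\]]*\]", "", peptide)


def precursor_mz(peptide: str, charge: int) -> float:
    masses = parse_peptide(peptide)
    return (sum(masses) + WATER + charge * PROTON) / charge


def fragment_mz(peptide: str, series: str, ordinal: int, charge: int) -> float:
    """m/z of a y- or b-series fragment ion.

    y_n carries the C-terminal n residues plus water; b_n the N-terminal n
    residues. Both are protonated to the requested charge.
    """
    masses = parse_peptide(peptide)
    n = len(masses)
    if not 1 <= ordinal <= n - 1:
        raise ValueError(f"ordinal {ordinal} out of range for length-{n} peptide")
    if series == "y":
        neutral = sum(masses[n - ordinal:]) + WATER
    elif series == "b":
        neutral = sum(masses[:ordinal])
    else:
        raise ValueError(f"unknown ion series {series!r}")
    return (neutral + charge * PROTON) / charge


def fragment_ladder(peptide: str, charge: int = 1) -> list[tuple[str, int, int, float]]:
    """All y/b singly-charged fragments as (series, ordinal, charge, mz)."""
    masses = np.asarray(parse_peptide(peptide))
    n = len(masses)
    b_neutral = np.cumsum(masses)[: n - 1]
    y_neutral = np.cumsum(masses[::-1])[: n - 1] + WATER
    out = []
    for i in range(1, n):
        out.append(("b", i, charge, float((b_neutral[i - 1] + charge * PROTON) / charge)))
        out.append(("y", i, charge, float((y_neutral[i - 1] + charge * PROTON) / charge)))
    return out
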
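"""Natural-abundance correction of raw mass-isotopomer measurements.

Raw MS intensities mix the biological carbon labelling with natural heavy
isotopes of every atom in the detected ion (including derivatization
groups) and with natural 13C in the unlabelled backbone carbons.  With a
correction matrix M whose column i is the isotopologue pattern of an
analyte carrying exactly i enriched backbone carbons,

    measured = M @ carbon_mid,

the carbon MID is recovered by (non-negative) least squares and
renormalised to sum 1.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
from scipy.optimize import nnls

from .data import load_isotope_table

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class CorrectionError(ValueError):
    pass


def parse_formula(formula: str) -> dict[str, int]:
    """'C6H13O9P' -> {'C': 6, 'H': 13, 'O': 9, 'P': 1}."""
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise CorrectionError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not out:
        raise CorrectionError(f"cannot parse formula {formula!r}")
    return out


def _element_dist(element: str, count: int, table: dict) -> np.ndarray:
    """Mass-shift distribution of `count` atoms of an element."""
    if element not in table:
        raise CorrectionError(f"no isotope data for element {element}")
    single = np.zeros(max(shift for shift, _ in table[element]) + 1)
    for shift, frac in table[element]:
        single[shift] = frac
    dist = np.array([1.0])
    for _ in range(count):
        dist = np.convolve(dist, single)
    return dist


def correction_matrix(n_backbone: int, formula: str | None,
                      isotopes: dict | None = None,
                      n_rows: int | None = None) -> np.ndarray:
    """Column i: isotopologue pattern with i enriched backbone carbons.

    The remaining n_backbone - i carbons carry natural 13C; all other
    atoms of the ion formula contribute their natural mass-shift
    distribution.  Rows default to n_backbone + 1 (truncated tail).
    """
    table = isotopes or load_isotope_table()
    hetero = np.array([1.0])
    if formula:
        counts = parse_formula(formula)
        n_c = counts.pop("C", 0)
        if n_c < n_backbone:
            raise CorrectionError(
                f"ion formula {formula!r} has {n_c} C but fragment has {n_backbone}")
        extra_c = n_c - n_backbone  # derivatization / non-backbone carbons
        if extra_c:
            hetero = np.convolve(hetero, _element_dist("C", extra_c, table))
        for el, cnt in counts.items():
            hetero = np.convolve(hetero, _element_dist(el, cnt, table))
    rows = n_rows or n_backbone + 1
    M = np.zeros((rows, n_backbone + 1))
    for i in range(n_backbone + 1):
        col = _element_dist("C", n_backbone - i, table)
        col = np.convolve(col, hetero)
        pad = np.zeros(rows)
        seg = col[: rows - i]
        pad[i:i + seg.size] = seg
        M[:, i] = pad
    return M


def correct_natural_abundance(raw: np.ndarray, n_backbone: int,
                              formula: str | None = None,
                              isotopes: dict | None = None,
                              clamp_tol: float = 1e-6) -> np.ndarray:
    """Remove natural-abundance and derivatization mass shifts from a raw MID.

    `raw` may be longer than n_backbone + 1 (heteroatom tail).  Solves the
    correction matrix by non-negative least squares and renormalises; a
    plain least-squares solution with negative fractions beyond
    `clamp_tol` triggers a warning before clamping.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or raw.size < n_backbone + 1:
        raise CorrectionError(
            f"raw MID needs >= {n_backbone + 1} entries, got {raw.size}")
    M = correction_matrix(n_backbone, formula, isotopes, n_rows=raw.size)
    unconstrained, *_ = np.linalg.lstsq(M, raw, rcond=None)
    if np.any(unconstrained < -clamp_tol):
        worst = float(unconstrained.min())
        warnings.warn(
            f"natural-abundance correction produced negative fractions "
            f"(min {worst:.3g}); clamping to zero", stacklevel=2)
    corrected, _ = nnls(M, raw)
    total = corrected.sum()
    if total <= 0:
        raise CorrectionError("corrected MID sums to zero")
    return corrected / total
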
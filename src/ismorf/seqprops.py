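"""Sequence-property summaries: hydrophobicity (GRAVY) and composition.

Hydrophobicity is the grand average of hydropathy (GRAVY): the mean
Kyte-Doolittle hydropathy over residues.  Group comparisons use the
two-sided Mann-Whitney U test (exact when both groups are small and
tie-free, normal approximation with tie correction otherwise).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger("ismorf")

#: Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class ProteinProps:
    id: str
    length: int
    gravy: float
    aa_freqs: dict[str, float]
    gc_source: float | None = None


def gravy(protein: str, scale: dict[str, float] | None = None) -> float:
    """Mean hydropathy per residue (Kyte-Doolittle by default).

    Residues outside the scale (e.g. X) are excluded from the mean with a
    warning; an empty or all-unknown protein is an error.
    """
    if not protein:
        raise ValueError("empty protein")
    table = scale or KYTE_DOOLITTLE
    values = [table[aa] for aa in protein if aa in table]
    n_unknown = len(protein) - len(values)
    if n_unknown:
        logger.warning("gravy: %d residues outside the hydropathy scale excluded",
                       n_unknown)
    if not values:
        raise ValueError("no residues with defined hydropathy")
    return sum(values) / len(values)


def protein_props(pid: str, protein: str, gc_source: float | None = None) -> ProteinProps:
    counts = {aa: protein.count(aa) for aa in AMINO_ACIDS}
    total = sum(counts.values())
    freqs = {aa: (c / total if total else 0.0) for aa, c in counts.items()}
    return ProteinProps(id=pid, length=len(protein), gravy=gravy(protein),
                        aa_freqs=freqs, gc_source=gc_source)


def _mann_whitney(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0      # degenerate: all values identical
    exact = len(a) <= 20 and len(b) <= 20 and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_props(group_a: list[ProteinProps], group_b: list[ProteinProps]) -> dict:
    """Two-sided Mann-Whitney comparison of GRAVY and length between groups.

    Reports per-metric p-values, medians and IQRs.  Each group must have at
    least 5 members.
    """
    if len(group_a) < 5 or len(group_b) < 5:
        raise ValueError("each group needs >= 5 members")
    report: dict = {"n_a": len(group_a), "n_b": len(group_b)}
    for metric in ("gravy", "length"):
        a = np.asarray([getattr(p, metric) for p in group_a], dtype=float)
        b = np.asarray([getattr(p, metric) for p in group_b], dtype=float)
        report[metric] = {
            "p_value": _mann_whitney(a, b),
            "median_a": float(np.median(a)),
            "median_b": float(np.median(b)),
            "iqr_a": (float(np.quantile(a, 0.25)), float(np.quantile(a, 0.75))),
            "iqr_b": (float(np.quantile(b, 0.25)), float(np.quantile(b, 0.75))),
        }
    return report
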
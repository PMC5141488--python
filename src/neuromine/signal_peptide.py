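"""Heuristic secretory signal-peptide prediction.

Two classical observations drive the call:

1. an N-terminal hydrophobic core: some window of ``core_window`` residues
   lying within positions 2..30 whose mean Kyte-Doolittle hydropathy reaches
   ``h_min``;
2. the von Heijne (-3,-1) rule: the residues at the cleavage position and two
   before it prefer small side chains (A, G, S, C, T).

The cleavage position is searched in 10..45, anchored just downstream of the
last qualifying hydrophobic window (signal peptidase cuts a few residues
after the h-region).  The score combines both components monotonically into
[0, 1]; the default decision threshold is 0.5.  A precursor whose N-terminus
is missing (``n_complete`` false) is forced absent: the true signal is not in
the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .orf import Precursor

# Kyte & Doolittle hydropathy; X treated as neutral.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

SMALL_RESIDUES = frozenset("AGSCT")


@dataclass
class SignalParams:
    h_min: float = 1.6            # minimum mean hydropathy of the core window
    core_window: int = 8          # window length, residues
    core_region_end: int = 30     # windows must lie within positions 2..this
    min_cleavage: int = 10        # cleavage position searched in this range
    max_cleavage: int = 45
    search_span: int = 7          # how far past the core end to search
    threshold: float = 0.5        # decision threshold on the score


@dataclass
class SignalPrediction:
    present: bool
    cleavage_after: Optional[int]  # 1-based last signal residue; None if absent
    score: float = field(default=0.0)


def _small(seq: str, pos1: int) -> bool:
    """1-based small-residue lookup, False out of range."""
    return 1 <= pos1 <= len(seq) and seq[pos1 - 1] in SMALL_RESIDUES


def predict_signal_peptide(
    precursor: Union[Precursor, str],
    params: SignalParams | None = None,
) -> SignalPrediction:
    params = params or SignalParams()
    if isinstance(precursor, Precursor):
        seq = precursor.sequence
        if not precursor.n_complete:
            return SignalPrediction(False, None, 0.0)
    else:
        seq = precursor
    n = len(seq)
    if n < 12:
        return SignalPrediction(False, None, 0.0)

    w = params.core_window
    # hydrophobic-core windows, 1-based starts in 2..(core_region_end-w+1)
    best_mean = float("-inf")
    last_good_end = None
    for s in range(2, min(params.core_region_end - w + 1, n - w + 1) + 1):
        window = seq[s - 1 : s - 1 + w]
        mean = sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / w
        best_mean = max(best_mean, mean)
        if mean >= params.h_min:
            last_good_end = s + w - 1
    if best_mean == float("-inf"):
        return SignalPrediction(False, None, 0.0)

    # bounded monotone component in [0,1]; 0.5 exactly at h_min
    c_hydro = min(1.0, max(0.0, 0.5 + (best_mean - params.h_min)))

    if last_good_end is not None:
        lo = max(params.min_cleavage, last_good_end)
        hi = min(params.max_cleavage, last_good_end + params.search_span, n - 1)
    else:
        lo, hi = params.min_cleavage, min(params.max_cleavage, n - 1)
    if lo > hi:
        return SignalPrediction(False, None, round(0.4 * c_hydro, 6))

    # (-3,-1) preference: -1 (position p) weighted double
    best_p, best_pref = None, -1
    for p in range(lo, hi + 1):
        pref = 2 * _small(seq, p) + _small(seq, p - 2)
        if pref > best_pref:
            best_p, best_pref = p, pref
    c_cleave = best_pref / 3.0
    score = round(c_hydro * (0.4 + 0.6 * c_cleave), 6)
    present = score >= params.threshold
    return SignalPrediction(present, best_p if present else None, score)
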
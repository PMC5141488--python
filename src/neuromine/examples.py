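"""Worked-example precursors built from published architecture coordinates
of the *Cherax quadricarinatus* eyestalk neuropeptidome.

Each constructor assembles a synthetic stand-in precursor that embeds the
published numbers for one family — signal-peptide length, cleavage-site
positions in the K_nR convention, and the printed mature peptide — with
deterministic motif-free filler elsewhere.  Running the cleavage scanner and
peptide release on these chains reproduces the published architecture
arithmetic exactly (e.g. ACP: signal 1..20 + K_33_R dibasic site => a
12-residue mature peptide at 21..32).

The bursicon-α chain is the published sequence itself, reported without any
convertase site; it is kept verbatim as a negative control for the scanner.
"""

from __future__ import annotations

from .orf import Precursor
from .processing import CleavageRules
from .signal_peptide import SignalPrediction

#: published partial bursicon-α chain (no signal peptide, no cleavage site)
BURSICON_ALPHA = "SGIFLSCPGQILTRAPIDCMCRPCTDVEEGTVLAQEIANFIHDSPMGNVPFLK"

_FILLER = "ASTNQDEV"  # motif-free, no basics, no glycine


def _filler(n: int) -> str:
    return (_FILLER * (n // len(_FILLER) + 1))[:n]


def _signal(length: int) -> str:
    """Deterministic signal peptide: Met + hydrophobic core + polar c-region
    with small residues at the -3/-1 positions."""
    hydro = ("VLLLVVFFLLIIVVFFLLIIVVFFLLIIVVFFLLIIVVFF")[: length - 6]
    return "M" + hydro + "DN" + "A" + "Q" + "S"


def _example(
    signal_len: int, body: str, tail: str = "SDETN"
) -> tuple[Precursor, SignalPrediction]:
    seq = _signal(signal_len) + body + tail
    precursor = Precursor(id="example", sequence=seq)
    return precursor, SignalPrediction(True, signal_len, 1.0)


def acp_style() -> tuple[Precursor, SignalPrediction]:
    """20-aa signal, 12-aa mature peptide at 21..32, dibasic K_33_R."""
    return _example(20, _filler(12) + "KR")


def myosuppressin_style() -> tuple[Precursor, SignalPrediction, CleavageRules]:
    """29-aa signal, K_84_R, monobasic R_97 after the QDLDHVFLRFamide donor;
    the 11-aa mature peptide spans 86..96.  Monobasic cleavage is the
    catalog-driven myosuppressin override."""
    prec, sig = _example(29, _filler(54) + "KR" + "QDLDHVFLRFG" + "R", "SDE")
    return prec, sig, CleavageRules(monobasic=True)


def sifamide_style() -> tuple[Precursor, SignalPrediction]:
    """27-aa signal, GYRKPPFNGSIFamide (donor G at 40), dibasic K_41_R.
    The internal RK pair at 30 is not an enabled convertase site."""
    return _example(27, "GYRKPPFNGSIF" + "G" + "KR")


def rpch_style() -> tuple[Precursor, SignalPrediction]:
    """21-aa signal, QLNFSPGWamide (9-aa span with donor), dibasic K_31_R."""
    return _example(21, "QLNFSPGW" + "G" + "KR")


def ccap_style() -> tuple[Precursor, SignalPrediction]:
    """Dibasic K_46_R, PFCNAFTGCamide span at 48..57, dibasic K_58_K."""
    return _example(24, _filler(21) + "KR" + "PFCNAFTGC" + "G" + "KK")


def dh31_style() -> tuple[Precursor, SignalPrediction]:
    """23-aa signal, dibasic K_70_R, 31-aa amidated mature peptide at
    72..102 (donor G at 103), dibasic site at 104."""
    return _example(23, _filler(46) + "KR" + _filler(31) + "G" + "RR")
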
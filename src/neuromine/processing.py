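"""Prohormone processing: cleavage-site scanning, peptide release, PTMs,
and architecture assembly.

Coordinate convention ("K_nR"): a cleavage site's ``position`` indexes the
FIRST basic residue of the run, 1-based on the precursor.  Mature spans run
from the previous site's last residue + 1 to the next site's position - 1;
a multibasic run (e.g. R_37_KR) is one site object and cleavage occurs after
its final basic residue.  This makes every printed worked-example
architecture arithmetically consistent (ACP K_33_R / 12-aa peptide, CCAP
K_46_R + PFCNAFTGCamide + K_58_K, myosuppressin K_84_R + R_97, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import AssemblyError, ContractError
from .orf import Precursor
from .signal_peptide import SignalPrediction

BASIC = frozenset("KR")


@dataclass
class CleavageRules:
    """Which basic-residue patterns count as prohormone-convertase sites.

    ``enabled_pairs`` governs length-2 runs (RK is off by default: it is a
    poor convertase substrate); any run of three or more basics is always a
    site.  ``monobasic`` admits single-R sites, but only when the R is
    immediately preceded by G — the exposed amidation donor of the upstream
    peptide (the classic GR/GKR processing signal).  Monobasic cleavage is
    off by default and enabled per family via the catalog.
    """

    enabled_pairs: tuple[str, ...] = ("KR", "RR", "KK")
    monobasic: bool = False


@dataclass
class CleavageSite:
    position: int  # 1-based index of the first basic residue
    residues: str  # the basic run, e.g. "KR", "R", "RKR"

    def __post_init__(self) -> None:
        if not self.residues or set(self.residues) - BASIC:
            raise ValueError(f"site residues must be K/R, got {self.residues!r}")

    @property
    def end(self) -> int:
        return self.position + len(self.residues) - 1

    @property
    def kind(self) -> str:
        n = len(self.residues)
        return "monobasic" if n == 1 else "dibasic" if n == 2 else "multibasic"


@dataclass
class PTMSettings:
    amidation: bool = True
    # Pyroglutamate is catalog-driven (per family); globally off.
    pyroglutamate: bool = False


@dataclass
class MaturePeptide:
    """A released segment; ``core`` excludes the C-terminal glycine donor."""

    parent_id: str
    span_start: int  # 1-based inclusive bounds BEFORE modification
    span_end: int
    core: str
    amidated: bool = False
    pyroglutamate: bool = False

    def __post_init__(self) -> None:
        expected = len(self.core) + (1 if self.amidated else 0)
        if self.span_end - self.span_start + 1 != expected:
            raise ValueError(
                f"{self.parent_id}: span {self.span_start}..{self.span_end} "
                f"inconsistent with core length {len(self.core)} "
                f"(amidated={self.amidated})"
            )
        if self.pyroglutamate and not self.core.startswith("Q"):
            raise ValueError(f"{self.parent_id}: pyroglutamate requires Q start")

    @property
    def display(self) -> str:
        return (
            ("p" if self.pyroglutamate else "")
            + self.core
            + ("amide" if self.amidated else "")
        )

    @property
    def cys_count(self) -> int:
        return self.core.count("C")


def scan_cleavage_sites(
    sequence: str, rules: CleavageRules | None = None
) -> list[CleavageSite]:
    """Report maximal K/R runs that qualify as convertase sites, sorted by
    position.  Runs never overlap by construction (they are maximal)."""
    rules = rules or CleavageRules()
    sites: list[CleavageSite] = []
    i, n = 0, len(sequence)
    while i < n:
        if sequence[i] not in BASIC:
            i += 1
            continue
        j = i
        while j < n and sequence[j] in BASIC:
            j += 1
        run = sequence[i:j]
        keep = False
        if len(run) >= 3:
            keep = True
        elif len(run) == 2:
            keep = run in rules.enabled_pairs
        elif rules.monobasic and run == "R" and i > 0 and sequence[i - 1] == "G":
            keep = True
        if keep:
            sites.append(CleavageSite(position=i + 1, residues=run))
        i = j
    return sites


def infer_ptms(
    span_sequence: str,
    at_c_terminus_of_precursor: bool = False,
    settings: PTMSettings | None = None,
    min_peptide_length: int = 3,
) -> tuple[str, bool, bool]:
    """Return (core, amidated, pyroglutamate) for a released span.

    Amidation: the span ends in the glycine donor, the setting is on, and the
    resulting core is still at least ``min_peptide_length`` long.  Terminal
    spans follow the same rule.  Pyroglutamate: core starts with Q and the
    (catalog-driven) setting is on.
    """
    if not span_sequence:
        raise ValueError("empty span")
    settings = settings or PTMSettings()
    core, amidated = span_sequence, False
    if (
        settings.amidation
        and span_sequence.endswith("G")
        and len(span_sequence) - 1 >= min_peptide_length
    ):
        core, amidated = span_sequence[:-1], True
    pyro = settings.pyroglutamate and core.startswith("Q")
    return core, amidated, pyro


def release_peptides(
    precursor: Precursor,
    signal: SignalPrediction,
    sites: Sequence[CleavageSite],
    min_peptide_length: int = 3,
    ptm: PTMSettings | None = None,
) -> list[MaturePeptide]:
    """Release the mature peptides between the signal peptide and/or the
    cleavage sites.  Spans shorter than ``min_peptide_length`` are left as
    spacers (they reappear as spacer segments in the architecture)."""
    seq = precursor.sequence
    n = len(seq)
    prev_end = 0
    for s in sites:
        if s.position <= prev_end:
            raise ContractError(
                f"{precursor.id}: overlapping/unsorted cleavage sites at "
                f"position {s.position}"
            )
        if s.end > n:
            raise ContractError(
                f"{precursor.id}: site at {s.position} extends past sequence"
            )
        prev_end = s.end

    start = (signal.cleavage_after or 0) + 1 if signal.present else 1
    bounds: list[tuple[int, int]] = []
    cursor = start
    for s in sites:
        bounds.append((cursor, s.position - 1))
        cursor = s.end + 1
    bounds.append((cursor, n))

    peptides: list[MaturePeptide] = []
    for a, b in bounds:
        if b - a + 1 < min_peptide_length:
            continue
        core, amidated, pyro = infer_ptms(
            seq[a - 1 : b], b == n, ptm, min_peptide_length
        )
        peptides.append(
            MaturePeptide(
                parent_id=precursor.id,
                span_start=a,
                span_end=b,
                core=core,
                amidated=amidated,
                pyroglutamate=pyro,
            )
        )
    return peptides


def count_disulfide_potential(peptide: MaturePeptide) -> tuple[int, int, bool]:
    """(cys_count, bridge_estimate, odd_parity) from the peptide core."""
    c = peptide.cys_count
    return c, c // 2, c % 2 == 1


@dataclass
class Segment:
    role: str  # signal | cprp | peptide | spacer | cleavage
    start: int
    end: int


@dataclass
class PrecursorArchitecture:
    precursor_id: str
    length: int
    segments: list[Segment]
    peptides: list[MaturePeptide]
    sites: list[CleavageSite]
    signal: SignalPrediction
    partial: bool = field(default=False)


def build_architecture(
    precursor: Precursor,
    signal: SignalPrediction,
    sites: Sequence[CleavageSite],
    peptides: Sequence[MaturePeptide],
) -> PrecursorArchitecture:
    """Tile the precursor into ordered segments and validate the tiling.

    Every residue belongs to exactly one segment; uncovered residues become
    spacers.  Raises :class:`AssemblyError` naming the offending element when
    inputs are mutually inconsistent.
    """
    n = len(precursor.sequence)
    claimed: list[tuple[int, int, str, str]] = []
    if signal.present:
        if not signal.cleavage_after or not (1 <= signal.cleavage_after <= n):
            raise AssemblyError(f"{precursor.id}: signal end outside precursor")
        claimed.append((1, signal.cleavage_after, "signal", "signal"))
    for s in sites:
        if s.position < 1 or s.end > n:
            raise AssemblyError(
                f"{precursor.id}: cleavage site {s.residues}@{s.position} "
                f"outside precursor"
            )
        claimed.append((s.position, s.end, "cleavage", f"{s.residues}@{s.position}"))
    for p in peptides:
        if p.span_start < 1 or p.span_end > n:
            raise AssemblyError(
                f"{precursor.id}: peptide {p.display} outside precursor"
            )
        claimed.append((p.span_start, p.span_end, "peptide", p.display))

    claimed.sort(key=lambda c: (c[0], c[1]))
    segments: list[Segment] = []
    cursor = 1
    for a, b, role, name in claimed:
        if a < cursor:
            raise AssemblyError(
                f"{precursor.id}: element {name!r} overlaps previous segment"
            )
        if a > cursor:
            segments.append(Segment("spacer", cursor, a - 1))
        segments.append(Segment(role, a, b))
        cursor = b + 1
    if cursor <= n:
        segments.append(Segment("spacer", cursor, n))

    # tiling invariant
    pos = 1
    for seg in segments:
        if seg.start != pos or seg.end < seg.start:
            raise AssemblyError(f"{precursor.id}: tiling gap at position {pos}")
        pos = seg.end + 1
    if pos != n + 1:
        raise AssemblyError(f"{precursor.id}: tiling does not cover 1..{n}")

    return PrecursorArchitecture(
        precursor_id=precursor.id,
        length=n,
        segments=segments,
        peptides=list(peptides),
        sites=list(sites),
        signal=signal,
        partial=(not signal.present and not precursor.n_complete),
    )
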
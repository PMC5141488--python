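"""Six-frame ORF finding and precursor selection.

Conventions
-----------
* Coordinates are 1-based inclusive on the *forward* strand of the transcript;
  reverse-strand ORFs carry a negative frame sign.
* The standard genetic code only; codons containing N translate to X; an ORF
  never starts at an X residue (leading X is trimmed).
* An ORF spans whole codons; when terminated by an in-frame stop the stop
  codon is included in the nucleotide span but excluded from the protein.
* With ``require_start`` an ORF begins at the first Met of each stop-delimited
  frame segment; without it the whole segment is reported, so 5'-truncated
  partial precursors remain representable (completeness is recorded in flags,
  not enforced).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .seqio import FastaRecord

# Standard code; any codon containing N translates to X (no IUPAC
# disambiguation), and stops are '*'.
_CODON = dict(standard_dna_table.forward_table)
_CODON.update({codon: "*" for codon in standard_dna_table.stop_codons})


@dataclass
class OpenReadingFrame:
    transcript_id: str
    frame: int  # one of +1,+2,+3,-1,-2,-3
    nt_start: int  # 1-based inclusive, forward strand
    nt_end: int
    protein: str
    has_start: bool
    has_stop: bool


@dataclass
class Precursor:
    """A candidate prepropeptide chain with completeness flags."""

    id: str
    sequence: str
    n_complete: bool = True
    c_complete: bool = True
    source: Optional[OpenReadingFrame] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"precursor {self.id!r}: empty sequence")
        if self.n_complete and not self.sequence.startswith("M"):
            raise ValueError(
                f"precursor {self.id!r}: n_complete but first residue is "
                f"{self.sequence[0]!r}, not M"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _translate_frame(nt: str) -> str:
    return "".join(
        _CODON.get(nt[i : i + 3], "X")
        for i in range(0, len(nt) - len(nt) % 3, 3)
    )


def find_orfs(
    transcript: FastaRecord,
    min_protein_length: int = 50,
    require_start: bool = False,
) -> list[OpenReadingFrame]:
    """Scan all six frames; results sorted by descending protein length,
    ties by (frame, nt_start)."""
    seq = transcript.sequence
    length = len(seq)
    rc = str(Seq(seq).reverse_complement())
    orfs: list[OpenReadingFrame] = []

    for strand, oriented in ((1, seq), (-1, rc)):
        for offset in range(3):
            frame = strand * (offset + 1)
            prot = _translate_frame(oriented[offset:])
            if not prot:
                continue
            # stop-delimited segments, tracked in protein coordinates
            seg_start = 0
            for i in range(len(prot) + 1):
                at_stop = i < len(prot) and prot[i] == "*"
                at_end = i == len(prot)
                if not (at_stop or at_end):
                    continue
                a, b = seg_start, i  # protein slice [a, b)
                seg_start = i + 1
                has_stop = at_stop
                if b <= a:
                    continue
                if require_start:
                    rel = prot.find("M", a, b)
                    if rel == -1:
                        continue
                    a = rel
                else:
                    while a < b and prot[a] == "X":
                        a += 1
                    if a >= b:
                        continue
                protein = prot[a:b]
                if len(protein) < min_protein_length:
                    continue
                # 1-based codon coordinates on the oriented strand
                nt_s = offset + 3 * a + 1
                nt_e = offset + 3 * (b + (1 if has_stop else 0))
                if strand == -1:
                    nt_s, nt_e = length - nt_e + 1, length - nt_s + 1
                orfs.append(
                    OpenReadingFrame(
                        transcript_id=transcript.id,
                        frame=frame,
                        nt_start=nt_s,
                        nt_end=nt_e,
                        protein=protein,
                        has_start=protein.startswith("M"),
                        has_stop=has_stop,
                    )
                )
    orfs.sort(key=lambda o: (-len(o.protein), o.frame, o.nt_start))
    return orfs


def select_precursor(
    orfs: Sequence[OpenReadingFrame], policy: str = "longest"
) -> list[Precursor]:
    """Convert ORFs from one transcript to Precursors.

    ``longest`` keeps the single longest ORF and reuses the transcript id so
    downstream records stay keyed by transcript; ``all`` converts every ORF
    under a frame-qualified id.
    """
    if policy not in ("longest", "all"):
        raise ValueError(f"unknown policy {policy!r}")
    if not orfs:
        return []

    def _to_precursor(orf: OpenReadingFrame, pid: str) -> Precursor:
        return Precursor(
            id=pid,
            sequence=orf.protein,
            n_complete=orf.has_start,
            c_complete=orf.has_stop,
            source=orf,
        )

    if policy == "longest":
        best = min(orfs, key=lambda o: (-len(o.protein), o.frame, o.nt_start))
        return [_to_precursor(best, best.transcript_id)]
    return [
        _to_precursor(o, f"{o.transcript_id}|f{o.frame:+d}@{o.nt_start}")
        for o in orfs
    ]
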
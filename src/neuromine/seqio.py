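"""FASTA reading/writing with strict alphabet validation.

Headers are split at the first whitespace into id and description.  Sequences
are stored uppercase; for nucleotide input U is mapped to T.  Coordinates used
elsewhere in the package are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FastaParseError, SequenceAlphabetError

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class FastaRecord:
    """One sequence record; ``sequence`` is uppercase and validated."""

    id: str
    sequence: str
    description: str = field(default="")

    def __len__(self) -> int:
        return len(self.sequence)


# A transcript record is simply a FastaRecord read with alphabet="nucleotide".
TranscriptRecord = FastaRecord


def _alphabet_set(alphabet: str) -> frozenset:
    if alphabet == "nucleotide":
        return NUCLEOTIDE_ALPHABET
    if alphabet == "protein":
        return PROTEIN_ALPHABET
    raise ValueError(f"unknown alphabet {alphabet!r}")


def read_fasta(path: str | Path, alphabet: str = "protein") -> list[FastaRecord]:
    """Read all records from a FASTA file, in file order.

    Raises
    ------
    FastaParseError
        if sequence data precedes any header (names the line number).
    SequenceAlphabetError
        if a record contains characters outside ``alphabet`` (names the id).
    """
    allowed = _alphabet_set(alphabet)
    records: list[FastaRecord] = []
    cur_id: str | None = None
    cur_desc = ""
    cur_seq: list[str] = []

    def _flush() -> None:
        if cur_id is None:
            return
        seq = "".join(cur_seq).upper()
        if alphabet == "nucleotide":
            seq = seq.replace("U", "T")
        bad = set(seq) - allowed
        if bad:
            raise SequenceAlphabetError(
                f"record {cur_id!r}: characters {sorted(bad)} outside "
                f"{alphabet} alphabet"
            )
        records.append(FastaRecord(cur_id, seq, cur_desc))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                parts = header.split(None, 1)
                cur_id = parts[0] if parts else ""
                if not cur_id:
                    raise FastaParseError(f"line {lineno}: empty record id")
                cur_desc = parts[1] if len(parts) > 1 else ""
                cur_seq = []
            else:
                if cur_id is None:
                    raise FastaParseError(
                        f"line {lineno}: sequence data before any '>' header"
                    )
                cur_seq.append(line)
        _flush()
    return records


def write_fasta(
    records: Iterable[FastaRecord] | Sequence[FastaRecord],
    path: str | Path,
    width: int = 60,
) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width`` columns."""
    if width < 1:
        raise ValueError("width must be >= 1")
    records = list(records)
    seen: set[str] = set()
    dupes: set[str] = set()
    for rec in records:
        (dupes if rec.id in seen else seen).add(rec.id)
    dupes = sorted(dupes)
    if dupes:
        raise ValueError(f"duplicate record ids: {dupes}")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
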
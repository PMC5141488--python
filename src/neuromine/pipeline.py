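"""End-to-end mining: keyword pre-filter -> ORFs -> processing -> family
assignment -> curation, plus catalog export in TSV/JSON/GFF3/FASTA.

The keyword channel is optional: with no annotation table every ORF-derived
precursor enters processing.  BLAST is never run here — an annotation table
(query id, subject description, e-value) is an input, not an output.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import catalog as catalog_mod
from .catalog import (
    Catalog,
    FamilyAssignment,
    assign_family,
    classify_chh_type,
    classify_cys_rich,
    load_motif_catalog,
    match_peptide_families,
)
from .errors import NeuromineError
from .orf import Precursor, find_orfs, select_precursor
from .processing import (
    CleavageRules,
    CleavageSite,
    MaturePeptide,
    PrecursorArchitecture,
    PTMSettings,
    Segment,
    build_architecture,
    release_peptides,
    scan_cleavage_sites,
)
from .seqio import (
    NUCLEOTIDE_ALPHABET,
    FastaRecord,
    read_fasta,
    write_fasta,
)
from .signal_peptide import SignalParams, SignalPrediction, predict_signal_peptide

logger = logging.getLogger("neuromine.pipeline")


@dataclass
class AnnotationRow:
    query_id: str
    subject_description: str
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"{self.query_id}: negative e-value")


def read_annotation_table(path: str | Path) -> list[AnnotationRow]:
    """BLAST-tabular-style TSV: query id, subject description, e-value."""
    rows: list[AnnotationRow] = []
    with open(path) as fh:
        for rec in csv.reader(fh, delimiter="\t"):
            if not rec or rec[0].startswith("#"):
                continue
            evalue = float(rec[2]) if len(rec) > 2 and rec[2] else 0.0
            rows.append(AnnotationRow(rec[0], rec[1] if len(rec) > 1 else "", evalue))
    return rows


def keyword_matches(
    annotations: Sequence[AnnotationRow], keywords: Sequence[str]
) -> dict[str, list[str]]:
    """Map query id -> sorted keyword terms found (case-insensitive substring
    match on the subject description)."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    lowered = [(k, k.lower()) for k in keywords]
    hits: dict[str, set[str]] = {}
    for row in annotations:
        desc = row.subject_description.lower()
        for term, low in lowered:
            if low in desc:
                hits.setdefault(row.query_id, set()).add(term)
    return {qid: sorted(terms) for qid, terms in hits.items()}


def filter_by_keywords(
    annotations: Sequence[AnnotationRow], keywords: Sequence[str]
) -> set[str]:
    return set(keyword_matches(annotations, keywords))


@dataclass
class PipelineConfig:
    min_orf_aa: int = 50
    require_start: bool = False
    orf_policy: str = "longest"
    input_alphabet: str = "auto"  # auto | nucleotide | protein
    signal: SignalParams = field(default_factory=SignalParams)
    cleavage: CleavageRules = field(default_factory=CleavageRules)
    min_peptide_length: int = 3
    catalog_path: Optional[str] = None
    keywords: Optional[list[str]] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in (
            "min_orf_aa",
            "require_start",
            "orf_policy",
            "input_alphabet",
            "min_peptide_length",
            "catalog_path",
            "keywords",
        ):
            if key in doc:
                setattr(cfg, key, doc[key])
        for key, value in (doc.get("signal") or {}).items():
            setattr(cfg.signal, key, value)
        cl = doc.get("cleavage") or {}
        if "enabled_pairs" in cl:
            cfg.cleavage.enabled_pairs = tuple(cl["enabled_pairs"])
        if "monobasic" in cl:
            cfg.cleavage.monobasic = bool(cl["monobasic"])
        return cfg


@dataclass
class CurationRecord:
    precursor_id: str
    status: str  # complete | partial | rejected
    evidence: list[str] = field(default_factory=list)
    family_call: Optional[str] = None


@dataclass
class CatalogEntry:
    architecture: PrecursorArchitecture
    curation: CurationRecord


def process_precursor(
    precursor: Precursor, config: PipelineConfig, catalog: Catalog
) -> tuple[PrecursorArchitecture, list[Optional[FamilyAssignment]]]:
    """Annotate one precursor: signal, sites, peptides, PTMs, families.

    Monobasic cleavage is catalog-driven: a second scanning pass with
    monobasic sites enabled runs only when a monobasic-allowed family's motif
    occurs inside a first-pass released peptide (flush matching cannot fire
    before the monobasic cut exists).  Pyroglutamate is likewise applied
    after family assignment, only for families flagged in the catalog.
    """
    signal = predict_signal_peptide(precursor, config.signal)
    sites = scan_cleavage_sites(precursor.sequence, config.cleavage)
    peptides = release_peptides(
        precursor, signal, sites, config.min_peptide_length, PTMSettings()
    )

    if not config.cleavage.monobasic:
        mono_motifs = [m for m in catalog if m.monobasic_allowed]
        import re as _re

        def _triggers(pep: MaturePeptide) -> bool:
            return any(_re.search(m.regex, pep.core) for m in mono_motifs)

        if mono_motifs and any(_triggers(p) for p in peptides):
            rules = dataclasses.replace(config.cleavage, monobasic=True)
            sites = scan_cleavage_sites(precursor.sequence, rules)
            peptides = release_peptides(
                precursor, signal, sites, config.min_peptide_length, PTMSettings()
            )

    assignments: list[Optional[FamilyAssignment]] = []
    for idx, pep in enumerate(peptides):
        ref = f"{precursor.id}:{pep.span_start}-{pep.span_end}"
        assignment = assign_family(match_peptide_families(pep, catalog), ref)
        if (
            assignment
            and assignment.motif.pyroglutamate
            and pep.core.startswith("Q")
        ):
            pep.pyroglutamate = True
        assignments.append(assignment)

    arch = build_architecture(precursor, signal, sites, peptides)
    return arch, assignments


def curate_candidate(
    precursor: Precursor,
    architecture: PrecursorArchitecture,
    assignments: Sequence[Optional[FamilyAssignment]],
    keyword_hits: Sequence[str] = (),
    cys_rules=catalog_mod.DEFAULT_CYS_RULES,
) -> CurationRecord:
    """Deterministic curation status.

    complete: signal present AND family evidence (motif OR keyword OR
    cysteine framework) AND both termini complete.  partial: family evidence
    with a missing-completeness flag.  rejected otherwise.  Cysteine-
    framework evidence requires processing evidence (>= 1 cleavage site): a
    bare cysteine count on an unprocessed chain is not family evidence.
    """
    evidence: list[str] = []
    if architecture.signal.present:
        evidence.append("signal_present")
    motif_families: list[tuple[int, str]] = []
    for a in assignments:
        if a is not None:
            evidence.append(f"motif_match:{a.family}")
            motif_families.append((a.specificity, a.family))
    for term in keyword_hits:
        evidence.append(f"keyword_match:{term}")

    cys_families: list[str] = []
    if architecture.sites:
        chh_type, _cprp = classify_chh_type(architecture)
        if chh_type != "not_chh":
            cys_families.append("CHH")
        assigned = {id(p) for a, p in zip(assignments, architecture.peptides) if a}
        for pep in architecture.peptides:
            if id(pep) in assigned:
                continue
            suggestion = classify_cys_rich(pep, cys_rules)
            if suggestion and suggestion not in cys_families:
                cys_families.append(suggestion)
    for fam in cys_families:
        evidence.append(f"cys_framework:{fam}")

    if not precursor.n_complete:
        evidence.append("n_incomplete")
    if not precursor.c_complete:
        evidence.append("c_incomplete")

    family_evidence = bool(motif_families or keyword_hits or cys_families)
    if (
        architecture.signal.present
        and family_evidence
        and precursor.n_complete
        and precursor.c_complete
    ):
        status = "complete"
    elif family_evidence and (not precursor.n_complete or not precursor.c_complete):
        status = "partial"
    else:
        status = "rejected"

    if motif_families:
        family_call = max(motif_families, key=lambda sf: (sf[0], sf[1]))[1]
    elif cys_families:
        family_call = cys_families[0]
    elif keyword_hits:
        family_call = sorted(keyword_hits)[0]
    else:
        family_call = None

    return CurationRecord(
        precursor_id=architecture.precursor_id,
        status=status,
        evidence=evidence,
        family_call=family_call,
    )


def _looks_nucleotide(records: Sequence[FastaRecord]) -> bool:
    chars = set()
    for rec in records:
        chars |= set(rec.sequence)
    return bool(records) and chars <= (NUCLEOTIDE_ALPHABET | {"U"})


def mine_catalog(
    sequences: str | Path,
    annotations: str | Path | None = None,
    config: PipelineConfig | None = None,
) -> list[CatalogEntry]:
    """Run the full mining pipeline over a FASTA file.

    Deterministic given inputs + config; logs per-stage counts.
    """
    config = config or PipelineConfig()
    catalog = load_motif_catalog(config.catalog_path)
    keywords = config.keywords if config.keywords else catalog.keywords

    alphabet = config.input_alphabet
    if alphabet == "auto":
        # nucleotide strings are a subset of the protein alphabet, so probe
        # as protein first and narrow
        probe = read_fasta(sequences, "protein")
        alphabet = "nucleotide" if _looks_nucleotide(probe) else "protein"
    records = read_fasta(sequences, alphabet)
    logger.info("read %d %s records", len(records), alphabet)

    hits_by_id: dict[str, list[str]] = {}
    if annotations is not None:
        rows = read_annotation_table(annotations)
        hits_by_id = keyword_matches(rows, keywords)
        records = [r for r in records if r.id in hits_by_id]
        logger.info("keyword pre-filter kept %d records", len(records))

    precursors: list[Precursor] = []
    if alphabet == "nucleotide":
        for rec in records:
            orfs = find_orfs(rec, config.min_orf_aa, config.require_start)
            precursors.extend(select_precursor(orfs, config.orf_policy))
    else:
        for rec in records:
            precursors.append(
                Precursor(
                    id=rec.id,
                    sequence=rec.sequence,
                    n_complete=rec.sequence.startswith("M"),
                    c_complete=True,
                )
            )
    logger.info("derived %d precursors", len(precursors))

    entries: list[CatalogEntry] = []
    for prec in precursors:
        try:
            arch, assignments = process_precursor(prec, config, catalog)
        except NeuromineError as exc:
            raise type(exc)(f"record {prec.id!r}: {exc}") from exc
        record = curate_candidate(
            prec, arch, assignments, hits_by_id.get(prec.id, ())
        )
        entries.append(CatalogEntry(arch, record))
    n_complete = sum(1 for e in entries if e.curation.status == "complete")
    logger.info(
        "curated %d entries (%d complete)", len(entries), n_complete
    )
    return entries


# ---------------------------------------------------------------- export ----


def _arch_to_dict(arch: PrecursorArchitecture) -> dict:
    return {
        "precursor_id": arch.precursor_id,
        "length": arch.length,
        "partial": arch.partial,
        "signal": {
            "present": arch.signal.present,
            "cleavage_after": arch.signal.cleavage_after,
            "score": arch.signal.score,
        },
        "segments": [
            {"role": s.role, "start": s.start, "end": s.end} for s in arch.segments
        ],
        "sites": [
            {"position": s.position, "residues": s.residues, "kind": s.kind}
            for s in arch.sites
        ],
        "peptides": [
            {
                "parent_id": p.parent_id,
                "span_start": p.span_start,
                "span_end": p.span_end,
                "core": p.core,
                "amidated": p.amidated,
                "pyroglutamate": p.pyroglutamate,
                "display": p.display,
                "cys_count": p.cys_count,
            }
            for p in arch.peptides
        ],
    }


def _arch_from_dict(doc: dict) -> PrecursorArchitecture:
    return PrecursorArchitecture(
        precursor_id=doc["precursor_id"],
        length=doc["length"],
        partial=doc["partial"],
        signal=SignalPrediction(
            present=doc["signal"]["present"],
            cleavage_after=doc["signal"]["cleavage_after"],
            score=doc["signal"]["score"],
        ),
        segments=[Segment(s["role"], s["start"], s["end"]) for s in doc["segments"]],
        sites=[
            CleavageSite(position=s["position"], residues=s["residues"])
            for s in doc["sites"]
        ],
        peptides=[
            MaturePeptide(
                parent_id=p["parent_id"],
                span_start=p["span_start"],
                span_end=p["span_end"],
                core=p["core"],
                amidated=p["amidated"],
                pyroglutamate=p["pyroglutamate"],
            )
            for p in doc["peptides"]
        ],
    )


def export_catalog(
    entries: Sequence[CatalogEntry], format: str, path: str | Path
) -> None:
    """Write the mined catalog as tsv, json, gff3 or fasta (mature peptides)."""
    if format == "tsv":
        frame = pd.DataFrame(
            [
                {
                    "precursor_id": e.architecture.precursor_id,
                    "length_aa": e.architecture.length,
                    "status": e.curation.status,
                    "family_call": e.curation.family_call or "",
                    "signal_length": (
                        e.architecture.signal.cleavage_after
                        if e.architecture.signal.present
                        else 0
                    ),
                    "n_sites": len(e.architecture.sites),
                    "n_peptides": len(e.architecture.peptides),
                    "peptide_displays": ";".join(
                        p.display for p in e.architecture.peptides
                    ),
                }
                for e in entries
            ],
            columns=[
                "precursor_id",
                "length_aa",
                "status",
                "family_call",
                "signal_length",
                "n_sites",
                "n_peptides",
                "peptide_displays",
            ],
        )
        frame.to_csv(path, sep="\t", index=False)
    elif format == "json":
        doc = [
            {
                "architecture": _arch_to_dict(e.architecture),
                "curation": {
                    "precursor_id": e.curation.precursor_id,
                    "status": e.curation.status,
                    "evidence": e.curation.evidence,
                    "family_call": e.curation.family_call,
                },
            }
            for e in entries
        ]
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    elif format == "gff3":
        lines = ["##gff-version 3"]
        for e in entries:
            arch = e.architecture
            sid = arch.precursor_id
            if arch.signal.present:
                lines.append(
                    f"{sid}\tneuromine\tsignal_peptide\t1\t"
                    f"{arch.signal.cleavage_after}\t.\t+\t.\tID={sid}.sp"
                )
            for s in arch.sites:
                lines.append(
                    f"{sid}\tneuromine\tpropeptide_cleavage_site\t{s.position}\t"
                    f"{s.end}\t.\t+\t.\tID={sid}.site{s.position};Note={s.kind}"
                )
            for p in arch.peptides:
                notes = []
                if p.amidated:
                    notes.append("amidated")
                if p.pyroglutamate:
                    notes.append("pyroglutamate")
                note = f";Note={','.join(notes)}" if notes else ""
                lines.append(
                    f"{sid}\tneuromine\tmature_peptide\t{p.span_start}\t"
                    f"{p.span_end}\t.\t+\t.\tID={sid}.pep{p.span_start}{note}"
                )
        Path(path).write_text("\n".join(lines) + "\n")
    elif format == "fasta":
        records = [
            FastaRecord(
                id=f"{p.parent_id}|{p.span_start}-{p.span_end}",
                sequence=p.core,
                description=p.display,
            )
            for e in entries
            for p in e.architecture.peptides
        ]
        write_fasta(records, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def import_catalog_json(path: str | Path) -> list[CatalogEntry]:
    doc = json.loads(Path(path).read_text())
    return [
        CatalogEntry(
            architecture=_arch_from_dict(item["architecture"]),
            curation=CurationRecord(
                precursor_id=item["curation"]["precursor_id"],
                status=item["curation"]["status"],
                evidence=list(item["curation"]["evidence"]),
                family_call=item["curation"]["family_call"],
            ),
        )
        for item in doc
    ]


def render_architecture(arch: PrecursorArchitecture, width: int = 120) -> str:
    """One-line scaled glyph string, e.g. ``[SP 1-20]--[PEP 21-32]--(KR@33)``."""
    sites_by_pos = {s.position: s for s in arch.sites}
    peps_by_span = {(p.span_start, p.span_end): p for p in arch.peptides}
    parts: list[str] = []
    for seg in arch.segments:
        if seg.role == "signal":
            parts.append(f"[SP {seg.start}-{seg.end}]")
        elif seg.role == "cleavage":
            site = sites_by_pos[seg.start]
            parts.append(f"({site.residues}@{site.position})")
        elif seg.role == "peptide":
            pep = peps_by_span.get((seg.start, seg.end))
            flags = ""
            if pep is not None:
                if pep.pyroglutamate:
                    flags += " pQ"
                if pep.amidated:
                    flags += " amide"
            parts.append(f"[PEP {seg.start}-{seg.end}{flags}]")
        else:
            parts.append("~")
    text = "--".join(parts)
    return text if len(text) <= width else text[: width - 1] + "…"
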
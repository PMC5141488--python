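"""The family-motif catalog and family assignment.

A motif is a degenerate pattern over the 20-letter alphabet plus X (any
residue) and bracketed alternatives like ``[YF]``.  C-terminal motifs match
flush with the processed peptide core's C-terminus; "amide" in a published
motif is represented as ``requires_amidation``, never as a pattern character.
Specificity is the count of literal (non-X, non-alternative) positions; it
drives the winner among multiple matching families.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import yaml

from .errors import CatalogError
from .processing import MaturePeptide, PrecursorArchitecture

AA20 = "ACDEFGHIKLMNPQRSTVWY"


def parse_pattern(pattern: str) -> list[str]:
    """Tokenize a degenerate pattern; each token is 'X', a literal letter,
    or a string of alternatives (from ``[..]``)."""
    tokens: list[str] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j == -1:
                raise CatalogError(f"pattern {pattern!r}: unclosed '['")
            alts = pattern[i + 1 : j]
            if len(alts) < 2 or set(alts) - set(AA20):
                raise CatalogError(f"pattern {pattern!r}: bad alternatives [{alts}]")
            tokens.append(alts)
            i = j + 1
        elif ch == "X":
            tokens.append("X")
            i += 1
        elif ch in AA20:
            tokens.append(ch)
            i += 1
        else:
            raise CatalogError(f"pattern {pattern!r}: unknown token {ch!r}")
    if not tokens:
        raise CatalogError("empty pattern")
    return tokens


@dataclass(frozen=True)
class FamilyMotif:
    family: str
    pattern: str
    anchor: str = "c_terminal"  # or "anywhere"
    requires_amidation: bool = False
    pyroglutamate: bool = False
    monobasic_allowed: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        if self.anchor not in ("c_terminal", "anywhere"):
            raise CatalogError(f"{self.family}: bad anchor {self.anchor!r}")
        parse_pattern(self.pattern)  # validate eagerly

    @property
    def tokens(self) -> list[str]:
        return parse_pattern(self.pattern)

    @property
    def literal_count(self) -> int:
        return sum(1 for t in self.tokens if len(t) == 1 and t != "X")

    @property
    def regex(self) -> str:
        parts = []
        for t in self.tokens:
            if t == "X":
                parts.append(".")
            elif len(t) == 1:
                parts.append(t)
            else:
                parts.append(f"[{t}]")
        return "".join(parts)


@dataclass(frozen=True)
class CysFrameworkRule:
    family: str
    cys_count: int
    cprp_required: bool = False
    description: str = ""


@dataclass
class Catalog:
    motifs: list[FamilyMotif]
    cys_rules: list[CysFrameworkRule] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.motifs)

    def by_family(self, family: str) -> Optional[FamilyMotif]:
        for m in self.motifs:
            if m.family == family:
                return m
        return None


def load_motif_catalog(path: str | Path | None = None) -> Catalog:
    """Load a motif catalog (YAML); with no path, the shipped default."""
    if path is None:
        text = (resources.files("neuromine") / "data" / "motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise CatalogError(f"unreadable catalog: {exc}") from exc
    if not isinstance(doc, dict) or "motifs" not in doc:
        raise CatalogError("catalog must be a mapping with a 'motifs' list")
    motifs = []
    for entry in doc["motifs"]:
        family = entry.get("family", "<unnamed>")
        try:
            motifs.append(
                FamilyMotif(
                    family=family,
                    pattern=entry["pattern"],
                    anchor=entry.get("anchor", "c_terminal"),
                    requires_amidation=bool(entry.get("requires_amidation", False)),
                    pyroglutamate=bool(entry.get("pyroglutamate", False)),
                    monobasic_allowed=bool(entry.get("monobasic_allowed", False)),
                    source=entry.get("source", ""),
                )
            )
        except (CatalogError, KeyError) as exc:
            raise CatalogError(f"family {family!r}: {exc}") from exc
    cys_rules = [
        CysFrameworkRule(
            family=e["family"],
            cys_count=int(e["cys_count"]),
            cprp_required=bool(e.get("cprp_required", False)),
            description=e.get("description", ""),
        )
        for e in doc.get("cys_frameworks", [])
    ]
    keywords = [str(k) for k in doc.get("keywords", [])]
    return Catalog(motifs=motifs, cys_rules=cys_rules, keywords=keywords)


DEFAULT_CYS_RULES = (
    CysFrameworkRule("CHH", 6),
    CysFrameworkRule("neuroparsin", 12),
)


def match_peptide_families(
    peptide: MaturePeptide,
    catalog: Catalog | Sequence[FamilyMotif],
    ignore_amidation: bool = False,
) -> list[tuple[FamilyMotif, int]]:
    """All (motif, 1-based match position) pairs matching the peptide core.

    C-terminal motifs must end flush with the core; "anywhere" motifs report
    every (overlapping) start position.  A motif requiring amidation only
    matches an amidated peptide unless ``ignore_amidation``.
    """
    core = peptide.core
    if not core:
        raise ValueError("peptide core is empty")
    out: list[tuple[FamilyMotif, int]] = []
    for motif in catalog:
        if motif.requires_amidation and not peptide.amidated and not ignore_amidation:
            continue
        pat = motif.regex
        if motif.anchor == "c_terminal":
            m = re.search(pat + r"\Z", core)
            if m:
                out.append((motif, m.start() + 1))
        else:
            for m in re.finditer(f"(?=({pat}))", core):
                out.append((motif, m.start() + 1))
    return out


@dataclass
class FamilyAssignment:
    peptide_ref: str
    family: str
    motif: FamilyMotif
    position: int
    specificity: int
    alternatives: list[str] = field(default_factory=list)


def assign_family(
    matches: Sequence[tuple[FamilyMotif, int]],
    peptide_ref: str = "",
) -> Optional[FamilyAssignment]:
    """Pick the winning family: maximal literal count, ties broken by longer
    pattern then lexicographic family name.  Order-invariant."""
    if not matches:
        return None
    ranked = sorted(
        matches,
        key=lambda mp: (-mp[0].literal_count, -len(mp[0].tokens), mp[0].family, mp[1]),
    )
    winner, pos = ranked[0]
    alternatives = sorted({m.family for m, _ in matches if m.family != winner.family})
    return FamilyAssignment(
        peptide_ref=peptide_ref,
        family=winner.family,
        motif=winner,
        position=pos,
        specificity=winner.literal_count,
        alternatives=alternatives,
    )


def classify_chh_type(
    architecture: PrecursorArchitecture,
    min_cys: int = 6,
    min_cprp_length: int = 10,
) -> tuple[str, Optional[MaturePeptide]]:
    """CHH-superfamily precursor typing.

    ``chh_type_I``: a >=6-cysteine peptide preceded (after the signal) by
    another released segment of >= ``min_cprp_length`` residues terminated by
    a dibasic site — that segment is the CPRP.  ``chh_type_II_like``: the
    cysteine-rich peptide directly follows the signal.  Returns
    (type, cprp_peptide_or_None).
    """
    peptides = sorted(architecture.peptides, key=lambda p: p.span_start)
    signal_end = (
        architecture.signal.cleavage_after or 0
        if architecture.signal.present
        else 0
    )
    for idx, pep in enumerate(peptides):
        if pep.cys_count < min_cys:
            continue
        if idx > 0:
            prev = peptides[idx - 1]
            span_len = prev.span_end - prev.span_start + 1
            terminated = any(
                s.position == prev.span_end + 1 and len(s.residues) >= 2
                for s in architecture.sites
            )
            if (
                prev.span_start > signal_end
                and span_len >= min_cprp_length
                and terminated
            ):
                return "chh_type_I", prev
        if architecture.signal.present and pep.span_start == signal_end + 1:
            return "chh_type_II_like", None
    return "not_chh", None


def classify_cys_rich(
    peptide: MaturePeptide,
    rules: Sequence[CysFrameworkRule] = DEFAULT_CYS_RULES,
) -> Optional[str]:
    """Suggest a family by exact cysteine count (CHH 6, neuroparsin 12).
    Never overrides a motif-based assignment — callers apply it only when no
    motif matched."""
    for rule in rules:
        if peptide.cys_count == rule.cys_count:
            return rule.family
    return None
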
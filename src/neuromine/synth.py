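"""Synthetic prepropeptide generator with ground truth, plus recovery scoring.

The generator emulates the canonical secretory precursor layout: an
N-terminal signal peptide (Met + hydrophobic core + small residues at the
von Heijne -3/-1 positions), one or more mature peptides instantiating a
family motif (X positions randomized), glycine amidation donors, flanking
dibasic sites, an optional CPRP segment for CHH-type precursors, and a short
C-terminal tail.  Decoys are motif-free proteins without any enabled basic
pair, so pipeline specificity failures isolate the motif/curation logic
rather than the cleavage scanner.

The generator and the rule engine deliberately share the same coordinate
conventions ("K_nR" site indexing, donor glycine inside the span), so under
canonical settings the pipeline recovers every generated architecture
exactly — an executable consistency proof, not a claim about real data.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .catalog import Catalog, assign_family, load_motif_catalog, match_peptide_families
from .errors import GenerationError
from .orf import Precursor
from .pipeline import CatalogEntry, _arch_to_dict
from .processing import (
    CleavageRules,
    CleavageSite,
    MaturePeptide,
    PrecursorArchitecture,
    build_architecture,
    scan_cleavage_sites,
)
from .seqio import FastaRecord, write_fasta
from .signal_peptide import SignalPrediction, predict_signal_peptide

AA20 = "ACDEFGHIKLMNPQRSTVWY"
HYDRO_CORE = "LIVF"          # strongly hydrophobic h-region residues
SMALL = "AGSCT"              # favored at the -3/-1 cleavage positions
POLAR_C = "DENQHP"           # polar c-region filler
NO_BASIC = "".join(a for a in AA20 if a not in "KR")
NO_BASIC_NO_CYS = "".join(a for a in NO_BASIC if a != "C")


@dataclass
class GeneratorConfig:
    seed: int = 17
    n_true: int = 30
    n_decoys: int = 70
    families: Optional[list[str]] = None  # default: every motif family
    peptides_per_precursor: tuple[int, int] = (1, 3)
    signal_length: tuple[int, int] = (18, 30)
    spacer_length: tuple[int, int] = (0, 2)  # C-terminal tail after last site
    prefix_length: tuple[int, int] = (0, 4)  # N-terminal slack inside a span
    site_kinds: tuple[str, ...] = ("KR", "RR", "KK")
    amidation_rate: float = 0.5  # for motifs without obligate amidation
    cprp_length: tuple[int, int] = (12, 30)
    decoy_length: tuple[int, int] = (80, 200)
    background_kr_weight: float = 0.25  # K/R down-weight outside sites (decoys)
    hard_decoys: bool = False  # allow basic pairs in decoys (stress mode)
    max_resample: int = 200


@dataclass
class SyntheticTruth:
    precursor_id: str
    sequence: str
    architecture: PrecursorArchitecture
    families: list[Optional[str]]  # one entry per truth peptide
    is_decoy: bool = False


def _draw(rng: np.random.Generator, alphabet: str, k: int) -> str:
    if k <= 0:
        return ""
    return "".join(rng.choice(list(alphabet), size=k))


def generate_signal_peptide(rng: np.random.Generator, length: int) -> str:
    """A signal peptide satisfying the predictor's contract: Met start, a
    >=8-residue Kyte-Doolittle window of mean hydropathy >= 2 inside
    positions 2..(length-5), small residues at -3 and -1."""
    if not 10 <= length <= 45:
        raise ValueError("signal length must be in 10..45")
    chars = ["M"]
    chars += list(_draw(rng, HYDRO_CORE, length - 6))  # positions 2..length-5
    chars.append(rng.choice(list(POLAR_C)))            # -5
    chars.append(rng.choice(list(POLAR_C)))            # -4
    chars.append(rng.choice(list(SMALL)))              # -3
    chars.append(rng.choice(list(POLAR_C)))            # -2
    chars.append(rng.choice(list(SMALL)))              # -1
    return "".join(chars)


def _instantiate_motif(rng: np.random.Generator, tokens: Sequence[str]) -> str:
    out = []
    for t in tokens:
        if t == "X":
            out.append(rng.choice(list(NO_BASIC)))
        elif len(t) == 1:
            out.append(t)
        else:
            out.append(rng.choice(list(t)))
    return "".join(out)


def _rand_int(rng: np.random.Generator, bounds: tuple[int, int]) -> int:
    return int(rng.integers(bounds[0], bounds[1] + 1))


def generate_precursor(
    config: GeneratorConfig,
    family: str,
    rng: np.random.Generator,
    precursor_id: str = "synthetic",
    catalog: Catalog | None = None,
) -> SyntheticTruth:
    """One ground-truth precursor of the given family.

    ``family`` may be any motif family from the catalog, or "CHH" for a
    CHH-type-I-style precursor (signal + CPRP + dibasic site + 6-cysteine
    hormone).  The assembled sequence is verified against the rule engine
    (scan reproduces exactly the intended sites; each peptide's family winner
    is the intended family; the signal is detected) and resampled on the
    rare accidental violation.
    """
    catalog = catalog or load_motif_catalog()
    motif = catalog.by_family(family)
    if motif is None and family != "CHH":
        raise ValueError(f"unknown family {family!r}")

    for _ in range(config.max_resample):
        sig_len = _rand_int(rng, config.signal_length)
        signal_seq = generate_signal_peptide(rng, sig_len)
        parts: list[str] = [signal_seq]
        pos = sig_len
        sites: list[CleavageSite] = []
        peptides: list[MaturePeptide] = []
        families: list[Optional[str]] = []

        if family == "CHH":
            cprp = _draw(rng, NO_BASIC_NO_CYS, _rand_int(rng, config.cprp_length))
            parts.append(cprp)
            peptides.append(
                MaturePeptide(precursor_id, pos + 1, pos + len(cprp), cprp)
            )
            families.append(None)  # CPRP carries no family motif
            pos += len(cprp)
            res = str(rng.choice(list(config.site_kinds)))
            sites.append(CleavageSite(pos + 1, res))
            parts.append(res)
            pos += len(res)
            m = _rand_int(rng, (45, 60))
            body = list(_draw(rng, NO_BASIC_NO_CYS, m))
            for idx in sorted(rng.choice(m, size=6, replace=False)):
                body[int(idx)] = "C"
            hormone = "".join(body)
            parts.append(hormone)
            peptides.append(
                MaturePeptide(precursor_id, pos + 1, pos + m, hormone)
            )
            families.append("CHH")
            pos += m
        else:
            n_pep = _rand_int(rng, config.peptides_per_precursor)
            for pi in range(n_pep):
                prefix_len = _rand_int(rng, config.prefix_length)
                core = _instantiate_motif(rng, motif.tokens)
                if pi > 0 and prefix_len == 0 and core[0] in "KR":
                    prefix_len = 1  # keep the span from fusing with the site
                core = _draw(rng, NO_BASIC, prefix_len) + core
                amidated = motif.requires_amidation or (
                    rng.random() < config.amidation_rate
                )
                pyro = motif.pyroglutamate and core.startswith("Q")
                span = core + ("G" if amidated else "")
                parts.append(span)
                peptides.append(
                    MaturePeptide(
                        precursor_id, pos + 1, pos + len(span), core, amidated, pyro
                    )
                )
                families.append(motif.family)
                pos += len(span)
                res = str(rng.choice(list(config.site_kinds)))
                sites.append(CleavageSite(pos + 1, res))
                parts.append(res)
                pos += len(res)
            tail = _draw(rng, NO_BASIC, _rand_int(rng, config.spacer_length))
            parts.append(tail)
            pos += len(tail)

        sequence = "".join(parts)
        precursor = Precursor(precursor_id, sequence, True, True)

        # closure checks against the rule engine
        rules = CleavageRules(
            monobasic=bool(motif and motif.monobasic_allowed)
        )
        scanned = scan_cleavage_sites(sequence, rules)
        if [(s.position, s.residues) for s in scanned] != [
            (s.position, s.residues) for s in sites
        ]:
            continue
        if not predict_signal_peptide(precursor).present:
            continue
        ok = True
        for pep, fam in zip(peptides, families):
            got = assign_family(match_peptide_families(pep, catalog))
            if fam is None or fam == "CHH":
                if got is not None:
                    ok = False
                    break
            elif got is None or got.family != fam:
                ok = False
                break
        if not ok:
            continue

        truth_signal = SignalPrediction(True, sig_len, 1.0)
        arch = build_architecture(precursor, truth_signal, sites, peptides)
        return SyntheticTruth(precursor_id, sequence, arch, families, False)

    raise GenerationError(
        f"could not generate a valid {family} precursor in "
        f"{config.max_resample} attempts; consider loosening the config"
    )


def generate_decoy(
    config: GeneratorConfig,
    rng: np.random.Generator,
    precursor_id: str = "decoy",
    catalog: Catalog | None = None,
) -> SyntheticTruth:
    """A motif-free protein with no enabled basic pair (unless
    ``hard_decoys``), rejection-sampled with a cap."""
    catalog = catalog or load_motif_catalog()
    patterns = [re.compile(m.regex) for m in catalog.motifs]
    weights = np.array(
        [config.background_kr_weight if a in "KR" else 1.0 for a in AA20]
    )
    weights = weights / weights.sum()
    alphabet = list(AA20)

    for _ in range(config.max_resample):
        n = _rand_int(rng, config.decoy_length)
        chars = ["M"]
        while len(chars) < n:
            ch = str(rng.choice(alphabet, p=weights))
            if (
                not config.hard_decoys
                and ch in "KR"
                and chars[-1] in "KR"
            ):
                continue
            chars.append(ch)
        if chars[-1] == "G":  # avoid a spurious amidation donor at the end
            chars[-1] = "A"
        sequence = "".join(chars)
        if any(p.search(sequence) for p in patterns):
            continue
        if not config.hard_decoys and scan_cleavage_sites(sequence):
            continue
        precursor = Precursor(precursor_id, sequence, True, True)
        pep = MaturePeptide(precursor_id, 1, n, sequence)
        arch = build_architecture(
            precursor, SignalPrediction(False, None, 0.0), [], [pep]
        )
        return SyntheticTruth(precursor_id, sequence, arch, [None], True)

    raise GenerationError(
        f"could not generate a decoy in {config.max_resample} attempts; "
        f"consider loosening the constraints"
    )


def generate_benchmark(config: GeneratorConfig) -> list[SyntheticTruth]:
    """The full benchmark (true precursors + decoys) in seeded shuffled
    order, with neutral sequential ids."""
    rng = np.random.default_rng(config.seed)
    catalog = load_motif_catalog()
    families = config.families or [m.family for m in catalog.motifs]
    specs = ["true"] * config.n_true + ["decoy"] * config.n_decoys
    rng.shuffle(specs)
    out: list[SyntheticTruth] = []
    fam_i = 0
    for idx, kind in enumerate(specs):
        pid = f"syn_{idx:04d}"
        if kind == "true":
            family = families[fam_i % len(families)]
            fam_i += 1
            out.append(generate_precursor(config, family, rng, pid, catalog))
        else:
            out.append(generate_decoy(config, rng, pid, catalog))
    return out


def truth_to_dict(truth: SyntheticTruth) -> dict:
    fams = [f for f in truth.families if f]
    return {
        "is_decoy": truth.is_decoy,
        "family": fams[0] if fams else None,
        "families": truth.families,
        "sequence": truth.sequence,
        "signal_length": (
            truth.architecture.signal.cleavage_after
            if truth.architecture.signal.present
            else None
        ),
        "sites": [
            {"position": s.position, "residues": s.residues}
            for s in truth.architecture.sites
        ],
        "peptides": [
            {
                "span_start": p.span_start,
                "span_end": p.span_end,
                "core": p.core,
                "amidated": p.amidated,
                "pyroglutamate": p.pyroglutamate,
            }
            for p in truth.architecture.peptides
        ],
        "architecture": _arch_to_dict(truth.architecture),
    }


def generate_benchmark_set(
    config: GeneratorConfig, outdir: str | Path
) -> tuple[Path, Path]:
    """Write the benchmark FASTA plus the truth JSON; fully deterministic
    under a fixed seed (byte-identical files)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truths = generate_benchmark(config)
    fasta_path = outdir / "benchmark.faa"
    truth_path = outdir / "truth.json"
    write_fasta(
        [FastaRecord(t.precursor_id, t.sequence) for t in truths], fasta_path
    )
    doc = {t.precursor_id: truth_to_dict(t) for t in truths}
    truth_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return fasta_path, truth_path


@dataclass
class RecoveryMetrics:
    n_true: int
    n_decoys: int
    signal_exact: float
    signal_within2: float
    site_precision: float
    site_recall: float
    peptide_span_exact: float
    family_accuracy: float
    decoy_false_complete_rate: float

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _ratio(num: int, den: int, empty: float = 1.0) -> float:
    return num / den if den else empty


def evaluate_recovery(
    catalog_entries: Sequence[CatalogEntry],
    truth: dict | str | Path,
) -> RecoveryMetrics:
    """Score a mined catalog against a truth table (dict or JSON path).

    Truth entries absent from the catalog count as unrecovered; catalog
    entries with ids unknown to the truth are an error (mismatched inputs).
    """
    if not isinstance(truth, dict):
        truth = json.loads(Path(truth).read_text())
    by_id = {e.architecture.precursor_id: e for e in catalog_entries}
    unknown = sorted(set(by_id) - set(truth))
    if unknown:
        raise ValueError(f"catalog ids missing from truth: {unknown}")

    n_true = n_decoys = 0
    sig_exact = sig_within2 = sig_total = 0
    tp = fp = fn = 0
    span_hit = span_total = 0
    fam_hit = fam_total = 0
    false_complete = 0

    for pid, t in truth.items():
        entry = by_id.get(pid)
        if t["is_decoy"]:
            n_decoys += 1
            if entry and entry.curation.status == "complete":
                false_complete += 1
            continue
        n_true += 1

        true_sites = {(s["position"], s["residues"]) for s in t["sites"]}
        pred_sites = (
            {(s.position, s.residues) for s in entry.architecture.sites}
            if entry
            else set()
        )
        tp += len(true_sites & pred_sites)
        fp += len(pred_sites - true_sites)
        fn += len(true_sites - pred_sites)

        if t["signal_length"] is not None:
            sig_total += 1
            pred_sig = entry.architecture.signal if entry else None
            if pred_sig and pred_sig.present:
                delta = abs(pred_sig.cleavage_after - t["signal_length"])
                sig_exact += delta == 0
                sig_within2 += delta <= 2

        true_spans = {(p["span_start"], p["span_end"]) for p in t["peptides"]}
        pred_spans = (
            {(p.span_start, p.span_end) for p in entry.architecture.peptides}
            if entry
            else set()
        )
        span_total += len(true_spans)
        span_hit += len(true_spans & pred_spans)

        if t["family"] is not None:
            fam_total += 1
            if entry and entry.curation.family_call == t["family"]:
                fam_hit += 1

    return RecoveryMetrics(
        n_true=n_true,
        n_decoys=n_decoys,
        signal_exact=_ratio(sig_exact, sig_total),
        signal_within2=_ratio(sig_within2, sig_total),
        site_precision=_ratio(tp, tp + fp),
        site_recall=_ratio(tp, tp + fn, empty=0.0 if fn else 1.0),
        peptide_span_exact=_ratio(span_hit, span_total, empty=0.0),
        family_accuracy=_ratio(fam_hit, fam_total),
        decoy_false_complete_rate=_ratio(false_complete, n_decoys, empty=0.0),
    )
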
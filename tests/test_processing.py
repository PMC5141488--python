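"""Cleavage scanning, peptide release, PTM inference, architecture tiling."""

import re

import numpy as np
import pytest

import neuromine as nm
from neuromine import examples as ex
from neuromine.errors import AssemblyError, ContractError
from neuromine.orf import Precursor
from neuromine.processing import CleavageRules, CleavageSite, MaturePeptide
from neuromine.signal_peptide import SignalPrediction

# ------------------------------------------------------------- scanning ----


def oracle_sites(seq, rules=None):
    """Brute-force window oracle: every maximal [KR]+ run, kept by the same
    published rules, located independently via regex."""
    rules = rules or CleavageRules()
    out = []
    for m in re.finditer("[KR]+", seq):
        run = m.group()
        if len(run) >= 3:
            out.append((m.start() + 1, run))
        elif len(run) == 2 and run in rules.enabled_pairs:
            out.append((m.start() + 1, run))
        elif (
            len(run) == 1
            and rules.monobasic
            and run == "R"
            and m.start() > 0
            and seq[m.start() - 1] == "G"
        ):
            out.append((m.start() + 1, run))
    return out


def test_simple_dibasic():
    (site,) = nm.scan_cleavage_sites("AAAKRAAA")
    assert (site.position, site.residues, site.kind) == (4, "KR", "dibasic")


def test_bursicon_alpha_has_no_sites():
    assert nm.scan_cleavage_sites(ex.BURSICON_ALPHA) == []


def test_rk_pair_disabled_but_multibasic_reported():
    assert nm.scan_cleavage_sites("AAARKAAA") == []
    (site,) = nm.scan_cleavage_sites("AAARKRAAA")
    assert (site.position, site.residues, site.kind) == (4, "RKR", "multibasic")


def test_monobasic_requires_donor_context():
    assert nm.scan_cleavage_sites("AAGRAA") == []  # off by default
    rules = CleavageRules(monobasic=True)
    (site,) = nm.scan_cleavage_sites("AAGRAA", rules)
    assert (site.position, site.residues, site.kind) == (4, "R", "monobasic")
    assert nm.scan_cleavage_sites("AALRAA", rules) == []  # no donor G
    assert nm.scan_cleavage_sites("AAGKAA", rules) == []  # monobasic K never


@pytest.mark.parametrize("monobasic", [False, True])
def test_scanner_matches_window_oracle(monobasic):
    """1000 random 200-aa sequences: identical site lists to the
    brute-force run oracle."""
    rng = np.random.default_rng(3)
    aa = list("ACDEFGHIKLMNPQRSTVWY")
    rules = CleavageRules(monobasic=monobasic)
    for _ in range(1000):
        seq = "".join(rng.choice(aa, 200))
        got = [(s.position, s.residues) for s in nm.scan_cleavage_sites(seq, rules)]
        assert got == oracle_sites(seq, rules)


# -------------------------------------------------------------- release ----


def test_ccap_release_between_sites():
    prec, sig = ex.ccap_style()
    sites = nm.scan_cleavage_sites(prec.sequence)
    peps = nm.release_peptides(prec, sig, sites)
    ccap = [p for p in peps if p.span_start == 48][0]
    assert (ccap.span_end, ccap.core, ccap.amidated) == (57, "PFCNAFTGC", True)
    assert ccap.display == "PFCNAFTGCamide"


def test_no_sites_no_signal_whole_chain():
    prec = Precursor("p", "MSTNQDEVAST")
    peps = nm.release_peptides(prec, SignalPrediction(False, None, 0.0), [])
    assert len(peps) == 1
    pep = peps[0]
    assert (pep.span_start, pep.span_end) == (1, 11)
    assert pep.core == prec.sequence and not pep.amidated


def test_short_fragments_become_spacers():
    prec = Precursor("p", "MAAAKRSTKRAAAA")  # 2-aa fragment between sites
    sites = nm.scan_cleavage_sites(prec.sequence)
    peps = nm.release_peptides(prec, SignalPrediction(False, None, 0.0), sites)
    assert [(p.span_start, p.span_end) for p in peps] == [(1, 4), (11, 14)]


def test_overlapping_sites_rejected():
    prec = Precursor("p", "MAAAKRAAAA")
    bad = [CleavageSite(5, "KR"), CleavageSite(6, "R")]
    with pytest.raises(ContractError):
        nm.release_peptides(prec, SignalPrediction(False, None, 0.0), bad)


# ----------------------------------------------------------------- PTMs ----


@pytest.mark.parametrize(
    "span,pyro,display",
    [
        ("QTFQYSRGWTNG", True, "pQTFQYSRGWTNamide"),
        ("QLNFSPGWG", False, "QLNFSPGWamide"),
        ("ACDEF", False, "ACDEF"),
    ],
)
def test_ptm_inference_examples(span, pyro, display):
    core, amidated, got_pyro = nm.infer_ptms(
        span, settings=nm.PTMSettings(pyroglutamate=pyro)
    )
    pep = MaturePeptide("p", 1, len(span), core, amidated, got_pyro)
    assert pep.display == display


def test_amidation_respects_min_core_length():
    core, amidated, _ = nm.infer_ptms("AAG", min_peptide_length=3)
    assert core == "AAG" and not amidated


def test_disulfide_potential():
    def pep(core):
        return MaturePeptide("p", 1, len(core), core)

    assert nm.count_disulfide_potential(pep("C" * 6 + "A")) == (6, 3, False)
    assert nm.count_disulfide_potential(pep("ACDC" * 6)) == (12, 6, False)
    assert nm.count_disulfide_potential(pep("CADE")) == (1, 0, True)
    assert nm.count_disulfide_potential(pep("ADE")) == (0, 0, False)


# --------------------------------------------------------- architecture ----


def test_ccap_architecture_segment_roles():
    prec, sig = ex.ccap_style()
    sites = nm.scan_cleavage_sites(prec.sequence)
    peps = nm.release_peptides(prec, sig, sites)
    arch = nm.build_architecture(prec, sig, sites, peps)
    roles = [s.role for s in arch.segments]
    assert roles == [
        "signal", "peptide", "cleavage", "peptide", "cleavage", "peptide",
    ]
    assert arch.segments[0].end == 24


def test_architecture_without_features_is_one_peptide():
    prec = Precursor("p", "MSTNQDEVAST")
    sig = SignalPrediction(False, None, 0.0)
    peps = nm.release_peptides(prec, sig, [])
    arch = nm.build_architecture(prec, sig, [], peps)
    assert [s.role for s in arch.segments] == ["peptide"]
    assert (arch.segments[0].start, arch.segments[0].end) == (1, 11)


def test_inconsistent_inputs_name_offender():
    prec = Precursor("p", "MAAAKRAAAA")
    sig = SignalPrediction(False, None, 0.0)
    outside = MaturePeptide("p", 8, 20, "A" * 13)
    with pytest.raises(AssemblyError, match="outside precursor"):
        nm.build_architecture(prec, sig, [], [outside])
    overlap = MaturePeptide("p", 4, 7, "AKRA")
    with pytest.raises(AssemblyError, match="overlap"):
        nm.build_architecture(prec, sig, [CleavageSite(5, "KR")], [overlap])


def test_tiling_conservation_on_synthetic_set():
    """Segments tile each synthetic precursor exactly: re-concatenating the
    segment substrings in order reproduces the chain (200 architectures)."""
    rng = np.random.default_rng(5)
    catalog = nm.load_motif_catalog()
    families = [m.family for m in catalog.motifs]
    config = nm.GeneratorConfig(seed=5)
    for i in range(200):
        family = families[i % len(families)]
        truth = nm.generate_precursor(config, family, rng, f"s{i}", catalog)
        arch = truth.architecture
        rebuilt = "".join(
            truth.sequence[s.start - 1 : s.end] for s in arch.segments
        )
        assert rebuilt == truth.sequence
        bounds = [(s.start, s.end) for s in arch.segments]
        assert bounds[0][0] == 1 and bounds[-1][1] == len(truth.sequence)
        assert all(b0[1] + 1 == b1[0] for b0, b1 in zip(bounds, bounds[1:]))


def test_amidation_soundness_on_synthetic_set():
    """Every amidated peptide's span ends in the glycine donor."""
    rng = np.random.default_rng(6)
    config = nm.GeneratorConfig()
    catalog = nm.load_motif_catalog()
    for i, family in enumerate(m.family for m in catalog.motifs):
        truth = nm.generate_precursor(config, family, rng, f"s{i}", catalog)
        for pep in truth.architecture.peptides:
            if pep.amidated:
                assert truth.sequence[pep.span_end - 1] == "G"
            assert pep.core == truth.sequence[
                pep.span_start - 1 : pep.span_end - (1 if pep.amidated else 0)
            ]


# ----------------------------------------- printed architecture numbers ----


def test_acp_position_arithmetic():
    prec, sig = ex.acp_style()
    sites = nm.scan_cleavage_sites(prec.sequence)
    assert [(s.position, s.residues) for s in sites] == [(33, "KR")]
    pep = nm.release_peptides(prec, sig, sites)[0]
    assert (pep.span_start, pep.span_end) == (21, 32)
    assert pep.span_end - pep.span_start + 1 == 12


def test_myosuppressin_position_arithmetic():
    prec, sig, rules = ex.myosuppressin_style()
    sites = nm.scan_cleavage_sites(prec.sequence, rules)
    assert [(s.position, s.residues) for s in sites] == [(84, "KR"), (97, "R")]
    pep = [p for p in nm.release_peptides(prec, sig, sites) if p.span_start == 86][0]
    assert pep.span_end == 96 and pep.display == "QDLDHVFLRFamide"
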
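# Methods

## The processing model

A secretory neuropeptide precursor (prepropeptide) is modeled as a tiling of
1-based, inclusive segments:

```
[signal 1..s] [peptide] [site] [peptide] [site] ... [spacer]
```

Every stage annotates this tiling and the package enforces the conservation
invariant throughout: segments cover each residue exactly once, and
re-concatenating them in position order reproduces the input chain.

**Coordinates.** Cleavage sites follow the `K_nR` convention used in the
crustacean neuropeptide literature: `n` indexes the *first* basic residue of
the site, mature spans run from the previous site's last residue + 1 to the
next site's position − 1, and a multibasic run (`R_37_KR`) is a single site
object with cleavage after its final basic residue. This convention is the
one under which the published worked-example architectures (ACP, CCAP,
myosuppressin, SIFamide, RPCH, DH31) are arithmetically exact; the
acceptance script recomputes them.

**Cleavage rules.** Prohormone convertases prefer paired basic residues, so
the scanner reports maximal K/R runs that (i) are a dibasic pair from the
enabled set — KR, RR, KK by default; RK is a poor convertase substrate and
is off — or (ii) have length ≥ 3. Monobasic cleavage is high-false-positive
and is therefore off globally and enabled per family by the catalog
(myosuppressin). When enabled, a single R counts only if it is immediately
preceded by G — the amidation donor exposed by the upstream peptide, i.e.
the canonical GR/GKR processing signal. A bare single-R rule would wrongly
cut inside `QDLDHVFLRFamide` itself; the donor-context rule reproduces the
published K_84_R + R_97 myosuppressin architecture exactly. Because flush
C-terminal motif matching cannot succeed before the monobasic cut exists,
the pipeline runs a second scanning pass with monobasic sites on whenever a
monobasic-allowed family's motif occurs anywhere inside a first-pass
released peptide.

**PTMs.** A released span ending in G is amidated (the G is the donor and is
removed from the core) provided the remaining core is at least
`min_peptide_length` residues. Pyroglutamate (N-terminal Q cyclization) is
applied only for families the catalog flags (corazonin yes; RPCH
deliberately not, matching how its mature peptide is conventionally printed)
— a global Q rule would over-call. Displays are deterministic:
`("p" if pyroglutamate) + core + ("amide" if amidated)`.

**Signal peptides.** The predictor is a two-component heuristic, not a
neural network: (1) a hydrophobic core — best 8-residue window within
positions 2..30 with mean Kyte–Doolittle hydropathy compared against
`h_min = 1.6`; (2) the von Heijne (−3,−1) rule — small residues (A,G,S,C,T)
at the cleavage position and two before it, searched within 10..45 and
anchored just downstream of the last qualifying hydrophobic window (signal
peptidase cuts a few residues past the h-region). The score is
`c_hydro * (0.4 + 0.6 * c_cleave)` with `c_hydro = clip(0.5 + H − h_min)`
and `c_cleave` the (−3,−1) preference with the −1 position weighted double;
it is bounded in [0, 1], monotone in both components, and compared against a
0.5 threshold. Chains shorter than 12 residues, and chains whose N-terminus
is missing (`n_complete` false), are always called absent. This intentionally
trades accuracy for transparency; an external predictor can be substituted
upstream by supplying a `SignalPrediction` directly to the release/assembly
functions.

**Family assignment.** Motifs are degenerate patterns over the 20-letter
alphabet plus `X` (any) and bracketed alternatives, matched flush against
the processed core for C-terminal anchors. "amide" in a published motif is
represented as a `requires_amidation` flag, never as a pattern character,
because matching operates on processed cores. The winner among multiple
matches is the motif with the most literal positions (ties: longer pattern,
then family name) — e.g. `QDLDHVFLRFamide` matches both myosuppressin
(10 literals) and the generic FLRFamide motif (3), and myosuppressin wins.
Families with no usable short motif (PDH, CFSH-like, GPA2/GPB5,
insulin-like, eclosion hormone, elevenin, prohormone-4,
vasopressin-neurophysin, bursicon) are reachable only through the keyword
channel. Cysteine frameworks (CHH 6, neuroparsin 12) are a fallback
suggestion and never override a motif assignment.

**Curation.** `complete` = signal present AND family evidence (motif,
keyword, or cysteine framework) AND both termini complete; `partial` =
family evidence plus a missing-completeness flag (the published bursicon-α
case: motif-level evidence, no signal, 5′-truncated); otherwise `rejected`.
Cysteine-framework evidence additionally requires processing evidence (at
least one cleavage site in the architecture): a bare cysteine count on an
unprocessed chain is not family evidence. This codifies a manual-curation
step that has no published rejection thresholds; the logic table is
exhaustively unit-tested.

## Defaults that matter

| parameter | default | why |
|---|---|---|
| `min_orf_aa` | 50 | keeps short PDH-like precursors (~79 aa) safely above threshold with margin for partials |
| `require_start` | off | 5′-truncated partials must remain representable |
| enabled dibasic pairs | KR, RR, KK | RK is a poor convertase substrate |
| `monobasic` | off (catalog per family) | high false-positive rate; donor-context (G before R) required when on |
| `min_peptide_length` | 3 aa | prevents 1–2 aa artifacts between adjacent sites |
| `h_min` | 1.6 | hydrophobic-core calling threshold (Kyte–Doolittle mean) |
| signal cleavage range | 10..45 | observed signal-peptide length range |
| NW scoring | BLOSUM62, linear gap −8 | standard protein scoring; deterministic traceback diagonal > up > left |

## The synthetic generator

The generator emulates the canonical precursor layouts: signal peptide
(Met + hydrophobic core from {L,I,V,F}, polar c-region, small residues at
−3/−1; default length 18–30 aa), then alternating blocks of mature peptide
(0–4 random non-basic prefix residues + a motif instantiation with `X`
positions randomized) + glycine donor where amidated + a dibasic site, and a
0–2 aa tail; CHH-type precursors instead carry a CPRP segment, a dibasic
site and a 6-cysteine hormone. Decoys are motif-free chains containing no
basic pair (a `hard_decoys` mode allows sites but still no motifs), so
specificity failures isolate the motif/curation logic from the scanner.
K and R are excluded from all non-site draws and every assembled chain is
re-verified against the rule engine (scan reproduces exactly the intended
sites, each peptide's family winner is the intended family, the signal is
detected), with rejection sampling on the rare accidental violation.

Because generator and rule engine share one coordinate convention, the
canonical benchmark (30 true + 70 decoys) is recovered *exactly* — site
recall/precision 1.0, family accuracy 1.0, decoy false-complete rate 0.
This closure is an executable consistency proof of the `K_nR` ledger, **not**
evidence about real transcriptomes: real data contain non-canonical sites,
convertase-context effects, signal peptides the heuristic will miss,
composition bias, and assembly artifacts, none of which the generator
models. Background composition is uniform by default; no attempt is made to
match a real eyestalk proteome.

## Phylogenetics stand-in

Family grouping uses pairwise Needleman–Wunsch identity distances
(1 − identity over both-aligned columns) and classical neighbor joining
(Saitou–Nei Q-criterion; ties broken by the lexicographically smallest pair
of cluster representatives; negative branch-length estimates clamped to 0
with a warning), written as Newick with 6-decimal branch lengths. This is a
deliberate desk-scale stand-in for maximum-likelihood analysis with
bootstrap support, which is out of scope (it would require a multiple
sequence alignment this package does not compute). NJ provably recovers the
topology of exactly additive matrices, which the tests exercise against an
independent reader.

## Numerical and degenerate-input choices

- Ambiguous codons containing N translate to X; an ORF never starts at X.
- `find_orfs` sorts by descending protein length, ties by (frame, start).
- Alignment traceback prefers diagonal, then a gap in the second sequence,
  then in the first; scores are exact floats from the BLOSUM62 table.
- A chain with no signal and no sites releases as a single unmodified
  peptide; spans shorter than `min_peptide_length` become spacer segments.
- All randomness flows through `numpy.random.default_rng(seed)`; fixed seed
  implies byte-identical generator output and exports.

## Problem sizes

Test and acceptance runs use desk-scale inputs chosen once: ≤ 1 kb
transcripts for ORF oracle checks, 200-aa chains for scanner oracle checks
(1000 draws), 500 random peptides for the motif-matcher oracle, sequences of
length ≤ 6 for brute-force alignment enumeration, trees of ≤ 8 taxa for NJ
recovery, and the 30 + 70 canonical benchmark. The full suite runs in a few
seconds on one CPU.

## Known limitations

- The signal heuristic is far weaker than modern predictors; it exists to
  make the pipeline self-contained and its contract testable.
- Monobasic cleavage outside the donor-G context, furin sites, and
  disulfide connectivity (pairing) are not modeled.
- The curation table is this package's codification of a manual procedure;
  real curators also weigh BLAST context and cross-species alignments.
- NJ trees carry no support values and are not comparable to published
  ML/bootstrap figures.
- Two catalog transcriptions are low-confidence as printed in the source
  results (AST-A `XYXFLG` vs the canonical A-type `Y/FXFGL`; the HIGSLYamide
  slash rendering); they are flagged in the catalog's `source` field.
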
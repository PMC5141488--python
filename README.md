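# neuromine

Rule-based mining of neuropeptide precursors from transcriptome assemblies,
modeled on the curation practice used for crustacean neuropeptidomes (the
motivating system is the *Cherax quadricarinatus* eyestalk ganglion, the
tissue that houses the X-organ/sinus-gland neuroendocrine complex).

Starting from transcripts (nucleotide FASTA) or candidate protein chains,
the pipeline derives prepropeptide **architectures** and curates them into a
family catalog:

1. **ORF finding** — six-frame translation under the standard genetic code;
   completeness (Met start, in-frame stop) is recorded, not enforced, so
   5′-truncated partials stay representable.
2. **Signal peptide** — a heuristic combining a Kyte–Doolittle hydrophobic
   core (mean hydropathy ≥ 1.6 over an 8-residue window within positions
   2–30) with the von Heijne (−3,−1) small-residue rule; score in [0, 1],
   call threshold 0.5.
3. **Cleavage sites** — prohormone-convertase sites as maximal K/R runs:
   dibasic KR/RR/KK (RK off by default), any tri-or-more-basic run, and —
   per-family only — monobasic R immediately preceded by the glycine
   amidation donor (the classic GR/GKR processing signal). Positions use the
   field's `K_nR` convention: *n* indexes the first basic residue.
4. **Mature peptides and PTMs** — spans between signal/site boundaries;
   a C-terminal glycine becomes an amide (`PFCNAFTGCamide`), an N-terminal
   glutamine cyclizes to pyroglutamate only for catalog-flagged families
   (`pQTFQYSRGWTNamide`).
5. **Family assignment** — a shipped catalog of 22 degenerate motifs
   (`X` = any residue, `[YF]` = alternatives) matched flush against processed
   peptide cores; ties resolved by motif specificity (count of literal
   positions). Cysteine-framework rules type CHH-superfamily precursors
   (6 cysteines → 3 disulfide bridges, with or without a CPRP segment) and
   neuroparsins (12 cysteines).
6. **Curation** — `complete` requires a signal peptide plus family evidence
   (motif, keyword, or cysteine framework) on a both-ends-complete chain;
   family evidence on a truncated chain gives `partial`; everything else is
   `rejected`.

A synthetic-precursor generator produces ground-truth architectures (and
motif-free decoys) so every stage is testable without sequencing data, and a
small phylogenetics module (Needleman–Wunsch, identity distances, neighbor
joining, Newick) supports family grouping at desk scale.

## Worked example

```python
import neuromine as nm
from neuromine.orf import Precursor

# a CCAP-style precursor: 24-aa signal, K_46_R, PFCNAFTGC + donor G, K_58_K
from neuromine.examples import ccap_style
precursor, signal = ccap_style()

sites = nm.scan_cleavage_sites(precursor.sequence)
peptides = nm.release_peptides(precursor, signal, sites)
arch = nm.build_architecture(precursor, signal, sites, peptides)
print([(s.position, s.residues) for s in sites])
print([p.display for p in peptides])
print(nm.render_architecture(arch))
```

prints

```
[(46, 'KR'), (58, 'KK')]
['ASTNQDEVASTNQDEVASTNQ', 'PFCNAFTGCamide', 'SDETN']
[SP 1-24]--[PEP 25-45]--(KR@46)--[PEP 48-57 amide]--(KK@58)--[PEP 60-64]
```

i.e. the two dibasic sites at positions 46 and 58 release the amidated
mature peptide `PFCNAFTGCamide` from the span 48–57, exactly the published
CCAP architecture arithmetic; the flanking spans are filler in this
synthetic stand-in.

The same from a shell, over a synthetic benchmark:

```sh
neuromine simulate -o bench --seed 17            # FASTA + truth JSON
neuromine run bench/benchmark.faa --out mined    # catalog.{tsv,json}, peptides.faa, architectures.gff3
neuromine tree mined/peptides.faa -o tree.nwk    # NJ tree of mature peptides
```

## Layout

```
src/neuromine/
  seqio.py           FASTA I/O with strict alphabets
  orf.py             six-frame ORFs, precursor selection
  signal_peptide.py  hydrophobicity + (-3,-1) signal heuristic
  processing.py      cleavage rules, peptide release, PTMs, architectures
  catalog.py         motif catalog, family assignment, cysteine frameworks
  pipeline.py        end-to-end mining, curation, exports (TSV/JSON/GFF3/FASTA)
  phylo.py           global alignment, distances, neighbor joining, Newick
  synth.py           ground-truth generator, decoys, recovery metrics
  examples.py        published worked-example architectures
  data/motifs.yaml   the shipped motif/framework/keyword catalog
```

See `docs/methods.md` for the model, parameter defaults, and limitations.
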
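# Degenerate neuropeptide family motifs (X = any residue, [..] = alternatives)
# and cysteine-framework rules, transcribed from the C. quadricarinatus
# eyestalk neuropeptidome results.  "amide" in a published motif is encoded as
# requires_amidation; the glycine donor is never part of the pattern because
# matching operates on processed peptide cores.
motifs:
  - family: AST-A
    pattern: XYXFLG
    anchor: c_terminal
    requires_amidation: true
    source: "A-type allatostatin C-terminus as printed (XYXFLGamide); note the canonical A-type consensus Y/FXFGLamide differs - low confidence"
  - family: AST-B
    pattern: XWXXXXGXW
    anchor: c_terminal
    requires_amidation: true
    source: "B-type allatostatin XWXXXXGXWamide"
  - family: AST-C
    pattern: PISCF
    anchor: c_terminal
    requires_amidation: true
    source: "C-type allatostatin PISCFamide"
  - family: CCAP
    pattern: PFCNAFTGC
    anchor: c_terminal
    requires_amidation: true
    source: "crustacean cardioactive peptide PFCNAFTGCamide"
  - family: CCHamide
    pattern: GHSCXGAH
    anchor: c_terminal
    requires_amidation: true
    source: "CCHamide consensus GHSCXGAHamide"
  - family: corazonin
    pattern: QTFQYSRGWTN
    anchor: c_terminal
    requires_amidation: true
    pyroglutamate: true
    source: "corazonin pQTFQYSRGWTNamide"
  - family: FLRFamide
    pattern: "X[YF]LRF"
    anchor: c_terminal
    requires_amidation: true
    source: "FLRFamide X-Y/F-LRFamide"
  - family: GSEFLamide
    pattern: XGSEFL
    anchor: c_terminal
    requires_amidation: true
    source: "GSEFLamide XGSEFLamide"
  - family: HIGSLYamide
    pattern: "H[LI][AG]SL[YH]K"
    anchor: c_terminal
    requires_amidation: true
    source: "HIGSLYRamide HL/IA/GSLY/HKamide - ambiguous slash rendering, low confidence"
  - family: kinin
    pattern: XFSAWA
    anchor: c_terminal
    requires_amidation: true
    source: "kinin XFSAWAamide"
  - family: myosuppressin
    pattern: QDLDHVFLRF
    anchor: c_terminal
    requires_amidation: true
    monobasic_allowed: true
    source: "myosuppressin QDLDHVFLRFamide; released by K_84_R plus monobasic R_97"
  - family: NPF
    pattern: RPRF
    anchor: c_terminal
    requires_amidation: true
    source: "neuropeptide F RPRFamide"
  - family: orcokinin
    pattern: XFDEIDRXGFGFX
    anchor: c_terminal
    requires_amidation: true
    source: "orcokinin XFDEIDRXGFGFXamide; amide state varies across the literature"
  - family: proctolin
    pattern: RYLPT
    anchor: c_terminal
    requires_amidation: false
    source: "proctolin RYLPT (free acid)"
  - family: pyrokinin
    pattern: FXPRL
    anchor: c_terminal
    requires_amidation: true
    source: "pyrokinin/PBAN FXPRLamide"
  - family: RPCH
    pattern: QLNFSPGW
    anchor: c_terminal
    requires_amidation: true
    pyroglutamate: false
    source: "red pigment-concentrating hormone QLNFSPGWamide (printed without pQ)"
  - family: RYamide
    pattern: XXXXXRY
    anchor: c_terminal
    requires_amidation: true
    source: "RYamide XXXXXRYamide"
  - family: SIFamide
    pattern: GYRKPPFNGSIF
    anchor: c_terminal
    requires_amidation: true
    source: "SIFamide GYRKPPFNGSIFamide"
  - family: sNPF
    pattern: XPXRLRF
    anchor: c_terminal
    requires_amidation: true
    source: "short neuropeptide F XPXRLRFamide"
  - family: sulfakinin
    pattern: DYGHXRF
    anchor: c_terminal
    requires_amidation: true
    source: "sulfakinin DYGHXRFamide"
  - family: tachykinin
    pattern: APSGFLGMR
    anchor: c_terminal
    requires_amidation: true
    source: "tachykinin APSGFLGMRamide"
  - family: WXXXRamide
    pattern: WXXXR
    anchor: c_terminal
    requires_amidation: true
    source: "natalisin-like WXXXRamide"

cys_frameworks:
  - family: CHH
    cys_count: 6
    cprp_required: false
    description: "CHH superfamily: six conserved cysteines, three disulfide bridges; type I precursors carry a CPRP between signal and hormone"
  - family: neuroparsin
    cys_count: 12
    cprp_required: false
    description: "neuroparsin: 12 cysteines, possibly six disulfide bridges"

# keyword channel defaults (case-insensitive substring match on annotation
# descriptions); families with no usable short motif are reachable only here
keywords:
  - allatostatin
  - bursicon
  - cardioactive
  - CCHamide
  - corazonin
  - crustacean female sex hormone
  - CFSH
  - diuretic hormone
  - eclosion
  - elevenin
  - hyperglycemic
  - molt-inhibiting
  - molt inhibiting
  - ion transport peptide
  - FLRFamide
  - glycoprotein hormone
  - GPA2
  - GPB5
  - GSEFLamide
  - HIGSLY
  - insulin
  - kinin
  - myosuppressin
  - neuroparsin
  - neuropeptide F
  - orcokinin
  - pigment-dispersing
  - pigment dispersing
  - red pigment
  - prohormone
  - proctolin
  - pyrokinin
  - RYamide
  - SIFamide
  - sulfakinin
  - tachykinin
  - natalisin
  - vasopressin
  - neurophysin
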
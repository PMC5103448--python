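# Default Hox/ParaHox diagnostic-signature catalog.
#
# Labels: the ancestral lophotrochozoan toolkit of 11 Hox paralog groups and
# 3 ParaHox genes.  Coordinates are canonical homeodomain positions 1-60;
# flank offsets count away from the domain (-1 immediately before position 1,
# +1 immediately after position 60).  Features with an empty pattern and
# weight 0 are placeholders: the signature is localised in the literature but
# its residues are not printed, so it is excluded from scoring until a user
# fills it in (e.g. from `hoxminer discover` output).
groups:
  - name: Hox1
    class: hox
    features:
      - region: HD_POS
        positions: [2, 3]
        predicates: [non-basic, non-basic]
        weight: 1.0
        scope: bilaterian
        note: two non-basic residues in the N-terminal arm of the homeodomain
      - region: HD_POS
        positions: [6, 7, 8]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: conserved motif, residues not printed"
      - region: HD_POS
        positions: [29]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: unique single-residue signature"
      - region: HD_POS
        positions: [56]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: unique single-residue signature"
      - region: C_FLANK
        window: [1, 2]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: conserved motif at offsets +1/+2, residues not printed"
  - name: Hox2
    class: hox
    features:
      - region: HD_POS
        positions: [3, 4, 5]
        predicates: [basic, non-basic, basic]
        weight: 1.0
        scope: bilaterian
        note: DNA-contacting residue at position 4 between conserved basic residues
      - region: HD_POS
        positions: [2]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: unique single-residue signature"
      - region: HD_POS
        positions: [24]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: unique single-residue signature"
      - region: HD_POS
        positions: [58, 59]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: unique signature at positions 58-59"
  - name: Hox3
    class: hox
    features:
      - region: HD_POS
        positions: [3, 4, 5]
        predicates: [basic, non-basic, basic]
        weight: 1.0
        scope: bilaterian
        note: DNA-contacting residue at position 4 between conserved basic residues
      - region: HD_POS
        positions: [36, 37]
        pattern: "AL"
        weight: 1.0
        required: true
        scope: lophotrochozoan
        note: lophotrochozoan AL motif; required to separate Hox3 from Hox2
      - region: HD_POS
        positions: [14]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: conserved bilaterian residue"
  - name: Hox4
    class: hox
    features:
      - region: N_FLANK
        window: [-60, -1]
        pattern: "YPWM"
        weight: 1.0
        scope: bilaterian
        note: hexapeptide motif upstream of the homeodomain (shared with Hox5)
      - region: C_FLANK
        window: [1, 30]
        pattern: "LPNTK"
        weight: 1.0
        scope: bilaterian
        note: diagnostic motif downstream of the homeodomain
  - name: Hox5
    class: hox
    features:
      - region: N_FLANK
        window: [-60, -1]
        pattern: "YPWM"
        weight: 1.0
        scope: bilaterian
        note: hexapeptide motif upstream of the homeodomain (shared with Hox4)
      - region: C_FLANK
        offset: 1
        pattern: "HIAKNM"
        weight: 1.0
        scope: molluscan
        note: molluscan six-residue motif immediately after position 60
  - name: Lox5
    class: hox
    features:
      - region: C_FLANK
        window: [1, 30]
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: Lox5 parapeptide, residues not printed"
  - name: Antp
    class: hox
    features:
      - region: N_FLANK
        window: [-30, -1]
        pattern: ""
        weight: 0.0
        scope: bilaterian
        note: "placeholder: Hox-PBC interaction region right before the homeodomain"
  - name: Lox4
    class: hox
    features:
      - region: C_FLANK
        window: [1, 30]
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: Ubd-A parapeptide, residues not printed"
  - name: Lox2
    class: hox
    features:
      - region: C_FLANK
        window: [1, 30]
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: Ubd-A parapeptide, residues not printed"
  - name: Post2
    class: hox
    features:
      - region: HD_POS
        positions: []
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: distinctive homeodomain residues, positions not printed"
  - name: Post1
    class: hox
    features:
      - region: HD_POS
        positions: []
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: distinctive homeodomain residues, positions not printed"
  - name: Gsx
    class: parahox
    features:
      - region: C_FLANK
        window: [1, 30]
        pattern: "LRTCD"
        weight: 1.0
        scope: lophotrochozoan
        note: lophotrochozoan pentapeptide in the C-terminal arm
  - name: Xlox
    class: parahox
    features:
      - region: N_FLANK
        window: [-60, -1]
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: flanking signature peptides, residues not printed"
  - name: Cdx
    class: parahox
    features:
      - region: N_FLANK
        window: [-60, -1]
        pattern: ""
        weight: 0.0
        scope: lophotrochozoan
        note: "placeholder: flanking signature peptides, residues not printed"
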
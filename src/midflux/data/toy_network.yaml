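# Toy glycolysis/TCA-like network used for examples and ground-truth tests.
#
# Atom indices are 0-based carbon backbone positions.  GLC feeds pyruvate via
# two glycolytic half-reactions (top and bottom carbon halves), acetyl units
# come from a PDH-like mixing node (pyruvate decarboxylation vs an unlabeled
# lipogenic source), and 2-oxoglutarate mixes a citrate-derived (IDH-like)
# entry with a glutamine-derived entry.  Tracers mimic 50% [1,2-13C2]glucose
# and 100% [U-13C]glutamine.

compounds:
  GLC: 6   # glucose (source)
  GLN: 5   # glutamine (source)
  CO2: 1   # carbon dioxide pool (source, unlabeled)
  ACX: 2   # unlabeled acetyl source, lipogenic (source)
  PYR: 3   # pyruvate
  ACA: 2   # acetyl unit
  OAA: 4   # oxaloacetate
  CIT: 6   # citrate
  AKG: 5   # 2-oxoglutarate
  GLU: 5   # glutamate

reactions:
  - id: glyc_top        # glucose C3..C1 -> pyruvate C1..C3
    type: cleavage
    product: PYR
    substrates:
      - compound: GLC
        map: {2: 0, 1: 1, 0: 2}
  - id: glyc_bottom     # glucose C4..C6 -> pyruvate C1..C3
    type: cleavage
    product: PYR
    substrates:
      - compound: GLC
        map: {3: 0, 4: 1, 5: 2}
  - id: pdh             # pyruvate -CO2 -> acetyl
    type: cleavage
    product: ACA
    substrates:
      - compound: PYR
        map: {1: 0, 2: 1}
  - id: lipo            # unlabeled acetyl source
    type: transfer
    product: ACA
    substrates:
      - compound: ACX
        map: {0: 0, 1: 1}
  - id: pc              # pyruvate carboxylation
    type: condensation
    product: OAA
    substrates:
      - compound: PYR
        map: {0: 0, 1: 1, 2: 2}
      - compound: CO2
        map: {0: 3}
  - id: akg_oaa         # oxidative TCA flux, loses one carbon
    type: cleavage
    product: OAA
    substrates:
      - compound: AKG
        map: {1: 0, 2: 1, 3: 2, 4: 3}
  - id: cs              # citrate synthase: acetyl + oxaloacetate
    type: condensation
    product: CIT
    substrates:
      - compound: ACA
        map: {0: 0, 1: 1}
      - compound: OAA
        map: {0: 2, 1: 3, 2: 4, 3: 5}
  - id: idh             # citrate -CO2 -> 2-oxoglutarate
    type: cleavage
    product: AKG
    substrates:
      - compound: CIT
        map: {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
  - id: glu_akg         # glutamine-derived entry
    type: transfer
    product: AKG
    substrates:
      - compound: GLU
        map: {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}
  - id: gls             # glutaminase: glutamine -> glutamate
    type: transfer
    product: GLU
    substrates:
      - compound: GLN
        map: {0: 0, 1: 1, 2: 2, 3: 3, 4: 4}

mixing:
  PYR:
    - {reaction: glyc_top, fraction: 0.5}
    - {reaction: glyc_bottom, fraction: 0.5}
  ACA:
    - {reaction: pdh, fraction: 0.8}
    - {reaction: lipo, fraction: 0.2}
  OAA:
    - {reaction: pc, fraction: 0.5}
    - {reaction: akg_oaa, fraction: 0.5}
  AKG:
    - {reaction: idh, fraction: 0.7}
    - {reaction: glu_akg, fraction: 0.3}

sources:
  GLC: unlabeled
  GLN: unlabeled
  CO2: unlabeled
  ACX: unlabeled

tracers:
  glc:                       # 50% [1,2-13C2]glucose
    GLC: {"110000": 0.5, "000000": 0.5}
    GLN: unlabeled
  gln:                       # 100% [U-13C]glutamine
    GLN: {"11111": 1.0}
    GLC: unlabeled

fragments:
  PYR:
    - {mz: 174, atoms: [0, 1, 2], formula: C6H12NO3Si, tracer_atoms: 3}
    - {mz: 158, atoms: [1, 2], formula: C5H12NO2Si, tracer_atoms: 2}
  ACA:
    - {mz: 117, atoms: [0, 1], formula: C4H9O2Si, tracer_atoms: 2}
  OAA:
    - {mz: 304, atoms: [0, 1, 2, 3], formula: C10H22NO4Si2, tracer_atoms: 4}
    - {mz: 218, atoms: [1, 2, 3], formula: C8H20NO2Si2, tracer_atoms: 3}
  CIT:
    - {mz: 465, atoms: [0, 1, 2, 3, 4, 5], formula: C16H33O7Si4, tracer_atoms: 6}
    - {mz: 375, atoms: [1, 2, 3, 4, 5], formula: C13H27O5Si3, tracer_atoms: 5}
  AKG:
    - {mz: 288, atoms: [0, 1, 2, 3, 4], formula: C10H18NO4Si2, tracer_atoms: 5}
    - {mz: 198, atoms: [1, 2, 3, 4], formula: C8H16NO2Si, tracer_atoms: 4}
  GLU:
    - {mz: 363, atoms: [0, 1, 2, 3, 4], formula: C14H32NO4Si3, tracer_atoms: 5}
    - {mz: 246, atoms: [1, 2, 3, 4], formula: C10H24NO2Si2, tracer_atoms: 4}
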
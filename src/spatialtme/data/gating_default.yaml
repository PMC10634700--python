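# Default exclusive gating hierarchy: 23 terminal cell states, 18 of them
# T cell states. Siblings are evaluated in listed order; the first matching
# predicate wins. Cells matching no terminal gate fall into the residual
# "Other" leaf. `require_any` groups need at least one positive marker each.
schema_version: 1
residual_leaf: Other
panel:
  - CD3
  - CD8
  - FOXP3
  - PANCK
  - CD20
  - CD68
  - ASMA
  - TOX1
  - TIM3
  - TCF-1
  - CD38
  - PD-1
  - EOMES
  - CD39
  - CD44
  - LAG-3
  - T-BET
  - KI67
  - GRZB
nodes:
  - {name: root, parent: null}

  # ---- T cell compartment -------------------------------------------------
  - {name: T cell, parent: root, require_positive: [CD3]}

  - {name: CD8 T, parent: T cell, require_positive: [CD8]}
  - {name: T_NAIVE, parent: CD8 T, terminal: true,
     require_positive: [TCF-1],
     require_negative: [CD44, PD-1, TOX1, EOMES, TIM3, LAG-3]}
  - {name: T_EFF, parent: CD8 T, terminal: true,
     require_positive: [CD44, T-BET],
     require_negative: [TCF-1, PD-1, TIM3, LAG-3]}
  - {name: T_EM, parent: CD8 T, terminal: true,
     require_positive: [CD44, TCF-1, T-BET]}
  - {name: T_EMRA, parent: CD8 T, terminal: true,
     require_positive: [T-BET, EOMES], require_negative: [CD44]}
  - {name: T_EX, parent: CD8 T, terminal: true,
     require_positive: [PD-1], require_negative: [TOX1],
     require_any: [[TIM3, LAG-3]]}
  - {name: T_TEX, parent: CD8 T, terminal: true,
     require_positive: [PD-1], require_any: [[TOX1, EOMES]]}
  - {name: CD44+ T_OTHER, parent: CD8 T, terminal: true,
     require_positive: [CD44]}
  - {name: CD44- T_OTHER, parent: CD8 T, terminal: true,
     require_negative: [CD44]}

  - {name: CD4 T, parent: T cell, require_negative: [CD8]}

  - {name: T_REG, parent: CD4 T, require_positive: [FOXP3]}
  - {name: T-BET+ T_REG, parent: T_REG, terminal: true,
     require_positive: [T-BET]}
  - {name: mT_REG, parent: T_REG, terminal: true,
     require_positive: [CD44], require_negative: [T-BET]}
  - {name: Naive T_REG, parent: T_REG, terminal: true,
     require_negative: [CD44, T-BET]}

  - {name: Th, parent: CD4 T, require_negative: [FOXP3]}

  - {name: Th1, parent: Th, require_positive: [T-BET]}
  - {name: Th1 T_EFF, parent: Th1, terminal: true,
     require_positive: [CD44],
     require_negative: [TCF-1, PD-1, TIM3, LAG-3]}
  - {name: Th1 T_EM, parent: Th1, terminal: true,
     require_positive: [CD44, TCF-1]}
  - {name: Th1 T_EMRA, parent: Th1, terminal: true,
     require_positive: [EOMES], require_negative: [CD44]}
  - {name: CD44+ Th1 T_OTHER, parent: Th1, terminal: true,
     require_positive: [CD44]}
  - {name: CD44- Th1 T_OTHER, parent: Th1, terminal: true,
     require_negative: [CD44]}

  - {name: Th other, parent: Th, require_negative: [T-BET]}
  - {name: CD44+ Th, parent: Th other, terminal: true,
     require_positive: [CD44]}
  - {name: CD44- Th, parent: Th other, terminal: true,
     require_negative: [CD44]}

  # ---- non-T compartment --------------------------------------------------
  - {name: non-T, parent: root, require_negative: [CD3]}
  - {name: Neoplastic epithelial, parent: non-T, terminal: true,
     require_positive: [PANCK]}
  - {name: B cell, parent: non-T, terminal: true,
     require_positive: [CD20], require_negative: [PANCK]}
  - {name: Myeloid, parent: non-T, terminal: true,
     require_positive: [CD68], require_negative: [PANCK, CD20]}
  - {name: Mesenchymal, parent: non-T, terminal: true,
     require_positive: [ASMA], require_negative: [PANCK, CD20, CD68]}
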
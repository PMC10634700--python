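"""Hierarchical phenotyping and T cell functionality barcodes.

Assigns every cell exactly one of 23 states by walking the exclusive
marker-gating hierarchy (first matching sibling wins), then encodes each
T cell's functional phenotype as a 10-bit barcode over the fixed marker
order TOX1, TIM3, TCF-1, CD38, PD-1, EOMES, CD39, CD44, LAG-3, T-BET.
"""

import logging

from spatialtme import (
    GeneratorConfig,
    assign_barcodes,
    assign_states,
    generate_cohort,
    load_gating_config,
)

logging.disable(logging.WARNING)

gating = load_gating_config()
print(f"taxonomy: {len(gating.leaves)} states, "
      f"{len(gating.t_state_leaves)} of them T cell states\n")

config = GeneratorConfig(
    seed=7,
    n_patients_per_cohort={"naive": 2, "aCD40": 2},
    regions_per_patient={"IA": 2},
    cells_per_region=400,
)
cells, regions, patients, truth = generate_cohort(config)
cells = assign_states(cells, gating)
cells = assign_barcodes(cells, gating)

agreement = (cells["state"] == truth.cells["planted_state"]).mean()
print(f"planted-state recovery: {agreement:.1%}")  # exact by construction

print("\nmost common cell states:")
print(cells["state"].value_counts().head(6).to_string())

barcodes = cells["barcode"].dropna()
print(f"\n{len(barcodes)} T cells carry {barcodes.nunique()} distinct "
      "barcodes (<= 1024 possible); the most common:")
print(barcodes.value_counts().head(5).to_string())
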
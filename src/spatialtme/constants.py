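"""Canonical tokens shared across the package.

All cohort, site, and marker labels are case-sensitive strings defined here
once; modules compare against these constants rather than re-declaring them.
"""

SCHEMA_VERSION = 1

#: Treatment cohorts: untreated-at-resection vs neoadjuvant agonistic CD40 antibody.
COHORT_NAIVE = "naive"
COHORT_ACD40 = "aCD40"
COHORTS = (COHORT_NAIVE, COHORT_ACD40)

#: Histopathologic site annotations: tumor, immune aggregate,
#: tumor-adjacent stroma, normal-adjacent pancreas.
SITE_T = "T"
SITE_IA = "IA"
SITE_TAS = "TAS"
SITE_NAP = "NAP"
SITES = (SITE_T, SITE_IA, SITE_TAS, SITE_NAP)

#: Disease-free survival groups after the median split of the treated cohort.
DFS_LONG = "long"
DFS_SHORT = "short"
DFS_GROUPS = (DFS_LONG, DFS_SHORT)

#: Fixed order of the 10 T cell functionality markers that form the barcode.
BARCODE_MARKERS = (
    "TOX1",
    "TIM3",
    "TCF-1",
    "CD38",
    "PD-1",
    "EOMES",
    "CD39",
    "CD44",
    "LAG-3",
    "T-BET",
)

#: Functional flags scored on T cells but NOT part of the barcode.
FLAG_KI67 = "KI67"
FLAG_GRZB = "GRZB"

#: Lineage markers used by the shipped gating hierarchy.
LINEAGE_MARKERS = ("CD3", "CD8", "FOXP3", "PANCK", "CD20", "CD68", "ASMA")

#: Full default antibody panel (lineage + barcode + functional flags).
DEFAULT_PANEL = LINEAGE_MARKERS + BARCODE_MARKERS + (FLAG_KI67, FLAG_GRZB)

#: Name of the residual taxonomy leaf catching cells matching no explicit gate.
RESIDUAL_LEAF = "Other"

#: Feature families in the region-by-feature matrix.
FAMILY_DENSITY = "density"
FAMILY_BARCODE = "barcode_density"
FAMILY_INTERACTION = "interaction"
FAMILIES = (FAMILY_DENSITY, FAMILY_BARCODE, FAMILY_INTERACTION)

#: Default spatial scales (microns).
INTERACTION_RADIUS_UM = 20.0
NEIGHBORHOOD_RADIUS_UM = 60.0
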
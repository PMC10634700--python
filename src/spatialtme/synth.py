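"""Synthetic multiplex-IHC-like cohorts with planted, recoverable structure.

The generator emulates the statistical shape of a two-cohort spatial
proteomics study: patients carry several tissue regions per histopathologic
site, each region is a spatial point pattern of cells with binary marker
positivity, and treatment / survival effects are planted as multiplicative
shifts on cell-state frequencies and functional-marker probabilities.

Two contracts make downstream stages exactly testable:

* **gating consistency** — marker positivity for a planted state is drawn
  from the exact conditional Bernoulli distribution given that the full
  positivity vector gates to that state under the configured hierarchy
  (small exhaustive enumeration of the free gating markers), so hierarchical
  phenotyping recovers every planted state with zero error;
* **stream independence** — every (patient, region) pair owns a named RNG
  stream derived from the master seed, so adding a region never perturbs
  the cells of another.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    BARCODE_MARKERS,
    COHORT_ACD40,
    COHORT_NAIVE,
    COHORTS,
    DEFAULT_PANEL,
    DFS_LONG,
    DFS_SHORT,
    FLAG_GRZB,
    FLAG_KI67,
    SITE_IA,
    SITES,
)
from .gating import Barcode, GatingConfig, GatingError, load_gating_config

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SpatialModel:
    """Spatial point model for one region.

    ``uniform`` scatters cells uniformly in the square region. ``clustered``
    places ``n_clusters`` Gaussian aggregates and draws cells of the
    configured states (immune cells, by default) around a randomly chosen
    aggregate center with probability ``cluster_fraction`` — emulating
    lymphocyte aggregates.
    """

    kind: str = "uniform"  # "uniform" | "clustered"
    n_clusters: int = 3
    cluster_sd_um: float = 40.0
    cluster_fraction: float = 0.85
    clustered_states: tuple[str, ...] = ()  # empty -> all T states + B cells

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "clustered"):
            raise ConfigError(f"unknown spatial model kind {self.kind!r}")
        if self.kind == "clustered":
            if self.n_clusters < 1:
                raise ConfigError("clustered model needs n_clusters >= 1")
            if self.cluster_sd_um <= 0:
                raise ConfigError("cluster_sd_um must be positive")


@dataclass
class EffectSpec:
    """Planted multiplicative shifts between cohorts and DFS groups.

    ``cohort_density[c][state]`` multiplies the frequency of *state* in
    cohort *c* (frequencies are renormalized afterwards);
    ``cohort_marker[c][marker]`` multiplies the positivity probability of a
    functional *marker* on T cells of cohort *c*. The ``dfs_*`` maps do the
    same between long and short survivors within the treated cohort.
    """

    cohort_density: dict = field(default_factory=dict)
    cohort_marker: dict = field(default_factory=dict)
    dfs_density: dict = field(default_factory=dict)
    dfs_marker: dict = field(default_factory=dict)

    @classmethod
    def null(cls) -> "EffectSpec":
        """No planted effect anywhere (chance-level contract)."""
        return cls()


def default_effects() -> EffectSpec:
    """Default planted effects, mirroring the directions the analysis targets.

    The treated cohort gains antigen-experienced Th1/CD8 density and
    T-BET/CD44/TCF-1/TIM3/CD39 functional positivity; the untreated cohort
    is enriched for exhaustion markers (TOX1/EOMES) and naive populations.
    Within the treated cohort, long survivors gain CD44/CD38/CD39/TIM3/LAG-3
    and short survivors gain TOX1/PD-1.
    """
    return EffectSpec(
        cohort_density={
            COHORT_ACD40: {
                "CD44+ Th1 T_OTHER": 1.9,
                "Th1 T_EM": 1.7,
                "CD44+ T_OTHER": 1.5,
                "T_EX": 1.4,
                "Mesenchymal": 1.3,
            },
            COHORT_NAIVE: {
                "T_NAIVE": 1.6,
                "B cell": 1.3,
            },
        },
        cohort_marker={
            COHORT_ACD40: {
                "CD44": 1.6,
                "T-BET": 1.6,
                "TCF-1": 1.4,
                "TIM3": 1.4,
                "CD39": 1.5,
            },
            COHORT_NAIVE: {
                "TOX1": 1.9,
                "EOMES": 1.6,
            },
        },
        dfs_density={
            DFS_LONG: {"CD44+ Th1 T_OTHER": 1.9, "Th1 T_EM": 1.5},
            DFS_SHORT: {"T_TEX": 1.5},
        },
        dfs_marker={
            DFS_LONG: {
                "CD44": 1.5,
                "CD38": 1.5,
                "CD39": 1.5,
                "TIM3": 1.3,
                "LAG-3": 1.5,
            },
            DFS_SHORT: {"TOX1": 1.9, "PD-1": 1.8},
        },
    )


#: Baseline per-marker positivity probabilities on T cells.
DEFAULT_MARKER_P = {
    "TOX1": 0.15,
    "TIM3": 0.12,
    "TCF-1": 0.25,
    "CD38": 0.20,
    "PD-1": 0.15,
    "EOMES": 0.12,
    "CD39": 0.18,
    "CD44": 0.45,
    "LAG-3": 0.10,
    "T-BET": 0.25,
    FLAG_KI67: 0.10,
    FLAG_GRZB: 0.08,
}

#: Baseline composition per site: lineage mass then T-state mass split.
_SITE_LINEAGE = {
    "T": {"Neoplastic epithelial": 0.40, "Mesenchymal": 0.15, "Myeloid": 0.12,
          "B cell": 0.03, "Other": 0.05, "_T": 0.25},
    "IA": {"Neoplastic epithelial": 0.05, "Mesenchymal": 0.07, "Myeloid": 0.08,
           "B cell": 0.25, "Other": 0.10, "_T": 0.45},
    "TAS": {"Neoplastic epithelial": 0.15, "Mesenchymal": 0.25, "Myeloid": 0.20,
            "B cell": 0.05, "Other": 0.10, "_T": 0.25},
    "NAP": {"Neoplastic epithelial": 0.15, "Mesenchymal": 0.20, "Myeloid": 0.35,
            "B cell": 0.03, "Other": 0.12, "_T": 0.15},
}

#: Relative weights of the 18 T states within the T compartment
#: (CD4 helper lineages roughly two-fold the CD8 compartment).
_T_STATE_WEIGHTS = {
    "T_NAIVE": 0.040, "T_EFF": 0.010, "T_EM": 0.015, "T_EMRA": 0.010,
    "T_EX": 0.020, "T_TEX": 0.020, "CD44+ T_OTHER": 0.090,
    "CD44- T_OTHER": 0.120,
    "T-BET+ T_REG": 0.020, "mT_REG": 0.040, "Naive T_REG": 0.050,
    "Th1 T_EFF": 0.010, "Th1 T_EM": 0.020, "Th1 T_EMRA": 0.010,
    "CD44+ Th1 T_OTHER": 0.060, "CD44- Th1 T_OTHER": 0.050,
    "CD44+ Th": 0.200, "CD44- Th": 0.215,
}


def default_state_frequencies() -> dict[str, pd.Series]:
    """Per-site baseline state frequency vectors over the 23 leaves."""
    out = {}
    for site, lineage in _SITE_LINEAGE.items():
        freq = {}
        t_mass = lineage["_T"]
        for state, mass in lineage.items():
            if state != "_T":
                freq[state] = mass
        total_w = sum(_T_STATE_WEIGHTS.values())
        for state, w in _T_STATE_WEIGHTS.items():
            freq[state] = t_mass * w / total_w
        s = pd.Series(freq, dtype=float)
        out[site] = s / s.sum()
    return out


@dataclass
class GeneratorConfig:
    """Study-shaped defaults: 18 untreated + 11 treated patients, four
    histopathologic sites per patient, clustered immune-aggregate regions."""

    seed: int = 0
    n_patients_per_cohort: dict = field(
        default_factory=lambda: {COHORT_NAIVE: 18, COHORT_ACD40: 11}
    )
    regions_per_patient: dict = field(
        default_factory=lambda: {"T": 3, "IA": 3, "TAS": 3, "NAP": 2}
    )
    area_mm2: float = 0.5
    cells_per_region: int = 250
    state_frequency: dict | None = None  # site -> Series over leaves
    marker_p: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_P))
    background_p: float = 0.02  # functional markers on non-T cells
    lineage_noise_p: float = 0.01  # irrelevant lineage markers
    spatial_model: dict | None = None  # site -> SpatialModel
    effect_spec: EffectSpec = field(default_factory=default_effects)
    dfs_lognormal: dict = field(
        default_factory=lambda: {
            DFS_LONG: (np.log(20.0), 0.25),
            DFS_SHORT: (np.log(5.0), 0.25),
        }
    )

    def __post_init__(self) -> None:
        if self.cells_per_region < 1:
            raise ConfigError("cells_per_region must be >= 1")
        if self.area_mm2 <= 0:
            raise ConfigError("area_mm2 must be positive")
        for site in self.regions_per_patient:
            if site not in SITES:
                raise ConfigError(f"unknown site {site!r}")
        for cohort in self.n_patients_per_cohort:
            if cohort not in COHORTS:
                raise ConfigError(f"unknown cohort {cohort!r}")
        if self.state_frequency is None:
            self.state_frequency = default_state_frequencies()
        for site, freq in self.state_frequency.items():
            if not np.isclose(float(freq.sum()), 1.0, atol=1e-9):
                raise ConfigError(f"state frequencies for {site!r} do not sum to 1")
            if (freq < 0).any() or (freq > 1).any():
                raise ConfigError("state frequencies must lie in [0, 1]")
        if self.spatial_model is None:
            self.spatial_model = {
                site: (
                    SpatialModel("clustered", n_clusters=3, cluster_sd_um=40.0)
                    if site == SITE_IA
                    else SpatialModel("uniform")
                )
                for site in SITES
            }


@dataclass
class TruthRecord:
    """Planted ground truth for recovery tests."""

    cells: pd.DataFrame  # cell_id, planted_state, planted_barcode
    dfs_group: dict  # patient_id -> long/short (treated patients only)
    effects: EffectSpec

    @property
    def planted_treatment_density_states(self) -> set[str]:
        out: set[str] = set()
        for shifts in self.effects.cohort_density.values():
            out |= set(shifts)
        return out

    @property
    def planted_treatment_markers(self) -> set[str]:
        out: set[str] = set()
        for shifts in self.effects.cohort_marker.values():
            out |= set(shifts)
        return out

    def is_planted_treatment_feature(self, family: str, key: str) -> bool:
        """Whether a feature column carries a planted treatment effect:
        a density of a shifted state, or a barcode containing a shifted
        functional marker."""
        if family == "density":
            return key in self.planted_treatment_density_states
        if family == "barcode_density":
            return any(f"{m}+" in key for m in self.planted_treatment_markers)
        return False

    @property
    def planted_dfs_density_states(self) -> set[str]:
        out: set[str] = set()
        for shifts in self.effects.dfs_density.values():
            out |= set(shifts)
        return out

    @property
    def planted_dfs_markers(self) -> set[str]:
        out: set[str] = set()
        for shifts in self.effects.dfs_marker.values():
            out |= set(shifts)
        return out


# ---------------------------------------------------------------------------
# Exact conditional marker sampling per taxonomy leaf
# ---------------------------------------------------------------------------

class LeafSampler:
    """Draws marker positivity consistent with a planted taxonomy leaf.

    For each leaf the gating path fixes some markers; the remaining gating
    markers that can influence the assignment are enumerated exhaustively
    and sampled from the Bernoulli product distribution conditioned on the
    hierarchy classifying the cell into exactly that leaf.
    """

    def __init__(self, gating: GatingConfig):
        self.gating = gating
        self._plan: dict[str, tuple[dict, tuple[str, ...], list[dict]]] = {}
        for leaf in gating.leaves:
            self._plan[leaf] = self._build_plan(leaf)
        self._weight_cache: dict = {}

    # -- plan construction -------------------------------------------------

    def _build_plan(self, leaf: str):
        g = self.gating
        if leaf == g.residual_leaf:
            assigned = self._residual_assignment()
            return assigned, (), [dict()]
        pos, neg, _ = g.path_requirements(leaf)
        assigned = {m: True for m in pos}
        assigned.update({m: False for m in neg})
        free = self._relevant_free_markers(leaf, assigned)
        valid = []
        for combo in itertools.product([False, True], repeat=len(free)):
            trial = dict(assigned)
            trial.update(zip(free, combo))
            if g.classify_one(trial) == leaf:
                valid.append(dict(zip(free, combo)))
        if not valid:
            raise GatingError(f"no marker assignment can gate to {leaf!r}")
        return assigned, free, valid

    def _relevant_free_markers(self, leaf: str, assigned: dict) -> tuple[str, ...]:
        """Unassigned markers whose value can change whether *leaf* is hit."""
        g = self.gating

        def definitely_false(node) -> bool:
            if any(assigned.get(m) is False for m in node.require_positive):
                return True
            if any(assigned.get(m) is True for m in node.require_negative):
                return True
            return any(
                all(assigned.get(m) is False for m in group)
                for group in node.require_any
            )

        # ancestors from root to the leaf
        chain = []
        cur = g._by_name[leaf]
        while cur is not None:
            chain.append(cur)
            cur = g._by_name.get(cur.parent) if cur.parent else None
        chain.reverse()
        free: list[str] = []

        def add(markers) -> None:
            for m in markers:
                if m not in assigned and m not in free:
                    free.append(m)

        for depth in range(1, len(chain)):
            parent, target = chain[depth - 1], chain[depth]
            for sibling in g.children(parent.name):
                if sibling.name == target.name:
                    add(m for group in target.require_any for m in group)
                    break
                if not definitely_false(sibling):
                    add(sibling.markers)
        return tuple(free)

    def _residual_assignment(self) -> dict:
        """A negative-marker template guaranteeing the residual leaf."""
        g = self.gating
        assigned: dict[str, bool] = {}

        def definitely_false(node) -> bool:
            if any(assigned.get(m) is False for m in node.require_positive):
                return True
            if any(assigned.get(m) is True for m in node.require_negative):
                return True
            return any(
                all(assigned.get(m) is False for m in group)
                for group in node.require_any
            )

        def falsify_subtree(node) -> None:
            for child in g.children(node.name):
                if definitely_false(child):
                    continue
                cand = [m for m in child.require_positive if m not in assigned]
                if cand:
                    assigned[cand[0]] = False
                    continue
                for group in child.require_any:
                    for m in group:
                        if m not in assigned:
                            assigned[m] = False
                if definitely_false(child):
                    continue
                if child.terminal:
                    raise GatingError(
                        "cannot construct a residual cell: gate "
                        f"{child.name!r} is unavoidable"
                    )
                falsify_subtree(child)

        falsify_subtree(g.root)
        return assigned

    # -- sampling ----------------------------------------------------------

    def _marker_probability(
        self, marker: str, leaf: str, cohort: str, dfs_label, config: GeneratorConfig
    ) -> float:
        if self.gating.is_t_state(leaf):
            p = config.marker_p.get(marker, config.lineage_noise_p)
            p *= config.effect_spec.cohort_marker.get(cohort, {}).get(marker, 1.0)
            if dfs_label is not None:
                p *= config.effect_spec.dfs_marker.get(dfs_label, {}).get(marker, 1.0)
        else:
            if marker in BARCODE_MARKERS or marker in (FLAG_KI67, FLAG_GRZB):
                p = config.background_p
            else:
                p = config.lineage_noise_p
        if p < 0.0 or p > 1.0:
            logger.warning(
                "marker probability for %s on %s clamped from %.3f to [0, 1]",
                marker, leaf, p,
            )
            p = min(max(p, 0.0), 1.0)
        return p

    def sample_positivity(
        self,
        leaf: str,
        cohort: str,
        dfs_label,
        config: GeneratorConfig,
        rng: np.random.Generator,
        size: int,
    ) -> pd.DataFrame:
        """Draw *size* positivity vectors gating exactly to *leaf*."""
        assigned, free, valid = self._plan[leaf]
        key = (leaf, cohort, dfs_label)
        if key not in self._weight_cache:
            probs = {
                m: self._marker_probability(m, leaf, cohort, dfs_label, config)
                for m in free
            }
            weights = np.ones(len(valid))
            for i, combo in enumerate(valid):
                for m, bit in combo.items():
                    p = min(max(probs[m], 1e-9), 1.0 - 1e-9)
                    weights[i] *= p if bit else 1.0 - p
            total = weights.sum()
            weights = weights / total if total > 0 else np.full(len(valid), 1.0 / len(valid))
            self._weight_cache[key] = weights
        weights = self._weight_cache[key]

        out = pd.DataFrame(False, index=range(size), columns=list(DEFAULT_PANEL))
        for m, bit in assigned.items():
            out[m] = bit
        if free:
            picks = rng.choice(len(valid), size=size, p=weights)
            for j, m in enumerate(free):
                out[m] = np.array([valid[k][m] for k in picks], dtype=bool)
        fixed = set(assigned) | set(free)
        for m in DEFAULT_PANEL:
            if m in fixed:
                continue
            p = self._marker_probability(m, leaf, cohort, dfs_label, config)
            out[m] = rng.random(size) < p
        return out


def sample_barcode(
    state: str,
    cohort: str,
    dfs_label,
    config: GeneratorConfig,
    rng: np.random.Generator,
    gating: GatingConfig | None = None,
    sampler: LeafSampler | None = None,
) -> Barcode:
    """Draw one functionality barcode for a T cell of *state*.

    Bits fixed by the state's gating predicate (e.g. CD44 on a CD44+ state)
    are forced; all other bits follow the per-marker Bernoulli model with the
    configured cohort and survival-group shifts applied.
    """
    if sampler is None:
        sampler = LeafSampler(gating or load_gating_config())
    if not sampler.gating.is_t_state(state):
        raise ConfigError(f"{state!r} is not a T state")
    row = sampler.sample_positivity(state, cohort, dfs_label, config, rng, 1)
    return Barcode.from_positivity(row.iloc[0].to_dict())


# ---------------------------------------------------------------------------
# Region and cohort generation
# ---------------------------------------------------------------------------

def _region_rng(seed: int, patient_id: str, region_id: str) -> np.random.Generator:
    ss = np.random.SeedSequence(
        [int(seed), zlib.crc32(patient_id.encode()), zlib.crc32(region_id.encode())]
    )
    return np.random.default_rng(ss)


def _patient_rng(seed: int, patient_id: str) -> np.random.Generator:
    ss = np.random.SeedSequence([int(seed), 7, zlib.crc32(patient_id.encode())])
    return np.random.default_rng(ss)


def _state_probs(
    config: GeneratorConfig, gating: GatingConfig, cohort: str, site: str, dfs_label
) -> pd.Series:
    freq = config.state_frequency[site].reindex(gating.leaves).fillna(0.0)
    shifts = config.effect_spec.cohort_density.get(cohort, {})
    for state, mult in shifts.items():
        if state in freq.index:
            freq[state] *= mult
    if dfs_label is not None:
        for state, mult in config.effect_spec.dfs_density.get(dfs_label, {}).items():
            if state in freq.index:
                freq[state] *= mult
    return freq / freq.sum()


def generate_region(
    region: pd.Series,
    config: GeneratorConfig,
    gating: GatingConfig,
    sampler: LeafSampler,
    rng: np.random.Generator,
    dfs_label=None,
) -> pd.DataFrame:
    """Generate the cell-table fragment for one region."""
    n = config.cells_per_region
    side_um = float(np.sqrt(region["area_mm2"])) * 1000.0
    probs = _state_probs(config, gating, region["cohort"], region["site"], dfs_label)
    states = rng.choice(probs.index.to_numpy(), size=n, p=probs.to_numpy())

    model = config.spatial_model[region["site"]]
    x = rng.uniform(0.0, side_um, size=n)
    y = rng.uniform(0.0, side_um, size=n)
    if model.kind == "clustered":
        clustered_states = set(model.clustered_states) or (
            set(gating.t_state_leaves) | {"B cell"}
        )
        centers = rng.uniform(0.0, side_um, size=(model.n_clusters, 2))
        eligible = np.isin(states, list(clustered_states))
        in_cluster = eligible & (rng.random(n) < model.cluster_fraction)
        idx = np.flatnonzero(in_cluster)
        if idx.size:
            which = rng.integers(0, model.n_clusters, size=idx.size)
            x[idx] = np.clip(
                centers[which, 0] + rng.normal(0.0, model.cluster_sd_um, idx.size),
                0.0, side_um,
            )
            y[idx] = np.clip(
                centers[which, 1] + rng.normal(0.0, model.cluster_sd_um, idx.size),
                0.0, side_um,
            )

    frames = []
    order = np.arange(n)
    for state in pd.unique(states):
        mask = states == state
        pos = sampler.sample_positivity(
            state, region["cohort"], dfs_label, config, rng, int(mask.sum())
        )
        pos.index = order[mask]
        frames.append(pos)
    positivity = pd.concat(frames).sort_index()

    cells = pd.DataFrame(
        {
            "cell_id": [f"{region['region_id']}_c{i:05d}" for i in range(n)],
            "region_id": region["region_id"],
            "x_um": x,
            "y_um": y,
        }
    )
    cells = pd.concat([cells, positivity.reset_index(drop=True)], axis=1)
    cells["planted_state"] = states
    return cells


def generate_cohort(
    config: GeneratorConfig, gating: GatingConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Generate (cells, regions, patients, truth) for a full synthetic study.

    Deterministic given ``config.seed``. Treated patients are split into
    planted long/short survival groups (n_long = n // 2) whose DFS months are
    drawn from well-separated log-normals, so the later median split recovers
    the planted grouping exactly.
    """
    gating = gating or load_gating_config()
    sampler = LeafSampler(gating)

    patients = []
    dfs_group: dict[str, str] = {}
    for cohort in (COHORT_NAIVE, COHORT_ACD40):
        n_pat = int(config.n_patients_per_cohort.get(cohort, 0))
        n_long = n_pat // 2
        for i in range(n_pat):
            pid = f"{'N' if cohort == COHORT_NAIVE else 'A'}{i + 1:02d}"
            row = {"patient_id": pid, "cohort": cohort, "dfs_months": np.nan}
            if cohort == COHORT_ACD40:
                group = DFS_LONG if i < n_long else DFS_SHORT
                dfs_group[pid] = group
                mu, sd = config.dfs_lognormal[group]
                row["dfs_months"] = float(
                    np.exp(_patient_rng(config.seed, pid).normal(mu, sd))
                )
            patients.append(row)
    patients = pd.DataFrame(patients).set_index("patient_id", drop=False)

    regions = []
    for pid, prow in patients.iterrows():
        for site, count in config.regions_per_patient.items():
            for k in range(int(count)):
                regions.append(
                    {
                        "region_id": f"{pid}_{site}_{k + 1}",
                        "patient_id": pid,
                        "cohort": prow["cohort"],
                        "site": site,
                        "area_mm2": float(config.area_mm2),
                    }
                )
    regions = pd.DataFrame(regions).set_index("region_id", drop=False)

    fragments = []
    for _, rrow in regions.iterrows():
        rng = _region_rng(config.seed, rrow["patient_id"], rrow["region_id"])
        fragments.append(
            generate_region(
                rrow, config, gating, sampler, rng,
                dfs_label=dfs_group.get(rrow["patient_id"]),
            )
        )
    cells = pd.concat(fragments, ignore_index=True)

    planted_barcode = np.full(len(cells), None, dtype=object)
    t_leaves = set(gating.t_state_leaves)
    is_t = cells["planted_state"].isin(t_leaves).to_numpy()
    bits = cells.loc[:, list(BARCODE_MARKERS)].to_numpy().astype(bool)
    markers = np.array(BARCODE_MARKERS, dtype=object)
    planted_barcode[is_t] = [
        "".join(f"{m}+" for m in markers[row]) or "NEG" for row in bits[is_t]
    ]

    truth = TruthRecord(
        cells=pd.DataFrame(
            {
                "cell_id": cells["cell_id"],
                "planted_state": cells["planted_state"],
                "planted_barcode": planted_barcode,
            }
        ),
        dfs_group=dfs_group,
        effects=config.effect_spec,
    )
    cells = cells.drop(columns=["planted_state"])
    return cells, regions, patients, truth
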
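"""End-to-end orchestration of the three analyses.

``run_treatment_analysis`` trains one elastic-net model per histopathologic
site to classify treated vs untreated regions; ``run_dfs_analysis`` trains
per-site models for long vs short disease-free survival within the treated
cohort (no model for normal-adjacent pancreas, which has too few regions by
design), then runs the recurrent-neighborhood stage on the treated
immune-aggregate regions. Every stage consumes the stage before it:
phenotyping -> features -> models -> interpretation (top features,
group-difference tests, barcode profile clustering, RCN residency).

The full pipeline is a pure function of (input tables, config, seed): two
runs with the same inputs produce identical report bundles.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import pandas as pd

from . import barcodes as bc
from . import features as ft
from . import models as ml
from . import rcn as rcn_mod
from . import stats as st
from .constants import (
    COHORT_ACD40,
    COHORT_NAIVE,
    DFS_SHORT,
    FAMILY_BARCODE,
    FLAG_GRZB,
    FLAG_KI67,
    INTERACTION_RADIUS_UM,
    NEIGHBORHOOD_RADIUS_UM,
    SITE_IA,
    SITE_NAP,
    SITES,
)
from .gating import GatingConfig, assign_barcodes, assign_states, load_gating_config
from .io import validate_dataset


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AnalysisConfig:
    seed: int = 0
    top_k: int = 15
    importance_share_k: int = 30
    interaction_radius_um: float = INTERACTION_RADIUS_UM
    rcn_radius_um: float = NEIGHBORHOOD_RADIUS_UM
    rcn_k_min: int = 2
    rcn_k_max: int = 12
    rcn_restarts: int = 10
    alpha: float = 5e-2
    l1_ratio: float = 0.5
    barcode_cluster_count: int = 4
    bh_alpha: float = 0.05

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Shared stages
# ---------------------------------------------------------------------------

def prepare_dataset(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    gating: GatingConfig | None = None,
    require_dfs: bool = False,
):
    """Validate, phenotype and barcode the dataset."""
    gating = gating or load_gating_config()
    report = validate_dataset(cells, regions, patients, require_dfs=require_dfs)
    if report.errors:
        raise PipelineError("validate", "; ".join(i.message for i in report.errors))
    cells = assign_states(cells, gating)
    cells = assign_barcodes(cells, gating)
    return cells, regions, patients, gating


def _site_model(
    task: str,
    site: str,
    matrix: pd.DataFrame,
    regions: pd.DataFrame,
    labels: pd.Series,
    config: AnalysisConfig,
) -> ml.ModelResult:
    spec = ml.TaskSpec(
        task=task,
        site=site,
        seed=config.seed,
        alpha=config.alpha,
        l1_ratio=config.l1_ratio,
    )
    return ml.run_lopo(spec, matrix, regions, labels)


def _interpret_model(
    result: ml.ModelResult,
    site_matrix: pd.DataFrame,
    site_labels: pd.Series,
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    gating: GatingConfig,
    config: AnalysisConfig,
    negative_class: str,
) -> dict:
    """Top features, their directions, group tests, and barcode clustering."""
    top = result.top_features(config.top_k)
    stats = st.mann_whitney_feature_test(
        site_matrix, site_labels, features=list(top.index)
    )
    adjusted = st.bh_adjust(stats["p"], alpha=config.bh_alpha)
    stats = stats.join(adjusted[["q", "significant"]])

    profiles = []
    for (family, key), row in top.iterrows():
        if family != FAMILY_BARCODE:
            continue
        group = (
            result.spec.positive_class if row["direction"] > 0 else negative_class
        )
        profile = bc.barcode_state_proportions(
            key, result.spec.site, group, cells, regions, patients,
            gating.t_state_leaves,
        )
        if not profile.empty:
            profiles.append(profile)
    barcode_clusters = None
    if len(profiles) >= 2:
        corr = bc.correlate_barcodes(profiles)
        n_clusters = min(config.barcode_cluster_count, len(corr))
        labels_, order = bc.cluster_barcodes(corr, n_clusters)
        barcode_clusters = {
            "correlation": corr,
            "clusters": labels_,
            "leaf_order": order,
        }
    return {
        "metrics": result.metrics,
        "confusion": result.confusion,
        "n_features": len(result.feature_names),
        "top_features": top,
        "top_share": result.top_k_share(config.importance_share_k),
        "stats": stats,
        "barcode_clusters": barcode_clusters,
        "model": result,
    }


# ---------------------------------------------------------------------------
# Analyses
# ---------------------------------------------------------------------------

def run_treatment_analysis(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    matrix: pd.DataFrame,
    gating: GatingConfig,
    config: AnalysisConfig,
) -> dict:
    """Per-site treated-vs-untreated models with interpretation."""
    labels = ml.region_labels("treatment", regions, patients)
    out = {}
    for site in SITES:
        site_ids = regions.index[regions["site"] == site]
        site_ids = [r for r in site_ids if r in matrix.index]
        if not site_ids:
            continue
        site_matrix = matrix.loc[site_ids]
        site_labels = labels.loc[site_ids]
        try:
            result = _site_model(
                "treatment", site, site_matrix, regions, site_labels, config
            )
            out[site] = _interpret_model(
                result, site_matrix, site_labels, cells, regions, patients,
                gating, config, negative_class=COHORT_NAIVE,
            )
        except ml.ModelError as exc:
            raise PipelineError(f"treatment:{site}", str(exc)) from exc
    return out


def run_dfs_analysis(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    matrix: pd.DataFrame,
    gating: GatingConfig,
    config: AnalysisConfig,
) -> dict:
    """Per-site survival models within the treated cohort, plus the
    recurrent-neighborhood stage on treated immune-aggregate regions."""
    patients = ml.derive_dfs_labels(patients)
    labels = ml.region_labels("dfs", regions, patients)
    treated_ids = regions.index[regions["cohort"] == COHORT_ACD40]
    out: dict = {"sites": {}, "rcn": None}
    for site in SITES:
        if site == SITE_NAP:
            continue  # too few normal-adjacent regions by design
        site_ids = [
            r for r in treated_ids
            if regions.loc[r, "site"] == site and r in matrix.index
        ]
        if not site_ids:
            continue
        site_matrix = matrix.loc[site_ids]
        site_labels = labels.reindex(site_ids)
        try:
            result = _site_model("dfs", site, site_matrix, regions, site_labels, config)
            out["sites"][site] = _interpret_model(
                result, site_matrix, site_labels, cells, regions, patients,
                gating, config, negative_class=DFS_SHORT,
            )
        except ml.ModelError as exc:
            raise PipelineError(f"dfs:{site}", str(exc)) from exc

    if SITE_IA in out["sites"]:
        out["rcn"] = _rcn_stage(
            cells, regions, patients, gating, config,
            out["sites"][SITE_IA]["top_features"],
            out["sites"][SITE_IA]["model"].spec.positive_class,
        )
    return out


def _rcn_stage(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    gating: GatingConfig,
    config: AnalysisConfig,
    ia_top_features: pd.DataFrame,
    positive_class: str,
) -> dict:
    """Neighborhood compositions and RCN clustering over treated IA regions,
    residency of the survival model's top barcodes, functional fractions."""
    ia_ids = regions.index[
        (regions["site"] == SITE_IA) & (regions["cohort"] == COHORT_ACD40)
    ]
    taxonomy = gating.leaves
    comp_frames = []
    for rid in ia_ids:
        sub = cells[cells["region_id"] == rid]
        if len(sub):
            comp_frames.append(
                rcn_mod.neighborhood_composition(
                    sub, taxonomy, radius_um=config.rcn_radius_um
                )
            )
    if not comp_frames:
        raise PipelineError("rcn", "no treated immune-aggregate cells found")
    compositions = pd.concat(comp_frames)
    model = rcn_mod.fit_rcn(
        compositions,
        taxonomy,
        k_range=range(config.rcn_k_min, config.rcn_k_max + 1),
        seed=config.seed,
        n_restarts=config.rcn_restarts,
        radius_um=config.rcn_radius_um,
    )
    summaries = rcn_mod.rcn_summaries(model, cells, regions)

    top_barcodes = [
        (key, positive_class if row["direction"] > 0 else DFS_SHORT)
        for (family, key), row in ia_top_features.iterrows()
        if family == FAMILY_BARCODE
    ]
    residency = None
    if top_barcodes:
        residency = rcn_mod.barcode_rcn_residency(
            top_barcodes, cells, regions, patients, model
        )
    functional = {
        FLAG_KI67: rcn_mod.functional_fraction_by_rcn(
            cells, model, FLAG_KI67, gating.t_state_leaves,
            gating.treg_state_leaves, exclude_treg=False,
        ),
        FLAG_GRZB: rcn_mod.functional_fraction_by_rcn(
            cells, model, FLAG_GRZB, gating.t_state_leaves,
            gating.treg_state_leaves, exclude_treg=True,
        ),
    }
    return {
        "model": model,
        "k": model.k,
        "summaries": summaries,
        "residency": residency,
        "functional": functional,
        "top_barcodes": top_barcodes,
    }


# ---------------------------------------------------------------------------
# Full run + serializable bundle
# ---------------------------------------------------------------------------

def run_full(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    config: AnalysisConfig | None = None,
    gating: GatingConfig | None = None,
    tasks: tuple[str, ...] = ("treatment", "dfs"),
) -> dict:
    """Run the requested analyses end-to-end on raw input tables."""
    config = config or AnalysisConfig()
    require_dfs = "dfs" in tasks
    cells, regions, patients, gating = prepare_dataset(
        cells, regions, patients, gating, require_dfs=require_dfs
    )
    matrix = ft.compute_features(
        cells, regions, gating.leaves, radius_um=config.interaction_radius_um
    )
    bundle: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "n_cells": int(len(cells)),
        "n_regions": int(len(regions)),
        "n_features": int(matrix.shape[1]),
        "matrix": matrix,
    }
    if "treatment" in tasks:
        bundle["treatment"] = run_treatment_analysis(
            cells, regions, patients, matrix, gating, config
        )
    if "dfs" in tasks:
        bundle["dfs"] = run_dfs_analysis(
            cells, regions, patients, matrix, gating, config
        )
    return bundle


def bundle_report(bundle: dict) -> dict:
    """JSON-serializable summary of a report bundle (used for file output
    and for whole-pipeline determinism checks)."""

    def site_block(block: dict) -> dict:
        top = block["top_features"]
        return {
            "metrics": {k: round(float(v), 10) for k, v in block["metrics"].items()},
            "confusion": block["confusion"],
            "n_features": block["n_features"],
            "top_share": round(float(block["top_share"]), 10),
            "top_features": [
                {
                    "family": fam,
                    "key": key,
                    "importance": round(float(r["importance"]), 10),
                    "direction": int(r["direction"]),
                }
                for (fam, key), r in top.iterrows()
            ],
            "significant": int(block["stats"]["significant"].sum()),
            "barcode_cluster_sizes": (
                sorted(
                    block["barcode_clusters"]["clusters"].value_counts().tolist()
                )
                if block["barcode_clusters"]
                else None
            ),
        }

    out: dict = {
        "config_hash": bundle["config_hash"],
        "n_cells": bundle["n_cells"],
        "n_regions": bundle["n_regions"],
        "n_features": bundle["n_features"],
    }
    if "treatment" in bundle:
        out["treatment"] = {
            site: site_block(b) for site, b in bundle["treatment"].items()
        }
    if "dfs" in bundle:
        out["dfs"] = {
            site: site_block(b) for site, b in bundle["dfs"]["sites"].items()
        }
        rcn_block = bundle["dfs"]["rcn"]
        if rcn_block is not None:
            res = rcn_block["residency"]
            out["rcn"] = {
                "k": rcn_block["k"],
                "assignments_head": rcn_block["model"]
                .assignments.head(20)
                .tolist(),
                "mean_composition": rcn_block["summaries"]["mean_composition"]
                .round(10)
                .to_dict(),
                "residency_clusters": (
                    {f"{g}:{b}": int(c) for (g, b), c in res["clusters"].items()}
                    if res
                    else None
                ),
                "functional": {
                    flag: frame.round(10).fillna(-1).to_dict()
                    for flag, frame in rcn_block["functional"].items()
                },
            }
    return out


def write_bundle(bundle: dict, out_dir) -> None:
    """Write the report bundle as CSV/JSON files under *out_dir*."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    from .io import write_feature_matrix

    write_feature_matrix(bundle["matrix"], os.path.join(out_dir, "features.csv"))
    with open(os.path.join(out_dir, "report.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle_report(bundle), fh, indent=2, sort_keys=True)
    for task in ("treatment", "dfs"):
        if task not in bundle:
            continue
        blocks = bundle[task] if task == "treatment" else bundle[task]["sites"]
        for site, block in blocks.items():
            prefix = os.path.join(out_dir, f"{task}_{site}")
            block["top_features"].to_csv(prefix + "_importance.csv")
            block["stats"].to_csv(prefix + "_pq.csv")
            block["model"].pooled.to_csv(prefix + "_predictions.csv", index=False)
    if "dfs" in bundle and bundle["dfs"]["rcn"] is not None:
        rcn_block = bundle["dfs"]["rcn"]
        rcn_dir = os.path.join(out_dir, "rcn")
        os.makedirs(rcn_dir, exist_ok=True)
        rcn_block["model"].assignments.rename("rcn").to_csv(
            os.path.join(rcn_dir, "assignments.csv"), index_label="cell_id"
        )
        rcn_block["model"].centroids.to_csv(
            os.path.join(rcn_dir, "centroids.csv"), index_label="rcn"
        )
        if rcn_block["residency"]:
            rcn_block["residency"]["residency"].to_csv(
                os.path.join(rcn_dir, "residency.csv")
            )
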
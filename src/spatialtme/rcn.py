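"""Recurrent cellular neighborhood (RCN) analysis.

Every cell seeds a neighborhood: all cells (seed included) whose centroids
lie within a 60 μm radius, summarized as the vector of taxonomy-state
proportions. Neighborhood vectors pooled across the regions of interest are
grouped by K-means; the number of clusters is picked by the elbow of the
inertia curve (maximum perpendicular distance to the chord joining its
endpoints). Each resulting cluster — an RCN — is a recurring spatial motif
of cellular composition.

Downstream summaries follow the study design: per-RCN mean compositions,
per-region RCN proportions, residency profiles of predictive barcoded
T cells over RCNs (log10+1 transformed, Ward-clustered into two groups),
and per-RCN fractions of proliferating (Ki-67+) or cytotoxic (GrzB+)
T cells against the overall baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from sklearn.cluster import KMeans

from .constants import NEIGHBORHOOD_RADIUS_UM

logger = logging.getLogger(__name__)


def neighborhood_composition(
    cells: pd.DataFrame,
    taxonomy: list[str],
    radius_um: float = NEIGHBORHOOD_RADIUS_UM,
    include_seed: bool = True,
) -> pd.DataFrame:
    """Per-seed state-proportion vectors for the cells of one region.

    Returns a frame indexed by ``cell_id`` with one column per taxonomy
    leaf plus ``n_neighbors`` (the seed itself counts by default, so the
    count is at least 1 and proportions always sum to 1).
    """
    n = len(cells)
    if n == 0:
        return pd.DataFrame(columns=list(taxonomy) + ["n_neighbors"])
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    state_idx = pd.Categorical(
        cells["state"], categories=taxonomy
    ).codes.astype(int)
    if (state_idx < 0).any():
        raise ValueError("cells carry states outside the taxonomy")
    tree = cKDTree(xy)
    neighbor_lists = tree.query_ball_point(xy, r=float(radius_um))
    comp = np.zeros((n, len(taxonomy)))
    counts = np.zeros(n, dtype=int)
    for i, neigh in enumerate(neighbor_lists):
        members = [j for j in neigh if include_seed or j != i]
        counts[i] = len(members)
        if members:
            np.add.at(comp[i], state_idx[members], 1)
            comp[i] /= counts[i]
    out = pd.DataFrame(comp, index=cells["cell_id"].to_numpy(), columns=taxonomy)
    out["n_neighbors"] = counts
    return out


def elbow_k(inertias: pd.Series) -> int:
    """Elbow of a non-increasing inertia curve over candidate K.

    Both axes are normalized to [0, 1]; the chosen K maximizes the
    perpendicular distance to the chord joining the first and last points.
    Ties (including a perfectly linear decay) break toward the smallest K.
    """
    ks = np.asarray(inertias.index, dtype=float)
    ys = inertias.to_numpy(float)
    if len(ks) < 3:
        raise ValueError("need at least 3 candidate K values for the elbow")
    if np.any(np.diff(ys) > 1e-9 * max(1.0, abs(ys[0]))):
        raise ValueError("inertia curve is not non-increasing")
    x = (ks - ks[0]) / (ks[-1] - ks[0])
    span = ys[0] - ys[-1]
    y = (ys - ys[-1]) / span if span > 0 else np.zeros_like(ys)
    # distance from (x, y) to the chord through (0, 1) and (1, 0)
    dist = np.abs(x + y - 1.0) / np.sqrt(2.0)
    return int(ks[int(np.argmax(dist))])


@dataclass
class RCNModel:
    radius_um: float
    k: int
    centroids: pd.DataFrame  # K x taxonomy
    assignments: pd.Series  # cell_id -> RCN index (1-based)
    inertia_curve: pd.Series  # candidate K -> best inertia
    compositions: pd.DataFrame


def fit_rcn(
    compositions: pd.DataFrame,
    taxonomy: list[str],
    k_range: range = range(2, 13),
    seed: int = 0,
    n_restarts: int = 10,
    radius_um: float = NEIGHBORHOOD_RADIUS_UM,
) -> RCNModel:
    """K-means over neighborhood compositions with elbow-selected K.

    RCN indices are relabelled by descending member count (RCN1 is the
    largest), so labels are stable across runs. Degenerate input (all
    compositions identical) falls back to a single cluster with a warning.
    """
    X = compositions[list(taxonomy)].to_numpy(float)
    if len(X) < max(k_range):
        raise ValueError(
            f"need at least {max(k_range)} compositions, got {len(X)}"
        )
    if np.allclose(X, X[0], atol=1e-12):
        logger.warning("all compositions identical; falling back to K=1")
        assignments = pd.Series(1, index=compositions.index)
        centroids = pd.DataFrame([X[0]], index=[1], columns=taxonomy)
        return RCNModel(
            radius_um, 1, centroids, assignments,
            pd.Series(dtype=float), compositions,
        )

    fits = {}
    inertias = {}
    # K=1 needs no clustering (inertia is the total sum of squares); it
    # anchors the elbow curve so a genuine two-cluster structure is
    # selectable (the chord construction can never pick an endpoint).
    inertias[1] = float(((X - X.mean(axis=0)) ** 2).sum())
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        km.fit(X)
        fits[k] = km
        inertias[k] = float(km.inertia_)
    curve = pd.Series(inertias).sort_index()
    # best-of-restarts inertia should be non-increasing in K; re-run
    # offending fits with more restarts if sampling noise violated it
    for _ in range(3):
        bad = np.flatnonzero(np.diff(curve.to_numpy()) > 0)
        if bad.size == 0:
            break
        for idx in bad:
            k = int(curve.index[idx + 1])
            if k not in fits:
                continue
            km = KMeans(n_clusters=k, n_init=n_restarts * 5, random_state=seed + 1)
            km.fit(X)
            if km.inertia_ < fits[k].inertia_:
                fits[k] = km
                curve.loc[k] = float(km.inertia_)
    k_star = elbow_k(curve)
    if k_star not in fits:  # degenerate flat curve ties to the K=1 anchor
        k_star = min(fits)
    best = fits[k_star]

    raw = best.labels_
    order = pd.Series(raw).value_counts().index.to_numpy()
    relabel = {old: new + 1 for new, old in enumerate(order)}
    assignments = pd.Series(
        [relabel[r] for r in raw], index=compositions.index
    )
    centroids = pd.DataFrame(
        best.cluster_centers_[order], index=range(1, k_star + 1), columns=taxonomy
    )
    return RCNModel(radius_um, k_star, centroids, assignments, curve, compositions)


def rcn_summaries(
    model: RCNModel, cells: pd.DataFrame, regions: pd.DataFrame
) -> dict:
    """Mean member composition per RCN, per-region RCN proportions, and
    region/patient exclusivity flags (an RCN recurring in >= 2 regions and
    >= 2 patients is not an artifact of a single tissue)."""
    taxonomy = [c for c in model.compositions.columns if c != "n_neighbors"]
    members = model.compositions.loc[:, taxonomy]
    mean_composition = members.groupby(model.assignments).mean()
    mean_composition.index.name = "rcn"

    assigned = cells.set_index("cell_id").loc[model.assignments.index]
    table = pd.DataFrame(
        {"region_id": assigned["region_id"].to_numpy(), "rcn": model.assignments.to_numpy()}
    )
    per_region = (
        table.groupby(["region_id", "rcn"]).size().unstack(fill_value=0)
    )
    per_region = per_region.div(per_region.sum(axis=1), axis=0)

    patient_of = regions["patient_id"]
    table["patient_id"] = table["region_id"].map(patient_of)
    recurrence = table.groupby("rcn").agg(
        n_regions=("region_id", "nunique"), n_patients=("patient_id", "nunique")
    )
    recurrence["recurrent"] = (recurrence["n_regions"] >= 2) & (
        recurrence["n_patients"] >= 2
    )
    return {
        "mean_composition": mean_composition,
        "region_proportions": per_region,
        "recurrence": recurrence,
    }


def barcode_rcn_residency(
    top_barcodes: list[tuple[str, str]],  # (barcode, DFS group)
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    model: RCNModel,
    n_clusters: int = 2,
) -> dict:
    """Residency of predictive barcoded T cells over RCNs, clustered in two.

    Each row is one (barcode, survival-group) entry: among T cells carrying
    that barcode in modelled regions from patients of that group, the
    proportion assigned to each RCN (row sums to 1). Rows are log10+1
    transformed and Ward-clustered (Euclidean) into *n_clusters* groups;
    the per-cluster mean RCN-fraction profile is reported.
    """
    rcn_of = model.assignments
    labels = patients["dfs_label"]
    rows = {}
    for barcode, group in top_barcodes:
        group_regions = set(
            regions.index[regions["patient_id"].map(labels) == group]
        )
        sub = cells[
            cells["barcode"].eq(barcode)
            & cells["region_id"].isin(group_regions)
            & cells["cell_id"].isin(rcn_of.index)
        ]
        if sub.empty:
            logger.warning(
                "barcode %r (%s) has no cells in scope; row dropped", barcode, group
            )
            continue
        counts = rcn_of.loc[sub["cell_id"]].value_counts()
        counts = counts.reindex(model.centroids.index).fillna(0.0)
        rows[(group, barcode)] = counts / counts.sum()
    if not rows:
        raise ValueError("no barcode has expressing cells in scope")
    residency = pd.DataFrame(rows).T
    residency.index.names = ["group", "barcode"]
    residency.columns = [f"RCN{k}" for k in residency.columns]

    transformed = np.log10(residency + 1.0)
    if len(residency) == 1:
        clusters = pd.Series([1], index=residency.index)
    else:
        Z = linkage(transformed.to_numpy(), method="ward", metric="euclidean")
        clusters = pd.Series(
            fcluster(Z, t=min(n_clusters, len(residency)), criterion="maxclust"),
            index=residency.index,
        )
    cluster_profiles = residency.groupby(clusters).mean()
    cluster_profiles.index.name = "cluster"
    return {
        "residency": residency,
        "clusters": clusters,
        "cluster_profiles": cluster_profiles,
    }


def functional_fraction_by_rcn(
    cells: pd.DataFrame,
    model: RCNModel,
    flag_marker: str,
    t_states: list[str],
    treg_states: list[str],
    exclude_treg: bool = False,
) -> pd.DataFrame:
    """Fraction of flag-positive T cells per RCN, with the overall baseline.

    ``exclude_treg`` drops regulatory T states from both numerator and
    denominator (used for the cytotoxicity flag, which T regulatory cells
    are not expected to express). RCNs with zero in-scope T cells report a
    missing fraction with count 0; raw counts accompany every fraction.
    """
    if flag_marker not in cells.columns:
        raise ValueError(f"flag marker {flag_marker!r} not in cell table")
    scope_states = [s for s in t_states if not (exclude_treg and s in treg_states)]
    sub = cells[
        cells["state"].isin(scope_states) & cells["cell_id"].isin(model.assignments.index)
    ]
    rcn = model.assignments.loc[sub["cell_id"]].to_numpy()
    flag = sub[flag_marker].to_numpy().astype(bool)
    out = []
    for k in model.centroids.index:
        in_k = rcn == k
        n_t = int(in_k.sum())
        n_pos = int(flag[in_k].sum())
        out.append(
            {
                "rcn": int(k),
                "n_t_cells": n_t,
                "n_positive": n_pos,
                "fraction": n_pos / n_t if n_t else np.nan,
            }
        )
    frame = pd.DataFrame(out).set_index("rcn")
    baseline = float(flag.sum() / len(flag)) if len(flag) else np.nan
    frame.attrs["baseline"] = baseline
    frame.attrs["baseline_n"] = int(len(flag))
    return frame
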
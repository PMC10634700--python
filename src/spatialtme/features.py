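"""Region-level tumor-microenvironment features.

Three feature families are computed per tissue region and assembled into one
region x feature matrix:

* ``density`` — cells of each taxonomy state per mm² of tissue;
* ``barcode_density`` — T cells carrying each functionality barcode per mm²;
* ``interaction`` — counts of unordered cell pairs whose centroids lie
  within 20 μm of each other, binned by the unordered state pair and
  normalized by the summed densities of the states involved (a same-state
  pair divides by that single state's density once).

Interactions are computed within a region only; regions are independent
tissue frames, so coordinates never compare across regions. The distance
rule is inclusive (≤ radius) and evaluated on squared distances so the
boundary never suffers square-root rounding.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    FAMILY_BARCODE,
    FAMILY_DENSITY,
    FAMILY_INTERACTION,
    INTERACTION_RADIUS_UM,
)


def compute_state_densities(
    cells: pd.DataFrame, region: pd.Series, taxonomy: list[str]
) -> pd.Series:
    """Cells/mm² for every taxonomy leaf (absent states are 0)."""
    area = float(region["area_mm2"])
    if area <= 0:
        raise ValueError(f"region {region['region_id']!r} has non-positive area")
    counts = cells["state"].value_counts()
    return counts.reindex(taxonomy).fillna(0.0).astype(float) / area


def compute_barcode_densities(cells: pd.DataFrame, region: pd.Series) -> pd.Series:
    """T cells/mm² per observed barcode; non-T cells are ignored."""
    area = float(region["area_mm2"])
    if area <= 0:
        raise ValueError(f"region {region['region_id']!r} has non-positive area")
    barcodes = cells["barcode"].dropna()
    if barcodes.empty:
        return pd.Series(dtype=float)
    return barcodes.value_counts().astype(float) / area


def find_interactions_bruteforce(
    cells: pd.DataFrame, radius_um: float = INTERACTION_RADIUS_UM
) -> dict[tuple[str, str], int]:
    """O(n²) reference pair scan (squared-distance comparison, inclusive)."""
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    states = cells["state"].to_numpy()
    r2 = float(radius_um) ** 2
    counts: dict[tuple[str, str], int] = {}
    n = len(cells)
    for i in range(n):
        d2 = (xy[i + 1 :, 0] - xy[i, 0]) ** 2 + (xy[i + 1 :, 1] - xy[i, 1]) ** 2
        for j in np.flatnonzero(d2 <= r2):
            key = tuple(sorted((states[i], states[i + 1 + j])))
            counts[key] = counts.get(key, 0) + 1
    return counts


def find_interactions(
    cells: pd.DataFrame, radius_um: float = INTERACTION_RADIUS_UM
) -> dict[tuple[str, str], int]:
    """Count qualifying unordered cell pairs per unordered state pair.

    A pair qualifies when the Euclidean centroid distance is ≤ *radius_um*;
    each unordered cell pair is counted once and a cell never pairs with
    itself. Accelerated with a k-d tree; exact-equal to the brute force scan.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be positive")
    if len(cells) < 2:
        return {}
    xy = cells[["x_um", "y_um"]].to_numpy(float)
    states = cells["state"].to_numpy()
    pairs = cKDTree(xy).query_pairs(r=float(radius_um), output_type="ndarray")
    counts: dict[tuple[str, str], int] = {}
    for i, j in pairs:
        key = tuple(sorted((states[i], states[j])))
        counts[key] = counts.get(key, 0) + 1
    return counts


def normalize_interactions(
    counts: dict[tuple[str, str], int], densities: pd.Series
) -> dict[tuple[str, str], float]:
    """Divide each pair count by the summed densities of the distinct states
    involved: count{A,B}/(d_A + d_B) for A != B, count{A,A}/d_A."""
    out: dict[tuple[str, str], float] = {}
    for (a, b), count in counts.items():
        denom = float(densities[a]) if a == b else float(densities[a]) + float(densities[b])
        if denom <= 0:
            if count > 0:
                raise ValueError(
                    f"pair {(a, b)} has count {count} but zero summed density"
                )
            out[(a, b)] = 0.0
        else:
            out[(a, b)] = count / denom
    return out


def pair_key(a: str, b: str) -> str:
    """Canonical string key for an unordered state pair."""
    a, b = sorted((a, b))
    return f"{a}|{b}"


def assemble_feature_matrix(
    densities: dict[str, pd.Series],
    barcode_densities: dict[str, pd.Series],
    interactions: dict[str, dict[tuple[str, str], float]],
    taxonomy: list[str],
    barcode_inventory: list[str] | None = None,
    pair_inventory: list[str] | None = None,
) -> pd.DataFrame:
    """Assemble the region x feature matrix with deterministic column order.

    Columns are a 2-level (family, key) index: one density per taxonomy
    leaf, then one column per barcode observed anywhere in the dataset
    (lexicographic), then one per interaction pair observed anywhere
    (lexicographic). Entries unobserved in a region are 0, not missing.
    Explicit inventories may be supplied to pin the column namespace.
    """
    region_ids = list(densities)
    if set(barcode_densities) != set(region_ids) or set(interactions) != set(region_ids):
        raise ValueError("feature families cover different region sets")
    region_ids = sorted(region_ids)

    if barcode_inventory is None:
        observed: set[str] = set()
        for s in barcode_densities.values():
            observed |= set(s.index)
        barcode_inventory = sorted(observed)
    else:
        barcode_inventory = sorted(barcode_inventory)
    if pair_inventory is None:
        pairs: set[str] = set()
        for d in interactions.values():
            pairs |= {pair_key(a, b) for a, b in d}
        pair_inventory = sorted(pairs)
    else:
        pair_inventory = sorted(pair_inventory)

    columns = pd.MultiIndex.from_tuples(
        [(FAMILY_DENSITY, s) for s in taxonomy]
        + [(FAMILY_BARCODE, b) for b in barcode_inventory]
        + [(FAMILY_INTERACTION, p) for p in pair_inventory],
        names=["family", "key"],
    )
    expected = len(taxonomy) + len(barcode_inventory) + len(pair_inventory)
    assert len(columns) == expected, "feature namespace identity violated"

    rows = np.zeros((len(region_ids), expected))
    n_dens, n_bar = len(taxonomy), len(barcode_inventory)
    for i, rid in enumerate(region_ids):
        rows[i, :n_dens] = densities[rid].reindex(taxonomy).fillna(0.0).to_numpy()
        rows[i, n_dens : n_dens + n_bar] = (
            barcode_densities[rid].reindex(barcode_inventory).fillna(0.0).to_numpy()
        )
        inter = pd.Series(
            {pair_key(a, b): v for (a, b), v in interactions[rid].items()},
            dtype=float,
        )
        rows[i, n_dens + n_bar :] = inter.reindex(pair_inventory).fillna(0.0).to_numpy()
    matrix = pd.DataFrame(
        rows, index=pd.Index(region_ids, name="region_id"), columns=columns
    )
    if (matrix.to_numpy() < 0).any():
        raise ValueError("feature matrix contains negative entries")
    return matrix


def compute_features(
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    taxonomy: list[str],
    radius_um: float = INTERACTION_RADIUS_UM,
) -> pd.DataFrame:
    """End-to-end feature computation for all regions of a dataset."""
    densities: dict[str, pd.Series] = {}
    barcode_densities: dict[str, pd.Series] = {}
    interactions: dict[str, dict] = {}
    grouped = dict(tuple(cells.groupby("region_id", sort=False)))
    for rid, region in regions.iterrows():
        sub = grouped.get(rid, cells.iloc[0:0])
        dens = compute_state_densities(sub, region, taxonomy)
        densities[rid] = dens
        barcode_densities[rid] = compute_barcode_densities(sub, region)
        counts = find_interactions(sub, radius_um=radius_um)
        interactions[rid] = normalize_interactions(counts, dens)
    return assemble_feature_matrix(
        densities, barcode_densities, interactions, taxonomy
    )


def top_barcodes_by_density(
    matrix: pd.DataFrame, region_ids: list[str], k: int = 15
) -> list[str]:
    """Barcodes ranked by mean density over a region group, descending.

    Ties break lexicographically by barcode name; returns min(k, observed).
    """
    if not region_ids:
        raise ValueError("empty region group")
    block = matrix.loc[list(region_ids), (FAMILY_BARCODE, slice(None))]
    means = block.mean(axis=0)
    means.index = [key for _, key in means.index]
    means = means[means > 0]
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]
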
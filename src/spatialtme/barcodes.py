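"""Which T cell states express each predictive barcode, and how barcodes
group by the similarity of their expressing-state profiles.

For a barcode that a model found predictive of a group (a treatment cohort
or a survival group), only T cells carrying that barcode inside regions of
the model's histopathologic site *and* of that group are counted. The
resulting per-barcode proportion vectors over the 18 T states are compared
by Pearson correlation and grouped by agglomerative clustering on the
1 - r distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import squareform

from .constants import COHORTS, DFS_GROUPS

logger = logging.getLogger(__name__)


@dataclass
class BarcodeStateProfile:
    barcode: str
    site: str
    group: str  # cohort or DFS group the barcode was predictive of
    proportions: pd.Series  # over the T-state leaves, sums to 1
    n_cells: int

    @property
    def empty(self) -> bool:
        return self.n_cells == 0


def barcode_state_proportions(
    barcode: str,
    site: str,
    group: str,
    cells: pd.DataFrame,
    regions: pd.DataFrame,
    patients: pd.DataFrame,
    t_states: list[str],
) -> BarcodeStateProfile:
    """Proportions of T states among cells expressing *barcode* in scope."""
    if group in COHORTS:
        in_group = regions["cohort"] == group
    elif group in DFS_GROUPS:
        labels = patients["dfs_label"]
        in_group = regions["patient_id"].map(labels) == group
    else:
        raise ValueError(f"unknown group {group!r}")
    scope_regions = set(regions.index[(regions["site"] == site) & in_group])
    sub = cells[
        cells["region_id"].isin(scope_regions) & (cells["barcode"] == barcode)
    ]
    counts = sub["state"].value_counts().reindex(t_states).fillna(0.0)
    total = float(counts.sum())
    if total == 0:
        return BarcodeStateProfile(barcode, site, group, counts, 0)
    return BarcodeStateProfile(barcode, site, group, counts / total, int(total))


def correlate_barcodes(profiles: list[BarcodeStateProfile]) -> pd.DataFrame:
    """Pearson correlation matrix of non-empty profiles (unit diagonal).

    A zero-variance proportion vector has no defined correlation; its
    off-diagonal entries are set to 0 with a warning.
    """
    keep = [p for p in profiles if not p.empty]
    if len(keep) < 2:
        raise ValueError("need at least 2 non-empty profiles to correlate")
    names = [f"{p.group}:{p.barcode}" for p in keep]
    data = np.vstack([p.proportions.to_numpy(float) for p in keep])
    sd = data.std(axis=1)
    corr = np.zeros((len(keep), len(keep)))
    ok = sd > 0
    if not ok.all():
        logger.warning(
            "%d zero-variance profiles: correlations set to 0", int((~ok).sum())
        )
    if ok.any():
        sub = np.corrcoef(data[ok])
        corr[np.ix_(ok, ok)] = sub
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=names, columns=names)


def cluster_barcodes(
    correlation: pd.DataFrame, n_clusters: int, method: str = "average"
) -> tuple[pd.Series, list[str]]:
    """Agglomerative clustering on 1 - r; returns labels and leaf order."""
    n = len(correlation)
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} profiles")
    if n == 1:
        return pd.Series([1], index=correlation.index), list(correlation.index)
    dist = 1.0 - correlation.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    Z = linkage(squareform(dist, checks=False), method=method)
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    order = [correlation.index[i] for i in leaves_list(Z)]
    return pd.Series(labels, index=correlation.index), order
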
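"""Group-difference testing of TME features with FDR control.

Two-sided Mann–Whitney U tests compare top features between two region
groups (treatment cohorts or survival groups); Benjamini–Hochberg step-up
correction is applied per analysis family and features with adjusted
p < 0.05 are flagged. Tests run on raw feature values: both the log10+1
and min-max transforms used elsewhere are strictly monotone, and a rank
test is invariant under them, so the choice of scale is immaterial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

#: Combined sample size at or below which the exact null is used (no ties).
_EXACT_N = 20


def mann_whitney_feature_test(
    matrix: pd.DataFrame,
    group_labels: pd.Series,
    features: list | None = None,
) -> pd.DataFrame:
    """Two-sided Mann–Whitney U per feature between the two label groups.

    The exact null distribution is used for combined n <= 20 without ties;
    otherwise the normal approximation with tie correction (and continuity
    correction) applies. Returns U, p, and per-group medians.
    """
    labels = group_labels.reindex(matrix.index).dropna()
    groups = pd.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    a_ids = labels.index[labels == groups[0]]
    b_ids = labels.index[labels == groups[1]]
    if len(a_ids) == 0 or len(b_ids) == 0:
        raise ValueError("both groups must be non-empty")
    cols = list(features) if features is not None else list(matrix.columns)
    rows = []
    for col in cols:
        if col not in matrix.columns:
            raise KeyError(f"feature {col!r} not in matrix")
        x = matrix.loc[a_ids, col].to_numpy(float)
        y = matrix.loc[b_ids, col].to_numpy(float)
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) + len(y) <= _EXACT_N and not has_ties) else "asymptotic"
        res = mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "feature": col,
                "U": float(res.statistic),
                "p": float(res.pvalue),
                f"median_{groups[0]}": float(np.median(x)),
                f"median_{groups[1]}": float(np.median(y)),
            }
        )
    return pd.DataFrame(rows).set_index("feature")


def bh_adjust(pvalues: pd.Series | np.ndarray, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini–Hochberg step-up q-values and significance flags.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1; a feature is
    flagged when q < alpha. Applied per analysis family (one model's
    top-feature set at a time).
    """
    p = np.asarray(pd.Series(pvalues), dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    index = pvalues.index if isinstance(pvalues, pd.Series) else None
    return pd.DataFrame(
        {"p": p, "q": q, "significant": q < alpha}, index=index
    )
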
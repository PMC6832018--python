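"""Differential abundance testing and category enrichment.

Per-feature two-sided Wilcoxon rank-sum tests between two sample groups
with Benjamini-Hochberg FDR control across all tested features, and
upper-tail hypergeometric enrichment of functional categories in a
selected feature set. The rank-sum test uses the exact null distribution
when both groups have at most 10 samples and the feature has no tied
values, and the normal approximation with continuity correction and
midrank ties otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

EXACT_MAX_GROUP = 10  # exact rank-sum null up to this per-group size


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _ranksum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p and U statistic with the exact/approximate
    switch described in the module docstring."""
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_MAX_GROUP and len(y) <= EXACT_MAX_GROUP and not ties:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_differential(
    matrix: pd.DataFrame,
    labels,
    fdr_threshold: float = 0.1,
    min_prevalence: int = 2,
) -> pd.DataFrame:
    """Two-group differential abundance over the rows of a feature matrix.

    Features nonzero in fewer than ``min_prevalence`` samples are excluded
    from testing (their p and q are NaN); constant features get p = 1 by
    convention and are flagged. Returns a frame with group means, the
    rank-sum statistic, p, BH q, the enriched group (sign of the mean
    difference) and a significance flag at ``fdr_threshold``.
    """
    labels = pd.Series(labels, index=matrix.columns) if not isinstance(labels, pd.Series) else labels
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError("differential testing requires exactly two groups")
    g1, g2 = groups
    cols1 = labels.index[labels == g1]
    cols2 = labels.index[labels == g2]
    if len(cols1) < 3 or len(cols2) < 3:
        raise ValueError("each group needs at least 3 samples")

    x1 = matrix[cols1].to_numpy(dtype=float)
    x2 = matrix[cols2].to_numpy(dtype=float)
    prevalence = (matrix.to_numpy() != 0).sum(axis=1)
    tested = prevalence >= min_prevalence

    rows = []
    for i, feature in enumerate(matrix.index):
        mean1, mean2 = x1[i].mean(), x2[i].mean()
        constant = len(np.unique(np.concatenate([x1[i], x2[i]]))) == 1
        if not tested[i]:
            stat, p = np.nan, np.nan
        elif constant:
            stat, p = np.nan, 1.0
        else:
            stat, p = _ranksum_p(x1[i], x2[i])
        enriched = g1 if mean1 > mean2 else (g2 if mean2 > mean1 else "none")
        rows.append((feature, mean1, mean2, stat, p, enriched, constant))
    result = pd.DataFrame(
        rows,
        columns=["feature_id", f"mean_{g1}", f"mean_{g2}", "statistic", "p", "enriched_group", "constant"],
    ).set_index("feature_id")
    result["q"] = np.nan
    mask = result["p"].notna()
    if mask.any():
        result.loc[mask, "q"] = bh_adjust(result.loc[mask, "p"].to_numpy())
    result["significant"] = result["q"] < fdr_threshold
    return result


def hypergeometric_enrichment(
    selected: set,
    categories: dict,
    universe: set,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric category enrichment with BH control.

    ``categories`` maps feature -> category or iterable of categories.
    For each category with members in the universe, the p-value is
    P(X >= overlap) for X ~ Hypergeom(|universe|, |category|, |selected|).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected)
    if not selected <= universe:
        raise ValueError("selected features must be a subset of the universe")

    members: dict[str, set] = {}
    for feature, cats in categories.items():
        if feature not in universe:
            continue
        for cat in ([cats] if isinstance(cats, str) else cats):
            members.setdefault(cat, set()).add(feature)

    rows = []
    for cat in sorted(members):
        cat_set = members[cat]
        overlap = len(cat_set & selected)
        p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(cat_set), len(selected)))
        rows.append((cat, len(universe), len(cat_set), len(selected), overlap, min(p, 1.0)))
    result = pd.DataFrame(
        rows,
        columns=["category", "universe_size", "category_size", "selected_size", "overlap", "p"],
    ).set_index("category")
    if len(result):
        result["q"] = bh_adjust(result["p"].to_numpy())
        result["significant"] = result["q"] < fdr_threshold
    return result
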
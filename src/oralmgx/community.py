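"""Community-level diversity, ordination and permutation tests.

Alpha diversity (richness, Shannon with natural log, Gini-Simpson),
Bray-Curtis dissimilarity, principal-coordinate analysis, and the three
distance-based permutation tests used to compare group community
structure: MRPP (group-size-weighted mean within-group distance), ANOSIM
(rank-based R) and Adonis/PERMANOVA (distance-based pseudo-F, which also
handles continuous phenotypes via the hat-matrix formulation).

Permutation p-values use the add-one rule p = (1 + b) / (1 + m), where b
counts permuted statistics at least as extreme as the observed one, so
the smallest attainable p is 1/(m+1) and p can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


# ---------------------------------------------------------------- diversity

def alpha_diversity(column) -> dict:
    """Richness, Shannon (natural log) and Gini-Simpson (1 - sum p^2) of one
    sample's abundances. Values are renormalised over positive entries."""
    values = np.asarray(column, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    positive = values[values > 0]
    if positive.size == 0:
        raise ValueError("all-zero abundance column has no diversity")
    p = positive / positive.sum()
    return {
        "richness": int(positive.size),
        "shannon": float(-(p * np.log(p)).sum()),
        "simpson": float(1.0 - (p ** 2).sum()),
    }


def diversity_table(matrix: pd.DataFrame) -> pd.DataFrame:
    """Alpha diversity per sample (columns of a feature x sample matrix)."""
    return pd.DataFrame({s: alpha_diversity(matrix[s]) for s in matrix.columns}).T


# ------------------------------------------------------------- dissimilarity

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """All-pairs Bray-Curtis d(x,y) = sum|x-y| / sum(x+y), samples in columns."""
    if matrix.shape[1] < 2:
        raise ValueError("Bray-Curtis needs at least 2 samples")
    X = matrix.to_numpy(dtype=float).T
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample column: Bray-Curtis undefined")
    d = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


# -------------------------------------------------------------------- PCoA

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives kept)
    proportion_explained: np.ndarray  # over positive eigenvalues only


def pcoa(distance: pd.DataFrame, n_axes: int = 2) -> OrdinationResult:
    """Classical PCoA: eigendecomposition of the Gower-centred -d^2/2 matrix.

    Coordinates are eigenvectors scaled by the square root of their
    (positive) eigenvalues. Negative eigenvalues — expected for the
    non-Euclidean Bray-Curtis — are reported but excluded from the
    variance-explained denominator. Sign convention: the first loading of
    each axis with magnitude above 1e-12 is made positive.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    d = np.asarray(distance, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    a = -0.5 * d ** 2
    centerer = np.eye(n) - np.ones((n, n)) / n
    g = centerer @ a @ centerer
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    positive = eigvals > max(1e-12, 1e-12 * abs(eigvals[0]) if n else 0)
    n_pos = int(positive.sum())
    k = min(n_axes, max(n_pos, 1))
    coords = np.zeros((n, k))
    for j in range(min(k, n_pos)):
        vec = eigvecs[:, j] * np.sqrt(eigvals[j])
        nonzero = np.nonzero(np.abs(vec) > 1e-12)[0]
        if nonzero.size and vec[nonzero[0]] < 0:
            vec = -vec
        coords[:, j] = vec
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else np.array([])
    index = distance.index if isinstance(distance, pd.DataFrame) else range(n)
    frame = pd.DataFrame(coords, index=index, columns=[f"PCo{j+1}" for j in range(k)])
    return OrdinationResult(frame, eigvals, proportion)


# -------------------------------------------------- permutation group tests

@dataclass
class GroupTestResult:
    method: str
    statistic: float
    n_permutations: int
    p_value: float


def _as_distance_array(distance) -> np.ndarray:
    d = np.asarray(distance, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("expected a square distance matrix")
    return d


def _perm_matrix(n: int, n_permutations: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.permuted(np.tile(np.arange(n), (n_permutations, 1)), axis=1)


def _anosim_stats(rank_matrix: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """Vectorised ANOSIM R for each row of label assignments."""
    n = rank_matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rank_matrix[iu]
    within = label_matrix[:, iu[0]] == label_matrix[:, iu[1]]
    r_w = (within * ranks).sum(axis=1) / within.sum(axis=1)
    between = ~within
    r_b = (between * ranks).sum(axis=1) / between.sum(axis=1)
    return (r_b - r_w) / (n * (n - 1) / 4.0)


def _mrpp_stats(d: np.ndarray, label_matrix: np.ndarray) -> np.ndarray:
    """Vectorised MRPP delta (weights n_g / N) per label assignment."""
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    dv = d[iu]
    deltas = np.empty(label_matrix.shape[0])
    groups = np.unique(label_matrix[0])
    for r in range(label_matrix.shape[0]):
        labels = label_matrix[r]
        delta = 0.0
        for g in groups:
            members = labels[iu[0]] == g
            both = members & (labels[iu[1]] == g)
            n_g = int((labels == g).sum())
            delta += (n_g / n) * dv[both].mean()
        deltas[r] = delta
    return deltas


def _adonis_f(g: np.ndarray, hat: np.ndarray, rank: int, perms: np.ndarray) -> np.ndarray:
    """Pseudo-F per permutation, permuting the Gower matrix rows/columns."""
    n = g.shape[0]
    total = np.trace(g)
    fs = np.empty(perms.shape[0])
    for r in range(perms.shape[0]):
        gp = g[np.ix_(perms[r], perms[r])]
        ss_model = np.einsum("ij,ji->", hat, gp)
        ss_resid = total - ss_model
        fs[r] = (ss_model / (rank - 1)) / (ss_resid / (n - rank))
    return fs


def _gower(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    return centerer @ (-0.5 * d ** 2) @ centerer


def _design_hat(design: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(design)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def permutation_group_test(
    distance,
    labels,
    method: str = "adonis",
    n_permutations: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """MRPP, ANOSIM or Adonis comparison of >= 2 groups on a distance
    matrix, with a label-permutation p-value under the add-one rule."""
    d = _as_distance_array(distance)
    labels = np.asarray(labels)
    n = d.shape[0]
    if len(labels) != n:
        raise ValueError("labels length must match the distance matrix")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if method in ("mrpp", "adonis") and (counts < 2).any():
        raise ValueError(f"{method} requires every group to have >= 2 samples")

    perms = _perm_matrix(n, n_permutations, seed)
    label_rows = np.vstack([labels, labels[perms]])
    if method == "anosim":
        iu_ranks = squareform(rankdata(squareform(d, checks=False)), checks=False)
        stats = _anosim_stats(iu_ranks, label_rows)
        observed, permuted = stats[0], stats[1:]
        b = int((permuted >= observed - 1e-12).sum())
    elif method == "mrpp":
        stats = _mrpp_stats(d, label_rows)
        observed, permuted = stats[0], stats[1:]
        b = int((permuted <= observed + 1e-12).sum())  # small delta = structure
    elif method == "adonis":
        design = np.column_stack(
            [np.ones(n)] + [(labels == g).astype(float) for g in groups[:-1]]
        )
        hat, rank = _design_hat(design)
        g_mat = _gower(d)
        identity = np.arange(n)[None, :]
        fs = _adonis_f(g_mat, hat, rank, np.vstack([identity, perms]))
        observed, permuted = fs[0], fs[1:]
        b = int((permuted >= observed - 1e-12).sum())
    else:
        raise ValueError(f"unknown method {method!r}")
    p = (1 + b) / (1 + n_permutations)
    return GroupTestResult(method, float(observed), n_permutations, float(p))


def phenotype_permanova(
    distance,
    metadata: pd.DataFrame,
    variable: str,
    n_permutations: int = 999,
    seed: int = 0,
) -> GroupTestResult:
    """Single-variable PERMANOVA of a clinical phenotype against a
    community distance matrix; categorical variables are dummy-coded and
    continuous ones enter as distance-based regression."""
    d = _as_distance_array(distance)
    n = d.shape[0]
    if isinstance(distance, pd.DataFrame):
        values = metadata.loc[distance.index, variable]
    else:
        values = metadata[variable]
    if values.isna().any():
        raise ValueError(f"variable {variable!r} has missing values")
    if values.nunique() < 2:
        raise ValueError(f"variable {variable!r} is constant: no between-group variance")
    if values.dtype == object or str(values.dtype) == "category":
        groups = np.unique(values)
        design = np.column_stack(
            [np.ones(n)] + [(values.to_numpy() == g).astype(float) for g in groups[:-1]]
        )
    else:
        design = np.column_stack([np.ones(n), values.to_numpy(dtype=float)])
    hat, rank = _design_hat(design)
    g_mat = _gower(d)
    perms = _perm_matrix(n, n_permutations, seed)
    fs = _adonis_f(g_mat, hat, rank, np.vstack([np.arange(n)[None, :], perms]))
    observed, permuted = fs[0], fs[1:]
    b = int((permuted >= observed - 1e-12).sum())
    return GroupTestResult(
        "permanova", float(observed), n_permutations, float((1 + b) / (1 + n_permutations))
    )
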
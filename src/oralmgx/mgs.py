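"""Metagenomic-species (MGS) clustering of co-abundant genes.

Differentially abundant genes are grouped into clusters whose abundances
co-vary across samples, a reference-free proxy for organisms. Stage 1 is
a greedy canopy procedure: the unassigned gene with the highest mean
abundance seeds a cluster that absorbs every unassigned gene whose
Spearman correlation with the *seed profile* exceeds ``rho_min`` (0.9).
Stage 2 drops clusters below 25 genes, then merges the survivors by
average-linkage hierarchical clustering of their mean profiles on the
distance 1 - rho, cut at rho 0.8. Each final MGS carries an enrichment
direction (majority direction of its member genes) and 25 "tracer" genes
(top mean abundance) for display.

The algorithm is seed-free and deterministic: seed ties are broken by
lexicographic gene id, so identical matrices yield identical MGS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from .diffabund import wilcoxon_differential

N_TRACER = 25


@dataclass
class MGS:
    id: str
    members: list
    mean_profile: pd.Series
    tracer_genes: list
    direction: str

    def validate(self, min_genes: int = 25) -> None:
        if len(self.members) < min_genes:
            raise ValueError(f"{self.id}: fewer than {min_genes} member genes")
        if not set(self.tracer_genes) <= set(self.members):
            raise ValueError(f"{self.id}: tracer genes not a subset of members")


@dataclass
class MarkerGenes:
    genes: list
    directions: dict = field(default_factory=dict)


def select_marker_genes(
    gene_matrix: pd.DataFrame, labels, fdr: float = 0.07
) -> MarkerGenes:
    """Differentially abundant genes (BH q < fdr) with their enrichment
    directions; delegates to the rank-sum differential test."""
    if gene_matrix.shape[1] < 10:
        raise ValueError("marker-gene selection needs >= 10 samples")
    result = wilcoxon_differential(gene_matrix, labels, fdr_threshold=fdr)
    significant = result[result["significant"].fillna(False)]
    if significant.empty:
        warnings.warn("no significant marker genes at the requested FDR", stacklevel=2)
    return MarkerGenes(
        genes=list(significant.index),
        directions=significant["enriched_group"].to_dict(),
    )


def _rank_rows(matrix: np.ndarray) -> np.ndarray:
    ranks = np.apply_along_axis(rankdata, 1, matrix)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norms = np.sqrt((ranks ** 2).sum(axis=1))
    norms[norms == 0] = 1.0
    return ranks / norms[:, None]


def canopy_cluster(marker_matrix: pd.DataFrame, rho_min: float = 0.9) -> list[list]:
    """Greedy canopy clustering of gene profiles by Spearman correlation
    with the seed profile. Seeds are picked by highest mean abundance
    (lexicographic gene id on ties); every unassigned gene with rho >
    rho_min to the seed joins the seed's cluster."""
    if marker_matrix.shape[1] < 3:
        raise ValueError("rank correlation is degenerate with fewer than 3 samples")
    if marker_matrix.empty:
        return []
    genes = list(marker_matrix.index)
    ranked = _rank_rows(marker_matrix.to_numpy(dtype=float))
    means = marker_matrix.mean(axis=1).to_numpy()
    # deterministic seed order: descending mean, gene id breaks ties
    order = sorted(range(len(genes)), key=lambda i: (-means[i], genes[i]))
    unassigned = np.ones(len(genes), dtype=bool)
    clusters = []
    for seed in order:
        if not unassigned[seed]:
            continue
        rho = ranked @ ranked[seed]
        take = unassigned & (rho > rho_min)
        take[seed] = True
        clusters.append([genes[i] for i in np.nonzero(take)[0]])
        unassigned &= ~take
    return clusters


def refine_mgs(
    clusters: list[list],
    marker_matrix: pd.DataFrame,
    min_genes: int = 25,
    merge_rho: float = 0.8,
    directions: dict | None = None,
) -> list[MGS]:
    """Second-stage MGS refinement: drop clusters below ``min_genes``,
    merge clusters whose mean profiles correlate above ``merge_rho``
    (average linkage on 1 - Spearman rho), and finalise tracer genes and
    enrichment directions."""
    survivors = [c for c in clusters if len(c) >= min_genes]
    if not survivors:
        warnings.warn("all clusters below the minimum gene count: no MGS", stacklevel=2)
        return []
    mean_profiles = np.vstack(
        [marker_matrix.loc[c].mean(axis=0).to_numpy() for c in survivors]
    )
    if len(survivors) == 1:
        merged_ids = np.array([1])
    else:
        rho = np.corrcoef(_rank_rows(mean_profiles))
        dist = np.clip(1.0 - rho, 0.0, 2.0)
        np.fill_diagonal(dist, 0.0)
        merged_ids = fcluster(
            linkage(squareform(dist, checks=False), method="average"),
            t=1.0 - merge_rho,
            criterion="distance",
        )
    final = []
    for k, cluster_id in enumerate(sorted(set(merged_ids))):
        members = sorted(
            gene
            for idx in np.nonzero(merged_ids == cluster_id)[0]
            for gene in survivors[idx]
        )
        profile = marker_matrix.loc[members].mean(axis=0)
        gene_means = marker_matrix.loc[members].mean(axis=1).sort_values(
            ascending=False, kind="stable"
        )
        tracers = list(gene_means.index[: min(N_TRACER, len(members))])
        if directions:
            votes = pd.Series([directions.get(g, "none") for g in members])
            direction = votes.value_counts().idxmax()
        else:
            direction = "none"
        mgs = MGS(
            id=f"MGS{k+1:02d}",
            members=members,
            mean_profile=profile,
            tracer_genes=tracers,
            direction=direction,
        )
        mgs.validate(min_genes)
        final.append(mgs)
    return final


def identify_mgs(
    gene_matrix: pd.DataFrame,
    labels,
    fdr: float = 0.07,
    rho_min: float = 0.9,
    min_genes: int = 25,
    merge_rho: float = 0.8,
) -> list[MGS]:
    """Full MGS pipeline: marker selection -> canopy -> refinement."""
    markers = select_marker_genes(gene_matrix, labels, fdr=fdr)
    if not markers.genes:
        return []
    marker_matrix = gene_matrix.loc[markers.genes]
    clusters = canopy_cluster(marker_matrix, rho_min=rho_min)
    return refine_mgs(
        clusters, marker_matrix, min_genes=min_genes, merge_rho=merge_rho,
        directions=markers.directions,
    )


def membership_table(mgs_list: list[MGS]) -> pd.DataFrame:
    rows = [
        (gene, mgs.id, gene in mgs.tracer_genes, mgs.direction)
        for mgs in mgs_list
        for gene in mgs.members
    ]
    return pd.DataFrame(rows, columns=["gene_id", "mgs_id", "tracer", "direction"])
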
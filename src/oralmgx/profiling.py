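"""Species/gene abundance estimation with multi-mapped read redistribution.

For a species S with U unique read pairs and average genome length l, the
unique abundance is Ab(U) = U / l. Each multi-mapping read pair, whose
aligned species set has size N, is split among those species by a
coefficient Co(S) = Ab(U, S) / sum over the set of Ab(U), so species better
supported by unique reads absorb a larger share. The multiple abundance
Ab(M, S) is the summed coefficient mass divided by l, and the total is

    Ab(S) = Ab(U) + Ab(M).

The estimator is one-pass: coefficients come from unique abundances only.
An optional iterated mode recomputes coefficients from the previous round's
total abundances until convergence, but the plain estimator is the default.
When no member of a multi-read's species set has any unique read the
coefficient is undefined; the default fallback splits the read uniformly
(Co = 1/N, preserving read mass), or the read can be dropped instead.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .qc import ReadPartition

PROFILE_COLUMNS = ["U", "Ab_U", "Ab_M", "Ab_S", "rel"]


def unique_abundance(partition: ReadPartition, lengths: dict) -> dict:
    """Ab(U) = U / l per species; species without unique reads get 0."""
    _check_lengths(partition, lengths)
    counts = {sid: 0 for sid in lengths}
    for sid in partition.unique.values():
        counts[sid] += 1
    return {sid: counts[sid] / lengths[sid] for sid in lengths}


def distribution_coefficients(
    read_species_set, ab_u: dict, zero_fallback: str = "uniform"
) -> dict:
    """Coefficients Co splitting one multi-read across its species set.

    Co(S) = Ab_U(S) / sum of Ab_U over the set; if the denominator is zero
    the read is split uniformly (Co = 1/N) or, with zero_fallback='drop',
    given all-zero coefficients. The returned values sum to 1 exactly
    (or 0 when dropped).
    """
    members = sorted(read_species_set)
    if len(members) < 2:
        raise ValueError("a multi-read species set must have N >= 2 members")
    denom = sum(ab_u.get(s, 0.0) for s in members)
    if denom == 0.0:
        if zero_fallback == "drop":
            return {s: 0.0 for s in members}
        return {s: 1.0 / len(members) for s in members}
    return {s: ab_u.get(s, 0.0) / denom for s in members}


def total_abundance(
    partition: ReadPartition,
    lengths: dict,
    zero_fallback: str = "uniform",
    iterate: int = 0,
) -> pd.DataFrame:
    """Per-species profile with U, Ab_U, Ab_M, Ab_S and relative abundance.

    ``iterate`` > 0 recomputes the split coefficients from the previous
    round's total abundances that many times (off by default; the one-pass
    estimator uses unique abundances only).
    """
    _check_lengths(partition, lengths)
    species = sorted(lengths)
    if not partition.unique and not partition.multi:
        warnings.warn("empty read partition: all-zero abundance profile", stacklevel=2)
    ab_u = unique_abundance(partition, lengths)
    u_counts = {sid: 0 for sid in species}
    for sid in partition.unique.values():
        u_counts[sid] += 1

    weights = ab_u
    for _ in range(iterate + 1):
        ab_m = {sid: 0.0 for sid in species}
        for members in partition.multi.values():
            co = distribution_coefficients(members, weights, zero_fallback)
            for sid, c in co.items():
                ab_m[sid] += c
        ab_m = {sid: ab_m[sid] / lengths[sid] for sid in species}
        ab_s = {sid: ab_u[sid] + ab_m[sid] for sid in species}
        weights = ab_s

    total = sum(ab_s.values())
    rel = {sid: (ab_s[sid] / total if total > 0 else 0.0) for sid in species}
    return pd.DataFrame(
        {
            "U": [u_counts[s] for s in species],
            "Ab_U": [ab_u[s] for s in species],
            "Ab_M": [ab_m[s] for s in species],
            "Ab_S": [ab_s[s] for s in species],
            "rel": [rel[s] for s in species],
        },
        index=pd.Index(species, name="species_id"),
    )


def profile_samples(
    partitions: dict,
    lengths: dict,
    multiread: str = "split",
    zero_fallback: str = "uniform",
    iterate: int = 0,
) -> pd.DataFrame:
    """Relative-abundance matrix (species x samples) from per-sample read
    partitions. ``multiread='drop'`` ignores multi-mapping reads entirely
    (the naive baseline the proportional split is compared against)."""
    if multiread not in ("split", "drop"):
        raise ValueError(f"unknown multiread mode {multiread!r}")
    columns = {}
    for sample, partition in partitions.items():
        if multiread == "drop":
            partition = ReadPartition(unique=dict(partition.unique), multi={})
        profile = total_abundance(partition, lengths, zero_fallback, iterate)
        columns[sample] = profile["rel"]
    matrix = pd.DataFrame(columns)
    matrix.index.name = "species_id"
    return matrix


def aggregate_taxa(matrix: pd.DataFrame, taxon_map: dict) -> pd.DataFrame:
    """Sum species relative abundances within higher taxa (genus, phylum)."""
    groups = pd.Series({sid: taxon_map.get(sid, "unclassified") for sid in matrix.index})
    return matrix.groupby(groups).sum()


def _check_lengths(partition: ReadPartition, lengths: dict) -> None:
    for sid, length in lengths.items():
        if length <= 0:
            raise ValueError(f"non-positive genome length for species {sid!r}")
    referenced = set(partition.unique.values())
    for members in partition.multi.values():
        referenced |= set(members)
    missing = referenced - set(lengths)
    if missing:
        raise KeyError(f"species missing from the lengths table: {sorted(missing)}")
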
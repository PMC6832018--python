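"""Synthetic saliva-metagenome communities with known ground truth.

Generates everything the analysis stages consume — reference genomes with
deliberately shared segments (to force multi-mapping reads), paired-end
reads with host contamination, species- and gene-level abundance matrices
with planted differential species, co-abundant gene clusters (MGS) and
inter-species correlations, and a clinical metadata table mimicking a
two-group caries/healthy cohort of preschool children.

Every generator is a pure function of its spec and seed. Base abundances
are log-normal (meanlog 0, sdlog 1) before per-sample normalisation —
heavy-tailed like real relative-abundance profiles and easy to invert in
tests. Group effects multiply the unnormalised scale so effect-size
bookkeeping stays exact pre-normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .qc import ReadPair

_BASES = np.frombuffer(b"ACGT", dtype="S1")

CARIES, HEALTHY = "caries", "healthy"


@dataclass
class CommunitySpec:
    """Design of a synthetic two-group community.

    ``shared_segments`` lists (species_a, species_b, length) triples whose
    segment is copied verbatim into both genomes, guaranteeing reads that
    multi-map. ``differential_species`` lists (species_id, log2 effect,
    enriched group). ``mgs_spec`` lists (n_genes, carrier species id): each
    entry plants a cluster of co-abundant genes riding the carrier's
    abundance profile. ``planted_edges`` lists (a, b, sign) inter-species
    correlations realised through shared latent factors.
    """

    n_species: int = 10
    genome_length: int = 5000
    shared_segments: list = field(default_factory=list)
    n_samples_per_group: int = 22
    differential_species: list = field(default_factory=list)
    mgs_spec: list = field(default_factory=list)
    planted_edges: list = field(default_factory=list)
    marker_penetrance: float = 1.0
    host_fraction: float = 0.0
    seed: int = 0

    def species_ids(self) -> list[str]:
        return [f"sp{i:03d}" for i in range(self.n_species)]

    def validate(self) -> None:
        if self.n_species < 1 or self.genome_length < 1:
            raise ValueError("n_species and genome_length must be positive")
        if not 0.0 <= self.host_fraction <= 1.0:
            raise ValueError("host_fraction must lie in [0, 1]")
        if not 0.0 < self.marker_penetrance <= 1.0:
            raise ValueError("marker_penetrance must lie in (0, 1]")
        seen_pairs = set()
        for a, b, length in self.shared_segments:
            if a == b:
                raise ValueError("shared segment must reference two distinct species")
            if frozenset((a, b)) in seen_pairs:
                raise ValueError(f"duplicate shared-segment pair ({a}, {b})")
            seen_pairs.add(frozenset((a, b)))
            if length > self.genome_length:
                raise ValueError(
                    f"shared segment of {length} bp does not fit a "
                    f"{self.genome_length} bp genome"
                )
        for n_genes, carrier in self.mgs_spec:
            if n_genes < 1:
                raise ValueError("planted MGS must contain at least one gene")
        for entry in self.differential_species:
            sid, effect, group = entry[:3]
            if not np.isfinite(effect):
                raise ValueError(f"non-finite effect size for {sid}")
            if group not in (CARIES, HEALTHY):
                raise ValueError(f"unknown enriched group {group!r}")
            if len(entry) > 3 and not 0.0 < entry[3] <= 1.0:
                raise ValueError(f"penetrance for {sid} must lie in (0, 1]")


@dataclass
class TruthSet:
    """Ground-truth record accompanying each generated dataset."""

    true_relative_abundance: pd.DataFrame | None = None
    true_differential_features: set = field(default_factory=set)
    true_mgs_membership: dict = field(default_factory=dict)
    true_edges: set = field(default_factory=set)
    true_informative_markers: set = field(default_factory=set)
    host_read_ids: set = field(default_factory=set)

    def validate(self) -> None:
        if self.true_relative_abundance is not None:
            sums = self.true_relative_abundance.sum(axis=0).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("truth relative-abundance columns must sum to 1")


@dataclass
class ReferenceSet:
    genomes: dict
    genes: pd.DataFrame  # gene_id, species_id, start, end (half-open)

    def lengths(self) -> dict:
        return {sid: len(seq) for sid, seq in self.genomes.items()}


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def generate_reference_set(spec: CommunitySpec, gene_length: int = 200) -> ReferenceSet:
    """One random genome per species; shared segments copied verbatim into
    both members of each pair; genes tile each genome as non-overlapping
    intervals of ``gene_length`` (last gene absorbs the remainder)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ids = spec.species_ids()
    genomes = {sid: np.array(list(_random_sequence(rng, spec.genome_length))) for sid in ids}
    for a, b, length in spec.shared_segments:
        segment = np.array(list(_random_sequence(rng, length)))
        pos_a = int(rng.integers(0, spec.genome_length - length + 1))
        pos_b = int(rng.integers(0, spec.genome_length - length + 1))
        genomes[a][pos_a : pos_a + length] = segment
        genomes[b][pos_b : pos_b + length] = segment
    sequences = {sid: "".join(arr) for sid, arr in genomes.items()}
    rows = []
    for sid in ids:
        n_genes = max(1, spec.genome_length // gene_length)
        for g in range(n_genes):
            start = g * gene_length
            end = spec.genome_length if g == n_genes - 1 else (g + 1) * gene_length
            rows.append((f"{sid}_g{g:04d}", sid, start, end))
    genes = pd.DataFrame(rows, columns=["gene_id", "species_id", "start", "end"])
    return ReferenceSet(sequences, genes)


def generate_host_genome(length: int = 20000, seed: int = 12345) -> str:
    """Bundled synthetic 'host' sequence standing in for a human reference;
    host reads are drawn from it so host removal exercises the same code
    path without any download."""
    return _random_sequence(np.random.default_rng(seed), length)


def generate_sample_reads(
    genomes: dict,
    truth_abundance: dict,
    n_reads: int,
    read_length: int = 100,
    host_genome: str | None = None,
    host_fraction: float = 0.0,
    seed: int = 0,
    lowq_rate: float = 0.0,
    insert_gap: int = 50,
    sample_id: str = "S",
):
    """Draw paired reads from genome positions.

    Species are sampled proportional to truth_abundance x genome length
    (per-base uniform sampling), so unique-read counts divided by genome
    length recover relative abundance. Mates are stored in reference
    orientation. Qualities follow a two-level model: Phred 40 everywhere
    except a ``lowq_rate`` per-base chance of Phred 1 (< the QC cutoff of
    3 used by the cleaning filters at their defaults).

    Returns (list of ReadPair, set of host read ids).
    """
    if not genomes:
        raise ValueError("empty genome set")
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not 0.0 <= host_fraction <= 1.0:
        raise ValueError("host_fraction must lie in [0, 1]")
    species = sorted(genomes)
    props = np.array([truth_abundance[s] for s in species], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("truth_abundance proportions must sum to 1")
    rng = np.random.default_rng(seed)
    lengths = np.array([len(genomes[s]) for s in species], dtype=float)
    weights = props * lengths
    weights /= weights.sum()

    n_host = int(round(host_fraction * n_reads))
    is_host = np.zeros(n_reads, dtype=bool)
    if n_host:
        is_host[rng.choice(n_reads, size=n_host, replace=False)] = True
    choice = rng.choice(len(species), size=n_reads, p=weights)

    span = 2 * read_length + insert_gap
    pairs, host_ids = [], set()
    for i in range(n_reads):
        rid = f"{sample_id}_r{i:07d}"
        if is_host[i]:
            if host_genome is None:
                raise ValueError("host_fraction > 0 requires a host genome")
            src = host_genome
            host_ids.add(rid)
        else:
            src = genomes[species[choice[i]]]
        start = int(rng.integers(0, len(src) - span + 1))
        b1 = src[start : start + read_length]
        b2 = src[start + read_length + insert_gap : start + span]
        if lowq_rate > 0:
            q1 = np.where(rng.random(read_length) < lowq_rate, 1, 40).astype(np.uint8)
            q2 = np.where(rng.random(read_length) < lowq_rate, 1, 40).astype(np.uint8)
        else:
            q1 = np.full(read_length, 40, dtype=np.uint8)
            q2 = np.full(read_length, 40, dtype=np.uint8)
        pairs.append(ReadPair(rid, b1, q1, b2, q2))
    return pairs, host_ids


@dataclass
class AbundanceData:
    """Generated abundance matrices plus sample labels.

    ``raw`` holds the unnormalised (pre-column-scaling) values on which
    planted effect ratios are exact; ``relative`` is column-normalised to
    sum 1 and is what the statistical stages consume.
    """

    raw: pd.DataFrame
    relative: pd.DataFrame
    labels: pd.Series  # sample -> group


def _sample_names(n_per_group) -> tuple[list, pd.Series]:
    """n_per_group is an int (equal groups) or (n_caries, n_healthy)."""
    n_c, n_h = (n_per_group, n_per_group) if np.isscalar(n_per_group) else n_per_group
    names = [f"C{i:02d}" for i in range(n_c)] + [f"H{i:02d}" for i in range(n_h)]
    labels = pd.Series([CARIES] * n_c + [HEALTHY] * n_h, index=names, name="group")
    return names, labels


def _species_raw(spec: CommunitySpec, rng: np.random.Generator, noise_sd: float,
                 profile_sd: float = 1.0):
    """Unnormalised species x samples matrix with planted structure.

    ``profile_sd`` scales the per-sample latent variation of each species'
    profile (the signal correlations and clusterings act on); ``noise_sd``
    is independent entry-level noise on top. With both at 0 a species is
    constant across samples, making planted group-effect ratios exact.
    """
    names, labels = _sample_names(spec.n_samples_per_group)
    ids = spec.species_ids()
    n, m = len(ids), len(names)
    mu = rng.normal(0.0, 1.0, size=n)  # log-normal base abundance
    z = profile_sd * rng.normal(0.0, 1.0, size=(n, m))  # per-sample latent variation
    # planted edges share the latent factor (negated for negative edges)
    for a, b, sign in spec.planted_edges:
        ia, ib = ids.index(a), ids.index(b)
        z[ib] = z[ia] if sign >= 0 else -z[ia]
    log_raw = mu[:, None] + z
    if noise_sd > 0:
        log_raw = log_raw + rng.normal(0.0, noise_sd, size=(n, m))
    raw = np.exp(log_raw)
    caries_cols = labels.to_numpy() == CARIES
    for entry in spec.differential_species:
        sid, effect, group = entry[:3]
        penetrance = entry[3] if len(entry) > 3 else spec.marker_penetrance
        i = ids.index(sid)
        cols = (caries_cols if group == CARIES else ~caries_cols).copy()
        if penetrance < 1.0:
            # polymicrobial realism: the effect hits only a random subset
            # of the enriched group's samples
            cols &= rng.random(m) < penetrance
        raw[i, cols] *= 2.0 ** effect
    return pd.DataFrame(raw, index=ids, columns=names), labels


def generate_abundance_matrix(
    spec: CommunitySpec,
    level: str = "species",
    noise_sd: float = 0.1,
    seed: int | None = None,
    n_background_genes: int = 200,
    profile_sd: float = 1.0,
    mgs_gene_scale: float = 0.02,
):
    """Generate a species- or gene-level abundance matrix plus truth.

    Species level: log-normal profiles, differential species multiplied by
    2**effect in their enriched group, planted edges realised as shared
    per-sample latent factors. Gene level: each planted MGS is n_genes
    scaled copies of its carrier species' profile (so within-cluster
    Spearman rho is 1 at noise_sd = 0, and the cluster inherits the
    carrier's group enrichment), plus independent background genes.
    Columns of ``relative`` are normalised to sum 1.
    """
    spec.validate()
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if level not in ("species", "gene"):
        raise ValueError(f"unknown abundance level {level!r}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    species_raw, labels = _species_raw(spec, rng, noise_sd, profile_sd)
    truth = TruthSet()
    truth.true_edges = {frozenset((a, b)) for a, b, _ in spec.planted_edges}
    truth.true_informative_markers = {e[0] for e in spec.differential_species}

    if level == "species":
        raw = species_raw
        truth.true_differential_features = set(truth.true_informative_markers)
    else:
        rows, index = [], []
        diff_species = {e[0] for e in spec.differential_species}
        for k, (n_genes, carrier) in enumerate(spec.mgs_spec):
            mgs_id = f"mgs{k:02d}"
            profile = species_raw.loc[carrier].to_numpy()
            # cluster genes carry a small share of total mass, as real
            # differential genes do, so their group shift does not
            # compositionally displace the background genes
            scales = mgs_gene_scale * np.exp(rng.normal(0.0, 1.0, size=n_genes))
            eps = (
                np.exp(rng.normal(0.0, noise_sd, size=(n_genes, len(profile))))
                if noise_sd > 0
                else np.ones((n_genes, len(profile)))
            )
            block = scales[:, None] * profile[None, :] * eps
            for g in range(n_genes):
                gid = f"{mgs_id}_g{g:04d}"
                index.append(gid)
                truth.true_mgs_membership[gid] = mgs_id
                if carrier in diff_species:
                    truth.true_differential_features.add(gid)
            rows.append(block)
        if n_background_genes:
            mu = rng.normal(0.0, 1.0, size=n_background_genes)
            z = profile_sd * rng.normal(
                0.0, 1.0, size=(n_background_genes, species_raw.shape[1])
            )
            noise = (
                rng.normal(0.0, noise_sd, size=z.shape) if noise_sd > 0 else 0.0
            )
            rows.append(np.exp(mu[:, None] + z + noise))
            index.extend(f"bg_g{g:04d}" for g in range(n_background_genes))
        raw = pd.DataFrame(np.vstack(rows), index=index, columns=species_raw.columns)

    relative = raw / raw.sum(axis=0)
    truth.true_relative_abundance = relative
    truth.validate()
    return AbundanceData(raw=raw, relative=relative, labels=labels), truth


def generate_metadata(
    n_samples: int,
    group_labels,
    onset_labels=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical metadata table for a caries/healthy preschool cohort.

    Ages are uniform over 45-73 months; dmfs is 0 for every healthy child
    and >= 8 for every caries child (the severe-ECC inclusion rule); the
    remaining phenotypes (gender, BMI, height, toothache history, diet
    frequency, parental education, income) are drawn from plausible
    marginal distributions and are independent of the microbiome unless a
    link is planted afterwards with :func:`plant_association`.
    """
    group_labels = list(group_labels)
    if len(group_labels) != n_samples:
        raise ValueError("group_labels length must equal n_samples")
    if onset_labels is not None and len(onset_labels) != n_samples:
        raise ValueError("onset_labels length must equal n_samples")
    rng = np.random.default_rng(seed)
    caries = np.array([g == CARIES for g in group_labels])
    age = rng.integers(45, 74, size=n_samples)
    gender = np.where(rng.random(n_samples) < 0.5, "F", "M")
    height = np.round(rng.normal(105.0, 6.0, size=n_samples), 1)
    bmi = np.round(rng.normal(15.5, 1.5, size=n_samples), 2)
    dmfs = np.where(caries, 8 + rng.poisson(6.0, size=n_samples), 0)
    dmft = np.where(caries, 1 + rng.poisson(4.0, size=n_samples), 0)
    toothache = np.where(
        caries, rng.random(n_samples) < 0.6, rng.random(n_samples) < 0.1
    ).astype(int)
    diet_freq = rng.integers(0, 4, size=n_samples)
    education = rng.integers(0, 3, size=n_samples)
    income = rng.integers(0, 3, size=n_samples)
    table = pd.DataFrame(
        {
            "group": group_labels,
            "age": age,
            "gender": gender,
            "height": height,
            "bmi": bmi,
            "dmfs": dmfs,
            "dmft": dmft,
            "toothache": toothache,
            "diet_freq": diet_freq,
            "education": education,
            "income": income,
        },
        index=pd.Index([f"S{i:02d}" for i in range(n_samples)], name="sample_id"),
    )
    if onset_labels is not None:
        table["onset"] = list(onset_labels)
    return table


def plant_association(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    feature: str,
    variable: str,
    coef: float,
    baseline: float = 0.55,
    covariate_coefs: dict | None = None,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Plant a linear phenotype link on the arcsine-sqrt scale.

    The feature's proportion becomes sin^2(baseline + coef*x + covariate
    terms + Gaussian noise), so an OLS fit of the transformed abundance on
    the raw variable recovers ``coef`` exactly at noise_sd = 0. The matrix
    is *not* re-normalised afterwards: re-scaling columns would distort
    the planted linear relation.
    """
    out = matrix.copy()
    x = metadata.loc[matrix.columns, variable].astype(float).to_numpy()
    y = baseline + coef * x
    for cov, c in (covariate_coefs or {}).items():
        v = metadata.loc[matrix.columns, cov]
        if v.dtype == object:
            v = (v == sorted(v.unique())[0]).astype(float)
        y = y + c * (v.astype(float).to_numpy() - v.astype(float).mean())
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=len(y))
    if (y <= 0).any() or (y >= np.pi / 2).any():
        raise ValueError("planted link leaves the arcsine-sqrt range; shrink coefficients")
    out.loc[feature] = np.sin(y) ** 2
    return out
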
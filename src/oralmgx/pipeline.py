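"""End-to-end pipeline orchestration with a reproducibility manifest.

A single :class:`RunConfig` carries every stage threshold (defaults are
the analysis' canonical values: taxa FDR 0.1, gene FDR 0.07, MGS rho 0.9
/ min 25 genes / merge rho 0.8, network rho 0.6 / FDR 0.05 / abundance
floor 0.01%, association q 0.1, classifier raw p 0.01 / subset interval
5) plus the master seed. Stages run in dependency order — simulate ->
qc -> profile -> diversity -> diff -> mgs -> network -> assoc ->
classify — and the manifest records the config hash, seed and a SHA-256
checksum of every output file, so identical config + seed reproduces
byte-identical results.

The read-level stages (qc, profile) run on a small simulated community
with shared genome segments and host contamination; the statistical
stages run on the larger simulated species/gene matrices. Each stage's
outputs are plain TSV/JSON under the run directory.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import associations, classifier, community, diffabund, mgs, network, profiling, qc, synthetic
from .io import (
    write_fasta,
    write_fastq_pairs,
    write_json,
    write_matrix_tsv,
    write_metadata_tsv,
)

ALL_STAGES = (
    "simulate",
    "qc",
    "profile",
    "diversity",
    "diff",
    "mgs",
    "network",
    "assoc",
    "classify",
)


@dataclass
class RunConfig:
    seed: int = 1
    stages: tuple = ALL_STAGES
    # synthetic-community scale
    n_samples_per_group: int = 22
    n_species: int = 200
    n_genes: int = 2000
    read_community_species: int = 10
    read_pairs_per_sample: int = 2000
    read_samples: int = 4
    host_fraction: float = 0.2
    # stage thresholds (canonical defaults)
    taxa_fdr: float = 0.1
    gene_fdr: float = 0.07
    mgs_rho: float = 0.9
    mgs_min_genes: int = 25
    mgs_merge_rho: float = 0.8
    network_rho: float = 0.6
    network_fdr: float = 0.05
    network_min_abundance: float = 1e-4
    association_q: float = 0.1
    classifier_p: float = 0.01
    classifier_interval: int = 5
    n_permutations: int = 199

    def validate(self) -> None:
        for name in ("taxa_fdr", "gene_fdr", "network_fdr", "association_q", "classifier_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("mgs_rho", "mgs_merge_rho", "network_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_permutations < 1 or self.read_pairs_per_sample < 1:
            raise ValueError("n_permutations and read_pairs_per_sample must be positive")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        if "stages" in payload:
            payload["stages"] = tuple(payload["stages"])
        config = cls(**payload)
        config.validate()
        return config


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns the manifest dict (also
    written to manifest.json in ``outdir``)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        runner = globals()[f"_stage_{stage}"]
        try:
            outputs = runner(config, outdir, state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed") from exc
        manifest["stages"][stage] = {
            name: _sha256(path) for name, path in sorted(outputs.items())
        }
    write_json(manifest, outdir / "manifest.json")
    return manifest


# ----------------------------------------------------------------- stages

def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    seed = config.seed
    # read-level community with shared segments forcing multi-mapping
    read_spec = synthetic.CommunitySpec(
        n_species=config.read_community_species,
        genome_length=5000,
        shared_segments=[("sp000", "sp001", 600)],
        host_fraction=config.host_fraction,
        seed=seed,
    )
    reference = synthetic.generate_reference_set(read_spec)
    host = synthetic.generate_host_genome(seed=seed + 7)
    rng = np.random.default_rng(seed)
    read_samples = {}
    truth_props = {}
    for i in range(config.read_samples):
        props = rng.dirichlet(np.ones(read_spec.n_species))
        props_map = dict(zip(sorted(reference.genomes), props))
        pairs, host_ids = synthetic.generate_sample_reads(
            reference.genomes,
            props_map,
            n_reads=config.read_pairs_per_sample,
            host_genome=host,
            host_fraction=config.host_fraction,
            seed=seed + 100 + i,
            lowq_rate=0.002,
            sample_id=f"R{i:02d}",
        )
        read_samples[f"R{i:02d}"] = (pairs, host_ids)
        truth_props[f"R{i:02d}"] = props_map
    # statistical community: species + gene matrices, metadata
    n_diff = 7
    diff = [
        (f"sp{i:03d}", 2.5, synthetic.CARIES if i % 2 == 0 else synthetic.HEALTHY)
        for i in range(n_diff)
    ]
    stat_spec = synthetic.CommunitySpec(
        n_species=config.n_species,
        n_samples_per_group=config.n_samples_per_group,
        differential_species=diff,
        mgs_spec=[(40, "sp000"), (40, "sp001"), (40, "sp002")],
        planted_edges=[("sp010", "sp011", 1), ("sp012", "sp013", -1)],
        seed=seed,
    )
    species_data, species_truth = synthetic.generate_abundance_matrix(
        stat_spec, level="species", seed=seed + 1
    )
    gene_data, gene_truth = synthetic.generate_abundance_matrix(
        stat_spec,
        level="gene",
        seed=seed + 2,
        n_background_genes=config.n_genes - sum(n for n, _ in stat_spec.mgs_spec),
    )
    metadata = synthetic.generate_metadata(
        len(species_data.labels), species_data.labels, seed=seed + 3
    )
    metadata.index = species_data.labels.index

    state.update(
        reference=reference,
        host=host,
        read_samples=read_samples,
        truth_props=truth_props,
        species_data=species_data,
        species_truth=species_truth,
        gene_data=gene_data,
        gene_truth=gene_truth,
        metadata=metadata,
    )
    outputs = {}
    write_fasta(reference.genomes, outdir / "genomes.fasta")
    outputs["genomes.fasta"] = outdir / "genomes.fasta"
    write_fasta({"host": host}, outdir / "host.fasta")
    outputs["host.fasta"] = outdir / "host.fasta"
    for name, (pairs, _) in read_samples.items():
        p1, p2 = outdir / f"{name}_1.fastq", outdir / f"{name}_2.fastq"
        write_fastq_pairs(pairs, p1, p2)
        outputs[p1.name], outputs[p2.name] = p1, p2
    write_matrix_tsv(species_data.relative, outdir / "species_matrix.tsv")
    outputs["species_matrix.tsv"] = outdir / "species_matrix.tsv"
    write_matrix_tsv(gene_data.relative, outdir / "gene_matrix.tsv")
    outputs["gene_matrix.tsv"] = outdir / "gene_matrix.tsv"
    write_metadata_tsv(metadata, outdir / "metadata.tsv")
    outputs["metadata.tsv"] = outdir / "metadata.tsv"
    write_json(
        {
            "true_differential": sorted(species_truth.true_differential_features),
            "true_edges": [sorted(e) for e in sorted(species_truth.true_edges, key=sorted)],
            "true_mgs": gene_truth.true_mgs_membership,
        },
        outdir / "truth.json",
    )
    outputs["truth.json"] = outdir / "truth.json"
    return outputs


def _stage_qc(config: RunConfig, outdir: Path, state: dict) -> dict:
    outputs = {}
    clean = {}
    logs = {}
    for name, (pairs, _) in state["read_samples"].items():
        kept, log = qc.process_reads(pairs, host_reference=state["host"])
        clean[name] = kept
        logs[name] = log.as_dict()
    state["clean_reads"] = clean
    path = outdir / "qc_log.json"
    write_json(logs, path)
    outputs["qc_log.json"] = path
    return outputs


def _stage_profile(config: RunConfig, outdir: Path, state: dict) -> dict:
    reference = state["reference"]
    aligner = qc.ExactReferenceAligner(reference.genomes, read_length=100)
    partitions = {
        name: qc.classify_alignments(aligner.align(pairs))
        for name, pairs in state["clean_reads"].items()
    }
    matrix = profiling.profile_samples(partitions, reference.lengths())
    state["profiled_matrix"] = matrix
    path = outdir / "profiled_species.tsv"
    write_matrix_tsv(matrix, path, index_label="species_id")
    return {"profiled_species.tsv": path}


def _stage_diversity(config: RunConfig, outdir: Path, state: dict) -> dict:
    matrix = state["species_data"].relative
    labels = state["species_data"].labels
    alpha = community.diversity_table(matrix)
    d = community.bray_curtis(matrix)
    ordination = community.pcoa(d, n_axes=2)
    tests = {
        method: asdict(
            community.permutation_group_test(
                d, labels.to_numpy(), method=method,
                n_permutations=config.n_permutations, seed=config.seed,
            )
        )
        for method in ("mrpp", "anosim", "adonis")
    }
    state["distance"] = d
    outputs = {}
    for name, frame in (
        ("alpha_diversity.tsv", alpha),
        ("pcoa_coordinates.tsv", ordination.coordinates),
    ):
        frame.to_csv(outdir / name, sep="\t")
        outputs[name] = outdir / name
    write_json(
        {"tests": tests, "eigenvalues": ordination.eigenvalues.tolist()},
        outdir / "group_tests.json",
    )
    outputs["group_tests.json"] = outdir / "group_tests.json"
    return outputs


def _stage_diff(config: RunConfig, outdir: Path, state: dict) -> dict:
    data = state["species_data"]
    result = diffabund.wilcoxon_differential(
        data.relative, data.labels, fdr_threshold=config.taxa_fdr
    )
    state["diff_species"] = result
    path = outdir / "differential_species.tsv"
    result.to_csv(path, sep="\t")
    return {"differential_species.tsv": path}


def _stage_mgs(config: RunConfig, outdir: Path, state: dict) -> dict:
    data = state["gene_data"]
    found = mgs.identify_mgs(
        data.relative,
        data.labels,
        fdr=config.gene_fdr,
        rho_min=config.mgs_rho,
        min_genes=config.mgs_min_genes,
        merge_rho=config.mgs_merge_rho,
    )
    state["mgs"] = found
    table = mgs.membership_table(found)
    path = outdir / "mgs_membership.tsv"
    table.to_csv(path, sep="\t", index=False)
    return {"mgs_membership.tsv": path}


def _stage_network(config: RunConfig, outdir: Path, state: dict) -> dict:
    data = state["species_data"]
    outputs = {}
    nets = {}
    for group in (synthetic.CARIES, synthetic.HEALTHY):
        samples = data.labels.index[data.labels == group]
        net = network.build_network(
            data.relative,
            samples,
            condition=group,
            min_abundance=config.network_min_abundance,
            rho_min=config.network_rho,
            fdr_max=config.network_fdr,
        )
        nets[group] = net
        path = outdir / f"network_{group}_edges.tsv"
        net.edges.to_csv(path, sep="\t", index=False)
        outputs[path.name] = path
        topo_path = outdir / f"network_{group}_topology.tsv"
        network.node_topology(net).to_csv(topo_path, sep="\t")
        outputs[topo_path.name] = topo_path
    report = network.compare_networks(nets[synthetic.CARIES], nets[synthetic.HEALTHY])
    write_json(report, outdir / "network_comparison.json")
    outputs["network_comparison.json"] = outdir / "network_comparison.json"
    state["networks"] = nets
    return outputs


def _stage_assoc(config: RunConfig, outdir: Path, state: dict) -> dict:
    data = state["species_data"]
    records, info = associations.associate(
        data.relative,
        state["metadata"],
        variables=["dmfs", "toothache", "diet_freq"],
        q_max=config.association_q,
    )
    path = outdir / "associations.tsv"
    records.to_csv(path, sep="\t", index=False)
    return {"associations.tsv": path}


def _stage_classify(config: RunConfig, outdir: Path, state: dict) -> dict:
    data = state["species_data"]
    panel, model, roc = classifier.build_classifier(
        data.relative,
        data.labels,
        positive=synthetic.CARIES,
        p_max=config.classifier_p,
        interval=config.classifier_interval,
    )
    outputs = {}
    panel_frame = pd.DataFrame(
        {
            "subset_size": panel.subset_sizes,
            "error_rate": panel.error_rates,
            "mcc": panel.mccs,
        }
    )
    path = outdir / "classifier_subsets.tsv"
    panel_frame.to_csv(path, sep="\t", index=False)
    outputs[path.name] = path
    (outdir / "classifier_model.json").write_text(model.to_json())
    outputs["classifier_model.json"] = outdir / "classifier_model.json"
    write_json(
        {
            "panel": panel.panel,
            "auc": roc.auc,
            "ci": [roc.ci_lower, roc.ci_upper],
        },
        outdir / "classifier_report.json",
    )
    outputs["classifier_report.json"] = outdir / "classifier_report.json"
    return outputs
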
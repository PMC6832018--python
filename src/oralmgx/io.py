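"""Plain-text readers and writers shared by the pipeline stages.

Matrices travel as TSV with features in rows, samples in columns and the
feature id in the first column; metadata as one row per sample; truth
records as JSON. Sequence data uses FASTA/FASTQ (Phred+33) via Biopython.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_matrix_tsv(matrix: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format="%.10g")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata_tsv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(pairs, path_1, path_2) -> None:
    """Write paired reads (mate 1 / mate 2 files) in Phred+33 FASTQ."""
    with open(path_1, "w") as f1, open(path_2, "w") as f2:
        for pair in pairs:
            q1 = "".join(chr(q + 33) for q in np.asarray(pair.quals_1))
            q2 = "".join(chr(q + 33) for q in np.asarray(pair.quals_2))
            f1.write(f"@{pair.id}/1\n{pair.bases_1}\n+\n{q1}\n")
            f2.write(f"@{pair.id}/2\n{pair.bases_2}\n+\n{q2}\n")


def read_fastq_pairs(path_1, path_2):
    """Read paired FASTQ files into ReadPair objects (mate order preserved)."""
    from .qc import ReadPair

    pairs = []
    it1 = SeqIO.parse(str(path_1), "fastq")
    it2 = SeqIO.parse(str(path_2), "fastq")
    for r1, r2 in zip(it1, it2):
        rid = r1.id.rsplit("/", 1)[0]
        pairs.append(
            ReadPair(
                id=rid,
                bases_1=str(r1.seq),
                quals_1=np.asarray(r1.letter_annotations["phred_quality"], dtype=np.uint8),
                bases_2=str(r2.seq),
                quals_2=np.asarray(r2.letter_annotations["phred_quality"], dtype=np.uint8),
            )
        )
    return pairs


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
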
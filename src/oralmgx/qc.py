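"""Read quality control and alignment classification.

Implements the shotgun-read cleaning contract used upstream of abundance
profiling: discard pairs with too many ambiguous or low-quality bases,
trim low-quality tails, remove host-derived pairs, and split the mapped
pairs into *unique* reads (one species) and *multiple* reads (two or more
species) — the U / M partition the abundance estimator consumes.

The pipeline applies trim -> filter -> host removal in that fixed order:
the ambiguous/low-quality filter then sees post-trim reads, so a read
whose only bad bases sit in a trimmable tail is rescued rather than
discarded. The order is configurable via :func:`process_reads`.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

_ACGT = frozenset(b"ACGT")


@dataclass
class ReadPair:
    """One paired-end read; qualities are raw Phred scores (not +33)."""

    id: str
    bases_1: str
    quals_1: np.ndarray
    bases_2: str
    quals_2: np.ndarray

    def validate(self) -> None:
        if len(self.bases_1) != len(self.quals_1) or len(self.bases_2) != len(self.quals_2):
            raise ValueError(f"malformed read record {self.id!r}: base/quality length mismatch")


@dataclass
class AlignmentRecord:
    """A (read pair, species) hit; both_mapped means both mates aligned."""

    read_id: str
    species_id: str
    both_mapped: bool = True


@dataclass
class ReadPartition:
    """Unique vs multiple assignment of mapped read pairs.

    ``unique`` maps read id -> the single species it matched (counted by U);
    ``multi`` maps read id -> the frozenset of >=2 species (the {M} sets).
    """

    unique: dict[str, str] = field(default_factory=dict)
    multi: dict[str, frozenset] = field(default_factory=dict)

    def validate(self) -> None:
        overlap = set(self.unique) & set(self.multi)
        if overlap:
            raise ValueError(f"reads in both unique and multi sets: {sorted(overlap)[:5]}")
        for rid, sp in self.multi.items():
            if len(sp) < 2:
                raise ValueError(f"multi read {rid!r} has fewer than 2 species")


@dataclass
class RejectionLog:
    ambiguous: int = 0
    low_quality: int = 0
    short_after_trim: int = 0
    host: int = 0
    kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "ambiguous": self.ambiguous,
            "low_quality": self.low_quality,
            "short_after_trim": self.short_after_trim,
            "host": self.host,
            "kept": self.kept,
        }


def _n_ambiguous(bases: str) -> int:
    return sum(1 for b in bases.encode() if b not in _ACGT)


def filter_reads(pairs, max_ambiguous: int = 5, max_lowq: int = 50, lowq_threshold: int = 2):
    """Discard pairs where either mate has > max_ambiguous non-ACGT bases
    or > max_lowq bases with Phred quality < lowq_threshold.

    Both conditions are tested independently (an OR rule): exceeding either
    one discards the pair. Returns (kept pairs, RejectionLog).
    """
    if max_ambiguous < 0 or max_lowq < 0 or lowq_threshold < 0:
        raise ValueError("filter thresholds must be >= 0")
    kept: list[ReadPair] = []
    log = RejectionLog()
    for pair in pairs:
        pair.validate()
        if (
            _n_ambiguous(pair.bases_1) > max_ambiguous
            or _n_ambiguous(pair.bases_2) > max_ambiguous
        ):
            log.ambiguous += 1
            continue
        if (
            int(np.count_nonzero(pair.quals_1 < lowq_threshold)) > max_lowq
            or int(np.count_nonzero(pair.quals_2 < lowq_threshold)) > max_lowq
        ):
            log.low_quality += 1
            continue
        kept.append(pair)
        log.kept += 1
    return kept, log


def trim_tail(pair: ReadPair, lowq_threshold: int = 2, min_len: int = 30):
    """Trim the maximal suffix of each mate whose qualities are all below
    lowq_threshold; drop the pair if any mate falls below min_len."""
    pair.validate()
    keep = []
    for bases, quals in ((pair.bases_1, pair.quals_1), (pair.bases_2, pair.quals_2)):
        good = np.nonzero(np.asarray(quals) >= lowq_threshold)[0]
        n_keep = 0 if len(good) == 0 else int(good[-1]) + 1
        if n_keep < min_len:
            return None
        keep.append((bases[:n_keep], np.asarray(quals)[:n_keep]))
    return ReadPair(pair.id, keep[0][0], keep[0][1], keep[1][0], keep[1][1])


def trim_tails(pairs, lowq_threshold: int = 2, min_len: int = 30):
    """Apply :func:`trim_tail` to a stream; returns (kept, n_dropped)."""
    kept, dropped = [], 0
    for pair in pairs:
        trimmed = trim_tail(pair, lowq_threshold=lowq_threshold, min_len=min_len)
        if trimmed is None:
            dropped += 1
        else:
            kept.append(trimmed)
    return kept, dropped


class ExactSubstringMatcher:
    """Host/reference matcher contract: a mate matches when its bases occur
    verbatim in the reference sequence. External-aligner adapters may
    substitute anything with the same ``__call__(bases) -> bool`` shape."""

    def __init__(self, reference: str):
        if not reference:
            raise ValueError("host matcher configured with an empty reference")
        self.reference = reference

    def __call__(self, bases: str) -> bool:
        return bases in self.reference


def remove_host_reads(pairs, host_reference, matcher=None):
    """Remove pairs with either mate matching the host reference.

    Returns (kept pairs, set of removed read ids, fraction removed).
    """
    if matcher is None:
        if host_reference is None:
            raise ValueError("host removal requires a host reference or matcher")
        matcher = ExactSubstringMatcher(host_reference)
    kept, removed = [], set()
    total = 0
    for pair in pairs:
        total += 1
        if matcher(pair.bases_1) or matcher(pair.bases_2):
            removed.add(pair.id)
        else:
            kept.append(pair)
    fraction = len(removed) / total if total else 0.0
    return kept, removed, fraction


def process_reads(
    pairs,
    host_reference=None,
    max_ambiguous: int = 5,
    max_lowq: int = 50,
    lowq_threshold: int = 2,
    min_len: int = 30,
    trim_first: bool = True,
):
    """Full QC: trim -> filter -> host removal (or filter first if
    ``trim_first`` is False). Returns (clean pairs, RejectionLog)."""
    if trim_first:
        pairs, n_short = trim_tails(pairs, lowq_threshold=lowq_threshold, min_len=min_len)
        pairs, log = filter_reads(pairs, max_ambiguous, max_lowq, lowq_threshold)
    else:
        pairs, log = filter_reads(pairs, max_ambiguous, max_lowq, lowq_threshold)
        pairs, n_short = trim_tails(pairs, lowq_threshold=lowq_threshold, min_len=min_len)
        log.kept -= n_short
    log.short_after_trim = n_short
    if host_reference is not None:
        pairs, removed, _ = remove_host_reads(pairs, host_reference)
        log.host = len(removed)
        log.kept = len(pairs)
    return pairs, log


def classify_alignments(records) -> ReadPartition:
    """Partition alignment records into unique vs multiple assignments.

    Pairs lacking a both-ends-mapped hit are excluded entirely; duplicate
    (read, species) records are deduplicated.
    """
    by_read: dict[str, set] = defaultdict(set)
    any_unmatched: dict[str, bool] = defaultdict(bool)
    for rec in records:
        if rec.both_mapped:
            by_read[rec.read_id].add(rec.species_id)
        else:
            any_unmatched[rec.read_id] = True
    partition = ReadPartition()
    for rid, species in by_read.items():
        if len(species) == 1:
            partition.unique[rid] = next(iter(species))
        else:
            partition.multi[rid] = frozenset(species)
    partition.validate()
    return partition


class ExactReferenceAligner:
    """Align error-free reads against a reference genome set by exact
    substring matching; a pair maps to species S when both mates occur in
    S's genome. A k-mer index accelerates full-length mates."""

    def __init__(self, genomes: dict[str, str], read_length: int | None = None):
        self.genomes = genomes
        self.read_length = read_length
        self._index: dict[str, frozenset] | None = None
        if read_length is not None:
            index: dict[str, set] = defaultdict(set)
            for sid, seq in genomes.items():
                for i in range(len(seq) - read_length + 1):
                    index[seq[i : i + read_length]].add(sid)
            self._index = {k: frozenset(v) for k, v in index.items()}

    def _mate_hits(self, bases: str) -> frozenset:
        if self._index is not None and len(bases) == self.read_length:
            return self._index.get(bases, frozenset())
        return frozenset(sid for sid, seq in self.genomes.items() if bases in seq)

    def align(self, pairs) -> list[AlignmentRecord]:
        records = []
        for pair in pairs:
            hits = self._mate_hits(pair.bases_1) & self._mate_hits(pair.bases_2)
            if hits:
                for sid in sorted(hits):
                    records.append(AlignmentRecord(pair.id, sid, both_mapped=True))
            else:
                records.append(AlignmentRecord(pair.id, "", both_mapped=False))
        return records
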
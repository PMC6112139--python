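"""Prealignment: FASTQ reading, adapter trimming, filtering, collapsing.

Reads are trimmed of their 3' adapter, filtered on length / quality /
alphabet, collapsed into unique sequences, and the per-sample observed
counts merged into one matrix of :class:`UniqueRead` records.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

_DNA_N = set("ACGTN")


@dataclass(frozen=True)
class PreprocessConfig:
    adapter: str = "none"
    min_length: int = 16
    max_length: int = 40
    min_quality: int = 20
    adapter_min_overlap: int = 8
    adapter_max_mismatch_rate: float = 0.1
    require_adapter: bool = False

    def __post_init__(self) -> None:
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


@dataclass
class UniqueRead:
    """A collapsed read: one distinct sequence with per-sample counts."""

    sequence: str
    counts: tuple[int, ...]
    total: int = field(init=False)

    def __post_init__(self) -> None:
        self.total = sum(self.counts)


@dataclass
class TrimResult:
    sequence: str | None  # None when rejected
    reason: str | None = None  # too_short / too_long / low_quality / bad_alphabet / no_adapter
    adapter_found: bool = False

    @property
    def kept(self) -> bool:
        return self.sequence is not None


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (sequence, quality) from a FASTQ or FASTQ.GZ file (phred+33)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not qual and seq:
                raise ValueError(f"truncated FASTQ record in {path}")
            if not header.startswith("@") or not plus.startswith("+"):
                raise ValueError(f"malformed FASTQ record in {path}: {header!r}")
            yield seq.upper(), qual


def _find_adapter(sequence: str, config: PreprocessConfig) -> int | None:
    """Leftmost start of a suffix-anchored adapter-prefix match, or None.

    At start ``i`` the adapter prefix of length min(len(adapter), len-i)
    is compared; a hit needs overlap >= adapter_min_overlap and mismatch
    rate <= adapter_max_mismatch_rate.
    """
    adapter = config.adapter
    n = len(sequence)
    for i in range(0, n - config.adapter_min_overlap + 1):
        overlap = min(len(adapter), n - i)
        if overlap < config.adapter_min_overlap:
            break
        allowed = int(config.adapter_max_mismatch_rate * overlap)
        mism = 0
        for a, b in zip(sequence[i : i + overlap], adapter[:overlap]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        if mism <= allowed:
            return i
    return None


def trim_adapter(
    read_sequence: str, qualities: str, config: PreprocessConfig
) -> TrimResult:
    """Trim the 3' adapter and apply length / quality / alphabet filters."""
    read_sequence = read_sequence.upper()
    if set(read_sequence) - _DNA_N:
        return TrimResult(None, "bad_alphabet")
    if qualities:
        mean_q = sum(ord(c) - 33 for c in qualities) / len(qualities)
        if mean_q < config.min_quality:
            return TrimResult(None, "low_quality")
    trimmed = read_sequence
    found = False
    if config.adapter and config.adapter != "none":
        pos = _find_adapter(read_sequence, config)
        if pos is not None:
            trimmed = read_sequence[:pos]
            found = True
        elif config.require_adapter:
            return TrimResult(None, "no_adapter")
    if "N" in trimmed:
        return TrimResult(None, "bad_alphabet", adapter_found=found)
    if len(trimmed) < config.min_length:
        return TrimResult(None, "too_short", adapter_found=found)
    if len(trimmed) > config.max_length:
        return TrimResult(None, "too_long", adapter_found=found)
    return TrimResult(trimmed, adapter_found=found)


def preprocess_fastq(
    path: str | Path, config: PreprocessConfig
) -> tuple[list[str], dict[str, int]]:
    """Trim and filter one FASTQ file; return kept sequences and stats."""
    kept: list[str] = []
    stats = {
        "input": 0,
        "kept": 0,
        "too_short": 0,
        "too_long": 0,
        "low_quality": 0,
        "bad_alphabet": 0,
        "no_adapter": 0,
    }
    for seq, qual in read_fastq(path):
        stats["input"] += 1
        result = trim_adapter(seq, qual, config)
        if result.kept:
            kept.append(result.sequence)
            stats["kept"] += 1
        else:
            stats[result.reason] += 1
    return kept, stats


def collapse_reads(
    streams: Sequence[Iterable[str]], sample_ids: Sequence[str]
) -> list[UniqueRead]:
    """Collapse per-sample read streams into unique reads with count vectors.

    Output is sorted by total count descending, then sequence ascending,
    so identical inputs in any stream order collapse identically.
    """
    if len(streams) != len(sample_ids):
        raise ValueError("one stream per sample id required")
    n = len(sample_ids)
    table: dict[str, list[int]] = {}
    for col, stream in enumerate(streams):
        for seq in stream:
            row = table.get(seq)
            if row is None:
                row = table[seq] = [0] * n
            row[col] += 1
    reads = [UniqueRead(seq, tuple(c)) for seq, c in table.items()]
    reads.sort(key=lambda r: (-r.total, r.sequence))
    return reads


def write_collapsed_tsv(
    reads: Sequence[UniqueRead], sample_ids: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\t" + "\t".join(sample_ids) + "\n")
        for r in reads:
            fh.write(r.sequence + "\t" + "\t".join(map(str, r.counts)) + "\n")
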
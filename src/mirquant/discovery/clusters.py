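"""Genome placement of unmapped reads, clustering, and stable ranges.

Reads are placed by exact match over both strands; reads failing a
full-length match may still be placed by an exact prefix match with up to
``max_soft_clip_3p`` trailing bases clipped, which keeps reads carrying
short non-templated 3' tails inside their cluster (their tail bases then
count against the genome in the per-position tallies). Reads matching more
than ``max_loci`` locations are discarded as repetitive.

The stable range of a cluster is the longest contiguous run of positions
whose count-weighted major symbol — the covering reads' bases plus an
"absent" symbol for non-covering reads — is a base with probability at or
above the threshold (default 0.8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from mirquant.libraries import SequenceLibrary
from mirquant.preprocess import UniqueRead

logger = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ClusterConfig:
    stable_threshold: float = 0.8
    max_cluster_gap: int = 10
    flank_near: int = 10
    flank_far: int = 70
    min_total_reads: int = 10
    min_distinct_sequences: int = 3
    max_loci: int = 20
    max_soft_clip_3p: int = 3

    def __post_init__(self) -> None:
        if not (0.5 < self.stable_threshold <= 1.0):
            raise ValueError("stable_threshold must be in (0.5, 1]")


@dataclass(frozen=True)
class Placement:
    chrom: str
    strand: str  # "+" | "-"
    start: int  # 0-based half-open genomic span of the FULL read
    end: int
    read: UniqueRead
    clipped_3p: int = 0  # trailing bases not matching the genome


@dataclass
class ClusterMember:
    offset: int  # 0-based offset of the read 5' end in assembled_sequence
    read: UniqueRead


@dataclass
class ReadCluster:
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    members: list[ClusterMember]
    assembled_sequence: str = ""
    stable_start: int = -1  # 0-based half-open on assembled_sequence
    stable_end: int = -1
    head_unstable_length: int = 0
    tail_unstable_length: int = 0
    rejected_reason: str | None = None

    @property
    def total_read_count(self) -> int:
        return sum(m.read.total for m in self.members)

    @property
    def sequence_type_count(self) -> int:
        return len({m.read.sequence for m in self.members})

    @property
    def stable_sequence(self) -> str:
        return self.assembled_sequence[self.stable_start : self.stable_end]

    @property
    def cluster_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.strand})"


def _occurrences(haystack: str, needle: str, limit: int) -> list[int]:
    hits: list[int] = []
    pos = haystack.find(needle)
    while pos >= 0 and len(hits) < limit:
        hits.append(pos)
        pos = haystack.find(needle, pos + 1)
    return hits


def map_unmapped_to_genome(
    unique_reads: Sequence[UniqueRead],
    genome: SequenceLibrary,
    config: ClusterConfig | None = None,
) -> list[Placement]:
    """Exact-match placements of every read over both genome strands."""
    config = config or ClusterConfig()
    placements: list[Placement] = []
    for read in unique_reads:
        seq = read.sequence
        hits: list[Placement] = []
        for clip in range(0, config.max_soft_clip_3p + 1):
            body = seq[: len(seq) - clip]
            if len(body) < 12:
                break
            for chrom, chrom_seq in genome.entries:
                for pos in _occurrences(chrom_seq, body, config.max_loci + 1):
                    hits.append(
                        Placement(
                            chrom=chrom,
                            strand="+",
                            start=pos,
                            end=pos + len(seq),
                            read=read,
                            clipped_3p=clip,
                        )
                    )
                rc_body = revcomp(body)
                for pos in _occurrences(chrom_seq, rc_body, config.max_loci + 1):
                    # on "-" the clipped tail hangs off the genomic start
                    hits.append(
                        Placement(
                            chrom=chrom,
                            strand="-",
                            start=pos - clip,
                            end=pos + len(body),
                            read=read,
                            clipped_3p=clip,
                        )
                    )
            if hits:
                break  # smallest clip wins; do not also place harder-clipped
        if len(hits) > config.max_loci:
            logger.debug("read %s... discarded as repetitive (%d loci)", seq[:12], len(hits))
            continue
        placements.extend(hits)
    placements.sort(key=lambda p: (p.chrom, p.strand, p.start, p.end, p.read.sequence))
    return placements


def build_clusters(
    placements: Sequence[Placement],
    genome: SequenceLibrary,
    config: ClusterConfig | None = None,
) -> list[ReadCluster]:
    """Merge same-chrom/strand placements within the gap into clusters."""
    config = config or ClusterConfig()
    ordered = sorted(
        placements, key=lambda p: (p.chrom, p.strand, p.start, p.end, p.read.sequence)
    )
    clusters: list[ReadCluster] = []
    group: list[Placement] = []

    def flush() -> None:
        if not group:
            return
        chrom, strand = group[0].chrom, group[0].strand
        start = min(p.start for p in group)
        end = max(p.end for p in group)
        chrom_seq = dict(genome.entries)[chrom]
        g0, g1 = max(start, 0), min(end, len(chrom_seq))
        assembled = chrom_seq[g0:g1]
        if strand == "-":
            assembled = revcomp(assembled)
        members = []
        for p in group:
            if strand == "+":
                offset = p.start - g0
            else:
                offset = g1 - p.end
            members.append(ClusterMember(offset=offset, read=p.read))
        members.sort(key=lambda m: (m.offset, m.read.sequence))
        clusters.append(
            ReadCluster(
                chrom=chrom,
                strand=strand,
                start=g0,
                end=g1,
                members=members,
                assembled_sequence=assembled,
            )
        )
        group.clear()

    for p in ordered:
        if group and (
            p.chrom != group[0].chrom
            or p.strand != group[0].strand
            or p.start - max(q.end for q in group) > config.max_cluster_gap
        ):
            flush()
        group.append(p)
    flush()
    return clusters


def compute_stable_range(
    cluster: ReadCluster, config: ClusterConfig | None = None
) -> ReadCluster:
    """Per-position major-symbol tally and longest qualifying run.

    Weights are read counts. A position qualifies when the heaviest base
    reaches ``stable_threshold`` of the total cluster read count and is not
    outweighed by absence. Ties between runs go to the leftmost.
    """
    config = config or ClusterConfig()
    if not cluster.members:
        raise ValueError("cluster has no members")
    span = len(cluster.assembled_sequence)
    total = cluster.total_read_count
    qualifies = [False] * span
    covered = [False] * span
    for pos in range(span):
        weights = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}
        cover_weight = 0
        for m in cluster.members:
            i = pos - m.offset
            if 0 <= i < len(m.read.sequence):
                weights[m.read.sequence[i]] += m.read.total
                cover_weight += m.read.total
        if cover_weight == 0:
            continue
        covered[pos] = True
        top = max(weights.values())
        absent = total - cover_weight
        if top >= absent and top / total >= config.stable_threshold:
            qualifies[pos] = True

    best_start = best_len = 0
    run_start = None
    for pos in range(span + 1):
        if pos < span and qualifies[pos]:
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            if pos - run_start > best_len:
                best_start, best_len = run_start, pos - run_start
            run_start = None
    if best_len == 0:
        cluster.rejected_reason = "no_stable_range"
        return cluster
    cluster.stable_start = best_start
    cluster.stable_end = best_start + best_len
    cluster.head_unstable_length = sum(covered[:best_start])
    cluster.tail_unstable_length = sum(covered[best_start + best_len :])
    return cluster
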
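"""Precursor extraction and the full per-cluster feature vector.

Two fold windows model the stable range as the 5p or the 3p arm of a
candidate hairpin (near/far flanks, defaults 10/70 nt); the window with
the lower pseudo-MFE wins (ties prefer the 5p model). Compositional
features are count-weighted over the reads covering each flank position
-3..-1 and +1..+6 of the stable range; positions covered by no read yield
0 with a companion ``*_covered`` indicator of 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

from mirquant.discovery.clusters import ClusterConfig, ReadCluster, revcomp
from mirquant.discovery.fold import StructureStats, fold, structure_stats
from mirquant.libraries import SequenceLibrary

logger = logging.getLogger(__name__)

_HEAD_POSITIONS = (-3, -2, -1)
_TAIL_POSITIONS = (1, 2, 3, 4, 5, 6)


def _feature_names() -> list[str]:
    names = [
        "count_bindings_in_miRNA",
        "exactMatchRatio",
        "pair_state_No",
        "pair_state_Yes",
        "mFE",
    ]
    names += [f"head_minus{-p}_TemplateNucleotide_percentage" for p in _HEAD_POSITIONS]
    names += [
        "hairpin_count",
        "stem_length",
        "distanceToloop",
        "percentage_PairedInMiRNA",
        "headUnstableLength",
        "tailUnstableLength",
    ]
    names += [f"tail_plus{p}_TemplateNucleotide_percentage" for p in _TAIL_POSITIONS]
    names += [f"tail_plus{p}_A_percentage" for p in (1, 2, 3)]
    # raw expressed-base composition (distinct from the non-templated-A features)
    for p in _HEAD_POSITIONS:
        names += [f"head_minus{-p}_base_{b}_percentage" for b in "ATCG"]
    for p in _TAIL_POSITIONS:
        names += [f"tail_plus{p}_base_{b}_percentage" for b in "ATCG"]
    names += [
        "binding_count",
        "armType_5p",
        "armType_3p",
        "armType_loop",
        "interiorLoopCount",
        "sequence_type_count",
        "total_read_count",
    ]
    names += [f"head_minus{-p}_covered" for p in _HEAD_POSITIONS]
    names += [f"tail_plus{p}_covered" for p in _TAIL_POSITIONS]
    return names


FEATURE_NAMES: tuple[str, ...] = tuple(_feature_names())


@dataclass
class PrecursorCandidate:
    sequence: str
    structure: str
    mfe: float
    arm_of_stable_range: str  # "5p" | "3p" | "loop"
    pair_state: bool
    window_start: int  # assembled-sequence coordinate of window position 0
    stats: StructureStats


def _window_sequence(
    cluster: ReadCluster, genome: SequenceLibrary, w0: int, w1: int
) -> tuple[str, int]:
    """Fetch assembled-coordinate window [w0, w1), strand-aware.

    Returns the sequence and the (possibly truncated) window start.
    """
    chrom_seq = dict(genome.entries)[cluster.chrom]
    if cluster.strand == "+":
        g0 = cluster.start + w0
        g1 = cluster.start + w1
        t0, t1 = max(g0, 0), min(g1, len(chrom_seq))
        if (t0, t1) != (g0, g1):
            logger.warning("fold window truncated at chromosome bounds")
        return chrom_seq[t0:t1], t0 - cluster.start
    g1 = cluster.end - w0
    g0 = cluster.end - w1
    t0, t1 = max(g0, 0), min(g1, len(chrom_seq))
    if (t0, t1) != (g0, g1):
        logger.warning("fold window truncated at chromosome bounds")
    return revcomp(chrom_seq[t0:t1]), cluster.end - t1


def extract_precursor(
    cluster: ReadCluster,
    genome: SequenceLibrary,
    config: ClusterConfig | None = None,
    folder: Callable[[str], tuple[str, float]] = fold,
) -> PrecursorCandidate:
    """Fold both arm models of the stable range; keep the lower-MFE one."""
    config = config or ClusterConfig()
    if cluster.stable_start < 0:
        raise ValueError("stable range not computed for cluster")
    s, e = cluster.stable_start, cluster.stable_end
    windows = [
        (s - config.flank_near, e + config.flank_far),  # stable range as 5p arm
        (s - config.flank_far, e + config.flank_near),  # stable range as 3p arm
    ]
    candidates: list[PrecursorCandidate] = []
    for w0, w1 in windows:
        seq, wstart = _window_sequence(cluster, genome, w0, w1)
        structure, mfe = folder(seq)
        ws, we = s - wstart, e - wstart
        ws, we = max(ws, 0), min(we, len(seq))
        stats = structure_stats(structure, ws, we)
        pair_state = _pair_state(cluster, wstart, stats)
        candidates.append(
            PrecursorCandidate(
                sequence=seq,
                structure=structure,
                mfe=mfe,
                arm_of_stable_range=stats.arm_type,
                pair_state=pair_state,
                window_start=wstart,
                stats=stats,
            )
        )
    # strictly lower MFE wins; tie prefers the 5p-arm model (candidates[0])
    return candidates[1] if candidates[1].mfe < candidates[0].mfe else candidates[0]


def _pair_state(
    cluster: ReadCluster, window_start: int, stats: StructureStats
) -> bool:
    """True iff some member read sits on the arm opposite the stable range."""
    loop_start, loop_end = stats.terminal_loop
    s, e = cluster.stable_start - window_start, cluster.stable_end - window_start
    stable_mid = (s + e) / 2
    loop_mid = (loop_start + loop_end) / 2
    for m in cluster.members:
        mid = m.offset + len(m.read.sequence) / 2 - window_start
        # read must be clear of the stable range and across the loop from it
        if s <= mid < e:
            continue
        m_start = m.offset - window_start
        m_end = m_start + len(m.read.sequence)
        if m_end > s and m_start < e:
            continue  # overlaps the stable range
        if (stable_mid - loop_mid) * (mid - loop_mid) < 0:
            return True
    return False


def compositional_features(
    cluster: ReadCluster, genome: SequenceLibrary
) -> dict[str, float]:
    """Flank composition, unstable lengths, and read-level summaries."""
    if cluster.stable_start < 0:
        raise ValueError("stable range not computed for cluster")
    chrom_seq = dict(genome.entries)[cluster.chrom]
    features: dict[str, float] = {}

    def genome_base(pos: int) -> str | None:
        # assembled coordinate -> genomic, strand-aware
        if cluster.strand == "+":
            g = cluster.start + pos
            if 0 <= g < len(chrom_seq):
                return chrom_seq[g]
        else:
            g = cluster.end - 1 - pos
            if 0 <= g < len(chrom_seq):
                return revcomp(chrom_seq[g])
        return None

    def flank(pos: int, prefix: str, with_nta: bool) -> None:
        gbase = genome_base(pos)
        cover = 0
        base_w = {"A": 0, "T": 0, "C": 0, "G": 0}
        template = 0
        for m in cluster.members:
            i = pos - m.offset
            if 0 <= i < len(m.read.sequence):
                w = m.read.total
                cover += w
                b = m.read.sequence[i]
                if b in base_w:
                    base_w[b] += w
                if gbase is not None and b == gbase:
                    template += w
        if cover:
            features[f"{prefix}_TemplateNucleotide_percentage"] = template / cover
            for b in "ATCG":
                features[f"{prefix}_base_{b}_percentage"] = base_w[b] / cover
            if with_nta:
                nta_a = base_w["A"] if gbase != "A" else 0
                features[f"{prefix}_A_percentage"] = nta_a / cover
            features[f"{prefix}_covered"] = 1.0
        else:
            features[f"{prefix}_TemplateNucleotide_percentage"] = 0.0
            for b in "ATCG":
                features[f"{prefix}_base_{b}_percentage"] = 0.0
            if with_nta:
                features[f"{prefix}_A_percentage"] = 0.0
            features[f"{prefix}_covered"] = 0.0

    for p in _HEAD_POSITIONS:
        flank(cluster.stable_start + p, f"head_minus{-p}", with_nta=False)
    for p in _TAIL_POSITIONS:
        flank(cluster.stable_end + p - 1, f"tail_plus{p}", with_nta=p <= 3)

    total = cluster.total_read_count
    stable_seq = cluster.stable_sequence
    exact = sum(
        m.read.total for m in cluster.members if m.read.sequence == stable_seq
    )
    features["exactMatchRatio"] = exact / total if total else 0.0
    features["headUnstableLength"] = float(cluster.head_unstable_length)
    features["tailUnstableLength"] = float(cluster.tail_unstable_length)
    features["sequence_type_count"] = float(cluster.sequence_type_count)
    features["total_read_count"] = float(total)
    return features


def compute_features(
    cluster: ReadCluster,
    genome: SequenceLibrary,
    config: ClusterConfig | None = None,
    folder: Callable[[str], tuple[str, float]] = fold,
) -> tuple[dict[str, float], PrecursorCandidate]:
    """Full feature vector (FEATURE_NAMES order) for one stable cluster."""
    config = config or ClusterConfig()
    candidate = extract_precursor(cluster, genome, config, folder=folder)
    stats = candidate.stats
    features = compositional_features(cluster, genome)
    features["count_bindings_in_miRNA"] = float(stats.count_bindings_in_mirna)
    features["percentage_PairedInMiRNA"] = stats.percentage_paired_in_mirna
    features["pair_state_No"] = 0.0 if candidate.pair_state else 1.0
    features["pair_state_Yes"] = 1.0 if candidate.pair_state else 0.0
    features["mFE"] = candidate.mfe
    features["hairpin_count"] = float(stats.hairpin_count)
    features["stem_length"] = float(stats.stem_length)
    features["distanceToloop"] = float(stats.distance_to_loop)
    features["binding_count"] = float(stats.binding_count)
    features["interiorLoopCount"] = float(stats.interior_loop_count)
    for arm in ("5p", "3p", "loop"):
        features[f"armType_{arm}"] = 1.0 if stats.arm_type == arm else 0.0
    ordered = {name: features[name] for name in FEATURE_NAMES}
    return ordered, candidate


def candidate_filter(
    clusters: Sequence[ReadCluster], config: ClusterConfig | None = None
) -> tuple[list[ReadCluster], list[tuple[ReadCluster, str]]]:
    """Keep clusters with enough reads and distinct sequences."""
    config = config or ClusterConfig()
    passing: list[ReadCluster] = []
    rejected: list[tuple[ReadCluster, str]] = []
    for cluster in clusters:
        if cluster.rejected_reason:
            rejected.append((cluster, cluster.rejected_reason))
        elif cluster.total_read_count < config.min_total_reads:
            rejected.append((cluster, "min_reads"))
        elif cluster.sequence_type_count < config.min_distinct_sequences:
            rejected.append((cluster, "min_sequences"))
        else:
            passing.append(cluster)
    return passing, rejected


def write_cluster_table(
    rows: Sequence[tuple[ReadCluster, dict[str, float]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "cluster_id\tchrom\tstrand\tstart\tend\tstable_start\tstable_end\t"
            + "\t".join(FEATURE_NAMES)
            + "\n"
        )
        for cluster, features in rows:
            fh.write(
                f"{cluster.cluster_id}\t{cluster.chrom}\t{cluster.strand}\t"
                f"{cluster.start}\t{cluster.end}\t{cluster.stable_start}\t"
                f"{cluster.stable_end}\t"
                + "\t".join(f"{features[n]:.6g}" for n in FEATURE_NAMES)
                + "\n"
            )
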
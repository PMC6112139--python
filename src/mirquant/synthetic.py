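"""Synthetic fixtures with the statistical structure the pipeline assumes.

Generates genomes with planted hairpin loci (arm + loop + reverse-complement
arm), negative loci (unstructured transcripts, CCA-capped tRNA-like
sequences, duplicated loci for multimapping tests), and reads that emulate
miRNA biogenesis: tight 5' starts, ragged 3' ends, non-templated A/U tails,
planted A->G editing fractions, adapters, and sequencing errors. All
randomness flows from one integer seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from mirquant.discovery.clusters import revcomp
from mirquant.libraries import SequenceLibrary

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    genome_length: int = 100_000
    n_mirna_loci: int = 20
    n_negative_loci: int = 40
    n_duplicate_loci: int = 1  # negative loci planted twice (multimapping)
    n_samples: int = 1
    reads_per_locus: tuple[int, int] = (20, 80)  # uniform inclusive range
    arm_length: int = 22
    loop_length: tuple[int, int] = (8, 12)
    locus_spacing: tuple[int, int] = (60, 140)
    # miRNA-style end model: tight 5', ragged 3'
    start_jitter: dict[int, float] = field(
        default_factory=lambda: {0: 0.86, -1: 0.05, 1: 0.05, -2: 0.02, 2: 0.02}
    )
    end_jitter: dict[int, float] = field(
        default_factory=lambda: {0: 0.40, -1: 0.20, 1: 0.20, -2: 0.10, 2: 0.10}
    )
    nta_tails: dict[str, float] = field(
        default_factory=lambda: {
            "": 0.50, "A": 0.16, "T": 0.12, "AA": 0.10, "TT": 0.06, "AAA": 0.04, "TTT": 0.02,
        }
    )
    # negative-style end model: ragged at both ends, no tails
    negative_jitter: dict[int, float] = field(
        default_factory=lambda: {-3: 0.1, -2: 0.15, -1: 0.15, 0: 0.2, 1: 0.15, 2: 0.15, 3: 0.1}
    )
    editing_sites: tuple[tuple[int, int, float], ...] = ()  # (mirna locus idx, 1-based pos, fraction)
    adapter: str = "AGATCGGAAGAGC"
    error_rate: float = 0.0

    def validated(self) -> "SimulationConfig":
        for dist in (self.start_jitter, self.end_jitter, self.nta_tails, self.negative_jitter):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("categorical probabilities must sum to 1")
        return self


@dataclass
class LocusTruth:
    locus_id: str
    label: str  # "mirna" | "negative"
    subtype: str  # "hairpin" | "fragment" | "trna_like" | "duplicate"
    chrom: str
    start: int  # 0-based half-open span of the canonical (mature) sequence
    end: int
    strand: str
    canonical_sequence: str
    precursor_start: int = -1
    precursor_end: int = -1
    arm: str = "5p"  # which hairpin arm the mature sits on
    editing: tuple[tuple[int, float], ...] = ()  # (1-based mature pos, fraction)


def _random_seq(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _draw(rng: random.Random, dist: dict) -> object:
    r = rng.random()
    acc = 0.0
    for key, p in dist.items():
        acc += p
        if r < acc:
            return key
    return key  # float round-off: last key


def make_genome(config: SimulationConfig) -> tuple[SequenceLibrary, list[LocusTruth]]:
    """Plant hairpin and negative loci into a random background genome."""
    config = config.validated()
    rng = random.Random(config.seed)
    editing_by_locus: dict[int, list[tuple[int, float]]] = {}
    for locus_idx, pos, frac in config.editing_sites:
        editing_by_locus.setdefault(locus_idx, []).append((pos, frac))

    pieces: list[str] = []
    truth: list[LocusTruth] = []
    cursor = 0

    def advance(seq: str) -> int:
        nonlocal cursor
        spacer = _random_seq(rng, rng.randint(*config.locus_spacing))
        pieces.append(spacer)
        cursor += len(spacer)
        start = cursor
        pieces.append(seq)
        cursor += len(seq)
        return start

    for i in range(config.n_mirna_loci):
        mature = list(_random_seq(rng, config.arm_length))
        for pos1, _ in editing_by_locus.get(i, ()):
            if pos1 <= len(mature) - 2:  # editable positions must hold an A
                mature[pos1 - 1] = "A"
        mature = "".join(mature)
        loop = _random_seq(rng, rng.randint(*config.loop_length))
        arm = "5p" if rng.random() < 0.5 else "3p"
        arm5 = mature if arm == "5p" else revcomp(mature)
        precursor = arm5 + loop + revcomp(arm5)
        pstart = advance(precursor)
        if arm == "5p":
            mstart, mend = pstart, pstart + len(arm5)
        else:
            mstart, mend = pstart + len(arm5) + len(loop), pstart + len(precursor)
        truth.append(
            LocusTruth(
                locus_id=f"syn-mir-{i}",
                label="mirna",
                subtype="hairpin",
                chrom="chr1",
                start=mstart,
                end=mend,
                strand="+",
                canonical_sequence=mature,
                precursor_start=pstart,
                precursor_end=pstart + len(precursor),
                arm=arm,
                editing=tuple(editing_by_locus.get(i, ())),
            )
        )

    duplicated: list[str] = []
    for i in range(config.n_negative_loci):
        subtype = ("fragment", "trna_like")[i % 2]
        if subtype == "trna_like":
            seq = _random_seq(rng, rng.randint(60, 75)) + "CCA"
            canonical = seq[-25:]  # reads cover the 3' fragment
        else:
            seq = _random_seq(rng, rng.randint(24, 30))
            canonical = seq
        start = advance(seq)
        cstart = start + (len(seq) - len(canonical))
        truth.append(
            LocusTruth(
                locus_id=f"syn-neg-{i}",
                label="negative",
                subtype=subtype,
                chrom="chr1",
                start=cstart,
                end=cstart + len(canonical),
                strand="+",
                canonical_sequence=canonical,
            )
        )
        if i < config.n_duplicate_loci:
            duplicated.append(canonical)

    for j, seq in enumerate(duplicated):
        start = advance(seq)
        truth.append(
            LocusTruth(
                locus_id=f"syn-dup-{j}",
                label="negative",
                subtype="duplicate",
                chrom="chr1",
                start=start,
                end=start + len(seq),
                strand="+",
                canonical_sequence=seq,
            )
        )

    pieces.append(_random_seq(rng, rng.randint(*config.locus_spacing)))
    cursor += len(pieces[-1])
    if cursor < config.genome_length:
        pieces.append(_random_seq(rng, config.genome_length - cursor))
    genome_seq = "".join(pieces)
    genome = SequenceLibrary(
        name="synthetic_genome", kind="genome", entries=[("chr1", genome_seq)]
    )
    return genome, truth


def make_reads(
    genome: SequenceLibrary,
    truth: Sequence[LocusTruth],
    config: SimulationConfig,
    with_adapter: bool = True,
) -> dict[str, list[tuple[str, str]]]:
    """Per-sample (sequence, quality) reads from every locus."""
    config = config.validated()
    rng = random.Random(config.seed + 1)
    chrom_seq = dict(genome.entries)["chr1"]
    samples = {f"S{k + 1}": [] for k in range(config.n_samples)}
    for locus in truth:
        for sample_reads in samples.values():
            n_reads = rng.randint(*config.reads_per_locus)
            for _ in range(n_reads):
                if locus.label == "mirna":
                    d5 = _draw(rng, config.start_jitter)
                    d3 = _draw(rng, config.end_jitter)
                    tail = _draw(rng, config.nta_tails)
                else:
                    d5 = _draw(rng, config.negative_jitter)
                    d3 = _draw(rng, config.negative_jitter)
                    tail = ""
                start = locus.start + d5
                end = locus.end + d3
                body = list(chrom_seq[start:end])
                for pos1, fraction in locus.editing:
                    # editing positions are mature-relative; never the last 2 nt
                    idx = (locus.start + pos1 - 1) - start
                    if 0 <= idx < len(body) - 2 and rng.random() < fraction:
                        if body[idx] == "A":
                            body[idx] = "G"
                seq = "".join(body) + tail
                if config.error_rate > 0:
                    seq = "".join(
                        rng.choice([b2 for b2 in _BASES if b2 != b])
                        if rng.random() < config.error_rate
                        else b
                        for b in seq
                    )
                if with_adapter:
                    seq += config.adapter
                sample_reads.append((seq, "I" * len(seq)))
    return samples


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            fh.write(f"@read_{i}\n{seq}\n+\n{qual}\n")


def make_libraries(
    truth: Sequence[LocusTruth], genome: SequenceLibrary
) -> dict[str, SequenceLibrary]:
    """Mature/hairpin/ncRNA libraries matching the planted loci."""
    chrom_seq = dict(genome.entries)["chr1"]
    mature, hairpin, ncrna = [], [], []
    for locus in truth:
        if locus.label == "mirna":
            mature.append((locus.locus_id, locus.canonical_sequence))
            hairpin.append(
                (
                    locus.locus_id + "-hairpin",
                    chrom_seq[locus.precursor_start : locus.precursor_end],
                )
            )
        else:
            ncrna.append((locus.locus_id, locus.canonical_sequence))
    return {
        "mature_miRNA": SequenceLibrary("syn_mature", "mature_miRNA", mature),
        "hairpin": SequenceLibrary("syn_hairpin", "hairpin", hairpin),
        "ncRNA": SequenceLibrary("syn_ncrna", "ncRNA", ncrna),
    }


def write_truth_table(truth: Sequence[LocusTruth], path: str | Path) -> None:
    rows = []
    for t in truth:
        rows.append(
            {
                "locus_id": t.locus_id,
                "label": t.label,
                "subtype": t.subtype,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "canonical_sequence": t.canonical_sequence,
                "precursor_start": t.precursor_start,
                "precursor_end": t.precursor_end,
                "arm": t.arm,
                "editing": ";".join(f"{p}:{f}" for p, f in t.editing),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def make_labeled_clusters(config: SimulationConfig):
    """End-to-end: genome -> reads -> clusters -> features -> labels.

    Returns a :class:`mirquant.model.LabeledDataset` plus the clusters and
    genome used, for downstream inspection. Clusters overlapping no truth
    locus are dropped (and counted in the returned report).
    """
    from mirquant.discovery import (
        build_clusters,
        compute_features,
        compute_stable_range,
        map_unmapped_to_genome,
    )
    from mirquant.model import LabeledDataset
    from mirquant.preprocess import collapse_reads

    genome, truth = make_genome(config)
    samples = make_reads(genome, truth, config, with_adapter=False)
    streams = [[seq for seq, _ in reads] for reads in samples.values()]
    unique = collapse_reads(streams, list(samples))
    placements = map_unmapped_to_genome(unique, genome)
    clusters = build_clusters(placements, genome)
    intervals = [(t.start, t.end, t.label) for t in truth]

    rows: list[dict[str, float]] = []
    labels: list[int] = []
    kept_clusters = []
    dropped = 0
    for cluster in clusters:
        cluster = compute_stable_range(cluster)
        if cluster.rejected_reason:
            dropped += 1
            continue
        label = None
        for start, end, lab in intervals:
            if cluster.start < end and start < cluster.end:
                label = lab
                break
        if label is None:
            dropped += 1
            continue
        features, _ = compute_features(cluster, genome)
        rows.append(features)
        labels.append(1 if label == "mirna" else 0)
        kept_clusters.append(cluster)
    dataset = LabeledDataset(
        features=pd.DataFrame(rows), labels=np.asarray(labels, dtype=int)
    )
    return dataset, kept_clusters, genome, truth, dropped
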
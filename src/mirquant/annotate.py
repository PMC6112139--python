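"""Cascade annotation of unique reads against the sequence libraries.

Reads are assigned at most once, walking the library cascade in a fixed
order: spike-in (optional), exact mature miRNA, hairpin, mature tRNA,
precursor tRNA, snoRNA, rRNA, other ncRNA, mRNA, and finally an
isomiR-tolerant mature miRNA pass (<=1 internal mismatch, <=3 non-templated
3' bases, bounded 5' offset). The tolerant pass runs last so that isomiR
greediness cannot steal reads from other RNA classes. "Canonical" means an
exact full-length match to a mature library sequence; per-miRNA rows whose
canonical fraction falls below a threshold are flagged and zeroed in the
primary table.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from mirquant.libraries import SequenceLibrary
from mirquant.preprocess import UniqueRead

logger = logging.getLogger(__name__)

#: cascade stages in assignment order; mature miRNA gets an exact pass early
#: and a tolerant isomiR pass last
CASCADE_ORDER = (
    "spike_in",
    "mature_exact",
    "hairpin",
    "tRNA_mature",
    "tRNA_precursor",
    "snoRNA",
    "rRNA",
    "ncRNA",
    "mRNA",
    "mature_isomir",
)

MANDATORY_KINDS = ("mature_miRNA",)


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class AnnotateConfig:
    max_mismatch: int = 1
    max_tail: int = 3
    offset5_min: int = -2
    offset5_max: int = 2
    max_trim3: int = 5
    canonical_ratio_threshold: float = 0.1


@dataclass
class AlignmentAssignment:
    read: UniqueRead
    library_kind: str
    target_id: str
    pass_type: str  # "exact" or "isomir"
    mismatch_positions: list[tuple[int, str, str]] = field(default_factory=list)
    soft_clipped_3p: str = ""
    offset_5p: int = 0  # read start minus canonical start (negative = upstream)
    trim_3p: int = 0  # templated 3' truncation relative to the mature end
    ambiguous: bool = False


@dataclass
class MiRNACountRow:
    mirna_id: str
    canonical_count: tuple[int, ...]
    total_count: tuple[int, ...]
    rpm: tuple[float, ...] = ()
    canonical_rpm: tuple[float, ...] = ()
    filtered: bool = False

    @property
    def canonical_ratio(self) -> float:
        total = sum(self.total_count)
        return sum(self.canonical_count) / total if total else 0.0


class _SubstringIndex:
    """Exact-substring lookup over a library via one concatenated string.

    Entries are sorted by id, so the leftmost hit is the lexicographically
    first matching entry; a second scan detects multi-entry ambiguity.
    """

    def __init__(self, library: SequenceLibrary):
        entries = sorted(library.entries)
        self._ids = [eid for eid, _ in entries]
        self._starts: list[int] = []
        parts: list[str] = []
        pos = 0
        for _, seq in entries:
            self._starts.append(pos)
            parts.append(seq)
            pos += len(seq) + 1
        self._big = "#".join(parts)

    def _entry_at(self, pos: int) -> int:
        return bisect.bisect_right(self._starts, pos) - 1

    def find(self, seq: str) -> tuple[str | None, bool]:
        pos = self._big.find(seq)
        if pos < 0:
            return None, False
        idx = self._entry_at(pos)
        # ambiguity: an occurrence inside a different entry
        nxt = pos
        while True:
            nxt = self._big.find(seq, nxt + 1)
            if nxt < 0:
                return self._ids[idx], False
            if self._entry_at(nxt) != idx:
                return self._ids[idx], True


class _IsomirIndex:
    """Seed-and-verify tolerant matcher against mature miRNA sequences.

    Two non-overlapping 8-mer seeds per read guarantee (pigeonhole) that a
    single mismatch cannot hide in both, and the bounded 5' offset plus
    short 3' tail keep at least one seed inside the mature body.
    """

    SEED = 8

    def __init__(self, library: SequenceLibrary, config: AnnotateConfig):
        self.library = library
        self.config = config
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for eid, seq in sorted(library.entries):
            for p in range(len(seq) - self.SEED + 1):
                self._kmers.setdefault(seq[p : p + self.SEED], []).append((eid, p))

    def _verify(
        self, read: str, target_id: str, start: int
    ) -> AlignmentAssignment | None:
        cfg = self.config
        mature = self.library.sequence(target_id)
        if not (cfg.offset5_min <= start <= cfg.offset5_max):
            return None
        mismatches: list[tuple[int, str, str]] = []
        overlap = 0
        tail_start = len(read)
        for i, base in enumerate(read):
            mpos = start + i
            if mpos < 0:
                continue  # 5' extension beyond the mature start
            if mpos >= len(mature):
                tail_start = i
                break
            overlap += 1
            if base != mature[mpos]:
                mismatches.append((i, base, mature[mpos]))
                if len(mismatches) > cfg.max_mismatch:
                    return None
        tail = read[tail_start:]
        if len(tail) > cfg.max_tail:
            return None
        trim = max(0, len(mature) - (start + len(read)))
        if trim > cfg.max_trim3:
            return None
        if overlap < len(mature) - cfg.max_trim3 - max(0, start):
            return None
        return AlignmentAssignment(
            read=None,  # filled by caller
            library_kind="mature_miRNA",
            target_id=target_id,
            pass_type="isomir",
            mismatch_positions=mismatches,
            soft_clipped_3p=tail,
            offset_5p=start,
            trim_3p=trim,
        )

    def find(self, read: str) -> AlignmentAssignment | None:
        if len(read) < self.SEED:
            return None
        seed_offsets = [0, self.SEED] if len(read) >= 2 * self.SEED else [0, len(read) - self.SEED]
        candidates: dict[tuple[str, int], AlignmentAssignment] = {}
        for s in seed_offsets:
            if s < 0:
                continue
            for target_id, p in self._kmers.get(read[s : s + self.SEED], ()):
                key = (target_id, p - s)
                if key in candidates:
                    continue
                aln = self._verify(read, target_id, p - s)
                if aln is not None:
                    candidates[key] = aln
        if not candidates:
            return None
        ranked = sorted(
            candidates.values(),
            key=lambda a: (
                len(a.mismatch_positions),
                abs(a.offset_5p),
                len(a.soft_clipped_3p),
                a.trim_3p,
                a.target_id,
            ),
        )
        best = ranked[0]
        if len(ranked) > 1:
            second = ranked[1]
            same_score = (
                len(second.mismatch_positions) == len(best.mismatch_positions)
                and abs(second.offset_5p) == abs(best.offset_5p)
                and len(second.soft_clipped_3p) == len(best.soft_clipped_3p)
                and second.target_id != best.target_id
            )
            if same_score:
                best.ambiguous = True
        return best


@dataclass
class AnnotationResult:
    assignments: list[AlignmentAssignment]
    unmapped: list[UniqueRead]
    sample_ids: tuple[str, ...]

    def class_summary(self) -> dict[str, list[int]]:
        """Reads per RNA class per sample (library kinds + unmapped)."""
        n = len(self.sample_ids)
        summary: dict[str, list[int]] = {}
        for a in self.assignments:
            row = summary.setdefault(a.library_kind, [0] * n)
            for i, c in enumerate(a.read.counts):
                row[i] += c
        row = summary.setdefault("unmapped", [0] * n)
        for r in self.unmapped:
            for i, c in enumerate(r.counts):
                row[i] += c
        return summary


def cascade_annotate(
    unique_reads: Sequence[UniqueRead],
    libraries: dict[str, SequenceLibrary],
    config: AnnotateConfig | None = None,
    sample_ids: Sequence[str] = ("sample",),
) -> AnnotationResult:
    """Assign each unique read to at most one library target."""
    config = config or AnnotateConfig()
    for kind in MANDATORY_KINDS:
        if kind not in libraries:
            raise AnnotationError(f"missing mandatory library: {kind}")
    mature = libraries["mature_miRNA"]

    exact_mature: dict[str, list[str]] = {}
    for eid, seq in mature.entries:
        exact_mature.setdefault(seq, []).append(eid)
    for ids in exact_mature.values():
        ids.sort()

    substr_indexes = {
        kind: _SubstringIndex(lib)
        for kind, lib in libraries.items()
        if kind not in {"mature_miRNA", "genome"}
    }
    isomir_index = _IsomirIndex(mature, config)

    assignments: list[AlignmentAssignment] = []
    unmapped: list[UniqueRead] = []
    for read in unique_reads:
        assignment = None
        for stage in CASCADE_ORDER:
            if stage == "mature_exact":
                ids = exact_mature.get(read.sequence)
                if ids:
                    assignment = AlignmentAssignment(
                        read=read,
                        library_kind="mature_miRNA",
                        target_id=ids[0],
                        pass_type="exact",
                        ambiguous=len(ids) > 1,
                    )
            elif stage == "mature_isomir":
                aln = isomir_index.find(read.sequence)
                if aln is not None:
                    aln.read = read
                    assignment = aln
            else:
                index = substr_indexes.get(stage)
                if index is None:
                    continue
                target, ambiguous = index.find(read.sequence)
                if target is not None:
                    assignment = AlignmentAssignment(
                        read=read,
                        library_kind=stage,
                        target_id=target,
                        pass_type="exact",
                        ambiguous=ambiguous,
                    )
            if assignment is not None:
                break
        if assignment is None:
            unmapped.append(read)
        else:
            assignments.append(assignment)
    return AnnotationResult(
        assignments=assignments, unmapped=unmapped, sample_ids=tuple(sample_ids)
    )


def count_mirnas(
    result: AnnotationResult, mature: SequenceLibrary
) -> list[MiRNACountRow]:
    """Per-miRNA canonical and total count vectors, attributed to parents.

    SNP-variant exact hits count as canonical for their parent; merged-group
    members accumulate under the group entry.
    """
    n = len(result.sample_ids)
    canon: dict[str, list[int]] = {}
    total: dict[str, list[int]] = {}
    for a in result.assignments:
        if a.library_kind != "mature_miRNA":
            continue
        parent = mature.parent(a.target_id)
        trow = total.setdefault(parent, [0] * n)
        for i, c in enumerate(a.read.counts):
            trow[i] += c
        if a.pass_type == "exact":
            crow = canon.setdefault(parent, [0] * n)
            for i, c in enumerate(a.read.counts):
                crow[i] += c
    rows = [
        MiRNACountRow(
            mirna_id=mid,
            canonical_count=tuple(canon.get(mid, [0] * n)),
            total_count=tuple(total[mid]),
        )
        for mid in sorted(total)
    ]
    return rows


def canonical_ratio_filter(
    rows: Sequence[MiRNACountRow], threshold: float = 0.1
) -> list[MiRNACountRow]:
    """Flag miRNAs whose canonical fraction falls below ``threshold``."""
    if not (0.0 <= threshold <= 0.5):
        raise AnnotationError(f"canonical-ratio threshold {threshold} outside [0, 0.5]")
    for row in rows:
        row.filtered = row.canonical_ratio < threshold
    return list(rows)


def compute_rpm(rows: Sequence[MiRNACountRow]) -> list[MiRNACountRow]:
    """Reads-per-million over the unfiltered miRNA-mapped total per sample."""
    if not rows:
        return []
    n = len(rows[0].total_count)
    denom = [0] * n
    for row in rows:
        if row.filtered:
            continue
        for i, c in enumerate(row.total_count):
            denom[i] += c
    for i, d in enumerate(denom):
        if d == 0:
            logger.warning("sample %d has zero miRNA-mapped reads; RPM set to 0", i)
    for row in rows:
        if row.filtered:
            row.rpm = tuple(0.0 for _ in range(n))
            row.canonical_rpm = tuple(0.0 for _ in range(n))
        else:
            row.rpm = tuple(
                c * 1e6 / denom[i] if denom[i] else 0.0
                for i, c in enumerate(row.total_count)
            )
            row.canonical_rpm = tuple(
                c * 1e6 / denom[i] if denom[i] else 0.0
                for i, c in enumerate(row.canonical_count)
            )
    return list(rows)


def write_count_tables(
    rows: Sequence[MiRNACountRow],
    sample_ids: Sequence[str],
    counts_path: str | Path,
    rpm_path: str | Path | None = None,
) -> None:
    """Primary count table (filtered rows zeroed) and optional RPM table."""
    with open(counts_path, "w") as fh:
        fh.write("miRNA\t" + "\t".join(sample_ids) + "\n")
        for row in rows:
            counts = (0,) * len(sample_ids) if row.filtered else row.total_count
            fh.write(row.mirna_id + "\t" + "\t".join(map(str, counts)) + "\n")
    if rpm_path is not None:
        with open(rpm_path, "w") as fh:
            fh.write("miRNA\t" + "\t".join(sample_ids) + "\n")
            for row in rows:
                fh.write(
                    row.mirna_id + "\t" + "\t".join(f"{x:.4f}" for x in row.rpm) + "\n"
                )


def write_summary(result: AnnotationResult, path: str | Path) -> None:
    summary = result.class_summary()
    with open(path, "w") as fh:
        fh.write("class\t" + "\t".join(result.sample_ids) + "\n")
        for cls in sorted(summary):
            fh.write(cls + "\t" + "\t".join(map(str, summary[cls])) + "\n")


def write_unmapped_fasta(unmapped: Sequence[UniqueRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, read in enumerate(unmapped):
            fh.write(f">unmapped_{i}_x{read.total}\n{read.sequence}\n")
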
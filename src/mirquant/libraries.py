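"""Annotation library construction, validation, and curation.

A :class:`SequenceLibrary` is the unit every alignment stage consumes: a
named, validated collection of DNA sequences of one RNA kind. Curation
steps implemented here: RNA->DNA alphabet mapping, CCA-tailing of tRNAs,
SNP expansion of mature miRNA libraries, and merging of near-identical
mature miRNAs into slash-joined groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

LIBRARY_KINDS = frozenset(
    {
        "mature_miRNA",
        "hairpin",
        "tRNA_mature",
        "tRNA_precursor",
        "snoRNA",
        "rRNA",
        "ncRNA",
        "mRNA",
        "spike_in",
        "genome",
    }
)

_DNA = set("ACGT")
_DNA_N = set("ACGTN")


class LibraryError(ValueError):
    """Validation or parse failure while building a library."""


@dataclass(frozen=True)
class SnpAnnotation:
    """A known SNP inside a mature miRNA sequence.

    ``position`` is 1-based on the mature sequence.
    """

    mirna_id: str
    position: int
    ref: str
    alt: str
    frequency: float = 0.0

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise LibraryError(f"SNP for {self.mirna_id}: ref equals alt ({self.ref})")
        if not (0.0 <= self.frequency <= 1.0):
            raise LibraryError(f"SNP frequency out of [0,1]: {self.frequency}")
        if self.position < 1:
            raise LibraryError(f"SNP position must be 1-based positive: {self.position}")


@dataclass(frozen=True)
class MergeGroup:
    representative_id: str
    member_ids: tuple[str, ...]


@dataclass
class SequenceLibrary:
    """An indexed, validated collection of sequences of one RNA kind."""

    name: str
    kind: str
    entries: list[tuple[str, str]] = field(default_factory=list)
    #: maps variant entry ids (e.g. SNP-expanded) back to a parent id for counting
    parent_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LIBRARY_KINDS:
            raise LibraryError(f"unknown library kind: {self.kind!r}")
        self._validate()
        self._index = {eid: seq for eid, seq in self.entries}

    def _validate(self) -> None:
        seen: set[str] = set()
        alphabet = _DNA_N if self.kind == "genome" else _DNA
        for eid, seq in self.entries:
            if eid in seen:
                raise LibraryError(f"duplicate id in library {self.name!r}: {eid!r}")
            seen.add(eid)
            if not seq:
                raise LibraryError(f"empty sequence for id {eid!r} in {self.name!r}")
            bad = set(seq) - alphabet
            if bad:
                raise LibraryError(
                    f"invalid characters {sorted(bad)} in entry {eid!r} of {self.name!r}"
                )
            if self.kind == "mature_miRNA" and not (15 <= len(seq) <= 30):
                raise LibraryError(
                    f"mature miRNA {eid!r} length {len(seq)} outside [15, 30]"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self._index

    @property
    def ids(self) -> list[str]:
        return [eid for eid, _ in self.entries]

    def sequence(self, entry_id: str) -> str:
        return self._index[entry_id]

    def parent(self, entry_id: str) -> str:
        """Counting parent of an entry (itself unless it is a variant)."""
        return self.parent_of.get(entry_id, entry_id)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def build_library(fasta_path: str | Path, kind: str, name: str | None = None) -> SequenceLibrary:
    """Read a FASTA file into a validated :class:`SequenceLibrary`.

    RNA alphabet (U) is mapped to DNA (T); duplicate ids are rejected.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise LibraryError(f"FASTA file not found: {path}")
    entries: list[tuple[str, str]] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            entries.append((record.id, _normalize(str(record.seq))))
    except ValueError as exc:  # Biopython's malformed-record error
        raise LibraryError(f"malformed FASTA {path}: {exc}") from exc
    if not entries:
        logger.warning("FASTA %s produced an empty %s library", path, kind)
    return SequenceLibrary(name=name or path.stem, kind=kind, entries=entries)


def write_library(library: SequenceLibrary, fasta_path: str | Path, width: int = 70) -> None:
    """Write a library as FASTA wrapped at ``width`` columns."""
    with open(fasta_path, "w") as fh:
        for eid, seq in library.entries:
            fh.write(f">{eid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def add_cca_to_trnas(library: SequenceLibrary) -> SequenceLibrary:
    """Append "CCA" to the 3' end of every entry of a tRNA library.

    Not idempotent: callers must apply it exactly once.
    """
    if library.kind not in {"tRNA_mature", "tRNA_precursor"}:
        raise LibraryError(
            f"add_cca_to_trnas requires a tRNA library, got kind {library.kind!r}"
        )
    return SequenceLibrary(
        name=library.name,
        kind=library.kind,
        entries=[(eid, seq + "CCA") for eid, seq in library.entries],
        parent_of=dict(library.parent_of),
    )


def expand_snps(
    library: SequenceLibrary, snps: Sequence[SnpAnnotation]
) -> SequenceLibrary:
    """Add one variant entry per SNP, keeping originals untouched.

    Variant ids are ``<mirna_id>.SNP<n>`` with ``n`` counting SNPs per
    parent in input order; variants map back to the parent for counting.
    """
    index = {eid: seq for eid, seq in library.entries}
    counters: dict[str, int] = {}
    new_entries = list(library.entries)
    parent_of = dict(library.parent_of)
    for snp in snps:
        if snp.mirna_id not in index:
            raise LibraryError(f"SNP references unknown miRNA {snp.mirna_id!r}")
        seq = index[snp.mirna_id]
        if snp.position > len(seq):
            raise LibraryError(
                f"SNP position {snp.position} beyond sequence of {snp.mirna_id!r}"
            )
        found = seq[snp.position - 1]
        if found != _normalize(snp.ref):
            raise LibraryError(
                f"SNP ref mismatch for {snp.mirna_id} pos {snp.position}: "
                f"expected {snp.ref}, sequence has {found}"
            )
        counters[snp.mirna_id] = counters.get(snp.mirna_id, 0) + 1
        vid = f"{snp.mirna_id}.SNP{counters[snp.mirna_id]}"
        vseq = seq[: snp.position - 1] + _normalize(snp.alt) + seq[snp.position :]
        new_entries.append((vid, vseq))
        parent_of[vid] = snp.mirna_id
    return SequenceLibrary(
        name=library.name, kind=library.kind, entries=new_entries, parent_of=parent_of
    )


def _padded_hamming(a: str, b: str, wildcard_padding: bool = True) -> int:
    """Hamming distance after 3'-padding the shorter to the longer length.

    Padding positions are wildcards (distance 0) so a pure 3' length
    difference does not count as mismatch.
    """
    if len(a) > len(b):
        a, b = b, a
    d = sum(1 for x, y in zip(a, b) if x != y)
    if not wildcard_padding:
        d += len(b) - len(a)
    return d


def merge_similar_mirnas(
    library: SequenceLibrary, max_distance: int = 1
) -> tuple[SequenceLibrary, list[MergeGroup]]:
    """Collapse near-identical mature miRNAs into slash-joined group entries.

    Two sequences belong together when their padded Hamming distance is
    <= ``max_distance``; grouping is the transitive closure, so the result
    is independent of input order (up to the representative naming rule:
    members joined by "/" in input order, representative = lexicographically
    first member id).
    """
    if library.kind != "mature_miRNA":
        raise LibraryError("merge_similar_mirnas requires a mature_miRNA library")
    n = len(library.entries)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(n):
        for j in range(i + 1, n):
            if _padded_hamming(library.entries[i][1], library.entries[j][1]) <= max_distance:
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    new_entries: list[tuple[str, str]] = []
    parent_of = dict(library.parent_of)
    merge_groups: list[MergeGroup] = []
    for root in sorted(groups):
        members = groups[root]  # input order within group
        ids = [library.entries[i][0] for i in members]
        if len(members) == 1:
            new_entries.append(library.entries[members[0]])
            continue
        joined = "/".join(ids)
        rep = min(ids)
        # group sequence: the longest member (others are within distance 1)
        seq = max((library.entries[i][1] for i in members), key=len)
        new_entries.append((joined, seq))
        for eid in ids:
            parent_of[eid] = joined
        merge_groups.append(MergeGroup(representative_id=rep, member_ids=tuple(ids)))

    merged = SequenceLibrary(
        name=library.name, kind=library.kind, entries=new_entries, parent_of=parent_of
    )
    return merged, merge_groups


def read_snp_table(path: str | Path) -> list[SnpAnnotation]:
    """Read a TSV of (mirna_id, position, ref, alt, frequency)."""
    snps = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("mirna_id\t"):
                continue
            fields = line.split("\t")
            snps.append(
                SnpAnnotation(
                    mirna_id=fields[0],
                    position=int(fields[1]),
                    ref=fields[2],
                    alt=fields[3],
                    frequency=float(fields[4]) if len(fields) > 4 else 0.0,
                )
            )
    return snps


def write_merge_report(groups: Iterable[MergeGroup], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("representative_id\tmember_ids\n")
        for g in groups:
            fh.write(f"{g.representative_id}\t{';'.join(g.member_ids)}\n")
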
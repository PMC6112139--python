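"""isomiR classification and miRTop-style GFF3 serialization.

Every miRNA-assigned read is re-expressed relative to its precursor: a
1-based inclusive coordinate span, a compact CIGAR, and an ordered list of
variant tags (iso_5p, iso_3p, iso_add3p, iso_snp). The CIGAR dialect is
run-length "nM" for matches with a substituted position written as the
read's base letter (e.g. "13MA8M"). Non-templated 3' additions stay inside
the read span but never extend ``end`` past the precursor: coordinates are
clamped and the tail is carried by the Read attribute + iso_add3p tag, so
``apply_cigar(precursor[start..end]) + tail`` reconstructs the read.

Sign convention for iso_5p: positive = the read starts upstream (5') of the
canonical start.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from mirquant.annotate import AlignmentAssignment, AnnotationResult
from mirquant.libraries import SequenceLibrary

logger = logging.getLogger(__name__)

_UID_ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"


class GFF3Error(ValueError):
    pass


@dataclass
class IsomiRRecord:
    precursor_id: str
    mature_id: str
    start: int  # 1-based inclusive on the precursor
    end: int
    type: str  # "ref_miRNA" | "isomiR"
    variant_tags: tuple[str, ...]
    cigar: str
    read_sequence: str
    expression: tuple[int, ...]
    filter: str = "Pass"
    uid: str = field(default="")

    def __post_init__(self) -> None:
        if not self.uid:
            self.uid = sequence_uid(self.read_sequence)
        if self.type == "ref_miRNA" and self.variant_tags:
            raise GFF3Error("ref_miRNA records must carry no variant tags")
        if self.end < self.start:
            raise GFF3Error(f"end < start for {self.mature_id}")


def sequence_uid(sequence: str) -> str:
    """Deterministic, collision-free UID for a read sequence (base-62)."""
    value = len(sequence)
    for base in sequence:
        value = value * 5 + "ACGTN".index(base) + 1
    digits = []
    while value:
        value, r = divmod(value, 62)
        digits.append(_UID_ALPHABET[r])
    return "iso-" + "".join(reversed(digits))


def classify_isomir(
    assignment: AlignmentAssignment,
    mature_id: str,
    mature_sequence: str,
    precursor_id: str,
    precursor_sequence: str,
    mature_offset: int,
) -> IsomiRRecord:
    """Build the precursor-relative record for one aligned read.

    ``mature_offset`` is the 0-based position of the mature sequence inside
    the precursor; the precursor must contain the mature exactly there.
    """
    read = assignment.read.sequence
    expression = tuple(assignment.read.counts)
    if (
        precursor_sequence[mature_offset : mature_offset + len(mature_sequence)]
        != mature_sequence
    ):
        return IsomiRRecord(
            precursor_id=precursor_id,
            mature_id=mature_id,
            start=1,
            end=1,
            type="isomiR",
            variant_tags=("iso_snp",),
            cigar="",
            read_sequence=read,
            expression=expression,
            filter="Reject:precursor_mature_mismatch",
        )
    start0 = mature_offset + assignment.offset_5p  # precursor pos of read[0]
    if start0 < 0:
        return IsomiRRecord(
            precursor_id=precursor_id,
            mature_id=mature_id,
            start=1,
            end=1,
            type="isomiR",
            variant_tags=("iso_5p:+%d" % -assignment.offset_5p,),
            cigar="",
            read_sequence=read,
            expression=expression,
            filter="Reject:outside_precursor",
        )
    tail = assignment.soft_clipped_3p
    body_len = len(read) - len(tail)
    # split the mature-overhanging tail into a templated extension and a
    # genuinely non-templated addition by walking the precursor downstream
    ext = 0
    while (
        ext < len(tail)
        and start0 + body_len + ext < len(precursor_sequence)
        and tail[ext] == precursor_sequence[start0 + body_len + ext]
    ):
        ext += 1
    added = tail[ext:]
    end0 = start0 + body_len + ext  # exclusive

    tags: list[str] = []
    if assignment.offset_5p != 0:
        tags.append("iso_5p:%+d" % -assignment.offset_5p)
    if assignment.trim_3p > 0:
        tags.append("iso_3p:-%d" % assignment.trim_3p)
    elif ext > 0:
        tags.append("iso_3p:+%d" % ext)
    if added:
        tags.append("iso_add3p:+%d" % len(added))
    if assignment.mismatch_positions:
        tags.append("iso_snp")

    cigar = _build_cigar(read[: body_len + ext], precursor_sequence, start0)
    return IsomiRRecord(
        precursor_id=precursor_id,
        mature_id=mature_id,
        start=start0 + 1,
        end=end0,
        type="ref_miRNA" if not tags else "isomiR",
        variant_tags=tuple(tags),
        cigar=cigar,
        read_sequence=read,
        expression=expression,
    )


def _build_cigar(aligned_read: str, precursor: str, start0: int) -> str:
    parts: list[str] = []
    run = 0
    for i, base in enumerate(aligned_read):
        if base == precursor[start0 + i]:
            run += 1
        else:
            if run:
                parts.append(f"{run}M")
                run = 0
            parts.append(base)
    if run:
        parts.append(f"{run}M")
    return "".join(parts)


def apply_cigar(cigar: str, reference_slice: str) -> str:
    """Replay a CIGAR over the precursor slice it spans."""
    out: list[str] = []
    pos = 0
    for op in re.finditer(r"(\d+)M|([ACGTN])", cigar):
        if op.group(1):
            n = int(op.group(1))
            out.append(reference_slice[pos : pos + n])
            pos += n
        else:
            out.append(op.group(2))
            pos += 1
    if pos != len(reference_slice):
        raise GFF3Error(
            f"cigar {cigar!r} spans {pos} nt but slice has {len(reference_slice)}"
        )
    return "".join(out)


def reconstruct_read(record: IsomiRRecord, precursor_sequence: str) -> str:
    """Rebuild the read from precursor coordinates + declared additions."""
    body = apply_cigar(
        record.cigar, precursor_sequence[record.start - 1 : record.end]
    )
    added = 0
    for tag in record.variant_tags:
        if tag.startswith("iso_add3p:+"):
            added = int(tag.split("+")[1])
    return body + (record.read_sequence[-added:] if added else "")


def build_precursor_map(
    mature: SequenceLibrary, hairpin: SequenceLibrary
) -> dict[str, tuple[str, int]]:
    """Locate each mature sequence inside a hairpin entry (first hit wins)."""
    mapping: dict[str, tuple[str, int]] = {}
    hairpins = sorted(hairpin.entries)
    for mid, mseq in mature.entries:
        for hid, hseq in hairpins:
            pos = hseq.find(mseq)
            if pos >= 0:
                mapping[mid] = (hid, pos)
                break
    return mapping


def records_from_annotation(
    result: AnnotationResult,
    mature: SequenceLibrary,
    hairpin: SequenceLibrary,
) -> list[IsomiRRecord]:
    """Classify every miRNA-assigned read of an annotation run."""
    precursor_map = build_precursor_map(mature, hairpin)
    records: list[IsomiRRecord] = []
    for a in result.assignments:
        if a.library_kind != "mature_miRNA":
            continue
        located = precursor_map.get(a.target_id)
        if located is None:
            logger.warning("no precursor found for %s; record skipped", a.target_id)
            continue
        hid, offset = located
        records.append(
            classify_isomir(
                a,
                mature_id=a.target_id,
                mature_sequence=mature.sequence(a.target_id),
                precursor_id=hid,
                precursor_sequence=hairpin.sequence(hid),
                mature_offset=offset,
            )
        )
    return records


_ATTR_KEYS = ("UID", "Read", "Name", "Parent", "Variant", "Cigar", "Expression", "Filter")


def write_gff3(
    records: Iterable[IsomiRRecord],
    path: str | Path,
    sample_ids: Sequence[str] = ("sample",),
    comments: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("## COLDATA: " + ",".join(sample_ids) + "\n")
        fh.write(
            "## ATTRIBUTES: " + ",".join(_ATTR_KEYS) + "\n"
        )
        for comment in comments:
            fh.write("# " + comment + "\n")
        for rec in records:
            if rec.end < rec.start or rec.start < 1:
                logger.warning("refusing record with invalid coordinates: %s", rec)
                continue
            variant = ",".join(rec.variant_tags) if rec.variant_tags else "NA"
            attrs = (
                f"UID={rec.uid}; Read={rec.read_sequence}; Name={rec.mature_id}; "
                f"Parent={rec.precursor_id}; Variant={variant}; Cigar={rec.cigar}; "
                f"Expression={','.join(map(str, rec.expression))}; Filter={rec.filter}"
            )
            fh.write(
                "\t".join(
                    [
                        rec.precursor_id,
                        "mirquant",
                        rec.type,
                        str(rec.start),
                        str(rec.end),
                        ".",
                        "+",
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def parse_gff3(path: str | Path) -> tuple[list[IsomiRRecord], tuple[str, ...]]:
    """Strict parser for the dialect written by :func:`write_gff3`."""
    records: list[IsomiRRecord] = []
    sample_ids: tuple[str, ...] = ()
    with open(path) as fh:
        first = fh.readline()
        if first.strip() != "##gff-version 3":
            raise GFF3Error("missing ##gff-version 3 header")
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("## COLDATA:"):
                sample_ids = tuple(line.split(":", 1)[1].strip().split(","))
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFF3Error(f"expected 9 columns, got {len(cols)}: {line!r}")
            attrs: dict[str, str] = {}
            for item in cols[8].split("; "):
                key, _, value = item.partition("=")
                attrs[key] = value
            missing = [k for k in _ATTR_KEYS if k not in attrs]
            if missing:
                raise GFF3Error(f"missing attributes {missing} in line {line!r}")
            variant = attrs["Variant"]
            tags = () if variant == "NA" else tuple(variant.split(","))
            records.append(
                IsomiRRecord(
                    precursor_id=cols[0],
                    mature_id=attrs["Name"],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    type=cols[2],
                    variant_tags=tags,
                    cigar=attrs["Cigar"],
                    read_sequence=attrs["Read"],
                    expression=tuple(int(x) for x in attrs["Expression"].split(",")),
                    filter=attrs["Filter"],
                    uid=attrs["UID"],
                )
            )
    return records, sample_ids
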
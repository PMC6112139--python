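"""A-to-I editing detection over miRNA-assigned reads.

Editing is read out as an A->G change at an adenosine of the mature
sequence. Candidate sites pass four exclusion criteria before testing:

1. positions confusable with miRNA-family or SNP A/G differences
   (blacklist);
2. miRNAs located in repeat elements (blacklist);
3. miRNAs whose canonical-sequence RPM is below 1 in every sample;
4. miRNAs whose A->G-switched mature sequence, trimmed of its last two 3'
   bases, exact-matches more than one genomic locus.

Surviving sites get a one-sided binomial test against a sequencing-error
rate with Benjamini-Hochberg correction; a site is significant when the
adjusted p-value passes alpha and the editing fraction reaches the minimum
in at least one sample. The binomial/BH combination stands in for an
unpublished procedure and both rates are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from scipy import stats

from mirquant.annotate import AnnotationResult, MiRNACountRow
from mirquant.libraries import SequenceLibrary

logger = logging.getLogger(__name__)

EXCLUSION_REASONS = ("family_or_snp", "repeat_element", "low_canonical_rpm", "multimapping")


class EditingError(ValueError):
    pass


@dataclass
class EditingSite:
    mirna_id: str
    position: int  # 1-based on the mature sequence; reference base is A
    a_counts: tuple[int, ...]
    g_counts: tuple[int, ...]
    other_counts: tuple[int, ...]
    excluded_by: frozenset[str] = frozenset()
    p_value: float = 1.0
    adjusted_p: float = 1.0
    significant: bool = False

    @property
    def a_count(self) -> int:
        return sum(self.a_counts)

    @property
    def g_count(self) -> int:
        return sum(self.g_counts)

    @property
    def other_count(self) -> int:
        return sum(self.other_counts)

    @property
    def coverage(self) -> int:
        return self.a_count + self.g_count + self.other_count

    @property
    def editing_fraction(self) -> float:
        denom = self.a_count + self.g_count
        return self.g_count / denom if denom else 0.0

    def sample_fraction(self, i: int) -> float:
        denom = self.a_counts[i] + self.g_counts[i]
        return self.g_counts[i] / denom if denom else 0.0


@dataclass
class EditingBlacklists:
    family_snp_sites: frozenset[tuple[str, int]] = frozenset()
    repeat_mirnas: frozenset[str] = frozenset()


def tally_sites(
    result: AnnotationResult, mature: SequenceLibrary
) -> list[EditingSite]:
    """Per-(miRNA, A-position) base tallies from internal mismatches only.

    Non-templated 3' tails never contribute; SNP-variant exact hits are
    skipped because their divergence is a known polymorphism, not editing.
    """
    n = len(result.sample_ids)
    # (mirna, pos0) -> [a per sample, g per sample, other per sample]
    table: dict[tuple[str, int], list[list[int]]] = {}
    for a in result.assignments:
        if a.library_kind != "mature_miRNA":
            continue
        if mature.parent(a.target_id) != a.target_id:
            continue  # SNP-expanded variant: known polymorphism
        mseq = mature.sequence(a.target_id)
        mismatch_at = {mp + a.offset_5p: base for mp, base, _ in a.mismatch_positions}
        body_len = len(a.read.sequence) - len(a.soft_clipped_3p)
        lo = max(a.offset_5p, 0)
        hi = min(len(mseq), a.offset_5p + body_len)
        for mp in range(lo, hi):
            if mseq[mp] != "A":
                continue
            base = mismatch_at.get(mp, "A")
            row = table.get((a.target_id, mp))
            if row is None:
                row = table[(a.target_id, mp)] = [[0] * n, [0] * n, [0] * n]
            slot = 0 if base == "A" else 1 if base == "G" else 2
            for i, c in enumerate(a.read.counts):
                row[slot][i] += c
    sites = [
        EditingSite(
            mirna_id=mid,
            position=pos0 + 1,
            a_counts=tuple(row[0]),
            g_counts=tuple(row[1]),
            other_counts=tuple(row[2]),
        )
        for (mid, pos0), row in sorted(table.items())
    ]
    return sites


def count_genome_loci(genome: SequenceLibrary, probe: str, cap: int = 2) -> int:
    """Exact-match occurrence count of ``probe`` over both genome strands.

    Stops early at ``cap`` occurrences (only ">1" matters to criterion 4).
    """
    comp = str.maketrans("ACGTN", "TGCAN")
    probes = [probe, probe.translate(comp)[::-1]]
    found = 0
    for _, chrom_seq in genome.entries:
        for p in probes:
            pos = chrom_seq.find(p)
            while pos >= 0:
                found += 1
                if found >= cap:
                    return found
                pos = chrom_seq.find(p, pos + 1)
    return found


def apply_exclusions(
    sites: Sequence[EditingSite],
    blacklists: EditingBlacklists,
    rows: Sequence[MiRNACountRow],
    mature: SequenceLibrary,
    genome: SequenceLibrary | None = None,
    check_multimapping: bool = True,
) -> list[EditingSite]:
    """Mark each site with the exclusion criteria it violates (order-free)."""
    if check_multimapping and genome is None:
        raise EditingError("criterion 4 (multimapping) requires a genome library")
    canonical_rpm = {row.mirna_id: row.canonical_rpm for row in rows}
    out: list[EditingSite] = []
    multimap_cache: dict[tuple[str, int], bool] = {}
    for site in sites:
        reasons: set[str] = set()
        if (site.mirna_id, site.position) in blacklists.family_snp_sites:
            reasons.add("family_or_snp")
        if site.mirna_id in blacklists.repeat_mirnas:
            reasons.add("repeat_element")
        rpm = canonical_rpm.get(site.mirna_id, ())
        if not rpm or max(rpm) < 1.0:
            reasons.add("low_canonical_rpm")
        if check_multimapping:
            key = (site.mirna_id, site.position)
            hit = multimap_cache.get(key)
            if hit is None:
                mseq = mature.sequence(site.mirna_id)
                switched = (
                    mseq[: site.position - 1] + "G" + mseq[site.position :]
                )
                probe = switched[:-2]  # trim the last two 3' nucleotides
                hit = count_genome_loci(genome, probe) > 1
                multimap_cache[key] = hit
            if hit:
                reasons.add("multimapping")
        out.append(
            EditingSite(
                mirna_id=site.mirna_id,
                position=site.position,
                a_counts=site.a_counts,
                g_counts=site.g_counts,
                other_counts=site.other_counts,
                excluded_by=frozenset(reasons),
            )
        )
    return out


def test_significance(
    sites: Sequence[EditingSite],
    error_rate: float = 0.001,
    alpha: float = 0.05,
    min_fraction: float = 0.01,
) -> list[EditingSite]:
    """One-sided binomial test vs ``error_rate`` with BH correction.

    Excluded or zero-coverage sites are skipped (p = 1, not significant).
    """
    testable = [
        i
        for i, s in enumerate(sites)
        if not s.excluded_by and (s.a_count + s.g_count) > 0
    ]
    pvals = []
    for i in testable:
        s = sites[i]
        n = s.a_count + s.g_count
        pvals.append(float(stats.binom.sf(s.g_count - 1, n, error_rate)))
    adjusted = (
        stats.false_discovery_control(pvals, method="bh") if pvals else []
    )
    out = list(sites)
    for j, i in enumerate(testable):
        s = sites[i]
        n_samples = len(s.a_counts)
        fraction_ok = any(
            s.sample_fraction(k) >= min_fraction for k in range(n_samples)
        )
        out[i] = EditingSite(
            mirna_id=s.mirna_id,
            position=s.position,
            a_counts=s.a_counts,
            g_counts=s.g_counts,
            other_counts=s.other_counts,
            excluded_by=s.excluded_by,
            p_value=pvals[j],
            adjusted_p=float(adjusted[j]),
            significant=bool(adjusted[j] <= alpha and fraction_ok),
        )
    return out


def read_blacklists(
    family_snp_path: str | Path | None = None,
    repeat_path: str | Path | None = None,
) -> EditingBlacklists:
    family: set[tuple[str, int]] = set()
    repeats: set[str] = set()
    if family_snp_path:
        with open(family_snp_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("mirna_id\t"):
                    continue
                mid, pos = line.split("\t")[:2]
                family.add((mid, int(pos)))
    if repeat_path:
        with open(repeat_path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    repeats.add(line.split("\t")[0])
    return EditingBlacklists(
        family_snp_sites=frozenset(family), repeat_mirnas=frozenset(repeats)
    )


def write_site_report(
    sites: Sequence[EditingSite], sample_ids: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        frac_cols = "\t".join(f"fraction_{s}" for s in sample_ids)
        fh.write(
            "mirna_id\tposition\tpooled_fraction\t"
            + frac_cols
            + "\ta_count\tg_count\tother_count\texcluded_by\tp\tadjusted_p\tsignificant\n"
        )
        for s in sites:
            fracs = "\t".join(
                f"{s.sample_fraction(i):.6f}" for i in range(len(sample_ids))
            )
            fh.write(
                f"{s.mirna_id}\t{s.position}\t{s.editing_fraction:.6f}\t{fracs}\t"
                f"{s.a_count}\t{s.g_count}\t{s.other_count}\t"
                f"{';'.join(sorted(s.excluded_by)) or '.'}\t"
                f"{s.p_value:.4g}\t{s.adjusted_p:.4g}\t{int(s.significant)}\n"
            )
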
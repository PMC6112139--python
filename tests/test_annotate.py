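import numpy as np
import pytest
from scipy import stats as sps

from _oracles import isomir_scan_brute
from mirquant.annotate import (
    AnnotationError,
    canonical_ratio_filter,
    cascade_annotate,
    compute_rpm,
    count_mirnas,
    MiRNACountRow,
)
from mirquant.libraries import SequenceLibrary
from mirquant.preprocess import UniqueRead


def run(reads, libraries, samples=("s1",), config=None):
    return cascade_annotate(reads, libraries, config=config, sample_ids=samples)


class TestCascade:
    def test_exact_mature(self, mature_library):
        read = UniqueRead(mature_library.sequence("mirA"), (4,))
        result = run([read], {"mature_miRNA": mature_library})
        (a,) = result.assignments
        assert (a.library_kind, a.pass_type, a.target_id) == ("mature_miRNA", "exact", "mirA")

    def test_trna_cca_suffix_wins_over_isomir(self, mature_library, trna_library):
        trna_seq = trna_library.sequence("trna1")
        read = UniqueRead(trna_seq[-22:], (1,))  # ends with CCA
        result = run([read], {"mature_miRNA": mature_library, "tRNA_mature": trna_library})
        (a,) = result.assignments
        assert a.library_kind == "tRNA_mature" and a.target_id == "trna1"

    def test_isomir_with_tail(self, mature_library):
        read = UniqueRead(mature_library.sequence("mirA") + "AA", (2,))
        result = run([read], {"mature_miRNA": mature_library})
        (a,) = result.assignments
        assert a.pass_type == "isomir"
        assert a.soft_clipped_3p == "AA" and a.offset_5p == 0
        # oracle agreement
        hits = isomir_scan_brute(read.sequence, dict(mature_library.entries))
        assert ("mirA", 0, 0, "AA", 0) in hits

    def test_isomir_matches_exhaustive_oracle(self, mature_library):
        matures = dict(mature_library.entries)
        cases = []
        mirA = matures["mirA"]
        cases.append(mirA[2:] + "T")          # 5' offset +2 with a tail
        cases.append("GG" + mirA)             # 5' offset -2
        cases.append(mirA[:10] + "C" + mirA[11:])  # internal mismatch
        cases.append(mirA[:-3])               # 3' trim
        cases.append(mirA[:10])               # too short a fragment: no hit
        for seq in cases:
            result = run([UniqueRead(seq, (1,))], {"mature_miRNA": SequenceLibrary(
                "m", "mature_miRNA", list(matures.items()))})
            hits = isomir_scan_brute(seq, matures)
            if hits:
                assert len(result.assignments) == 1
                a = result.assignments[0]
                assert (a.target_id, a.offset_5p) in {(t, o) for t, o, *_ in hits}
            else:
                assert result.assignments == []

    def test_partition_invariant(self, mature_library, trna_library):
        reads = [
            UniqueRead(mature_library.sequence("mirA"), (1,)),
            UniqueRead(trna_library.sequence("trna1")[-20:], (1,)),
            UniqueRead("GCGCGCGCATATATATGCGCGC", (1,)),
        ]
        result = run(reads, {"mature_miRNA": mature_library, "tRNA_mature": trna_library})
        assert len(result.assignments) + len(result.unmapped) == len(reads)
        assigned = {a.read.sequence for a in result.assignments}
        unmapped = {r.sequence for r in result.unmapped}
        assert assigned.isdisjoint(unmapped)

    def test_cascade_monotonic_in_later_libraries(self, mature_library, trna_library):
        mrna = SequenceLibrary("mrna", "mRNA", [("tx1", "GCGCGCGCATATATATGCGCGCAAAAAA")])
        reads = [
            UniqueRead(mature_library.sequence("mirB"), (1,)),
            UniqueRead(trna_library.sequence("trna2")[-25:], (1,)),
            UniqueRead("GCGCGCGCATATATATGCGCGC", (1,)),
        ]
        base = run(reads, {"mature_miRNA": mature_library, "tRNA_mature": trna_library})
        extended = run(
            reads,
            {"mature_miRNA": mature_library, "tRNA_mature": trna_library, "mRNA": mrna},
        )
        early = {(a.read.sequence, a.target_id) for a in base.assignments}
        late = {(a.read.sequence, a.target_id) for a in extended.assignments}
        assert early <= late
        assert ("GCGCGCGCATATATATGCGCGC", "tx1") in late

    def test_missing_mandatory_library(self):
        with pytest.raises(AnnotationError, match="mandatory"):
            run([], {})

    def test_ambiguous_exact_flagged(self):
        seq = "TGAGGTAGTAGGTTGTATAGTT"
        lib = SequenceLibrary("m", "mature_miRNA", [("a", seq), ("b", seq)])
        result = run([UniqueRead(seq, (1,))], {"mature_miRNA": lib})
        (a,) = result.assignments
        assert a.ambiguous and a.target_id == "a"


class TestCounting:
    def make_rows(self, canonical, total):
        return [
            MiRNACountRow("m%d" % i, (c,), (t,))
            for i, (c, t) in enumerate(zip(canonical, total))
        ]

    def test_ratio_kept(self):
        rows = canonical_ratio_filter(self.make_rows([100], [100]))
        assert not rows[0].filtered and rows[0].canonical_ratio == 1.0

    def test_ratio_filtered(self):
        rows = canonical_ratio_filter(self.make_rows([5], [100]))
        assert rows[0].filtered and rows[0].canonical_ratio == pytest.approx(0.05)

    def test_threshold_range(self):
        with pytest.raises(AnnotationError):
            canonical_ratio_filter([], threshold=0.6)
        canonical_ratio_filter([], threshold=0.0)
        canonical_ratio_filter([], threshold=0.5)

    def test_low_threshold_accepts(self):
        rows = canonical_ratio_filter(self.make_rows([5], [100]), threshold=0.05)
        assert not rows[0].filtered

    def test_rpm_single(self):
        rows = compute_rpm(canonical_ratio_filter(self.make_rows([10], [10])))
        assert rows[0].rpm == (1e6,)

    def test_rpm_proportional(self):
        rows = self.make_rows([750_000, 250_000], [750_000, 250_000])
        rows = compute_rpm(canonical_ratio_filter(rows))
        assert rows[0].rpm == (750_000.0,)
        assert rows[1].rpm == (250_000.0,)

    def test_rpm_zero_denominator(self, caplog):
        rows = [MiRNACountRow("m", (0,), (0,), filtered=False)]
        with caplog.at_level("WARNING"):
            rows = compute_rpm(rows)
        assert rows[0].rpm == (0.0,)
        assert "zero" in caplog.text

    def test_rpm_sums_to_million(self):
        rows = self.make_rows([10, 20, 5], [30, 50, 20])
        rows = compute_rpm(canonical_ratio_filter(rows))
        assert sum(r.rpm[0] for r in rows) == pytest.approx(1e6)

    def test_filtered_rows_zeroed_in_rpm_denominator(self):
        rows = [
            MiRNACountRow("keep", (90,), (90,)),
            MiRNACountRow("drop", (1,), (100,)),
        ]
        rows = compute_rpm(canonical_ratio_filter(rows))
        assert rows[0].rpm == (1e6,)
        assert rows[1].rpm == (0.0,)

    def test_variant_counts_attributed_to_parent(self, mature_library):
        from mirquant.libraries import SnpAnnotation, expand_snps

        lib = expand_snps(mature_library, [SnpAnnotation("mirA", 3, "A", "C")])
        variant_seq = lib.sequence("mirA.SNP1")
        result = run([UniqueRead(variant_seq, (7,))], {"mature_miRNA": lib})
        rows = count_mirnas(result, lib)
        assert [(r.mirna_id, r.total_count) for r in rows] == [("mirA", (7,))]

    def test_spike_in_excluded_from_rpm_denominator(self, mature_library):
        spike = SequenceLibrary("sp", "spike_in", [("spike1", "GTCAGTCAGTCAGTCAGTCAGT")])
        reads = [
            UniqueRead(mature_library.sequence("mirA"), (10,)),
            UniqueRead("GTCAGTCAGTCAGTCAGTCAGT", (90,)),
        ]
        result = run(reads, {"mature_miRNA": mature_library, "spike_in": spike})
        rows = compute_rpm(canonical_ratio_filter(count_mirnas(result, mature_library)))
        assert rows[0].rpm == (1e6,)  # spike-in reads do not dilute miRNA RPM
        summary = result.class_summary()
        assert summary["spike_in"] == [90]


class TestProportionRecovery:
    def test_chi_square_on_planted_composition(self, mature_library):
        rng = np.random.default_rng(1)
        probs = np.array([0.6, 0.3, 0.1])
        n = 100_000
        counts = rng.multinomial(n, probs)
        reads = [
            UniqueRead(mature_library.sequence(mid), (int(c),))
            for mid, c in zip(["mirA", "mirB", "mirC"], counts)
        ]
        result = run(reads, {"mature_miRNA": mature_library})
        rows = count_mirnas(result, mature_library)
        observed = np.array([sum(r.total_count) for r in rows], dtype=float)
        _, p = sps.chisquare(observed, probs * n)
        assert p > 0.01
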
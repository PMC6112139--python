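# mirquant

Small RNA-seq analysis toolkit: miRNA quantification with a canonical-ratio
filter, miRTop-style GFF3 isomiR reporting, A-to-I editing detection with
four exclusion criteria, and novel miRNA discovery from genomic read
clusters scored by an mRMR-selected RBF-SVM.

## What it does

- **preprocess** — FASTQ(.gz) reading, 3′ adapter trimming, quality/length
  filtering, collapsing to unique reads, and merging counts across samples.
- **libraries** — build/validate annotation libraries from FASTA (mature
  miRNA, hairpin, tRNA, snoRNA, rRNA, ncRNA, mRNA, spike-in, genome), with
  CCA-tailing of tRNAs, SNP expansion of mature miRNAs, and merging of
  near-identical mature miRNAs into slash-joined groups.
- **annotate** — cascade alignment of unique reads (spike-in → exact mature
  miRNA → hairpin → tRNA → snoRNA → rRNA → ncRNA → mRNA → tolerant isomiR
  pass), canonical-ratio filtering (default 0.1, range 0–0.5), count and
  RPM tables, per-class summary.
- **isomir_gff3** — classifies each miRNA-assigned read against its
  precursor (iso_5p / iso_3p / iso_add3p / iso_snp) and writes a
  round-trippable GFF3 with CIGAR values.
- **editing** — per-position A→G tallies, four exclusion criteria
  (family/SNP blacklist, repeat-element blacklist, canonical RPM < 1,
  genomic multimapping of the switched sequence trimmed by 2 nt), binomial
  significance testing with BH correction.
- **discovery** — exact-match genome placement of unmapped reads, gap-based
  clustering, the 0.8-threshold stable range, hairpin folding (maximum
  base-pairing with GU wobble; a thermodynamic folder can be plugged in),
  structural + compositional feature vectors, and ≥10 reads / ≥3 sequences
  candidate filtering.
- **model** — mRMR (MID) feature ranking, forward stepwise selection over
  repeated 4:1 splits, standardized RBF-SVM with 10-fold CV grid search
  over C, γ ∈ {1e-4 … 1e3} scored by MCC, JSON model serialization,
  prediction, and quality scores (1 − ranking percentile).
- **synthetic** — deterministic generator of genomes with planted hairpins,
  reads with tight 5′ ends / ragged 3′ ends / A-U non-templated tails /
  planted editing fractions, matching libraries, and truth tables.

## CLI

```bash
# synthetic fixtures (genome, libraries, truth table, FASTQ)
mirquant simulate --seed 1 --out-dir sim/

# quantify; add --gff for isomiR GFF3 and --a-to-i for editing detection
mirquant annotate --fastq sim/S1.fastq --mature sim/mature_miRNA.fa \
    --hairpin sim/hairpin.fa --genome sim/genome.fa --gff --a-to-i \
    --out-dir results/

# train the novel-miRNA model (on synthetic data, or --features TSV)
mirquant train --seed 1 --out model.json

# discover novel miRNA candidates from unmapped reads
mirquant predict --unmapped results/unmapped.fa --genome sim/genome.fa \
    --model model.json --out-dir novel/
```

Every run writes a `manifest.json` (version, resolved config, input
checksums, per-stage counts); identical inputs and seeds reproduce all
outputs byte-for-byte.

## Acceptance

Acceptance is property-based (oracle agreement for the stable range,
folding, structure statistics, MCC, mRMR; SVM recovery on synthetic
clusters; editing-fraction recovery; GFF3 round trips; filter boundaries;
end-to-end determinism) and lives in `tests/test_acceptance.py`. The
report script runs the full pipeline end to end and emits the target JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

There are no numeric acceptance targets reproducible offline (the source
method's headline numbers require multi-GB SRA datasets), so the emitted
object is empty; a non-zero exit indicates a pipeline failure.

## Conventions

- Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive.
- `iso_5p:+n` means the read starts n nt upstream (5′) of the canonical
  start.
- The CIGAR dialect is run-length `nM` with substituted positions written
  as the read's base (e.g. `13MA8M`); non-templated 3′ additions never
  extend `end` past the precursor and are declared via `iso_add3p` with the
  tail carried in the `Read` attribute.
- "Canonical" means an exact full-length match to the mature library
  sequence.
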
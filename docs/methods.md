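# Methods

## The detection model

An LTR-retroelement insertion that is absent from the reference leaves two
signatures in paired-end data. First, fragments straddling either junction
produce pairs with one end in unique flanking sequence and the mate inside
the element; the mate cannot map (the element is not in the reference) or
multi-maps (it falls in repetitive sequence), while the anchor maps uniquely.
Second, reads crossing a junction are chimeric: a reference prefix joined to
an element terminus. teseek uses the first signature to localize
(one-end-anchored mining and clustering) and the second to refine
(split-read breakpoint and TSD estimation).

Coordinate conventions. Internally everything is 0-based half-open; output
positions are 1-based. An insertion's "position" is the first base of the
target-site duplication (TSD). With position `p` (1-based), `p0 = p − 1` and
TSD length `t`, the mutant haplotype is
`ref[:p0+t] + element + ref[p0:]` — the `t` bases starting at `p0` appear on
both sides of the element and no reference base is lost. Consequently the
left junction (last reference base before the element) lies at `p0 + t` and
the right junction at `p0`, so `t = left − right`, which is how the TSD is
measured from junction reads.

## Pipeline stages and defaults

**Alignment.** Ungapped exhaustive Hamming placement of each 36-bp mate on
both strands with `max_mismatch = 2`, found by exact k-mer seeding with
`max_mismatch + 1` non-overlapping seeds (`seed_len = read_len // 3 = 12`).
By the pigeonhole principle at most `max_mismatch` mismatches cannot corrupt
all seeds, so the seeded search provably returns the same hit set as an
exhaustive scan over every offset and strand — the property the test suite
asserts against a brute-force oracle. Two seeds of length 18 would be
marginally faster but lose that guarantee (two mismatches can hit one seed
each), which is why three shorter seeds were chosen. A read is *unique* only
if exactly one placement exists at the best mismatch tier; equal-best ties
are *multi*; reads with > 20% N are unmapped. Gapped alignment is not
supported: at 36 bp an indel-containing read simply goes unmapped, which the
downstream logic tolerates.

**Pair classes.** PROPER = both unique, opposite strands, inward-facing,
implied fragment length within `frag_mean ± 4·frag_sd` (default [180, 420]);
OEA = exactly one unique end, mate unmapped or multi; BOTH_UNMAPPED;
DISCORDANT_OTHER.

**Mate filtering and classification.** DUST-style score
`Σ c(c−1)/2 / (k−1)` over 3-mer counts, threshold 2.0 (a 36-mer of pure
dinucleotide repeat scores ≈ 8, random sequence ≈ 0.5); all-N/>20%-N reads
are failed. Survivors are matched ungapped on both strands against each
library consensus (k = 12 exact-k-mer prefilter, then full scan), accepted at
identity ≥ 0.90 over ≥ 20 aligned bases. Offsets falling in either identical
LTR copy are reported as region `LTR` with both candidate offsets.

**Clustering and calling.** Single-linkage per (side, family) with
`max_gap = 300` (anchor spread is bounded by fragment length); clusters need
`min_support = 5` distinct pairs — the support floor is applied per cluster.
A call requires paired left+right clusters by default (`--single-side`
relaxes this). Left-cluster breakpoint estimate = max anchor end;
right-cluster = min anchor start.

**Refinement.** Junction candidates are all non-uniquely-mapped reads. For
each read (both orientations of read and element), every split with ≥ 5 bp
on each side is tested: the element side must match an element terminus with
≤ 1 mismatch, the reference side must occur exactly within ± 300 bp of the
cluster estimate. Each read votes once per side for the placement closest to
the estimate; majority vote per side wins, vote ties or a negative
left−right difference mark the call ambiguous. With no junction reads the
TSD is unknown and the confidence interval falls back to the anchor
clusters ± fragment length.

**Zygosity.** Reference-spanning support = PROPER pairs whose fragment
interval covers the reported position with ≥ one read length on each side.
hom if that count ≤ 1, het if both supports ≥ `min_support`, else ambiguous.
Allele-ratio tests are deliberately avoided: capture arrays designed on
repeat-free probes deplete insertion-allele fragments, so the
insertion:reference ratio is biased (the motivating dataset showed a
166:1127 skew at a true heterozygous site).

**Novelty.** A call is novel if no same-family annotation lies within
`novelty_window = 300` bp of the site.

**Variant scan.** Unique-mapping records only. Per column the dominant
non-reference base is tested: het when `het_min ≤ VAF < 0.75`, hom_alt at
≥ 0.75, presets `initial = 0.40` and `relaxed = 0.25`; columns below
`min_depth = 8` are skipped (a guard against threshold instability at
trivial depth — immaterial at capture-scale coverage). Multi-allelic columns
are flagged. The ungapped aligner makes the scan effectively SNV-only; the
deletion row of the pileup is populated only by imported alignments.

**Coverage.** Depth counts every mapped primary placement (unique + multi):
raw depth is the capture-QC quantity, and unique-only depth would crater the
~49%-repetitive stretches by construction. The variant scan, in contrast,
stays unique-only.

**Expression statistics.** Pfaffl ratio
`E_t^ΔCt_t / E_ref^ΔCt_ref` with `ΔCt = mean Ct(calibrator) − mean Ct(sample)`
and efficiencies defaulting to 2.0 (perfect doubling) when unmeasured;
calibrating on wildtype makes the wildtype fold change exactly 1. The t test
is the classic pooled-variance two-tailed form (Welch behind a flag), with a
documented zero-variance convention (equal means → p = 1, unequal → p = 0).
The Fisher test is the exact conditional two-sided test under the
probability-mass rule — hypergeometric terms are accumulated in log space
(lgamma), with a 1e−7 relative tolerance for floating-point ties; mid-p is
not used.

## The simulator

The generator emulates the statistical structure of a targeted-capture run
over a repeat-dense interval:

- **Reference** (default 10 kb): random DNA with non-overlapping diverged
  copies (5% per-copy substitution) of `n_families = 3` random consensi
  placed until ~49% of bases are annotated; copies share enough identity
  that short reads genuinely multi-map, and ≥ 80 bp unique spacers keep
  anchors possible.
- **Element**: random DNA with byte-identical 847-bp LTRs flanking a
  6,834-bp internal sequence (8,528 bp total). Open-reading-frame content is
  not modelled.
- **Reads**: 36-bp inward-facing pairs from fragments
  ~ Normal(300, 30) truncated to [72, 600], drawn with equal per-haplotype
  prior; read count = `coverage × mean haplotype length / (2 × read_len)`.
  Errors are uniform substitutions (default 0.005), constant qualities.
- **Capture**: each fragment is accepted with probability
  `max(0.05, fraction of its bases outside annotated repeats)`; the inserted
  element is masked as repeat on the mutant haplotype. Sampling continues
  until the target pair count is reached, so bias reshapes where coverage
  lands rather than the yield — this reproduces the depletion of
  insertion-supporting reads relative to reference-spanning ones without
  tuning. The fragment spread, error profile and depletion strength are
  modelling choices; the source data report none of them quantitatively.
- **Determinism**: one master seed; each stream (reference, element,
  fragments, errors, site/SNV choice) derives its own seed by a fixed
  offset, so identical seeds give byte-identical FASTQ.

What the simulator does **not** model: realistic repeat taxonomy, indel
errors, GC/hexamer bias, chimeric library artifacts, quality-score decay,
solo-LTR or truncated insertions. Passing tests therefore demonstrate the
inference logic is correct under the stated generative model, not that the
caller is robust to every artifact of real libraries.

## Problem sizes used in the checks

The bundled end-to-end checks run 10-kb references at 50× for single-run
parameter recovery and an 8-kb / 30× grid across 20 seeds × three genotypes
for the recovery/false-positive/zygosity sweep — small enough to iterate on
comfortably, large enough that every cluster-support and spanning-count
threshold operates in its intended regime. The acceptance script
(`scripts/acceptance.py`) uses the 10-kb / 50× error-free heterozygous
configuration and recomputes the TSD from scratch at the given seed.

## Known limitations

- Single-region, single-insertion scope; no genome-wide scan.
- Uniqueness is binary (no mapping-quality model); MAPQ on export is 37/0.
- TSD refinement assumes the element termini in the library are exact; a
  diverged terminal sequence would shift votes or leave the TSD unknown.
- Insertions inside or within a fragment length of annotated repeats lose
  anchors to multi-mapping and may fall below the support floor — the same
  blind spot the probe design imposes on the real assay.
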
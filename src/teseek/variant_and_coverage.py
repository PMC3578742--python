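"""SNV scanning with VAF thresholds, coverage statistics, tandem repeats.

The variant scan follows the two-pass threshold scheme used for
heterozygous-template capture data: a column is called heterozygous when the
dominant non-reference base reaches the het floor (initial pass 40%, relaxed
pass 25%) and homozygous-alternate at 75% and above. Coverage statistics
summarize a targeted-capture run: bases covered, mean depth over the
interval, proper-pair fraction, and a depth histogram. Tandem-repeat counting
genotypes microsatellite markers (e.g. a TATC repeat) from assembled
sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .read_mapping import AlignedPair, PairClass, Uniqueness

PRESETS = {"initial": 0.40, "relaxed": 0.25}
DEFAULT_HOM_MIN = 0.75
DEFAULT_MIN_DEPTH = 8

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_BASES = "ACGTN"


@dataclass(frozen=True)
class PileupColumn:
    position: int                   # 0-based
    depth: int
    counts: tuple[int, int, int, int, int, int]   # A C G T N deletion

    def __post_init__(self):
        if sum(self.counts) != self.depth:
            raise ValueError("pileup counts must sum to depth")


@dataclass(frozen=True)
class VariantCall:
    position: int                   # 1-based in output
    ref: str
    alt: str
    vaf: float
    depth: int
    genotype: str                   # het | hom_alt
    multiallelic: bool = False


def _unique_records(aligned: Sequence[AlignedPair]):
    for ap in aligned:
        for rec in (ap.rec1, ap.rec2):
            if rec.uniqueness is Uniqueness.UNIQUE:
                yield rec


def pileup(aligned: Sequence[AlignedPair], reference: str) -> np.ndarray:
    """(6, L) base-count matrix (A,C,G,T,N,del) from unique records.

    Records are ungapped here, so the deletion row stays zero unless imported
    alignments carry deletions (not produced by the built-in aligner).
    """
    L = len(reference)
    counts = np.zeros((6, L), dtype=np.int32)
    for rec in _unique_records(aligned):
        seq = rec.sequence if rec.strand == "+" else _rc(rec.sequence)
        # clipped bases do not contribute to columns
        seq = seq[rec.clip5: len(seq) - rec.clip3 or None]
        start = rec.start
        for i, base in enumerate(seq):
            if start + i >= L:
                break
            counts[_BASE_INDEX.get(base, 4), start + i] += 1
    return counts


def _rc(seq: str) -> str:
    from .synthetic_data import revcomp
    return revcomp(seq)


def pileup_columns(counts: np.ndarray) -> list[PileupColumn]:
    depths = counts.sum(axis=0)
    return [PileupColumn(int(p), int(depths[p]), tuple(int(x) for x in counts[:, p]))
            for p in np.flatnonzero(depths)]


def pileup_and_call(aligned: Sequence[AlignedPair], reference: str,
                    het_min: float = PRESETS["initial"],
                    hom_min: float = DEFAULT_HOM_MIN,
                    min_depth: int = DEFAULT_MIN_DEPTH,
                    reference_name: str | None = None) -> list[VariantCall]:
    """VAF-threshold variant calls from the dominant non-reference base.

    het when het_min <= VAF < hom_min, hom_alt when VAF >= hom_min; columns
    below ``min_depth`` are skipped. Columns where a second alternate base
    also reaches the het floor are flagged multiallelic.
    """
    if reference_name is not None:
        for ap in aligned:
            for rec in (ap.rec1, ap.rec2):
                if rec.mapped and rec.reference not in (None, reference_name):
                    raise ValueError(
                        f"alignment reference {rec.reference!r} does not match "
                        f"{reference_name!r}")
    counts = pileup(aligned, reference.upper())
    depths = counts.sum(axis=0)
    calls: list[VariantCall] = []
    for pos in np.flatnonzero(depths >= min_depth):
        ref_base = reference[pos].upper()
        ref_i = _BASE_INDEX.get(ref_base, 4)
        col = counts[:4, pos]
        alt_counts = [(int(col[i]), _BASES[i]) for i in range(4) if i != ref_i]
        alt_counts.sort(key=lambda t: (-t[0], t[1]))
        alt_n, alt_base = alt_counts[0]
        depth = int(depths[pos])
        vaf = alt_n / depth
        if vaf < het_min:
            continue
        genotype = "hom_alt" if vaf >= hom_min else "het"
        multi = len(alt_counts) > 1 and alt_counts[1][0] / depth >= het_min
        calls.append(VariantCall(int(pos) + 1, ref_base, alt_base, vaf,
                                 depth, genotype, multi))
    return calls


def write_variant_report(calls: Sequence[VariantCall], region_name: str,
                         path: str | Path) -> None:
    """VCF-like TSV (CHROM, POS, REF, ALT, VAF, DEPTH, GT)."""
    with open(path, "w") as fh:
        fh.write("CHROM\tPOS\tREF\tALT\tVAF\tDEPTH\tGT\n")
        for c in calls:
            fh.write(f"{region_name}\t{c.position}\t{c.ref}\t{c.alt}"
                     f"\t{c.vaf:.4f}\t{c.depth}\t{c.genotype}\n")


# ---------------------------------------------------------------------------
# Coverage statistics
# ---------------------------------------------------------------------------

@dataclass
class CoverageStats:
    interval: tuple[int, int]
    covered_bases: int
    fraction_covered: float
    mean_depth: float
    proper_pair_fraction: float
    histogram: np.ndarray           # histogram[d] = number of positions at depth d

    def to_tsv(self, path: str | Path) -> None:
        lo, hi = self.interval
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            fh.write(f"interval_start\t{lo}\n")
            fh.write(f"interval_end\t{hi}\n")
            fh.write(f"covered_bases\t{self.covered_bases}\n")
            fh.write(f"fraction_covered\t{self.fraction_covered:.4f}\n")
            fh.write(f"mean_depth\t{self.mean_depth:.2f}\n")
            fh.write(f"proper_pair_fraction\t{self.proper_pair_fraction:.4f}\n")


def coverage_stats(aligned: Sequence[AlignedPair],
                   interval: tuple[int, int]) -> CoverageStats:
    """Depth and pairing summary over a target interval.

    Depth counts every mapped primary placement (unique and multi): raw
    coverage is the quantity of interest for capture QC, and restricting to
    unique placements would artificially crater repeat-dense stretches.
    """
    lo, hi = interval
    if hi <= lo:
        raise ValueError("empty interval")
    width = hi - lo
    depth = np.zeros(width, dtype=np.int64)
    n_pairs = 0
    n_proper_on_target = 0
    for ap in aligned:
        n_pairs += 1
        on_target = False
        for rec in (ap.rec1, ap.rec2):
            if not rec.mapped:
                continue
            s = max(rec.start, lo)
            e = min(rec.end, hi)
            if s < e:
                depth[s - lo:e - lo] += 1
                on_target = True
        if on_target and ap.pair_class is PairClass.PROPER:
            n_proper_on_target += 1
    covered = int((depth > 0).sum())
    hist = np.bincount(depth)
    return CoverageStats(
        interval=(lo, hi),
        covered_bases=covered,
        fraction_covered=covered / width,
        mean_depth=float(depth.mean()),
        proper_pair_fraction=(n_proper_on_target / n_pairs) if n_pairs else 0.0,
        histogram=hist,
    )


def write_depth_histogram(stats: CoverageStats, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("depth\tn_positions\n")
        for d, n in enumerate(stats.histogram):
            if n:
                fh.write(f"{d}\t{int(n)}\n")


def covered_intervals_bed(aligned: Sequence[AlignedPair], region_name: str,
                          interval: tuple[int, int], path: str | Path) -> None:
    """BED of maximal depth>=1 intervals within the target."""
    stats_depth = np.zeros(interval[1] - interval[0], dtype=np.int64)
    lo, hi = interval
    for ap in aligned:
        for rec in (ap.rec1, ap.rec2):
            if rec.mapped:
                s, e = max(rec.start, lo), min(rec.end, hi)
                if s < e:
                    stats_depth[s - lo:e - lo] += 1
    covered = stats_depth > 0
    with open(path, "w") as fh:
        start = None
        for i, c in enumerate(covered):
            if c and start is None:
                start = i
            elif not c and start is not None:
                fh.write(f"{region_name}\t{start + lo}\t{i + lo}\n")
                start = None
        if start is not None:
            fh.write(f"{region_name}\t{start + lo}\t{len(covered) + lo}\n")


# ---------------------------------------------------------------------------
# Tandem-repeat (microsatellite) counting
# ---------------------------------------------------------------------------

def count_tandem_repeats(sequence: str, motif: str) -> tuple[int, int]:
    """Longest run of exact head-to-tail motif copies.

    Returns (copy count, 0-based start of the run); the leftmost maximal run
    wins ties, and an absent motif returns (0, -1).
    """
    if not motif:
        raise ValueError("empty motif")
    sequence, motif = sequence.upper(), motif.upper()
    m = len(motif)
    best_count, best_start = 0, -1
    i = 0
    while i <= len(sequence) - m:
        if sequence.startswith(motif, i):
            count = 1
            j = i + m
            while sequence.startswith(motif, j):
                count += 1
                j += m
            if count > best_count:
                best_count, best_start = count, i
            i += 1          # allow runs at every phase; leftmost max wins
        else:
            i += 1
    return best_count, best_start
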
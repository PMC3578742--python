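"""Unique-mapping ungapped paired-end alignment for short reads.

A minimal aligner for 36-bp-scale reads on desk-scale references: exhaustive
up-to-``max_mismatch`` Hamming placement on both strands, found by exact-match
k-mer seeding with ``max_mismatch + 1`` non-overlapping seeds per read.  With
that many seeds the pigeonhole principle guarantees every placement within the
mismatch budget shares at least one exact seed with the reference, so the
seeded search returns exactly the hit set an exhaustive scan would.

Pairs are classified as PROPER (both ends unique, inward-facing FR, fragment
length in bounds), OEA (one end anchored: exactly one end unique, the mate
unmapped or multi-mapping — the read class that carries insertion evidence),
BOTH_UNMAPPED, or DISCORDANT_OTHER.  SAM text import/export lets external
aligner output substitute for the built-in one.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .synthetic_data import ReadPair, revcomp

MAPQ_UNIQUE = 37
DEFAULT_MAX_MISMATCH = 2
DEFAULT_FRAG_BOUNDS = (300 - 4 * 30, 300 + 4 * 30)
MAX_N_FRACTION = 0.2


class Uniqueness(str, enum.Enum):
    UNIQUE = "unique"
    MULTI = "multi"
    UNMAPPED = "unmapped"


class PairClass(str, enum.Enum):
    PROPER = "PROPER"
    OEA = "OEA"
    BOTH_UNMAPPED = "BOTH_UNMAPPED"
    DISCORDANT_OTHER = "DISCORDANT_OTHER"


@dataclass(frozen=True)
class Hit:
    """One candidate placement: 0-based start, strand, mismatch count."""

    start: int
    strand: str
    mismatches: int


@dataclass
class AlignmentRecord:
    """One mate's alignment state (primary placement if mapped).

    ``sequence``/``quality`` are always in original (as-sequenced)
    orientation; SAM serialization reverse-complements for minus-strand
    records as the format requires.
    """

    read_id: str
    mate: int                      # 1 or 2
    sequence: str
    quality: str
    reference: str | None = None
    start: int | None = None       # 0-based
    strand: str | None = None
    mismatches: int | None = None
    aligned_len: int = 0
    clip5: int = 0
    clip3: int = 0
    uniqueness: Uniqueness = Uniqueness.UNMAPPED
    n_best: int = 0
    hits: list[Hit] = field(default_factory=list)

    @property
    def mapped(self) -> bool:
        return self.uniqueness is not Uniqueness.UNMAPPED

    @property
    def end(self) -> int:
        """0-based exclusive end of the aligned span."""
        if self.start is None:
            raise ValueError("unmapped record has no coordinates")
        return self.start + self.aligned_len


class ReferenceIndex:
    """Exact k-mer position index over the forward strand of one reference."""

    def __init__(self, name: str, sequence: str, seed_len: int = 12):
        if seed_len < 4:
            raise ValueError("seed length too short")
        self.name = name
        self.sequence = sequence.upper()
        self.seed_len = seed_len
        self._index: dict[str, list[int]] = {}
        k = seed_len
        for i in range(len(self.sequence) - k + 1):
            kmer = self.sequence[i:i + k]
            if "N" in kmer:
                continue
            self._index.setdefault(kmer, []).append(i)

    def __len__(self) -> int:
        return len(self.sequence)

    def seed_positions(self, kmer: str) -> list[int]:
        return self._index.get(kmer, ())


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count with early exit once ``limit`` is exceeded. N mismatches
    everything (including N)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def find_hits(sequence: str, index: ReferenceIndex,
              max_mismatch: int = DEFAULT_MAX_MISMATCH) -> list[Hit]:
    """All placements of ``sequence`` on either strand with Hamming distance
    <= max_mismatch, sorted by (mismatches, start, strand)."""
    L = len(sequence)
    n_seeds = max_mismatch + 1
    k = min(index.seed_len, L // n_seeds)
    if k < 4:
        raise ValueError("read too short for seeded search at this mismatch budget")
    ref = index.sequence
    hits: list[Hit] = []
    for strand, seq in (("+", sequence), ("-", revcomp(sequence))):
        if k == index.seed_len:
            lookup = index.seed_positions
        else:                       # fallback scan for short reads
            lookup = lambda kmer: [i for i in range(len(ref) - len(kmer) + 1)
                                   if ref[i:i + len(kmer)] == kmer]
        candidates: set[int] = set()
        for s in range(n_seeds):
            off = s * k
            for pos in lookup(seq[off:off + k]):
                start = pos - off
                if 0 <= start <= len(ref) - L:
                    candidates.add(start)
        for start in candidates:
            mm = _hamming(seq, ref[start:start + L], max_mismatch)
            if mm <= max_mismatch:
                hits.append(Hit(start, strand, mm))
    hits.sort(key=lambda h: (h.mismatches, h.start, h.strand))
    return hits


def align_read(read_id: str, mate: int, sequence: str, quality: str,
               index: ReferenceIndex,
               max_mismatch: int = DEFAULT_MAX_MISMATCH) -> AlignmentRecord:
    """Align one mate; uniqueness requires a single hit at the best mismatch
    tier (equal-best ties are multi). Reads with >20% N are unmapped."""
    sequence = sequence.upper()
    rec = AlignmentRecord(read_id, mate, sequence, quality)
    if sequence.count("N") > MAX_N_FRACTION * len(sequence):
        return rec
    hits = find_hits(sequence, index, max_mismatch)
    if not hits:
        return rec
    best = hits[0].mismatches
    n_best = sum(1 for h in hits if h.mismatches == best)
    top = hits[0]
    rec.reference = index.name
    rec.start = top.start
    rec.strand = top.strand
    rec.mismatches = top.mismatches
    rec.aligned_len = len(sequence)
    rec.uniqueness = Uniqueness.UNIQUE if n_best == 1 else Uniqueness.MULTI
    rec.n_best = n_best
    rec.hits = hits
    return rec


def classify_pair(rec1: AlignmentRecord, rec2: AlignmentRecord,
                  frag_bounds: tuple[int, int] = DEFAULT_FRAG_BOUNDS) -> PairClass:
    """Classify a mate pair; see module docstring for the four classes."""
    if rec1.read_id != rec2.read_id:
        raise ValueError(f"mismatched read ids {rec1.read_id!r}/{rec2.read_id!r}")
    u1, u2 = rec1.uniqueness, rec2.uniqueness
    if u1 is Uniqueness.UNMAPPED and u2 is Uniqueness.UNMAPPED:
        return PairClass.BOTH_UNMAPPED
    if u1 is Uniqueness.UNIQUE and u2 is Uniqueness.UNIQUE:
        if rec1.strand != rec2.strand:
            fwd, rev = (rec1, rec2) if rec1.strand == "+" else (rec2, rec1)
            if fwd.start <= rev.start:          # inward-facing FR
                flen = rev.end - fwd.start
                if frag_bounds[0] <= flen <= frag_bounds[1]:
                    return PairClass.PROPER
        return PairClass.DISCORDANT_OTHER
    if (u1 is Uniqueness.UNIQUE) != (u2 is Uniqueness.UNIQUE):
        other = u2 if u1 is Uniqueness.UNIQUE else u1
        if other in (Uniqueness.UNMAPPED, Uniqueness.MULTI):
            return PairClass.OEA
    return PairClass.DISCORDANT_OTHER


def fragment_interval(rec1: AlignmentRecord, rec2: AlignmentRecord) -> tuple[int, int]:
    """0-based half-open reference interval spanned by a proper pair."""
    fwd, rev = (rec1, rec2) if rec1.strand == "+" else (rec2, rec1)
    return fwd.start, rev.end


@dataclass
class AlignedPair:
    rec1: AlignmentRecord
    rec2: AlignmentRecord
    pair_class: PairClass


def align_pairs(pairs: Iterable[ReadPair], index: ReferenceIndex,
                max_mismatch: int = DEFAULT_MAX_MISMATCH,
                frag_bounds: tuple[int, int] = DEFAULT_FRAG_BOUNDS) -> list[AlignedPair]:
    out = []
    for rp in pairs:
        r1 = align_read(rp.pair_id, 1, rp.mate1, rp.qual1, index, max_mismatch)
        r2 = align_read(rp.pair_id, 2, rp.mate2, rp.qual2, index, max_mismatch)
        out.append(AlignedPair(r1, r2, classify_pair(r1, r2, frag_bounds)))
    return out


# ---------------------------------------------------------------------------
# SAM import/export (text SAM via pysam; 0-based internal <-> 1-based POS)
# ---------------------------------------------------------------------------

def write_sam(aligned: Sequence[AlignedPair], reference_name: str,
              reference_length: int, path: str | Path) -> None:
    """Write aligned pairs as SAM v1 text.

    Unique records get MAPQ 37, multi-mapping primaries MAPQ 0 with an NH tag;
    an unmapped mate inherits RNAME/POS from its mapped mate per the standard.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": reference_name, "LN": reference_length}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for ap in aligned:
            proper = ap.pair_class is PairClass.PROPER
            for rec, mate in ((ap.rec1, ap.rec2), (ap.rec2, ap.rec1)):
                seg = pysam.AlignedSegment(fh.header)
                seg.query_name = rec.read_id
                flag = 0x1 | (0x40 if rec.mate == 1 else 0x80)
                if proper:
                    flag |= 0x2
                if not rec.mapped:
                    flag |= 0x4
                if not mate.mapped:
                    flag |= 0x8
                if rec.mapped and rec.strand == "-":
                    flag |= 0x10
                if mate.mapped and mate.strand == "-":
                    flag |= 0x20
                seg.flag = flag
                seq, qual = rec.sequence, rec.quality
                if rec.mapped and rec.strand == "-":
                    seq, qual = revcomp(seq), qual[::-1]
                seg.query_sequence = seq
                seg.query_qualities = pysam.qualitystring_to_array(qual)
                if rec.mapped:
                    seg.reference_id = 0
                    seg.reference_start = rec.start
                    seg.mapping_quality = MAPQ_UNIQUE \
                        if rec.uniqueness is Uniqueness.UNIQUE else 0
                    cigar = ""
                    if rec.clip5:
                        cigar += f"{rec.clip5}S"
                    cigar += f"{rec.aligned_len}M"
                    if rec.clip3:
                        cigar += f"{rec.clip3}S"
                    seg.cigarstring = cigar
                    seg.set_tag("NM", int(rec.mismatches or 0))
                    if rec.n_best:
                        seg.set_tag("NH", int(rec.n_best))
                elif mate.mapped:
                    # placement convention for unmapped mates
                    seg.reference_id = 0
                    seg.reference_start = mate.start
                if mate.mapped:
                    seg.next_reference_id = 0
                    seg.next_reference_start = mate.start
                if proper:
                    lo, hi = fragment_interval(ap.rec1, ap.rec2)
                    tlen = hi - lo
                    seg.template_length = tlen if rec.strand == "+" else -tlen
                fh.write(seg)


def read_sam(path: str | Path) -> list[AlignedPair]:
    """Read SAM text back into aligned pairs.

    Uniqueness is recovered from MAPQ (0 => multi, otherwise unique); pair
    class is re-derived from the records so imported external alignments get
    the same downstream treatment as the built-in aligner's output.
    """
    by_id: dict[str, dict[int, AlignmentRecord]] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for ln, seg in enumerate(fh, start=1):
            try:
                rec = _segment_to_record(seg)
            except Exception as exc:    # pragma: no cover - defensive
                raise ValueError(f"malformed SAM record at line {ln}: {exc}") from exc
            by_id.setdefault(rec.read_id, {})[rec.mate] = rec
    out = []
    for rid, mates in by_id.items():
        if set(mates) != {1, 2}:
            raise ValueError(f"read {rid!r} lacks both mates in SAM input")
        r1, r2 = mates[1], mates[2]
        out.append(AlignedPair(r1, r2, classify_pair(r1, r2)))
    return out


def _segment_to_record(seg: pysam.AlignedSegment) -> AlignmentRecord:
    mate = 1 if seg.is_read1 else 2
    seq = seg.query_sequence or ""
    if seg.query_qualities is not None:
        qual = pysam.qualities_to_qualitystring(seg.query_qualities)
    else:
        qual = "I" * len(seq)
    if seg.is_unmapped:
        return AlignmentRecord(seg.query_name, mate, seq.upper(), qual)
    strand = "-" if seg.is_reverse else "+"
    if strand == "-":
        seq, qual = revcomp(seq.upper()), qual[::-1]
    clip5 = clip3 = 0
    aligned = 0
    if seg.cigartuples:
        tuples = seg.cigartuples
        if tuples[0][0] == 4:
            clip5 = tuples[0][1]
        if len(tuples) > 1 and tuples[-1][0] == 4:
            clip3 = tuples[-1][1]
        aligned = sum(n for op, n in tuples if op in (0, 7, 8))
    uniq = Uniqueness.UNIQUE if seg.mapping_quality > 0 else Uniqueness.MULTI
    nh = seg.get_tag("NH") if seg.has_tag("NH") else (1 if uniq is Uniqueness.UNIQUE else 2)
    return AlignmentRecord(
        seg.query_name, mate, seq.upper(), qual,
        reference=seg.reference_name, start=seg.reference_start,
        strand=strand,
        mismatches=int(seg.get_tag("NM")) if seg.has_tag("NM") else None,
        aligned_len=aligned, clip5=clip5, clip3=clip3,
        uniqueness=uniq, n_best=int(nh),
    )
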
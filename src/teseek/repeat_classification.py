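"""Low-complexity filtering and repeat-library classification of mate reads.

Unmapped mates of one-end-anchored pairs are the carriers of insertion
evidence, but they must first be cleaned: failed reads (mostly N) and
low-complexity sequence (poly-A tails, dinucleotide runs) produce spurious
matches and are dropped with a DUST-style triplet score. Survivors are
compared, ungapped on both strands, against a small library of repeat-family
consensus sequences; a read is classified to the family with the best local
match meeting identity and length minima.

For an LTR retroelement consensus laid out LTR-internal-LTR the two LTR
copies are identical, so an LTR hit is positionally ambiguous between the
5' and 3' copy; such hits are reported with both candidate offsets.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthetic_data import TEElement, read_fasta, revcomp

DUST_THRESHOLD = 2.0
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_LEN = 20
PREFILTER_K = 12
N_FAIL_FRACTION = 0.2


@dataclass(frozen=True)
class RepeatHit:
    """Best library match for one read."""

    family: str
    region: str                 # LTR | internal | ambiguous
    offset: int                 # 0-based offset of the match on the consensus
    offsets: tuple[int, ...]    # all equivalent offsets (2 for an LTR hit)
    strand: str                 # consensus strand relative to the read
    identity: float
    matched_len: int


@dataclass
class RepeatLibrary:
    """family -> consensus sequence, with optional LTR structure metadata."""

    consensi: dict[str, str]
    structures: dict[str, tuple[int, int]] = field(default_factory=dict)
    _kmers: dict[str, set[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.consensi:
            raise ValueError("empty repeat library")
        self.consensi = {f: s.upper() for f, s in self.consensi.items()}
        for fam, seq in self.consensi.items():
            kmers = set()
            for s in (seq, revcomp(seq)):
                for i in range(len(s) - PREFILTER_K + 1):
                    kmers.add(s[i:i + PREFILTER_K])
            self._kmers[fam] = kmers

    @classmethod
    def from_element(cls, element: TEElement) -> "RepeatLibrary":
        return cls({element.family: element.sequence},
                   {element.family: (element.ltr_length, element.internal_length)})

    @classmethod
    def from_fasta(cls, path: str | Path,
                   structures: dict[str, tuple[int, int]] | None = None
                   ) -> "RepeatLibrary":
        return cls(read_fasta(path), structures or {})

    def families(self) -> list[str]:
        return list(self.consensi)


# ---------------------------------------------------------------------------
# Low-complexity (DUST-style) filter
# ---------------------------------------------------------------------------

def low_complexity_score(sequence: str) -> tuple[float, bool]:
    """Triplet over-representation score and filtered flag.

    score = sum_t c_t (c_t - 1) / 2 / (k - 1) over 3-mer counts c_t in the
    sequence (k = number of 3-mers); a homopolymer scores ~k/2 while random
    sequence stays near 0.5. The flag is True when the score exceeds the
    DUST threshold or when the read failed (all N or >20% N).
    """
    if not sequence:
        raise ValueError("empty sequence")
    sequence = sequence.upper()
    if sequence.count("N") > N_FAIL_FRACTION * len(sequence):
        return float("inf"), True
    if len(sequence) < 4:
        return 0.0, False
    counts = Counter(sequence[i:i + 3] for i in range(len(sequence) - 2))
    k = len(sequence) - 2
    score = sum(c * (c - 1) / 2 for c in counts.values()) / (k - 1)
    return score, score > DUST_THRESHOLD


def passes_filters(sequence: str) -> bool:
    _, flagged = low_complexity_score(sequence)
    return not flagged


# ---------------------------------------------------------------------------
# Library classification
# ---------------------------------------------------------------------------

def _best_ungapped(read: str, consensus: str, min_identity: float,
                   min_len: int) -> tuple[int, int, int] | None:
    """Best ungapped placement of ``read`` along ``consensus`` allowing end
    overhang; returns (offset, matches, overlap_len) or None.

    ``offset`` is the consensus coordinate read base 0 aligns to (negative
    when the read overhangs the 5' end). Ranked by match count, then
    identity; leftmost offset wins ties.
    """
    L, C = len(read), len(consensus)
    if C < min_len:
        return None
    best: tuple[int, int, int] | None = None

    def consider(off: int, matches: int, overlap: int):
        nonlocal best
        if overlap < min_len or matches < min_identity * overlap:
            return
        if best is None or (matches, matches / overlap) > (
                best[1], best[1] / best[2]):
            best = (off, matches, overlap)

    if C >= L:
        # interior placements, vectorized
        r = np.frombuffer(read.encode(), dtype=np.uint8)
        c = np.frombuffer(consensus.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(c, L)
        match_counts = (windows == r).sum(axis=1)
        order = np.argsort(-match_counts, kind="stable")
        top = order[0]
        consider(int(top), int(match_counts[top]), L)
    # partial overlaps at the ends
    for off in range(-(L - min_len), 0):
        overlap = L + off
        matches = sum(1 for a, b in zip(read[-overlap:], consensus[:overlap])
                      if a == b and a != "N")
        consider(off, matches, overlap)
    for off in range(max(0, C - L + 1), C - min_len + 1):
        overlap = C - off
        matches = sum(1 for a, b in zip(read[:overlap], consensus[off:])
                      if a == b and a != "N")
        consider(off, matches, overlap)
    return best


def classify_repeat(sequence: str, library: RepeatLibrary,
                    min_identity: float = DEFAULT_MIN_IDENTITY,
                    min_len: int = DEFAULT_MIN_LEN) -> RepeatHit | None:
    """Classify a read against the library; None if nothing meets the minima.

    A k-mer prefilter (k=12) skips families sharing no exact 12-mer with the
    read on either strand; surviving families are scanned exhaustively.
    """
    sequence = sequence.upper()
    best_hit: RepeatHit | None = None
    best_key = (-1, -1.0)
    for fam, consensus in library.consensi.items():
        read_kmers = {sequence[i:i + PREFILTER_K]
                      for i in range(len(sequence) - PREFILTER_K + 1)}
        if read_kmers and not (read_kmers & library._kmers[fam]):
            continue
        for strand in "+-":
            read = sequence if strand == "+" else revcomp(sequence)
            res = _best_ungapped(read, consensus, min_identity, min_len)
            if res is None:
                continue
            off, matches, overlap = res
            key = (matches, matches / overlap)
            if key > best_key:
                best_key = key
                region, offsets = _element_region(
                    off, overlap, library.structures.get(fam), len(consensus))
                best_hit = RepeatHit(fam, region, off, offsets, strand,
                                     matches / overlap, overlap)
    return best_hit


def _element_region(offset: int, overlap: int,
                    structure: tuple[int, int] | None,
                    consensus_len: int) -> tuple[str, tuple[int, ...]]:
    """LTR / internal / ambiguous labelling by offset arithmetic.

    LTR hits are reported with both equivalent offsets (the 5' and 3' copies
    are identical, so the placement is genuinely ambiguous between them).
    """
    if structure is None:
        return "ambiguous", (offset,)
    ltr, internal = structure
    start, end = offset, offset + overlap
    ltr_shift = ltr + internal
    in_5ltr = end <= ltr
    in_3ltr = start >= ltr_shift
    in_internal = start >= ltr and end <= ltr_shift
    if in_5ltr or in_3ltr:
        a = start if in_5ltr else start - ltr_shift
        return "LTR", (a, a + ltr_shift)
    if in_internal:
        return "internal", (offset,)
    return "ambiguous", (offset,)


def classification_report(rows: list[tuple[str, RepeatHit | None]],
                          path: str | Path) -> None:
    """Optional per-read TSV of classifications."""
    with open(path, "w") as fh:
        fh.write("read_id\tfamily\tregion\toffset\tstrand\tidentity\tmatched_len\n")
        for read_id, hit in rows:
            if hit is None:
                fh.write(f"{read_id}\t.\t.\t.\t.\t.\t.\n")
            else:
                fh.write(f"{read_id}\t{hit.family}\t{hit.region}\t{hit.offset}"
                         f"\t{hit.strand}\t{hit.identity:.4f}\t{hit.matched_len}\n")
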
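"""Synthetic targeted-capture data with known truth.

This module builds the study system end to end: a repeat-dense reference
region, an LTR retroelement (two identical long terminal repeats flanking an
internal sequence), insertion alleles carrying the element with a target-site
duplication (TSD), and 36-bp paired-end read sets drawn from ~300-bp fragments
under a capture model that depletes fragments overlapping repetitive DNA
(hybridization probes are designed on unique sequence only, so
repeat-overlapping fragments are captured less efficiently).

Every generator is deterministic given its seed; stream seeds are derived
from a single master seed by fixed offsets.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# offsets for deriving independent RNG streams from one master seed
_SEED_MOD = 2**31
_STREAM_REFERENCE = 11
_STREAM_ELEMENT = 23
_STREAM_FRAGMENTS = 37
_STREAM_ERRORS = 41
_STREAM_SNVS = 53


def derive_seed(master_seed: int, offset: int) -> int:
    """Derive a sub-stream seed from a master seed; stays below 2**31."""
    return (int(master_seed) * 1_000_003 + offset) % _SEED_MOD


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def random_dna(length: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatAnnotation:
    """A repeat interval on a region: 0-based half-open, family label, strand."""

    start: int
    end: int
    family: str
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad repeat interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRegion:
    """A named reference sequence with repeat-interval annotations."""

    name: str
    sequence: str
    repeat_annotations: list[RepeatAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if len(self.sequence) == 0:
            raise ValueError("empty reference sequence")
        for ann in self.repeat_annotations:
            if ann.end > len(self.sequence):
                raise ValueError(f"annotation {ann} exceeds region length")

    def __len__(self) -> int:
        return len(self.sequence)

    def repeat_mask(self) -> np.ndarray:
        """Boolean mask, True at annotated repeat bases."""
        mask = np.zeros(len(self.sequence), dtype=bool)
        for ann in self.repeat_annotations:
            mask[ann.start:ann.end] = True
        return mask

    @property
    def repeat_fraction(self) -> float:
        """Fraction of bases covered by repeat annotations (union)."""
        return float(self.repeat_mask().mean())


@dataclass(frozen=True)
class TEElement:
    """An LTR retroelement: identical 5'/3' LTRs flanking an internal sequence."""

    family: str
    ltr_sequence: str
    internal_sequence: str

    @property
    def sequence(self) -> str:
        return self.ltr_sequence + self.internal_sequence + self.ltr_sequence

    @property
    def ltr_length(self) -> int:
        return len(self.ltr_sequence)

    @property
    def internal_length(self) -> int:
        return len(self.internal_sequence)

    @property
    def total_length(self) -> int:
        return 2 * len(self.ltr_sequence) + len(self.internal_sequence)


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth record for one simulated allele/sample."""

    sample: str
    genotype: str                      # wt | het | hom
    insertion_position: int | None     # 1-based coordinate of first duplicated base
    tsd_length: int
    family: str | None
    orientation: str | None            # + | -

    def __post_init__(self):
        if self.genotype not in ("wt", "het", "hom"):
            raise ValueError(f"bad genotype {self.genotype!r}")
        if self.genotype == "wt" and self.insertion_position is not None:
            raise ValueError("wildtype truth must not carry an insertion record")


@dataclass(frozen=True)
class FragmentOrigin:
    """Where a simulated fragment came from (haplotype coordinates)."""

    haplotype: str
    start: int
    end: int
    strand: str


@dataclass
class ReadPair:
    """Two inward-facing mates from opposite ends of one fragment."""

    pair_id: str
    mate1: str
    qual1: str
    mate2: str
    qual2: str
    origin: FragmentOrigin | None = None


@dataclass(frozen=True)
class Haplotype:
    """A sample chromosome: sequence plus a repeat mask used by the capture model."""

    name: str
    sequence: str
    repeat_mask: np.ndarray = field(repr=False, hash=False, compare=False)


# ---------------------------------------------------------------------------
# Reference and element construction
# ---------------------------------------------------------------------------

def build_reference(
    length: int,
    repeat_fraction: float,
    n_families: int = 3,
    seed: int = 0,
    divergence: float = 0.05,
    min_spacing: int = 80,
    name: str = "region",
) -> GenomeRegion:
    """Build a reference region whose annotated repeat content approximates
    ``repeat_fraction``.

    Repeats are diverged copies of per-family consensus sequences, so that a
    short read drawn from one copy genuinely multi-maps to the others. Copies
    are non-overlapping and separated by at least ``min_spacing`` unique bases
    so unique anchors exist between them.
    """
    if length <= 0:
        raise ValueError("reference length must be positive")
    if not 0.0 <= repeat_fraction <= 1.0:
        raise ValueError("repeat_fraction must lie in [0, 1]")
    if repeat_fraction > 0 and length < 1000:
        raise ValueError("need length >= 1000 for nonzero repeat_fraction")
    if n_families <= 0:
        raise ValueError("n_families must be positive")

    rng = np.random.default_rng(derive_seed(seed, _STREAM_REFERENCE))
    seq = np.array(list(random_dna(length, rng)))
    annotations: list[RepeatAnnotation] = []
    if repeat_fraction > 0:
        max_cons = max(200, min(1200, length // 4))
        cons_lens = rng.integers(max(150, max_cons // 3), max_cons + 1,
                                 size=n_families)
        consensi = [random_dna(int(n), rng) for n in cons_lens]

        target = int(round(repeat_fraction * length))
        occupied: list[tuple[int, int]] = []
        placed = 0
        attempts = 0
        while placed < target and attempts < 5000:
            attempts += 1
            fam = int(rng.integers(0, n_families))
            cons = consensi[fam]
            copy_len = min(len(cons), target - placed)
            if copy_len < 50:
                copy_len = min(len(cons), 50)
            if placed + copy_len > target + 50:
                break
            start = int(rng.integers(0, length - copy_len + 1))
            end = start + copy_len
            if any(start < e + min_spacing and end > s - min_spacing
                   for s, e in occupied):
                continue
            copy = _diverge(cons[:copy_len], divergence, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                copy = revcomp(copy)
            seq[start:end] = list(copy)
            occupied.append((start, end))
            annotations.append(RepeatAnnotation(start, end, f"fam{fam}", strand))
            placed += copy_len
        annotations.sort(key=lambda a: a.start)
    return GenomeRegion(name, "".join(seq), annotations)


def _diverge(sequence: str, rate: float, rng: np.random.Generator) -> str:
    """Apply random substitutions at the given per-base rate."""
    if rate <= 0:
        return sequence
    arr = np.array(list(sequence))
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def build_etn(ltr_len: int = 847, internal_len: int = 6834, seed: int = 0,
              family: str = "ETn") -> TEElement:
    """Build an LTR retroelement with identical 5'/3' LTRs.

    Defaults reproduce the Sd element geometry: 847-bp LTRs and a 6,834-bp
    internal sequence, 8,528 bp in total.
    """
    if ltr_len <= 0 or internal_len <= 0:
        raise ValueError("LTR and internal lengths must be positive")
    rng = np.random.default_rng(derive_seed(seed, _STREAM_ELEMENT))
    return TEElement(family, random_dna(ltr_len, rng), random_dna(internal_len, rng))


def insert_element(
    region: GenomeRegion,
    element: TEElement,
    position: int,
    tsd_length: int = 6,
    orientation: str = "+",
    sample: str = "sample",
    genotype: str = "het",
) -> tuple[str, SampleTruth]:
    """Insert ``element`` into ``region`` with a target-site duplication.

    ``position`` is the 1-based coordinate of the first duplicated base: the
    ``tsd_length`` reference bases starting there appear immediately 5' and 3'
    of the element in the mutant haplotype, and no reference base is lost.
    """
    if tsd_length < 0:
        raise ValueError("tsd_length must be non-negative")
    if orientation not in "+-":
        raise ValueError(f"bad orientation {orientation!r}")
    p0 = position - 1
    if not (0 <= p0 and p0 + tsd_length <= len(region)):
        raise ValueError(f"insertion position {position} out of range")
    elem_seq = element.sequence if orientation == "+" else revcomp(element.sequence)
    ref = region.sequence
    mutant = ref[: p0 + tsd_length] + elem_seq + ref[p0:]
    truth = SampleTruth(sample, genotype, position, tsd_length,
                        element.family, orientation)
    return mutant, truth


def wildtype_haplotype(region: GenomeRegion, name: str = "wt_hap") -> Haplotype:
    return Haplotype(name, region.sequence, region.repeat_mask())


def mutant_haplotype(
    region: GenomeRegion,
    element: TEElement,
    position: int,
    tsd_length: int = 6,
    orientation: str = "+",
    name: str = "mut_hap",
    sample: str = "sample",
    genotype: str = "het",
) -> tuple[Haplotype, SampleTruth]:
    """Mutant haplotype with the element region masked as repetitive.

    The inserted element is itself repetitive DNA, so the capture model must
    treat it as probe-free sequence: fragments overlapping it are depleted,
    which is what skews support toward the wildtype allele in real data.
    """
    mutant_seq, truth = insert_element(region, element, position, tsd_length,
                                       orientation, sample, genotype)
    p0 = position - 1
    ref_mask = region.repeat_mask()
    mask = np.concatenate([
        ref_mask[: p0 + tsd_length],
        np.ones(element.total_length, dtype=bool),
        ref_mask[p0:],
    ])
    assert mask.size == len(mutant_seq)
    return Haplotype(name, mutant_seq, mask), truth


def make_sample_haplotypes(
    region: GenomeRegion,
    genotype: str,
    element: TEElement | None = None,
    position: int | None = None,
    tsd_length: int = 6,
    orientation: str = "+",
    sample: str = "sample",
) -> tuple[list[Haplotype], SampleTruth]:
    """Diploid haplotype set for a wt / het / hom sample."""
    if genotype == "wt":
        hap = wildtype_haplotype(region)
        return [hap, hap], SampleTruth(sample, "wt", None, 0, None, None)
    if element is None or position is None:
        raise ValueError("mutant genotypes need an element and a position")
    mut, truth = mutant_haplotype(region, element, position, tsd_length,
                                  orientation, sample=sample, genotype=genotype)
    if genotype == "het":
        return [wildtype_haplotype(region), mut], truth
    if genotype == "hom":
        return [mut, mut], truth
    raise ValueError(f"bad genotype {genotype!r}")


def choose_insertion_site(region: GenomeRegion, flank: int = 200,
                          seed: int = 0) -> int:
    """Pick a 1-based insertion position with repeat-free flanks.

    Insertion detection needs unique sequence on both sides for anchors to map
    uniquely; this picks a position (deterministically per seed) whose +/-
    ``flank`` bp neighbourhood carries no annotated repeat. The flank
    requirement is relaxed if the region is too repeat-dense to satisfy it.
    """
    mask = region.repeat_mask()
    rng = np.random.default_rng(derive_seed(seed, _STREAM_SNVS + 1))
    for fl in (flank, flank // 2, flank // 4, 10):
        ok = [p for p in range(fl, len(region) - fl)
              if not mask[p - fl: p + fl].any()]
        if ok:
            return int(ok[int(rng.integers(0, len(ok)))]) + 1
    raise ValueError("no repeat-free insertion site available")


def plant_snvs(region: GenomeRegion, n: int, seed: int = 0,
               min_gap: int = 50) -> tuple[str, list[tuple[int, str, str]]]:
    """Plant ``n`` substitutions in unique (non-repeat) sequence.

    Returns the altered sequence and a list of (0-based position, ref base,
    alt base). Used to exercise the variant caller with known heterozygous
    sites when the altered sequence is paired with the reference.
    """
    rng = np.random.default_rng(derive_seed(seed, _STREAM_SNVS))
    mask = region.repeat_mask()
    candidates = np.flatnonzero(~mask)
    rng.shuffle(candidates)
    chosen: list[int] = []
    for p in candidates:
        if all(abs(p - q) >= min_gap for q in chosen):
            chosen.append(int(p))
        if len(chosen) == n:
            break
    if len(chosen) < n:
        raise ValueError(f"only {len(chosen)} unique positions available")
    chosen.sort()
    arr = list(region.sequence)
    out = []
    for p in chosen:
        ref = arr[p]
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(0, 3))]
        arr[p] = alt
        out.append((p, ref, alt))
    return "".join(arr), out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def simulate_read_pairs(
    haplotypes: Sequence[Haplotype],
    coverage: float,
    read_len: int = 36,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    error_rate: float = 0.005,
    capture_floor: float = 0.05,
    capture: bool = True,
    seed: int = 0,
    sample: str = "sample",
) -> list[ReadPair]:
    """Simulate inward-facing paired-end reads under targeted capture.

    Fragments are drawn uniformly from the haplotype set (equal prior per
    haplotype before capture), with lengths ~ Normal(frag_mean, frag_sd)
    truncated to [2*read_len, 2*frag_mean]. Each fragment is accepted with
    probability max(capture_floor, fraction of its bases outside annotated
    repeats); sampling continues until the target pair count
    round(coverage * mean haplotype length / (2 * read_len)) is reached, so
    capture bias reshapes where coverage lands rather than the read yield.
    Base-call errors are uniform substitutions at ``error_rate``.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0.0 <= error_rate <= 1.0:
        raise ValueError("error_rate must lie in [0, 1]")
    if not 0.0 < capture_floor <= 1.0:
        raise ValueError("capture_floor must lie in (0, 1]")
    if frag_mean < 2 * read_len:
        raise ValueError("fragment mean must be at least twice the read length")
    for hap in haplotypes:
        if len(hap.sequence) < frag_mean:
            raise ValueError(f"haplotype {hap.name} shorter than a fragment")

    frag_rng = np.random.default_rng(derive_seed(seed, _STREAM_FRAGMENTS))
    err_rng = np.random.default_rng(derive_seed(seed, _STREAM_ERRORS))

    mean_len = float(np.mean([len(h.sequence) for h in haplotypes]))
    n_target = int(round(coverage * mean_len / (2 * read_len)))
    # prefix sums of the repeat masks give O(1) unique-fraction lookups
    cums = [np.concatenate([[0], np.cumsum(h.repeat_mask.astype(np.int64))])
            for h in haplotypes]

    lo, hi = 2 * read_len, int(2 * frag_mean)
    pairs: list[ReadPair] = []
    qual = "I" * read_len
    attempts = 0
    max_attempts = max(1000, int(n_target / capture_floor * 4))
    while len(pairs) < n_target and attempts < max_attempts:
        attempts += 1
        hi_idx = int(frag_rng.integers(0, len(haplotypes)))
        hap = haplotypes[hi_idx]
        flen = int(round(frag_rng.normal(frag_mean, frag_sd)))
        flen = min(max(flen, lo), hi, len(hap.sequence))
        start = int(frag_rng.integers(0, len(hap.sequence) - flen + 1))
        end = start + flen
        if capture:
            rep = cums[hi_idx][end] - cums[hi_idx][start]
            p_accept = max(capture_floor, 1.0 - rep / flen)
            if frag_rng.random() >= p_accept:
                continue
        frag = hap.sequence[start:end]
        strand = "+" if frag_rng.random() < 0.5 else "-"
        left = frag[:read_len]
        right = revcomp(frag[-read_len:])
        mate1, mate2 = (left, right) if strand == "+" else (right, left)
        if error_rate > 0:
            mate1 = _apply_errors(mate1, error_rate, err_rng)
            mate2 = _apply_errors(mate2, error_rate, err_rng)
        pairs.append(ReadPair(
            pair_id=f"{sample}:{len(pairs)}",
            mate1=mate1, qual1=qual, mate2=mate2, qual2=qual,
            origin=FragmentOrigin(hap.name, start, end, strand),
        ))
    return pairs


def _apply_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if hits.size == 0:
        return read
    arr = list(read)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# File output (FASTA / FASTQ / BED / TSV truth)
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pair(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to <prefix>_1.fastq / <prefix>_2.fastq (Phred+33)."""
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_1.fastq")
    p2 = prefix.with_name(prefix.name + "_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rp in pairs:
            f1.write(f"@{rp.pair_id}/1\n{rp.mate1}\n+\n{rp.qual1}\n")
            f2.write(f"@{rp.pair_id}/2\n{rp.mate2}\n+\n{rp.qual2}\n")
    return p1, p2


def read_fastq_pair(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    recs1 = list(SeqIO.parse(str(path1), "fastq"))
    recs2 = list(SeqIO.parse(str(path2), "fastq"))
    if len(recs1) != len(recs2):
        raise ValueError("mate files differ in read count")
    pairs = []
    for r1, r2 in zip(recs1, recs2):
        pid = r1.id.rsplit("/", 1)[0]
        q1 = "".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"])
        q2 = "".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"])
        pairs.append(ReadPair(pid, str(r1.seq).upper(), q1,
                              str(r2.seq).upper(), q2))
    return pairs


def write_bed(region: GenomeRegion, path: str | Path) -> None:
    """Repeat annotations as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for ann in region.repeat_annotations:
            fh.write(f"{region.name}\t{ann.start}\t{ann.end}\t{ann.family}"
                     f"\t0\t{ann.strand}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            name, start, end = f[0], int(f[1]), int(f[2])
            family = f[3] if len(f) > 3 else "."
            strand = f[5] if len(f) > 5 else "+"
            out.append((name, start, end, family, strand))
    return out


def write_truth_table(truths: Sequence[SampleTruth], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgenotype\tposition_1based\ttsd\tfamily\torientation\n")
        for t in truths:
            pos = "" if t.insertion_position is None else str(t.insertion_position)
            fh.write(f"{t.sample}\t{t.genotype}\t{pos}\t{t.tsd_length}"
                     f"\t{t.family or ''}\t{t.orientation or ''}\n")


def write_fragment_table(pairs: Sequence[ReadPair], path: str | Path) -> None:
    """Per-pair fragment provenance (haplotype coordinates)."""
    with open(path, "w") as fh:
        fh.write("pair_id\thaplotype\tstart\tend\tstrand\n")
        for rp in pairs:
            o = rp.origin
            if o is not None:
                fh.write(f"{rp.pair_id}\t{o.haplotype}\t{o.start}\t{o.end}"
                         f"\t{o.strand}\n")
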
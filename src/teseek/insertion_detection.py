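"""One-end-anchored insertion detection with breakpoint/TSD refinement.

The core inference: read pairs in which one end maps uniquely inside the
target region while the mate fails to map (or multi-maps) but matches a
repeat-family consensus are collected as anchor candidates. Forward-strand
anchors sit upstream (left) of an insertion, reverse-strand anchors
downstream (right). Candidates are clustered per side and family by
single-linkage within ``max_gap``; clusters need ``min_support`` distinct
pairs (default 5). A left/right cluster pair at compatible positions becomes
an insertion site.

Breakpoints are refined from junction reads — reads matching the reference up
to a base and the element terminus beyond it. Because a retroelement
insertion duplicates its target site, the left junction sits ``tsd`` bases
downstream of the right junction in reference coordinates, so
``tsd = left_breakpoint - right_breakpoint``. The reported position is the
right breakpoint (the first duplicated base), serialized 1-based.

Zygosity is called from support thresholds, not allele ratios: targeted
capture with repeat-free probes depletes insertion-allele fragments, so the
insertion:reference read ratio is systematically skewed and uninformative.
A site with essentially no reference-spanning pairs is homozygous; one with
substantial support on both alleles is heterozygous.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .read_mapping import AlignedPair, PairClass, Uniqueness
from .repeat_classification import (RepeatHit, RepeatLibrary, classify_repeat,
                                    passes_filters)
from .synthetic_data import GenomeRegion, RepeatAnnotation, revcomp

DEFAULT_MIN_SUPPORT = 5
DEFAULT_MAX_GAP = 300
DEFAULT_NOVELTY_WINDOW = 300
DEFAULT_HOM_MAX = 1
MIN_CLIP = 5


@dataclass(frozen=True)
class AnchorCandidate:
    """A uniquely anchored pair whose mate is repeat-classified."""

    pair_id: str
    anchor_start: int       # 0-based
    anchor_end: int
    anchor_strand: str
    side: str               # left | right
    mate_hit: RepeatHit


@dataclass
class AnchorCluster:
    side: str
    family: str
    start: int              # anchor interval, 0-based half-open
    end: int
    pair_ids: list[str]
    breakpoint: int         # left: max anchor end; right: min anchor start

    @property
    def support(self) -> int:
        return len(set(self.pair_ids))


@dataclass
class BreakpointRefinement:
    left_breakpoint: int | None     # 0-based: ref offset where element begins
    right_breakpoint: int | None    # 0-based: first duplicated base
    tsd_length: int | None
    orientation: str | None
    n_junction_reads: int
    ambiguous: bool = False


@dataclass
class InsertionCall:
    region: str
    position: int           # 1-based, first duplicated base
    ci_lo: int              # 1-based confidence interval
    ci_hi: int
    family: str
    orientation: str
    support: int            # insertion-supporting pairs (both sides)
    ref_support: int        # reference-spanning proper pairs
    zygosity: str           # het | hom | ambiguous
    tsd_length: int | None
    novel: bool


# ---------------------------------------------------------------------------
# Anchor collection and clustering
# ---------------------------------------------------------------------------

def collect_oea(aligned: Sequence[AlignedPair], library: RepeatLibrary,
                target_interval: tuple[int, int] | None = None,
                min_identity: float | None = None,
                min_len: int | None = None) -> list[AnchorCandidate]:
    """One candidate per OEA pair whose anchor lies in the target interval and
    whose (filter-passing) mate matches the repeat library."""
    kwargs = {}
    if min_identity is not None:
        kwargs["min_identity"] = min_identity
    if min_len is not None:
        kwargs["min_len"] = min_len
    out: list[AnchorCandidate] = []
    for ap in aligned:
        if ap.pair_class is not PairClass.OEA:
            continue
        if ap.rec1.uniqueness is Uniqueness.UNIQUE:
            anchor, mate = ap.rec1, ap.rec2
        else:
            anchor, mate = ap.rec2, ap.rec1
        if target_interval is not None:
            lo, hi = target_interval
            if not (lo <= anchor.start < hi):
                continue
        if not passes_filters(mate.sequence):
            continue
        hit = classify_repeat(mate.sequence, library, **kwargs)
        if hit is None:
            continue
        side = "left" if anchor.strand == "+" else "right"
        out.append(AnchorCandidate(ap.rec1.read_id, anchor.start, anchor.end,
                                   anchor.strand, side, hit))
    out.sort(key=lambda c: c.anchor_start)
    return out


def cluster_anchors(candidates: Sequence[AnchorCandidate],
                    max_gap: int = DEFAULT_MAX_GAP,
                    min_support: int = DEFAULT_MIN_SUPPORT) -> list[AnchorCluster]:
    """Single-linkage clustering per (side, family); clusters below
    ``min_support`` distinct pairs are discarded."""
    groups: dict[tuple[str, str], list[AnchorCandidate]] = {}
    for c in candidates:
        groups.setdefault((c.side, c.mate_hit.family), []).append(c)
    clusters: list[AnchorCluster] = []
    for (side, family), group in groups.items():
        group.sort(key=lambda c: c.anchor_start)
        run: list[AnchorCandidate] = []
        for c in group:
            if run and c.anchor_start - run[-1].anchor_start > max_gap:
                clusters.extend(_finalize(run, side, family, min_support))
                run = []
            run.append(c)
        clusters.extend(_finalize(run, side, family, min_support))
    clusters.sort(key=lambda cl: cl.start)
    return clusters


def _finalize(run: list[AnchorCandidate], side: str, family: str,
              min_support: int) -> list[AnchorCluster]:
    if not run or len({c.pair_id for c in run}) < min_support:
        return []
    start = min(c.anchor_start for c in run)
    end = max(c.anchor_end for c in run)
    bp = end if side == "left" else start
    return [AnchorCluster(side, family, start, end,
                          [c.pair_id for c in run], bp)]


def pair_clusters(clusters: Sequence[AnchorCluster],
                  max_pair_dist: int = DEFAULT_MAX_GAP
                  ) -> list[tuple[AnchorCluster, AnchorCluster]]:
    """Pair left with right clusters of the same family whose breakpoint
    estimates agree within ``max_pair_dist``; greedy nearest-first."""
    lefts = [c for c in clusters if c.side == "left"]
    rights = [c for c in clusters if c.side == "right"]
    pairs = []
    used: set[id] = set()
    for lc in lefts:
        best = None
        for rc in rights:
            if id(rc) in used or rc.family != lc.family:
                continue
            d = abs(lc.breakpoint - rc.breakpoint)
            if d <= max_pair_dist and (best is None or d < best[0]):
                best = (d, rc)
        if best:
            used.add(id(best[1]))
            pairs.append((lc, best[1]))
    return pairs


# ---------------------------------------------------------------------------
# Breakpoint / TSD refinement from junction reads
# ---------------------------------------------------------------------------

def refine_breakpoints(left_cluster: AnchorCluster | None,
                       right_cluster: AnchorCluster | None,
                       junction_reads: Sequence[str],
                       reference: str,
                       element_sequence: str,
                       search_pad: int = 300,
                       min_clip: int = MIN_CLIP,
                       max_elem_mismatch: int = 1) -> BreakpointRefinement:
    """Pin per-side breakpoints at base resolution from split reads.

    A left-junction read is reference sequence followed by the element's
    first bases; a right-junction read is the element's last bases followed
    by reference. Each read votes (majority per side) for the reference
    coordinate of its junction; both element orientations are tried and the
    orientation is taken from the winning votes. ``tsd = left - right`` when
    non-negative; a negative difference is reported ambiguous with tsd 0.
    """
    if left_cluster is None and right_cluster is None:
        raise ValueError("need at least one cluster")
    est = (left_cluster or right_cluster).breakpoint
    if left_cluster is not None and right_cluster is not None:
        est = (left_cluster.breakpoint + right_cluster.breakpoint) // 2
    lo = max(0, est - search_pad)
    hi = min(len(reference), est + search_pad)
    window = reference[lo:hi]

    left_votes: dict[str, Counter] = {"+": Counter(), "-": Counter()}
    right_votes: dict[str, Counter] = {"+": Counter(), "-": Counter()}
    n_junction = 0
    elems = {"+": element_sequence, "-": revcomp(element_sequence)}
    for seq in junction_reads:
        found = False
        for read in (seq, revcomp(seq)):
            for orient, elem in elems.items():
                lbp = _left_junction_vote(read, elem, window, lo, est,
                                          min_clip, max_elem_mismatch)
                if lbp is not None:
                    left_votes[orient][lbp] += 1
                    found = True
                rbp = _right_junction_vote(read, elem, window, lo, est,
                                           min_clip, max_elem_mismatch)
                if rbp is not None:
                    right_votes[orient][rbp] += 1
                    found = True
        if found:
            n_junction += 1

    orient_score = {o: sum(left_votes[o].values()) + sum(right_votes[o].values())
                    for o in "+-"}
    orientation = max("+-", key=lambda o: orient_score[o]) \
        if any(orient_score.values()) else None
    lvotes = left_votes[orientation] if orientation else Counter()
    rvotes = right_votes[orientation] if orientation else Counter()
    left_bp = lvotes.most_common(1)[0][0] if lvotes else None
    right_bp = rvotes.most_common(1)[0][0] if rvotes else None
    tsd = None
    ambiguous = False
    if left_bp is not None and right_bp is not None:
        diff = left_bp - right_bp
        if diff >= 0:
            tsd = diff
        else:               # conflicting junction evidence
            tsd = 0
            ambiguous = True
        # conflicting votes within a side also flag ambiguity
        if (len(lvotes) > 1 and lvotes.most_common(2)[0][1] ==
                lvotes.most_common(2)[1][1]) or \
           (len(rvotes) > 1 and rvotes.most_common(2)[0][1] ==
                rvotes.most_common(2)[1][1]):
            ambiguous = True
    return BreakpointRefinement(left_bp, right_bp, tsd, orientation,
                                n_junction, ambiguous)


def _left_junction_vote(read: str, elem: str, window: str, window_offset: int,
                        est: int, min_clip: int, max_mm: int) -> int | None:
    """If ``read`` = ref-suffix + element-prefix, return the junction's
    reference coordinate (0-based offset where the element begins)."""
    L = len(read)
    best = None
    for k in range(min_clip, L - min_clip + 1):
        tail = read[k:]
        if _mismatches(tail, elem[:len(tail)], max_mm) > max_mm:
            continue
        refpart = read[:k]
        pos = window.find(refpart)
        while pos != -1:
            bp = window_offset + pos + k
            if best is None or abs(bp - est) < abs(best - est):
                best = bp
            pos = window.find(refpart, pos + 1)
    return best


def _right_junction_vote(read: str, elem: str, window: str, window_offset: int,
                         est: int, min_clip: int, max_mm: int) -> int | None:
    """If ``read`` = element-suffix + ref-prefix, return the reference
    coordinate of the first base after the element."""
    L = len(read)
    best = None
    for k in range(min_clip, L - min_clip + 1):
        head = read[:k]
        if _mismatches(head, elem[-k:], max_mm) > max_mm:
            continue
        refpart = read[k:]
        pos = window.find(refpart)
        while pos != -1:
            bp = window_offset + pos
            if best is None or abs(bp - est) < abs(best - est):
                best = bp
            pos = window.find(refpart, pos + 1)
    return best


def _orientation_vote(candidates: Sequence[AnchorCandidate],
                      left_cluster: AnchorCluster,
                      right_cluster: AnchorCluster) -> str | None:
    """Element orientation from mate strands relative to the consensus.

    A left-side mate is the inward (reverse) read of its fragment, so for a
    plus-orientation element it matches the consensus on the minus strand;
    a right-side mate matches on the plus strand. Majority vote."""
    ids = set(left_cluster.pair_ids) | set(right_cluster.pair_ids)
    votes = Counter()
    for c in candidates:
        if c.pair_id not in ids:
            continue
        s = c.mate_hit.strand
        if c.side == "left":
            votes["+" if s == "-" else "-"] += 1
        else:
            votes["+" if s == "+" else "-"] += 1
    return votes.most_common(1)[0][0] if votes else None


def _mismatches(a: str, b: str, limit: int) -> int:
    if len(a) != len(b):
        return limit + 1
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def call_insertion(left_cluster: AnchorCluster, right_cluster: AnchorCluster,
                   refinement: BreakpointRefinement | None,
                   aligned: Sequence[AlignedPair],
                   known_repeats: Sequence[RepeatAnnotation],
                   region_name: str,
                   read_len: int = 36,
                   min_support: int = DEFAULT_MIN_SUPPORT,
                   hom_max: int = DEFAULT_HOM_MAX,
                   novelty_window: int = DEFAULT_NOVELTY_WINDOW,
                   frag_mean: int = 300,
                   fallback_orientation: str | None = None) -> InsertionCall:
    """Assemble an insertion call from a paired cluster site."""
    family = left_cluster.family
    support = len(set(left_cluster.pair_ids) | set(right_cluster.pair_ids))

    if refinement is not None and refinement.right_breakpoint is not None:
        bp0 = refinement.right_breakpoint
        if refinement.left_breakpoint is not None:
            ci_lo0, ci_hi0 = bp0, bp0
        else:
            ci_lo0, ci_hi0 = bp0 - read_len, bp0 + read_len
    else:
        bp0 = right_cluster.breakpoint
        ci_lo0 = max(0, left_cluster.breakpoint - frag_mean)
        ci_hi0 = right_cluster.breakpoint + frag_mean

    # reference-spanning proper pairs: fragment covers the breakpoint with at
    # least a read length anchored on both sides
    ref_support = 0
    for ap in aligned:
        if ap.pair_class is not PairClass.PROPER:
            continue
        fwd, rev = ((ap.rec1, ap.rec2) if ap.rec1.strand == "+"
                    else (ap.rec2, ap.rec1))
        fs, fe = fwd.start, rev.end
        if fs + read_len <= bp0 and bp0 + read_len <= fe:
            ref_support += 1

    if ref_support <= hom_max:
        zygosity = "hom"
    elif ref_support >= min_support and support >= min_support:
        zygosity = "het"
    else:
        zygosity = "ambiguous"

    novel = not any(
        ann.family == family and
        ann.start - novelty_window <= bp0 < ann.end + novelty_window
        for ann in known_repeats)

    orientation = refinement.orientation if refinement else None
    if orientation is None:
        orientation = fallback_orientation or "+"

    tsd = refinement.tsd_length if refinement else None
    return InsertionCall(region_name, bp0 + 1, ci_lo0 + 1, ci_hi0 + 1,
                         family, orientation, support, ref_support,
                         zygosity, tsd, novel)


def detect_insertions(aligned: Sequence[AlignedPair], library: RepeatLibrary,
                      region: GenomeRegion,
                      min_support: int = DEFAULT_MIN_SUPPORT,
                      max_gap: int = DEFAULT_MAX_GAP,
                      novelty_window: int = DEFAULT_NOVELTY_WINDOW,
                      hom_max: int = DEFAULT_HOM_MAX,
                      read_len: int = 36,
                      frag_mean: int = 300,
                      require_both_sides: bool = True,
                      target_interval: tuple[int, int] | None = None
                      ) -> list[InsertionCall]:
    """Full detection pass: OEA collection -> clustering -> pairing ->
    junction refinement -> calling."""
    candidates = collect_oea(aligned, library, target_interval)
    clusters = cluster_anchors(candidates, max_gap, min_support)
    sites = pair_clusters(clusters, max_pair_dist=frag_mean)
    if not require_both_sides:
        paired = {id(c) for lc, rc in sites for c in (lc, rc)}
        for c in clusters:
            if id(c) not in paired:
                sites.append((c, c))
    if not sites:
        return []

    # junction-read pool: every read that did not map uniquely
    junction_pool = []
    for ap in aligned:
        for rec in (ap.rec1, ap.rec2):
            if rec.uniqueness is not Uniqueness.UNIQUE:
                junction_pool.append(rec.sequence)

    calls = []
    for lc, rc in sites:
        elem = library.consensi[lc.family]
        refinement = refine_breakpoints(
            lc if lc.side == "left" else None,
            rc if rc.side == "right" else None,
            junction_pool, region.sequence, elem,
            search_pad=frag_mean)
        calls.append(call_insertion(lc, rc, refinement, aligned,
                                    region.repeat_annotations, region.name,
                                    read_len, min_support, hom_max,
                                    novelty_window, frag_mean,
                                    fallback_orientation=_orientation_vote(
                                        candidates, lc, rc)))
    calls.sort(key=lambda c: c.position)
    return calls


# ---------------------------------------------------------------------------
# Report output
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = ("region\tposition_1based\tci_lo\tci_hi\tfamily\torientation"
                   "\tins_support\tref_support\tzygosity\ttsd\tnovel")


def write_insertion_report(calls: Sequence[InsertionCall],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_REPORT_COLUMNS + "\n")
        for c in calls:
            tsd = "unknown" if c.tsd_length is None else str(c.tsd_length)
            fh.write(f"{c.region}\t{c.position}\t{c.ci_lo}\t{c.ci_hi}"
                     f"\t{c.family}\t{c.orientation}\t{c.support}"
                     f"\t{c.ref_support}\t{c.zygosity}\t{tsd}"
                     f"\t{str(c.novel).lower()}\n")


def write_insertion_bed(calls: Sequence[InsertionCall],
                        path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.region}\t{c.position - 1}\t{c.position}"
                     f"\t{c.family}_insertion\t{c.support}\t{c.orientation}\n")
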
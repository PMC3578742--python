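"""Aligner correctness against a brute-force Hamming oracle, pair
classification, and SAM round-tripping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pysam

import teseek as ts
from teseek.read_mapping import (AlignmentRecord, PairClass, Uniqueness,
                                 classify_pair, find_hits, fragment_interval)
from teseek.synthetic_data import revcomp
from conftest import brute_force_hits


class TestAlignRead:
    def test_exact_unique_copy_maps_at_truth(self, region, index):
        mask = region.repeat_mask()
        start = next(p for p in range(len(region) - 36)
                     if not mask[p:p + 36].any())
        read = region.sequence[start:start + 36]
        rec = ts.align_read("r1", 1, read, "I" * 36, index)
        assert rec.uniqueness is Uniqueness.UNIQUE
        assert (rec.start, rec.strand, rec.mismatches) == (start, "+", 0)

    def test_identical_ltr_copies_force_multi(self, region, etn, index):
        """A read from inside one LTR copy of a planted element hits both
        identical copies and must classify multi."""
        mutant, _ = ts.insert_element(region, etn, 2000, 6)
        mut_region = ts.GenomeRegion("mut", mutant)
        mut_index = ts.ReferenceIndex("mut", mutant)
        read = etn.ltr_sequence[100:136]
        rec = ts.align_read("r1", 1, read, "I" * 36, mut_index)
        assert rec.uniqueness is Uniqueness.MULTI
        best = rec.hits[0].mismatches
        assert sum(1 for h in rec.hits if h.mismatches == best) >= 2

    def test_mostly_n_read_unmapped(self, index):
        rec = ts.align_read("r1", 1, "N" * 36, "I" * 36, index)
        assert rec.uniqueness is Uniqueness.UNMAPPED
        rec = ts.align_read("r1", 1, "N" * 10 + "A" * 26, "I" * 36, index)
        assert rec.uniqueness is Uniqueness.UNMAPPED

    def test_hit_set_equals_brute_force_scan(self, region, index):
        """Seeded search is exhaustive: identical hit sets to the oracle for
        exact, mutated and random reads."""
        rng = np.random.default_rng(42)
        reads = []
        for _ in range(60):                      # reads copied from reference
            s = int(rng.integers(0, len(region) - 36))
            read = list(region.sequence[s:s + 36])
            for _ in range(int(rng.integers(0, 4))):   # up to 3 mutations
                i = int(rng.integers(0, 36))
                read[i] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            if rng.random() < 0.5:
                read = revcomp(read)
            reads.append(read)
        for _ in range(40):                      # random reads
            reads.append("".join("ACGT"[i] for i in rng.integers(0, 4, 36)))
        for read in reads:
            expected = brute_force_hits(read, region.sequence, 2)
            got = {(h.start, h.strand, h.mismatches)
                   for h in find_hits(read, index, 2)}
            assert got == expected

    def test_oracle_equivalence_on_50kb_reference(self):
        big = ts.build_reference(50_000, 0.4, n_families=4, seed=8)
        index = ts.ReferenceIndex(big.name, big.sequence)
        rng = np.random.default_rng(7)
        for _ in range(40):
            s = int(rng.integers(0, len(big) - 36))
            read = list(big.sequence[s:s + 36])
            for i in rng.integers(0, 36, size=int(rng.integers(0, 3))):
                read[int(i)] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            expected = brute_force_hits(read, big.sequence, 2)
            got = {(h.start, h.strand, h.mismatches)
                   for h in find_hits(read, index, 2)}
            assert got == expected

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_oracle_equivalence_property(self, data):
        ref = ts.build_reference(2_000, 0.3, n_families=2, seed=5)
        index = ts.ReferenceIndex(ref.name, ref.sequence)
        start = data.draw(st.integers(0, len(ref) - 36))
        read = list(ref.sequence[start:start + 36])
        n_mut = data.draw(st.integers(0, 3))
        for _ in range(n_mut):
            i = data.draw(st.integers(0, 35))
            read[i] = data.draw(st.sampled_from("ACGT"))
        read = "".join(read)
        expected = brute_force_hits(read, ref.sequence, 2)
        got = {(h.start, h.strand, h.mismatches)
               for h in find_hits(read, index, 2)}
        assert got == expected

    def test_reverse_complement_symmetry(self, region, index):
        rng = np.random.default_rng(3)
        for _ in range(25):
            s = int(rng.integers(0, len(region) - 36))
            read = region.sequence[s:s + 36]
            fwd = {(h.start, h.strand, h.mismatches)
                   for h in find_hits(read, index, 2)}
            rev = {(h.start, "-" if h.strand == "+" else "+", h.mismatches)
                   for h in find_hits(revcomp(read), index, 2)}
            assert fwd == rev

    def test_leftmost_best_hit_listed_first(self, index):
        seq = index.sequence
        read = seq[1000:1036]
        hits = find_hits(read, index, 2)
        best = hits[0].mismatches
        starts = [h.start for h in hits if h.mismatches == best]
        assert starts == sorted(starts)


def _rec(read_id="p", mate=1, start=None, strand=None,
         uniqueness=Uniqueness.UNMAPPED, aligned_len=36):
    return AlignmentRecord(read_id, mate, "A" * 36, "I" * 36,
                           reference="region" if start is not None else None,
                           start=start, strand=strand,
                           mismatches=0 if start is not None else None,
                           aligned_len=aligned_len if start is not None else 0,
                           uniqueness=uniqueness)


class TestClassifyPair:
    def test_inward_facing_in_bounds_is_proper(self):
        r1 = _rec(mate=1, start=1000, strand="+", uniqueness=Uniqueness.UNIQUE)
        r2 = _rec(mate=2, start=1264, strand="-", uniqueness=Uniqueness.UNIQUE)
        assert classify_pair(r1, r2, (150, 500)) is PairClass.PROPER
        assert fragment_interval(r1, r2) == (1000, 1300)

    def test_unique_anchor_with_unmapped_mate_is_oea(self):
        r1 = _rec(mate=1, start=1000, strand="+", uniqueness=Uniqueness.UNIQUE)
        r2 = _rec(mate=2)
        assert classify_pair(r1, r2) is PairClass.OEA

    def test_unique_anchor_with_multi_mate_is_oea(self):
        r1 = _rec(mate=1)
        r2 = _rec(mate=2, start=500, strand="-", uniqueness=Uniqueness.UNIQUE)
        r1m = _rec(mate=1, start=700, strand="+", uniqueness=Uniqueness.MULTI)
        assert classify_pair(r1m, r2) is PairClass.OEA

    def test_both_unmapped(self):
        assert classify_pair(_rec(mate=1), _rec(mate=2)) is \
            PairClass.BOTH_UNMAPPED

    def test_outward_or_out_of_bounds_is_discordant(self):
        r1 = _rec(mate=1, start=1264, strand="+", uniqueness=Uniqueness.UNIQUE)
        r2 = _rec(mate=2, start=1000, strand="-", uniqueness=Uniqueness.UNIQUE)
        assert classify_pair(r1, r2, (150, 500)) is PairClass.DISCORDANT_OTHER
        r3 = _rec(mate=2, start=9000, strand="-", uniqueness=Uniqueness.UNIQUE)
        r4 = _rec(mate=1, start=1000, strand="+", uniqueness=Uniqueness.UNIQUE)
        assert classify_pair(r4, r3, (150, 500)) is PairClass.DISCORDANT_OTHER

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            classify_pair(_rec(read_id="a"), _rec(read_id="b"))

    def test_every_simulated_pair_gets_exactly_one_class(self, wt_run):
        classes = [ap.pair_class for ap in wt_run["aligned"]]
        assert all(isinstance(c, PairClass) for c in classes)
        proper = sum(c is PairClass.PROPER for c in classes) / len(classes)
        assert proper >= 0.95       # wildtype error-free data


class TestSamRoundtrip:
    def test_zero_based_start_serializes_to_pos_1(self, tmp_path):
        r1 = _rec(mate=1, start=0, strand="+", uniqueness=Uniqueness.UNIQUE)
        r2 = _rec(mate=2, start=264, strand="-", uniqueness=Uniqueness.UNIQUE)
        ap = ts.read_mapping.AlignedPair(r1, r2, classify_pair(r1, r2))
        path = tmp_path / "one.sam"
        ts.write_sam([ap], "region", 10_000, path)
        line = [l for l in path.read_text().splitlines()
                if not l.startswith("@")][0]
        assert line.split("\t")[3] == "1"

    def test_full_roundtrip_reproduces_records(self, het_run, region, tmp_path):
        aligned = het_run["aligned"][:1000]
        path = tmp_path / "run.sam"
        ts.write_sam(aligned, region.name, len(region), path)
        back = ts.read_sam(path)
        assert len(back) == len(aligned)
        orig = {(ap.rec1.read_id,): ap for ap in aligned}
        for ap_b in back:
            ap_o = orig[(ap_b.rec1.read_id,)]
            for ro, rb in ((ap_o.rec1, ap_b.rec1), (ap_o.rec2, ap_b.rec2)):
                assert rb.sequence == ro.sequence
                assert rb.uniqueness == ro.uniqueness
                if ro.mapped:
                    assert (rb.start, rb.strand) == (ro.start, ro.strand)
                    assert rb.mismatches == ro.mismatches
            assert ap_b.pair_class == ap_o.pair_class

    def test_output_validates_against_independent_field_split(self, het_run,
                                                              region, tmp_path):
        """pysam writes the SAM; a hand-split of the text must agree with
        what pysam reads back (1000-pair fixture)."""
        aligned = het_run["aligned"][:1000]
        path = tmp_path / "check.sam"
        ts.write_sam(aligned, region.name, len(region), path)
        body = [l.split("\t") for l in path.read_text().splitlines()
                if not l.startswith("@")]
        assert len(body) == 2000
        with pysam.AlignmentFile(str(path)) as fh:
            for fields, seg in zip(body, fh):
                assert fields[0] == seg.query_name
                assert int(fields[1]) == seg.flag
                if not seg.is_unmapped:
                    assert int(fields[3]) == seg.reference_start + 1
                assert fields[9] == (seg.query_sequence or "*")

    def test_unmapped_mate_inherits_anchor_position(self, tmp_path):
        r1 = _rec(mate=1, start=500, strand="+", uniqueness=Uniqueness.UNIQUE)
        r2 = _rec(mate=2)
        ap = ts.read_mapping.AlignedPair(r1, r2, classify_pair(r1, r2))
        path = tmp_path / "oea.sam"
        ts.write_sam([ap], "region", 10_000, path)
        lines = [l.split("\t") for l in path.read_text().splitlines()
                 if not l.startswith("@")]
        unmapped = next(f for f in lines if int(f[1]) & 0x4)
        assert unmapped[2] == "region" and int(unmapped[3]) == 501
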
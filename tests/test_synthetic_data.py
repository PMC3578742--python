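"""Generator contracts: repeat content, element bookkeeping, TSD convention,
read-pair geometry, capture bias, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import teseek as ts
from teseek.synthetic_data import (revcomp, write_fastq_pair, read_fastq_pair,
                                   write_fasta, read_fasta, write_bed, read_bed)


class TestBuildReference:
    def test_repeat_fraction_near_target(self):
        region = ts.build_reference(10_000, 0.49, n_families=3, seed=1)
        annotated = int(region.repeat_mask().sum())
        assert abs(annotated - 4900) <= 490          # within 10%

    def test_zero_fraction_means_no_annotations(self):
        region = ts.build_reference(1_000, 0.0, seed=1)
        assert region.repeat_annotations == []
        assert region.repeat_fraction == 0.0

    @pytest.mark.parametrize("length,fraction", [(0, 0.3), (-5, 0.0),
                                                 (1000, 1.5), (1000, -0.1)])
    def test_invalid_inputs_rejected(self, length, fraction):
        with pytest.raises(ValueError):
            ts.build_reference(length, fraction, seed=1)

    def test_deterministic_given_seed(self):
        a = ts.build_reference(5_000, 0.4, seed=9)
        b = ts.build_reference(5_000, 0.4, seed=9)
        assert a.sequence == b.sequence
        assert a.repeat_annotations == b.repeat_annotations

    def test_repeat_copies_share_family_consensus(self):
        """Copies of one family must be similar enough to multi-map."""
        region = ts.build_reference(10_000, 0.49, n_families=1, seed=3)
        anns = [a for a in region.repeat_annotations if a.length >= 200]
        assert len(anns) >= 2
        a, b = anns[0], anns[1]
        n = min(a.length, b.length, 200)
        sa = region.sequence[a.start:a.start + n]
        sb = region.sequence[b.start:b.start + n]
        if a.strand != b.strand:
            sb = revcomp(region.sequence[b.end - n:b.end])
        ident = sum(x == y for x, y in zip(sa, sb)) / n
        assert ident > 0.8


class TestBuildEtn:
    def test_study_geometry_total_length(self):
        etn = ts.build_etn(847, 6834, seed=7)
        assert etn.total_length == 8528

    def test_minimal_element(self):
        assert ts.build_etn(1, 1, seed=0).total_length == 3

    def test_ltr_copies_identical(self, etn):
        seq = etn.sequence
        assert seq[:847] == seq[-847:]
        assert etn.ltr_sequence == seq[:847]

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            ts.build_etn(0, 100)
        with pytest.raises(ValueError):
            ts.build_etn(100, -1)


class TestInsertElement:
    def test_tsd_duplicated_on_both_sides(self, region, etn):
        pos = 2000
        mutant, truth = ts.insert_element(region, etn, pos, tsd_length=6)
        p0 = pos - 1
        left_flank = mutant[p0:p0 + 6]
        right_flank = mutant[p0 + 6 + etn.total_length:
                             p0 + 12 + etn.total_length]
        assert left_flank == right_flank == region.sequence[p0:p0 + 6]

    def test_zero_tsd_degenerate(self, region, etn):
        mutant, _ = ts.insert_element(region, etn, 2000, tsd_length=0)
        assert len(mutant) == len(region) + etn.total_length

    def test_reversible(self, region, etn):
        pos, tsd = 3000, 6
        mutant, _ = ts.insert_element(region, etn, pos, tsd_length=tsd)
        p0 = pos - 1
        restored = mutant[:p0 + tsd] + mutant[p0 + tsd + etn.total_length + tsd:]
        assert restored == region.sequence

    def test_out_of_range_rejected(self, region, etn):
        with pytest.raises(ValueError):
            ts.insert_element(region, etn, len(region) + 10)

    @settings(max_examples=50, deadline=None)
    @given(pos=st.integers(min_value=1, max_value=980),
           tsd=st.integers(min_value=0, max_value=20),
           orientation=st.sampled_from("+-"))
    def test_length_bookkeeping_and_base_conservation(self, pos, tsd,
                                                      orientation):
        """No reference base is ever lost; lengths are exact for all
        (position, tsd, orientation) combinations."""
        region = ts.build_reference(1_000, 0.0, seed=4)
        element = ts.build_etn(20, 50, seed=4)
        mutant, truth = ts.insert_element(region, element, pos, tsd,
                                          orientation)
        assert len(mutant) == len(region) + element.total_length + tsd
        p0 = pos - 1
        assert mutant[:p0 + tsd] == region.sequence[:p0 + tsd]
        assert mutant[p0 + tsd + element.total_length:] == region.sequence[p0:]
        assert truth.insertion_position == pos


class TestSimulateReadPairs:
    def test_error_free_reads_are_haplotype_substrings(self, wt_run):
        hap = wt_run["haplotypes"][0].sequence
        rc = revcomp(hap)
        for rp in wt_run["pairs"][:500]:
            assert rp.mate1 in hap or rp.mate1 in rc
            assert rp.mate2 in hap or rp.mate2 in rc

    def test_pair_count_matches_coverage(self, wt_run):
        # 50x on a 10-kb wildtype region: ~ 50*10000/(2*36) = 6944 pairs
        assert abs(len(wt_run["pairs"]) - 6944) <= 0.15 * 6944

    def test_mates_inward_facing_from_fragment_ends(self, wt_run):
        hap = wt_run["haplotypes"][0].sequence
        rp = wt_run["pairs"][0]
        o = rp.origin
        frag = hap[o.start:o.end]
        left, right = frag[:36], revcomp(frag[-36:])
        assert {rp.mate1, rp.mate2} == {left, right}

    def test_truth_junction_fragments_only_from_mutant(self, het_run, etn,
                                                       insertion_site):
        """Fragments overlapping the element junctions come from the mutant
        haplotype only (the wildtype allele has no junction)."""
        p0 = insertion_site - 1
        junctions = (p0 + 6, p0 + 6 + etn.total_length)   # mutant coords
        overlapping = [rp.origin for rp in het_run["pairs"]
                       if rp.origin.haplotype == "mut_hap"
                       and any(rp.origin.start < j < rp.origin.end
                               for j in junctions)]
        assert overlapping, "expected junction-spanning mutant fragments"
        wt_names = {rp.origin.haplotype for rp in het_run["pairs"]}
        assert "wt_hap" in wt_names                # both alleles sampled

    def test_capture_bias_depletes_repeat_fragments(self, region):
        """Fragments fully inside annotated repeats are sampled at a lower
        rate than fragments fully in unique sequence."""
        hap = ts.make_sample_haplotypes(region, "wt")[0][0]
        pairs = ts.simulate_read_pairs([hap], 50, error_rate=0.0, seed=5)
        mask = region.repeat_mask()
        cum = np.concatenate([[0], np.cumsum(mask)])
        in_repeat = in_unique = 0
        for rp in pairs:
            o = rp.origin
            rep = cum[o.end] - cum[o.start]
            if rep == o.end - o.start:
                in_repeat += 1
            elif rep == 0:
                in_unique += 1
        # normalize by available bases
        rep_frac = float(mask.mean())
        rate_repeat = in_repeat / max(rep_frac, 1e-9)
        rate_unique = in_unique / max(1 - rep_frac, 1e-9)
        assert rate_repeat < 0.25 * rate_unique

    def test_het_draws_both_haplotypes(self, het_run):
        names = [rp.origin.haplotype for rp in het_run["pairs"]]
        frac_mut = names.count("mut_hap") / len(names)
        # mutant allele depleted by capture (element is probe-free) but present
        assert 0.05 < frac_mut < 0.5

    def test_invalid_parameters_rejected(self, region):
        hap = ts.make_sample_haplotypes(region, "wt")[0][0]
        with pytest.raises(ValueError):
            ts.simulate_read_pairs([hap], 0)
        with pytest.raises(ValueError):
            ts.simulate_read_pairs([hap], 10, error_rate=2.0)
        with pytest.raises(ValueError):
            ts.simulate_read_pairs([hap], 10, read_len=200, frag_mean=300)

    def test_identical_seed_gives_byte_identical_fastq(self, region, tmp_path):
        hap = ts.make_sample_haplotypes(region, "wt")[0][0]
        files = []
        for sub in ("a", "b"):
            d = tmp_path / sub
            d.mkdir()
            pairs = ts.simulate_read_pairs([hap], 10, seed=11)
            files.append(write_fastq_pair(pairs, d / "reads"))
        for fa, fb in zip(*files):
            assert fa.read_bytes() == fb.read_bytes()


class TestFileFormats:
    def test_fasta_roundtrip(self, etn, tmp_path):
        path = tmp_path / "e.fasta"
        write_fasta([("ETn", etn.sequence)], path)
        assert read_fasta(path) == {"ETn": etn.sequence}

    def test_fastq_roundtrip(self, region, tmp_path):
        hap = ts.make_sample_haplotypes(region, "wt")[0][0]
        pairs = ts.simulate_read_pairs([hap], 5, seed=6)
        p1, p2 = write_fastq_pair(pairs, tmp_path / "reads")
        back = read_fastq_pair(p1, p2)
        assert [(p.pair_id, p.mate1, p.mate2) for p in back] == \
               [(p.pair_id, p.mate1, p.mate2) for p in pairs]

    def test_bed_zero_based_half_open(self, region, tmp_path):
        path = tmp_path / "r.bed"
        write_bed(region, path)
        rows = read_bed(path)
        assert len(rows) == len(region.repeat_annotations)
        first = region.repeat_annotations[0]
        assert rows[0][1] == first.start and rows[0][2] == first.end
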
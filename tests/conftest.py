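"""Shared fixtures: one deterministic study-scale simulation reused across
modules, plus a brute-force alignment oracle."""

import numpy as np
import pytest

import teseek as ts
from teseek.synthetic_data import revcomp


def brute_force_hits(read: str, reference: str, max_mismatch: int):
    """Exhaustive Hamming scan over every offset and strand.

    Independent oracle for the seeded aligner: N in the read mismatches
    every reference base.
    """
    hits = set()
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    for strand, seq in (("+", read), ("-", revcomp(read))):
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(ref) < len(arr):
            continue
        windows = np.lib.stride_tricks.sliding_window_view(ref, len(arr))
        mm = (windows != arr).sum(axis=1)
        for start in np.flatnonzero(mm <= max_mismatch):
            hits.add((int(start), strand, int(mm[start])))
    return hits


@pytest.fixture(scope="session")
def region():
    """10-kb reference at the study's ~49% repeat density."""
    return ts.build_reference(10_000, 0.49, n_families=3, seed=1)


@pytest.fixture(scope="session")
def etn():
    """The study element geometry: 847-bp LTRs, 6,834-bp internal."""
    return ts.build_etn(847, 6834, seed=1)


@pytest.fixture(scope="session")
def library(etn):
    return ts.RepeatLibrary.from_element(etn)


@pytest.fixture(scope="session")
def index(region):
    return ts.ReferenceIndex(region.name, region.sequence)


@pytest.fixture(scope="session")
def insertion_site(region):
    return ts.choose_insertion_site(region, seed=1)


@pytest.fixture(scope="session")
def het_run(region, etn, index, insertion_site):
    """Error-free heterozygous 50x simulation, aligned: the workhorse
    fixture for detection and variant tests."""
    haps, truth = ts.make_sample_haplotypes(region, "het", etn,
                                            insertion_site, 6, "+")
    pairs = ts.simulate_read_pairs(haps, 50, error_rate=0.0, seed=1)
    aligned = ts.align_pairs(pairs, index)
    return {"haplotypes": haps, "truth": truth, "pairs": pairs,
            "aligned": aligned}


@pytest.fixture(scope="session")
def wt_run(region, index):
    """Error-free wildtype 50x simulation, aligned (false-positive control)."""
    haps, truth = ts.make_sample_haplotypes(region, "wt")
    pairs = ts.simulate_read_pairs(haps, 50, error_rate=0.0, seed=2)
    aligned = ts.align_pairs(pairs, index)
    return {"haplotypes": haps, "truth": truth, "pairs": pairs,
            "aligned": aligned}
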
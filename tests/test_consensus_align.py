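"""Aligner contracts checked against brute-force placement oracles."""

import numpy as np
import pytest

from tedosage.consensus_align import (
    CONTIGUOUS,
    SPLIT,
    UNALIGNED,
    AlignParams,
    ConsensusAligner,
    ConsensusIndex,
    compute_depth,
    estimate_genome_depth,
    left_align_junction,
    normalized_copy_number,
)
from tedosage.synthetic_data import TEConsensus, VariantDefinition

from conftest import random_seq, simulate_strain

TOY_PARAMS = AlignParams(k=11, min_overhang=12, max_mismatch_rate=0.04)


# ----------------------------------------------------------------------
# brute-force oracles
# ----------------------------------------------------------------------

def brute_contiguous(read: str, cons: str, max_rate: float):
    """Exhaustive whole-read placement: (offset, mismatches) or None."""
    best = None
    for off in range(len(cons) - len(read) + 1):
        mism = sum(a != b for a, b in zip(read, cons[off : off + len(read)]))
        if mism <= max_rate * len(read) and (best is None or mism < best[1]):
            best = (off, mism)
    return best


def equivalent_junctions(seq: str, junction):
    """All (donor, acceptor) pairs producing the same derived sequence."""
    d, a = junction
    dl = a - d - 1
    target = seq[:d] + seq[a - 1 :]
    return [
        (d2, d2 + dl + 1)
        for d2 in range(1, len(seq) - dl)
        if seq[:d2] + seq[d2 + dl :] == target
    ]


# ----------------------------------------------------------------------
# contiguous alignment
# ----------------------------------------------------------------------

def test_exact_substring_reads_align_contiguously_everywhere(toy_consensus):
    """Error-free reads from every position agree with the exhaustive
    all-placements oracle (unique placement on a random consensus)."""
    cons = toy_consensus.sequence
    aligner = ConsensusAligner(toy_consensus, TOY_PARAMS)
    for off in range(0, len(cons) - 30 + 1, 3):
        read = cons[off : off + 30]
        aln = aligner.align("r", read)
        oracle = brute_contiguous(read, cons, TOY_PARAMS.max_mismatch_rate)
        assert aln.status == CONTIGUOUS
        assert aln.junctions == []
        assert (aln.segments[0][1][0], aln.mismatches) == oracle == (off, 0)


def test_single_mismatch_reads_match_oracle(toy_consensus):
    cons = toy_consensus.sequence
    aligner = ConsensusAligner(toy_consensus, TOY_PARAMS)
    rng = np.random.default_rng(0)
    for trial in range(40):
        off = int(rng.integers(0, len(cons) - 30))
        pos = int(rng.integers(0, 30))
        read = list(cons[off : off + 30])
        read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        read = "".join(read)
        aln = aligner.align("r", read)
        oracle = brute_contiguous(read, cons, TOY_PARAMS.max_mismatch_rate)
        assert aln.status == CONTIGUOUS
        assert (aln.segments[0][1][0], aln.mismatches) == oracle


def test_random_read_is_unaligned(toy_consensus):
    read = random_seq(40, seed=999)
    assert read not in toy_consensus.sequence
    aln = ConsensusAligner(toy_consensus, TOY_PARAMS).align("r", read)
    assert aln.status == UNALIGNED
    assert aln.segments == []


def test_read_shorter_than_k_unaligned(toy_consensus):
    aln = ConsensusAligner(toy_consensus, TOY_PARAMS).align("r", "ACGTACG")
    assert aln.status == UNALIGNED


def test_reverse_complement_reads_align(toy_consensus):
    from tedosage._util import revcomp

    cons = toy_consensus.sequence
    aligner = ConsensusAligner(toy_consensus, TOY_PARAMS)
    aln = aligner.align("r", revcomp(cons[50:90]))
    assert aln.status == CONTIGUOUS
    assert aln.strand == "-"
    assert aln.segments[0][1] == (50, 90)


# ----------------------------------------------------------------------
# split alignment
# ----------------------------------------------------------------------

def test_junction_spanning_read_on_toy_consensus():
    """Deletion of positions 21-40 on a 60 bp consensus: a 30 bp read
    spanning the junction splits as (20, 41) up to left-alignment."""
    seq = random_seq(60, seed=7)
    cons = TEConsensus("toy60", seq + random_seq(140, seed=8))  # pad to >=200
    params = AlignParams(k=11, min_overhang=12, max_mismatch_rate=0.0)
    read = seq[5:20] + seq[40:55]  # anchors 15 + 15 around deletion 21-40
    aln = ConsensusAligner(cons, params).align("r", read)
    assert aln.status == SPLIT
    assert aln.junctions == [left_align_junction((20, 41), cons.sequence)]
    assert aln.mismatches == 0
    # deletion length is preserved by left-alignment
    d, a = aln.junctions[0]
    assert a - d - 1 == 20


def test_split_reads_recover_kp_junction_exactly(p_consensus):
    """Error-free junction-spanning reads from the KP-like variant yield
    the left-aligned truth junction for every anchor length >= k; guided
    alignment recovers anchors down to min_overhang."""
    kp = VariantDefinition("KP", ((807, 2561),))
    derived = kp.derived_sequence(p_consensus)
    truth = left_align_junction((807, 2561), p_consensus.sequence)
    params = AlignParams()

    novel = ConsensusAligner(p_consensus, params)
    for anchor in range(params.k, 100 - params.k + 1, 7):
        read = derived[807 - anchor : 807 - anchor + 100]
        aln = novel.align("r", read)
        assert aln.status == SPLIT, anchor
        assert aln.junctions == [truth], anchor

    guided = ConsensusAligner(p_consensus, params, guided_junctions=((807, 2561),))
    for anchor in (params.min_overhang, params.k - 1):
        read = derived[807 - anchor : 807 - anchor + 100]
        aln = guided.align("r", read)
        assert aln.status == SPLIT, anchor
        assert aln.junctions == [truth], anchor


def test_anchor_below_min_overhang_is_not_split(p_consensus):
    kp = VariantDefinition("KP", ((807, 2561),))
    derived = kp.derived_sequence(p_consensus)
    guided = ConsensusAligner(p_consensus, AlignParams(), guided_junctions=((807, 2561),))
    read = derived[807 - 5 : 807 - 5 + 100]  # 5-base anchor
    aln = guided.align("r", read)
    assert aln.status != SPLIT


# ----------------------------------------------------------------------
# junction left-alignment
# ----------------------------------------------------------------------

def test_left_align_is_leftmost_equivalent_junction():
    rng = np.random.default_rng(5)
    for trial in range(100):
        seq = "".join(np.array(list("AC"))[rng.integers(0, 2, size=30)])  # homopolymer-rich
        d = int(rng.integers(2, 20))
        a = d + int(rng.integers(2, 9))
        got = left_align_junction((d, a), seq)
        assert got == min(equivalent_junctions(seq, (d, a)))
        assert left_align_junction(got, seq) == got  # idempotent


def test_left_align_no_homology_fixed_point():
    seq = "ATCGATCGGC" * 3
    assert left_align_junction((4, 8), seq) == (4, 8)  # base(4)=G != base(7)=C


def test_left_align_invalid_junction_rejected(toy_consensus):
    with pytest.raises(ValueError):
        left_align_junction((0, 10), toy_consensus.sequence)
    with pytest.raises(ValueError):
        left_align_junction((10, 11), toy_consensus.sequence)


# ----------------------------------------------------------------------
# depth and copy number
# ----------------------------------------------------------------------

def test_depth_trivial_cases(toy_consensus):
    assert compute_depth([], 1000).mean == 0.0
    aligner = ConsensusAligner(toy_consensus, TOY_PARAMS)
    aln = aligner.align("r", toy_consensus.sequence[10:110])
    dv = compute_depth([aln], 1000)
    assert dv.mean == pytest.approx(0.1)
    assert dv.total_bases == 100


def test_depth_conservation_on_simulated_reads(p_consensus):
    """Sum of depth equals summed aligned segment lengths, exactly,
    including split reads whose deleted spans contribute zero."""
    _, _, reads, _ = simulate_strain(
        [p_consensus], [("P", "FL", 2, 1.0), ("P", "KP", 2, 1.0)],
        seed=21, background_length=6000, depth=10.0,
    )
    aligner = ConsensusAligner(p_consensus, AlignParams(), guided_junctions=((807, 2561),))
    alignments = [a for a in (aligner.align(n, s) for n, s in reads.all_reads()) if a.status != UNALIGNED]
    assert any(a.status == SPLIT for a in alignments)
    dv = compute_depth(alignments, p_consensus.length)
    assert dv.total_bases == sum(a.aligned_bases for a in alignments)


def test_normalized_copy_number_contract():
    assert normalized_copy_number(0.0, 30.0) == 0.0
    assert normalized_copy_number(30.0, 30.0) == 1.0
    with pytest.raises(ValueError):
        normalized_copy_number(10.0, 0.0)


def test_normalized_copy_number_recovers_simulated_copies(p_consensus):
    haps, _, reads, _ = simulate_strain(
        [p_consensus], [("P", "FL", 8, 1.0)], seed=22, background_length=30_000
    )
    params = AlignParams()
    genome_depth = estimate_genome_depth(
        reads.all_reads(), ConsensusIndex(haps.background, params.k), params
    )
    aligner = ConsensusAligner(p_consensus, params)
    alignments = [a for a in (aligner.align(n, s) for n, s in reads.all_reads()) if a.status != UNALIGNED]
    te_mean = compute_depth(alignments, p_consensus.length).mean
    cn = normalized_copy_number(te_mean, genome_depth)
    assert 7.2 <= cn <= 8.8


def test_normalized_copy_number_invariant_to_depth(p_consensus):
    """Halving the number of read pairs leaves the coverage ratio
    unchanged in expectation."""
    estimates = []
    for depth in (15.0, 30.0):
        haps, _, reads, _ = simulate_strain(
            [p_consensus], [("P", "FL", 5, 1.0)], seed=23,
            background_length=25_000, depth=depth,
        )
        params = AlignParams()
        genome_depth = estimate_genome_depth(
            reads.all_reads(), ConsensusIndex(haps.background, params.k), params
        )
        aligner = ConsensusAligner(p_consensus, params)
        alignments = [
            a for a in (aligner.align(n, s) for n, s in reads.all_reads()) if a.status != UNALIGNED
        ]
        estimates.append(compute_depth(alignments, p_consensus.length).mean / genome_depth)
    assert abs(estimates[0] - estimates[1]) / estimates[1] < 0.1
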
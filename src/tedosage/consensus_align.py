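"""Seeded alignment of reads to a TE consensus with deletion junctions.

Internal-deletion derivatives of a transposon produce reads whose two
halves map to discontiguous consensus positions, exactly like spliced
RNA-seq reads map across introns. This module repurposes that idea for
genomic reads: a k-mer-seeded aligner places each read either
contiguously on the consensus or as a two-anchor split alignment whose
gap is reported as a deletion junction (donor = last retained base,
acceptor = first retained base, 1-based). Junction dinucleotide content
carries no score: novel and non-canonical junctions are treated equally.

Guided junctions (for example a known KP-like deletion) are realigned
through derived sequences with the deletion applied, so junction-spanning
reads are recovered with anchors down to ``min_overhang`` bases even when
the junction has too little support for de-novo discovery. Novel
junctions additionally require each anchor to contain a full intact
k-mer seed.

Coordinates are 0-based half-open internally; junctions and all reports
are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._util import revcomp, seq_to_bytes
from .synthetic_data import TEConsensus

__all__ = [
    "AlignParams",
    "ConsensusIndex",
    "ReadAlignment",
    "ConsensusAligner",
    "DepthVector",
    "left_align_junction",
    "compute_depth",
    "normalized_copy_number",
    "estimate_genome_depth",
    "CONTIGUOUS",
    "SPLIT",
    "UNALIGNED",
]

CONTIGUOUS = "CONTIGUOUS"
SPLIT = "SPLIT"
UNALIGNED = "UNALIGNED"


@dataclass(frozen=True)
class AlignParams:
    """Seed length, split-anchor minimum and per-segment mismatch budget.

    ``min_overhang`` follows the 12-base minimum splice-junction overhang
    convention of spliced short-read aligners; ``k`` = 15 keeps seeds
    specific on a ~3 kb consensus while tolerating a low substitution
    error rate at ``max_mismatch_rate`` = 0.04 per segment.
    """

    k: int = 15
    min_overhang: int = 12
    max_mismatch_rate: float = 0.04

    def __post_init__(self):
        if self.k < 11:
            raise ValueError("seed length k must be >= 11")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if not (0.0 <= self.max_mismatch_rate < 0.5):
            raise ValueError("max_mismatch_rate must be in [0, 0.5)")


class ConsensusIndex:
    """Exact k-mer -> positions map over a reference sequence."""

    def __init__(self, reference: str, k: int = 15):
        if k < 11:
            raise ValueError("k must be >= 11")
        if len(reference) < k:
            raise ValueError("reference shorter than k")
        self.k = k
        self.reference = reference
        self.ref_bytes = seq_to_bytes(reference)
        ref = reference.encode("ascii")
        kmers: dict[bytes, list[int]] = {}
        for i in range(len(ref) - k + 1):
            kmers.setdefault(ref[i : i + k], []).append(i)
        self.kmers = kmers

    def __len__(self) -> int:
        return len(self.reference)

    def positions(self, kmer: bytes) -> list[int]:
        return self.kmers.get(kmer, ())


@dataclass
class ReadAlignment:
    """Placement of one read on the consensus.

    ``segments`` is an ordered list of ((read_start, read_end),
    (cons_start, cons_end)) half-open 0-based intervals; ``junctions``
    holds 1-based (donor, acceptor) pairs, one per gap between segments.
    """

    read_id: str
    status: str
    segments: list[tuple[tuple[int, int], tuple[int, int]]] = field(default_factory=list)
    mismatches: int = 0
    junctions: list[tuple[int, int]] = field(default_factory=list)
    strand: str = "+"

    @property
    def aligned_bases(self) -> int:
        return sum(re - rs for (rs, re), _ in self.segments)

    @property
    def consensus_span(self) -> tuple[int, int] | None:
        if not self.segments:
            return None
        return self.segments[0][1][0], self.segments[-1][1][1]


def left_align_junction(junction: tuple[int, int], consensus: str | TEConsensus) -> tuple[int, int]:
    """Canonical (leftmost) representation of a deletion junction.

    When the base at the donor equals the base just before the acceptor,
    the deletion can slide left one position without changing the derived
    sequence (microhomology); shifting until inequality gives every
    equivalent junction one canonical name. Idempotent.
    """
    seq = consensus.sequence if isinstance(consensus, TEConsensus) else consensus
    donor, acceptor = junction
    if not (1 <= donor and donor + 2 <= acceptor <= len(seq)):
        raise ValueError(f"junction {junction} invalid on consensus of length {len(seq)}")
    while donor > 1 and seq[donor - 1] == seq[acceptor - 2]:
        donor -= 1
        acceptor -= 1
    return donor, acceptor


class _GuidedReference:
    """Derived sequence (deletion applied) used to realign guided junctions."""

    def __init__(self, junction: tuple[int, int], consensus: str, k: int):
        donor, acceptor = junction
        self.junction = junction
        self.boundary = donor  # derived coordinate of the first post-junction base
        derived = consensus[:donor] + consensus[acceptor - 1 :]
        self.index = ConsensusIndex(derived, k)


class ConsensusAligner:
    """Aligns reads to one TE consensus, discovering deletion junctions."""

    def __init__(
        self,
        consensus: TEConsensus | str,
        params: AlignParams = AlignParams(),
        guided_junctions: tuple[tuple[int, int], ...] = (),
    ):
        seq = consensus.sequence if isinstance(consensus, TEConsensus) else consensus
        self.consensus = seq
        self.params = params
        self.index = ConsensusIndex(seq, params.k)
        self.guided = [
            _GuidedReference(left_align_junction(j, seq), seq, params.k) for j in guided_junctions
        ]

    # -- public API ---------------------------------------------------------

    def align(self, read_id: str, read: str) -> ReadAlignment:
        """Best placement of a read, trying both strands.

        Precedence: contiguous beats split; fewer mismatches beat more;
        for equal-score contiguous placements the smallest consensus
        start wins; for equal-score splits the smallest deletion, then
        the leftmost donor. Reads shorter than k are UNALIGNED.
        """
        if len(read) < self.params.k:
            return ReadAlignment(read_id, UNALIGNED)
        best: ReadAlignment | None = None
        for strand, seq in (("+", read), ("-", revcomp(read))):
            aln = self._align_one_strand(read_id, seq, strand)
            if aln.status == UNALIGNED:
                continue
            if best is None or _better(aln, best):
                best = aln
            if best.status == CONTIGUOUS and best.mismatches == 0:
                break  # cannot be beaten
        return best if best is not None else ReadAlignment(read_id, UNALIGNED)

    # -- internals ----------------------------------------------------------

    def _align_one_strand(self, read_id: str, seq: str, strand: str) -> ReadAlignment:
        arr = seq_to_bytes(seq)
        contig = self._contiguous(arr, seq, self.index)
        if contig is not None:
            offset, mism = contig
            return ReadAlignment(
                read_id,
                CONTIGUOUS,
                segments=[((0, len(seq)), (offset, offset + len(seq)))],
                mismatches=mism,
                strand=strand,
            )
        split = self._split(arr, seq)
        if split is not None:
            return ReadAlignment(
                read_id,
                SPLIT,
                segments=split["segments"],
                mismatches=split["mismatches"],
                junctions=[split["junction"]],
                strand=strand,
            )
        return ReadAlignment(read_id, UNALIGNED)

    def _contiguous(self, arr: np.ndarray, seq: str, index: ConsensusIndex):
        return _best_contiguous(arr, seq, index, self.params.max_mismatch_rate)

    def _split(self, arr: np.ndarray, seq: str):
        """Two-anchor split placement: novel candidates plus guided rescue."""
        L = len(seq)
        p = self.params
        if L < 2 * p.min_overhang:
            return None
        best = None

        def consider(cand):
            nonlocal best
            if cand is None:
                return
            if best is None or _split_better(cand, best):
                best = cand

        # novel junctions: prefix anchor seeded at read start, suffix at read end
        k = p.k
        ref = self.index.ref_bytes
        C = len(ref)
        enc = seq.encode("ascii")
        pref_offsets = [h for h in self.index.positions(enc[:k])]
        suff_offsets = [h - (L - k) for h in self.index.positions(enc[L - k :])]
        for c1 in pref_offsets:
            if c1 < 0:
                continue
            for a2 in suff_offsets:
                gap = a2 - c1
                if gap < 2 or a2 + L > C or c1 + L > C + gap:
                    continue
                consider(self._score_split(arr, c1, a2, gap))
        # guided junctions: contiguous placement on the derived sequence
        for g in self.guided:
            consider(self._guided_split(arr, seq, g))
        return best

    def _score_split(self, arr: np.ndarray, c1: int, a2: int, gap: int):
        """Best split point for prefix placement c1 / suffix placement a2."""
        L = len(arr)
        p = self.params
        ref = self.index.ref_bytes
        C = len(ref)
        max_s = min(L - p.min_overhang, C - c1)
        min_s = max(p.min_overhang, -a2 if a2 < 0 else 0)
        if min_s > max_s:
            return None
        pref_mism = np.cumsum(arr[:max_s] != ref[c1 : c1 + max_s])
        suf_diff = arr != ref[a2 : a2 + L] if a2 >= 0 else None
        if suf_diff is None:
            return None
        suf_cum = np.cumsum(suf_diff)
        s_vals = np.arange(min_s, max_s + 1)
        pm = np.concatenate(([0], pref_mism))[s_vals]
        sm = suf_cum[-1] - np.concatenate(([0], suf_cum))[s_vals]
        ok = (pm <= p.max_mismatch_rate * s_vals) & (sm <= p.max_mismatch_rate * (L - s_vals))
        if not ok.any():
            return None
        total = np.where(ok, pm + sm, np.iinfo(np.int64).max)
        i = int(np.argmin(total))
        s = int(s_vals[i])
        donor, acceptor = left_align_junction((c1 + s, c1 + s + gap + 1), self.consensus)
        shift = (c1 + s) - donor
        return {
            "mismatches": int(pm[i] + sm[i]),
            "deletion_length": gap,
            "junction": (donor, acceptor),
            "segments": [
                ((0, s - shift), (c1, c1 + s - shift)),
                ((s - shift, L), (acceptor - 1, acceptor - 1 + L - (s - shift))),
            ],
        }

    def _guided_split(self, arr: np.ndarray, seq: str, g: _GuidedReference):
        """Contiguous placement on a derived sequence spanning its junction."""
        contig = self._contiguous(arr, seq, g.index)
        if contig is None:
            return None
        off, mism = contig
        L = len(arr)
        b = g.boundary
        left, right = b - off, off + L - b
        if left < self.params.min_overhang or right < self.params.min_overhang:
            return None  # does not span, or anchors too short
        donor, acceptor = g.junction
        return {
            "mismatches": mism,
            "deletion_length": acceptor - donor - 1,
            "junction": (donor, acceptor),
            "segments": [
                ((0, left), (off, donor)),
                ((left, L), (acceptor - 1, acceptor - 1 + right)),
            ],
        }


def _best_contiguous(arr: np.ndarray, seq: str, index: ConsensusIndex, max_mismatch_rate: float):
    """Best whole-read placement within the mismatch budget, or None.

    Candidate offsets come from three seed k-mers (read start, middle,
    end); ties on mismatch count resolve to the smallest consensus start.
    """
    L = len(seq)
    k = index.k
    if L < k:
        return None
    enc = seq.encode("ascii")
    offsets: set[int] = set()
    for s in (0, (L - k) // 2, L - k):
        for pos in index.positions(enc[s : s + k]):
            offsets.add(pos - s)
    budget = int(max_mismatch_rate * L)
    ref = index.ref_bytes
    best = None
    for off in sorted(offsets):
        if off < 0 or off + L > len(ref):
            continue
        mism = int(np.count_nonzero(arr != ref[off : off + L]))
        if mism <= budget and (best is None or mism < best[1]):
            best = (off, mism)
    return best


def _better(a: ReadAlignment, b: ReadAlignment) -> bool:
    """Order alignments: contiguous first, then fewer mismatches."""
    rank = {CONTIGUOUS: 0, SPLIT: 1}
    ka = (rank[a.status], a.mismatches)
    kb = (rank[b.status], b.mismatches)
    return ka < kb


def _split_better(a: dict, b: dict) -> bool:
    ka = (a["mismatches"], a["deletion_length"], a["junction"][0])
    kb = (b["mismatches"], b["deletion_length"], b["junction"][0])
    return ka < kb


@dataclass
class DepthVector:
    """Per-base aligned-read depth over a consensus."""

    depth: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.depth.mean()) if len(self.depth) else 0.0

    @property
    def total_bases(self) -> float:
        return float(self.depth.sum())


def compute_depth(alignments, consensus_length: int) -> DepthVector:
    """Per-base depth; skipped (deleted) spans of split reads contribute 0.

    Conservation holds exactly: sum(depth) equals the summed aligned
    segment lengths.
    """
    diff = np.zeros(consensus_length + 1)
    for aln in alignments:
        for (_, _), (cs, ce) in aln.segments:
            diff[cs] += 1
            diff[ce] -= 1
    return DepthVector(np.cumsum(diff[:-1]))


def normalized_copy_number(te_mean_depth: float, genome_mean_depth: float) -> float:
    """Haploid copy-number estimate: TE mean depth over genome mean depth."""
    if genome_mean_depth <= 0:
        raise ValueError("genome mean depth must be > 0")
    if te_mean_depth < 0:
        raise ValueError("TE mean depth must be >= 0")
    return te_mean_depth / genome_mean_depth


def estimate_genome_depth(reads, background_index: ConsensusIndex, params: AlignParams = AlignParams()) -> float:
    """Mean single-copy depth: background-aligned bases / background length.

    Reads are placed contiguously (both strands) on the background
    reference; unplaceable reads (for example reads straddling a TE
    insertion boundary) contribute nothing.
    """
    total = 0
    rate = params.max_mismatch_rate
    for _, seq in reads:
        if len(seq) < params.k:
            continue
        if _best_contiguous(seq_to_bytes(seq), seq, background_index, rate) is not None:
            total += len(seq)
        else:
            rc = revcomp(seq)
            if _best_contiguous(seq_to_bytes(rc), rc, background_index, rate) is not None:
                total += len(seq)
    return total / len(background_index)
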
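"""Structural-variant catalogs of a TE family from split-read evidence.

Junction evidence collected from consensus alignments is turned into a
set of candidate structural variants (the full-length element plus one
single-deletion variant per retained junction), whose abundances are
estimated in mean-depth units by expectation-maximization over
fractional read-to-variant assignment — the same inference isoform
assemblers perform for transcript abundance. Variants below 1% of the
most abundant variant are filtered out, mirroring the minimum-isoform-
fraction convention of transcript assemblers, and retained variants are
classified as full-length, KP-like (matching a reference deletion
junction) or other deletion derivatives.

Multi-junction variants are not phased: short reads cannot connect
distant junctions of one element, so abundances are per-junction
classes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .consensus_align import SPLIT, CONTIGUOUS, ReadAlignment
from .synthetic_data import FULL_LENGTH_NAME, TEConsensus

__all__ = [
    "FULL_LENGTH",
    "KP",
    "OTHER",
    "JunctionEvidence",
    "StructuralVariant",
    "VariantCatalog",
    "MalformedJunctionError",
    "EMResult",
    "collect_junctions",
    "enumerate_variants",
    "estimate_abundances",
    "filter_variants",
    "classify_variant",
]

FULL_LENGTH = "FULL_LENGTH"
KP = "KP"
OTHER = "OTHER"


class MalformedJunctionError(ValueError):
    pass


@dataclass(frozen=True)
class JunctionEvidence:
    """A deletion breakpoint with split-read support."""

    junction: tuple[int, int]
    support: int
    guided: bool = False


@dataclass
class StructuralVariant:
    """A TE copy class on consensus coordinates with a depth abundance."""

    name: str
    junctions: tuple[tuple[int, int], ...] = ()
    abundance: float = 0.0
    variant_class: str | None = None

    @property
    def is_full_length(self) -> bool:
        return not self.junctions

    def derived_length(self, consensus_length: int) -> int:
        return consensus_length - sum(a - d - 1 for d, a in self.junctions)

    def deleted_interval(self) -> tuple[int, int] | None:
        """0-based half-open deleted span (single-junction variants)."""
        if not self.junctions:
            return None
        d, a = self.junctions[0]
        return d, a - 1


@dataclass
class VariantCatalog:
    family: str
    consensus_length: int
    retained: list[StructuralVariant] = field(default_factory=list)
    filtered: list[tuple[StructuralVariant, str]] = field(default_factory=list)

    def by_class(self, variant_class: str) -> list[StructuralVariant]:
        return [v for v in self.retained if v.variant_class == variant_class]

    def class_abundance(self, variant_class: str) -> float:
        return sum(v.abundance for v in self.by_class(variant_class))

    @property
    def total_abundance(self) -> float:
        return sum(v.abundance for v in self.retained)


def collect_junctions(
    alignments,
    guided: tuple[tuple[int, int], ...] = (),
    min_support: int = 2,
) -> list[JunctionEvidence]:
    """Merge identical junctions across reads and apply the support gate.

    Novel junctions need ``min_support`` split reads (suppresses chimeras
    from single sequencing errors); guided junctions are always retained,
    even at zero support. Junctions must already be left-aligned.
    """
    counts: Counter = Counter()
    for aln in alignments:
        if aln.status == SPLIT:
            counts.update(aln.junctions)
    guided_set = set(guided)
    evidence = [
        JunctionEvidence(j, counts.get(j, 0), guided=True) for j in sorted(guided_set)
    ]
    evidence.extend(
        JunctionEvidence(j, n, guided=False)
        for j, n in sorted(counts.items())
        if j not in guided_set and n >= min_support
    )
    return sorted(evidence, key=lambda e: e.junction)


def enumerate_variants(
    junctions,
    consensus: TEConsensus | int,
) -> list[StructuralVariant]:
    """Candidate variants: the full-length element plus one per junction.

    Overlapping-deletion junctions yield separate single-junction
    variants; no multi-junction phasing is attempted.
    """
    length = consensus.length if isinstance(consensus, TEConsensus) else int(consensus)
    candidates = [StructuralVariant(FULL_LENGTH_NAME)]
    seen = set()
    for j in junctions:
        junction = j.junction if isinstance(j, JunctionEvidence) else tuple(j)
        donor, acceptor = junction
        if acceptor <= donor + 1:
            raise MalformedJunctionError(f"junction {junction} deletes no base")
        if not (1 <= donor and acceptor <= length):
            raise MalformedJunctionError(f"junction {junction} outside consensus of length {length}")
        if junction in seen:
            continue
        seen.add(junction)
        candidates.append(StructuralVariant(f"del_{donor}_{acceptor}", (junction,)))
    return candidates


@dataclass
class EMResult:
    abundances: dict[str, float]
    converged: bool
    n_iter: int
    log_likelihood: float
    assigned_bases: float
    effective_lengths: dict[str, float] = None


def _compatible(aln: ReadAlignment, variants: list[StructuralVariant]) -> tuple[int, ...]:
    """Indices of candidates a read could originate from.

    A split read belongs to variants carrying exactly its junction; a
    contiguous read to every variant whose retained region contains its
    consensus interval.
    """
    if aln.status == SPLIT:
        j = aln.junctions[0]
        return tuple(i for i, v in enumerate(variants) if v.junctions == (j,))
    if aln.status != CONTIGUOUS:
        return ()
    cs, ce = aln.consensus_span
    out = []
    for i, v in enumerate(variants):
        iv = v.deleted_interval()
        if iv is None or ce <= iv[0] or cs >= iv[1]:
            out.append(i)
    return tuple(out)


def estimate_abundances(
    candidates: list[StructuralVariant],
    alignments,
    consensus_length: int,
    tol: float = 1e-6,
    max_iter: int = 200,
    junction_margin: int = 11,
) -> EMResult:
    """EM abundance estimation in per-copy depth units.

    The generative model: a variant with depth theta sheds reads
    uniformly over its *effective* start positions — derived length
    - mean read length + 1, minus ``2 x junction_margin`` positions per
    junction whose spanning reads fail the split-anchor rule. E-step:
    each read is assigned fractionally to its compatible variants in
    proportion to their current depth. M-step: depth of a variant =
    assigned bases / effective length. Read mass is conserved:
    sum(abundance x effective_length) equals the total aligned bases of
    reads compatible with at least one candidate; incompatible reads are
    excluded rather than forced onto the full-length class.

    Normalizing by effective rather than derived length keeps short
    deletion derivatives commensurable with the full-length element:
    per-length normalization would systematically underestimate their
    share, because a short variant offers proportionally fewer read
    start positions.

    The mixture log-likelihood is non-decreasing across iterations;
    convergence is declared when its relative change drops below ``tol``.
    """
    if not candidates:
        return EMResult({}, True, 0, 0.0, 0.0)
    names = [v.name for v in candidates]

    # equivalence classes: compatible-set -> (read count, total aligned bases)
    classes: dict[tuple[int, ...], list[float]] = {}
    for aln in alignments:
        comp = _compatible(aln, candidates)
        if not comp:
            continue
        entry = classes.setdefault(comp, [0.0, 0.0])
        entry[0] += 1.0
        entry[1] += aln.aligned_bases

    if not classes:
        result = EMResult({name: 0.0 for name in names}, True, 0, 0.0, 0.0)
        for v in candidates:
            v.abundance = 0.0
        return result

    comp_sets = list(classes)
    counts = np.array([classes[c][0] for c in comp_sets])
    bases = np.array([classes[c][1] for c in comp_sets])
    total_bases = float(bases.sum())
    mean_read_len = total_bases / float(counts.sum())
    lengths = np.array(
        [
            max(
                1.0,
                v.derived_length(consensus_length)
                - mean_read_len
                + 1.0
                - 2.0 * junction_margin * len(v.junctions),
            )
            for v in candidates
        ]
    )

    theta = np.full(len(candidates), 1.0, dtype=float)  # uniform initialization
    theta *= total_bases / float(theta @ lengths)

    def loglik(th: np.ndarray) -> float:
        norm = float(th @ lengths)
        ll = 0.0
        for c, n in zip(comp_sets, counts):
            mass = th[list(c)].sum()
            ll += n * (np.log(mass) if mass > 0 else -np.inf) if n else 0.0
        return ll - counts.sum() * np.log(norm)

    prev_ll = loglik(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        assigned = np.zeros(len(candidates))
        for c, b in zip(comp_sets, bases):
            idx = list(c)
            mass = theta[idx].sum()
            if mass <= 0:
                continue
            assigned[idx] += b * theta[idx] / mass
        theta = assigned / lengths
        ll = loglik(theta)
        assert ll >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        if abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            prev_ll = ll
            converged = True
            break
        prev_ll = ll

    abundances = {name: float(t) for name, t in zip(names, theta)}
    for v, t in zip(candidates, theta):
        v.abundance = float(t)
    return EMResult(
        abundances, converged, it, float(prev_ll), total_bases,
        effective_lengths=dict(zip(names, lengths.tolist())),
    )


def filter_variants(
    candidates: list[StructuralVariant],
    family: str,
    consensus_length: int,
    min_frac: float = 0.01,
) -> VariantCatalog:
    """Apply the minimum-abundance-fraction filter.

    A variant is retained iff its abundance is at least ``min_frac`` of
    the most abundant variant (boundary inclusive) and positive;
    filtered-out variants are recorded with a reason.
    """
    catalog = VariantCatalog(family=family, consensus_length=consensus_length)
    if not candidates:
        return catalog
    max_abund = max(v.abundance for v in candidates)
    for v in candidates:
        if v.abundance <= 0.0:
            catalog.filtered.append((v, "zero abundance"))
        elif v.abundance >= min_frac * max_abund:
            catalog.retained.append(v)
        else:
            catalog.filtered.append(
                (v, f"abundance {v.abundance:.4g} < {min_frac:g} of max {max_abund:.4g}")
            )
    assert sum(v.is_full_length for v in catalog.retained) <= 1
    return catalog


def classify_variant(
    variant: StructuralVariant,
    kp_reference_junction: tuple[int, int] | None,
    tolerance_bp: int = 0,
) -> str:
    """FULL_LENGTH, KP (junction matches the reference junction within
    ``tolerance_bp`` on both ends) or OTHER. Junctions must be
    left-aligned; with exact left-alignment the default tolerance of 0
    is well-defined."""
    if variant.is_full_length:
        return FULL_LENGTH
    if kp_reference_junction is not None and len(variant.junctions) == 1:
        (d, a), (dk, ak) = variant.junctions[0], kp_reference_junction
        if abs(d - dk) <= tolerance_bp and abs(a - ak) <= tolerance_bp:
            return KP
    return OTHER
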
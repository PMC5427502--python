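"""Synthetic strain genomes, short reads, annotation tables and phenotypes.

This module emulates the data a hybrid-dysgenesis dosage study consumes:

* inbred fly strains whose genomes carry 0-70 haploid copies of a DNA
  transposon (a P-element-like and a hobo-like family), as a mixture of
  full-length copies and internally deleted derivatives (including a
  KP-like variant defined by a characteristic deletion junction);
* paired-end genomic resequencing reads from those strains;
* TE-insertion annotation tables with per-insertion population
  frequencies, in the style of insertion callers such as TEMP/TIDAL;
* per-female F1 ovarian-atrophy phenotypes driven by paternal TE dosage
  through a logistic model with block and strain random intercepts.

Every generator takes an explicit integer seed and is byte-reproducible.
Truth tables record the realized copies, frequencies and junctions so
downstream estimators can be scored against ground truth.

The background genome is uniform random sequence: TE-derived reads are
unambiguous at k-mer scale, which isolates the estimators from
mappability confounds that are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import NUCLEOTIDES, revcomp, spawn_seed

__all__ = [
    "TEConsensus",
    "VariantDefinition",
    "TECopySpec",
    "StrainSimConfig",
    "PhenotypeSimConfig",
    "TrueInsertion",
    "TruthTable",
    "ReadPairs",
    "BackgroundCapacityError",
    "synthetic_consensus",
    "default_variants",
    "build_strain_haplotypes",
    "simulate_reads",
    "simulate_annotation_table",
    "simulate_phenotypes",
    "P_CONSENSUS_LENGTH",
    "HOBO_CONSENSUS_LENGTH",
    "KP_JUNCTION",
]

#: Default consensus lengths and the KP-like deletion junction
#: (donor = last retained base, acceptor = first retained base, 1-based).
#: Configurable defaults for a P-element-like and hobo-like family; the
#: sequences themselves are synthetic.
P_CONSENSUS_LENGTH = 2907
HOBO_CONSENSUS_LENGTH = 3016
KP_JUNCTION = (807, 2561)

FULL_LENGTH_NAME = "FL"


class BackgroundCapacityError(ValueError):
    """Background sequence too short to host the requested insertions."""


@dataclass(frozen=True)
class TEConsensus:
    """A transposon family consensus; the coordinate system for variants."""

    family_name: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 200:
            raise ValueError("consensus shorter than 200 bp")
        if set(self.sequence) - set(NUCLEOTIDES):
            raise ValueError("consensus alphabet must be A/C/G/T")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantDefinition:
    """A TE copy class: an ordered set of internal deletions.

    Each deletion is a 1-based (donor, acceptor) pair: donor is the last
    retained consensus base before the deletion, acceptor the first
    retained base after it, so bases [donor+1, acceptor-1] are removed.
    An empty deletion list denotes the full-length element.
    """

    name: str
    deletions: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "deletions", tuple(tuple(d) for d in self.deletions))
        prev_end = 0
        for donor, acceptor in self.deletions:
            if acceptor < donor + 2:
                raise ValueError(f"deletion ({donor},{acceptor}) removes no base")
            if donor <= prev_end:
                raise ValueError("deletions must be sorted and non-overlapping")
            prev_end = acceptor - 1
        if (not self.deletions) != (self.name == FULL_LENGTH_NAME) and self.name == FULL_LENGTH_NAME:
            raise ValueError("full-length variant cannot carry deletions")

    @property
    def is_full_length(self) -> bool:
        return not self.deletions

    def derived_length(self, consensus_length: int) -> int:
        return consensus_length - sum(a - d - 1 for d, a in self.deletions)

    def derived_sequence(self, consensus: TEConsensus) -> str:
        seq = consensus.sequence
        parts, pos = [], 0
        for donor, acceptor in self.deletions:
            parts.append(seq[pos:donor])  # retained through donor (1-based)
            pos = acceptor - 1
        parts.append(seq[pos:])
        derived = "".join(parts)
        assert len(derived) == self.derived_length(consensus.length)
        return derived


def synthetic_consensus(family_name: str = "P", length: int | None = None, seed: int = 715) -> TEConsensus:
    """Deterministic synthetic consensus for a TE family.

    The sequence is uniform random nucleotides (fixed internal seed per
    family), a synthetic stand-in with realistic length; it is not a
    database consensus.
    """
    if length is None:
        length = {"P": P_CONSENSUS_LENGTH, "hobo": HOBO_CONSENSUS_LENGTH}.get(family_name, 3000)
    rng = np.random.default_rng(spawn_seed(seed, "consensus", family_name, length))
    seq = "".join(np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=length)])
    return TEConsensus(family_name=family_name, sequence=seq)


def default_variants(consensus: TEConsensus, kp_junction: tuple[int, int] = KP_JUNCTION) -> dict[str, VariantDefinition]:
    """Default variant library for a family.

    The P-like family gets the full-length element, the KP-like variant
    and a non-KP deletion derivative; the hobo-like family gets a
    full-length element and one deletion derivative.
    """
    variants = {FULL_LENGTH_NAME: VariantDefinition(FULL_LENGTH_NAME)}
    if consensus.family_name == "P":
        variants["KP"] = VariantDefinition("KP", (kp_junction,))
        variants["ND"] = VariantDefinition("ND", ((400, 1900),))
    else:
        variants["DEL"] = VariantDefinition("DEL", ((600, 2200),))
    return variants


@dataclass(frozen=True)
class TECopySpec:
    """A block of identical insertions: family/variant, count, frequency.

    ``frequency`` is the segregation probability of each insertion on the
    second haplotype; haplotype 1 is fixed for every configured insertion
    (the simplest diploid model in which frequency-weighted copy number
    falls below total copy number).
    """

    family: str
    variant: str
    count: int
    frequency: float = 1.0

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("copy count must be >= 0")
        if not (0.0 < self.frequency <= 1.0):
            raise ValueError("insertion frequency must be in (0, 1]")


@dataclass
class StrainSimConfig:
    strain_id: str
    te_copies: list[TECopySpec] = field(default_factory=list)
    background_length: int = 50_000
    depth: float = 30.0
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self):
        self.te_copies = [c if isinstance(c, TECopySpec) else TECopySpec(**c) for c in self.te_copies]
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must be <= insert_mean")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.background_length < 1000:
            raise ValueError("background_length must be >= 1 kb")


@dataclass(frozen=True)
class TrueInsertion:
    insertion_id: str
    family: str
    variant: str
    site: int            # 0-based background coordinate of the insertion point
    frequency: float     # chromosome frequency: (1 + hap2 segregation prob) / 2
    on_hap2: bool


@dataclass
class TruthTable:
    """Ground truth for one simulated strain (recovery oracle)."""

    strain_id: str
    insertions: list[TrueInsertion]
    variant_definitions: dict[str, dict[str, VariantDefinition]]  # family -> name -> def

    def families(self) -> list[str]:
        return sorted({ins.family for ins in self.insertions})

    def haploid_cn(self, family: str) -> int:
        """Copies on the fixed haplotype (the configured count)."""
        return sum(1 for i in self.insertions if i.family == family)

    def realized_cn(self, family: str) -> int:
        """Total copies across both haplotypes."""
        return sum(1 + i.on_hap2 for i in self.insertions if i.family == family)

    def weighted_cn(self, family: str) -> float:
        """Expected copies per haploid genome: sum of chromosome frequencies."""
        return sum(i.frequency for i in self.insertions if i.family == family)

    def variant_proportions(self, family: str) -> dict[str, float]:
        """Realized-copy proportion per variant; empty if no copies."""
        counts: dict[str, int] = {}
        for ins in self.insertions:
            if ins.family == family:
                counts[ins.variant] = counts.get(ins.variant, 0) + 1 + ins.on_hap2
        total = sum(counts.values())
        return {v: c / total for v, c in counts.items()} if total else {}

    def junctions(self, family: str) -> list[tuple[int, int]]:
        """Deletion junctions of variants realized in this strain."""
        out: set[tuple[int, int]] = set()
        for ins in self.insertions:
            if ins.family == family:
                out.update(self.variant_definitions[family][ins.variant].deletions)
        return sorted(out)


@dataclass
class Haplotypes:
    strain_id: str
    sequences: tuple[str, str]
    background: str


def build_strain_haplotypes(
    config: StrainSimConfig,
    consensi: list[TEConsensus],
    variants: dict[str, dict[str, VariantDefinition]],
) -> tuple[Haplotypes, TruthTable]:
    """Build a diploid strain genome carrying the configured TE copies.

    Insertion sites are drawn without replacement from the background;
    every insertion is present on haplotype 1 and, independently with
    probability equal to its frequency, on haplotype 2 (segregating
    insertions within an inbred line).
    """
    rng = np.random.default_rng(spawn_seed(config.seed, "haplotypes", config.strain_id))
    cons_by_family = {c.family_name: c for c in consensi}

    expanded: list[tuple[str, str, float]] = []
    for spec in config.te_copies:
        if spec.family not in cons_by_family:
            raise ValueError(f"no consensus for family {spec.family!r}")
        if spec.variant not in variants.get(spec.family, {}):
            raise ValueError(f"variant {spec.variant!r} undefined for family {spec.family!r}")
        expanded.extend((spec.family, spec.variant, spec.frequency) for _ in range(spec.count))

    n_ins = len(expanded)
    if n_ins > config.background_length // 500:
        raise BackgroundCapacityError(
            f"{n_ins} insertions exceed capacity of a {config.background_length} bp background"
        )

    background = "".join(
        np.array(list(NUCLEOTIDES))[rng.integers(0, 4, size=config.background_length)]
    )
    sites = np.sort(rng.choice(config.background_length - 1, size=n_ins, replace=False)) + 1 if n_ins else np.array([], dtype=int)
    on_hap2 = rng.random(n_ins) < np.array([f for _, _, f in expanded]) if n_ins else np.array([], dtype=bool)

    insertions = [
        TrueInsertion(
            insertion_id=f"{config.strain_id}.{i:04d}",
            family=fam,
            variant=var,
            site=int(sites[i]),
            frequency=(1.0 + freq) / 2.0,
            on_hap2=bool(on_hap2[i]),
        )
        for i, (fam, var, freq) in enumerate(expanded)
    ]

    derived_cache = {
        (fam, name): vdef.derived_sequence(cons_by_family[fam])
        for fam in variants
        if fam in cons_by_family
        for name, vdef in variants[fam].items()
    }

    def assemble(carry: list[TrueInsertion]) -> str:
        parts, pos = [], 0
        for ins in carry:
            parts.append(background[pos:ins.site])
            parts.append(derived_cache[(ins.family, ins.variant)])
            pos = ins.site
        parts.append(background[pos:])
        return "".join(parts)

    hap1 = assemble(insertions)
    hap2 = assemble([i for i in insertions if i.on_hap2])
    truth = TruthTable(config.strain_id, insertions, variants)
    return Haplotypes(config.strain_id, (hap1, hap2), background), truth


@dataclass
class ReadPairs:
    """Paired-end reads; names encode origin for the truth table."""

    names: list[str]
    mate1: list[str]
    mate2: list[str]

    def __len__(self) -> int:
        return len(self.names)

    def all_reads(self):
        """Yield (read_id, sequence) for both mates."""
        for name, r1, r2 in zip(self.names, self.mate1, self.mate2):
            yield name + "/1", r1
            yield name + "/2", r2


def simulate_reads(haplotypes: Haplotypes, config: StrainSimConfig) -> ReadPairs:
    """Uniform paired-end sequencing of the two haplotypes.

    Fragment length ~ Normal(insert_mean, insert_sd) truncated below at
    read_length; substitution errors i.i.d. at ``error_rate``; expected
    total sequenced bases = depth x background_length, split equally
    between haplotypes. Read names encode haplotype, fragment start and
    fragment length (``strain:hap:start:fraglen:index``).
    """
    rng = np.random.default_rng(spawn_seed(config.seed, "reads", config.strain_id))
    rl = config.read_length
    names: list[str] = []
    mate1: list[str] = []
    mate2: list[str] = []
    nt = np.array(list(NUCLEOTIDES))

    for hap_idx, hap in enumerate(haplotypes.sequences):
        hap_len = len(hap)
        n_pairs = int(round(config.depth * config.background_length / (2 * 2 * rl)))
        frags = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)).astype(int),
            rl,
            hap_len,
        )
        starts = rng.integers(0, hap_len - frags + 1)
        # substitution errors: number per read, then positions and offsets
        n_err = rng.binomial(rl, config.error_rate, size=(n_pairs, 2))
        for i in range(n_pairs):
            s, f = int(starts[i]), int(frags[i])
            fragment = hap[s : s + f]
            r1 = fragment[:rl]
            r2 = revcomp(fragment[-rl:])
            if n_err[i, 0]:
                r1 = _mutate(r1, int(n_err[i, 0]), rng, nt)
            if n_err[i, 1]:
                r2 = _mutate(r2, int(n_err[i, 1]), rng, nt)
            names.append(f"{config.strain_id}:{hap_idx + 1}:{s}:{f}:{len(names)}")
            mate1.append(r1)
            mate2.append(r2)
    return ReadPairs(names, mate1, mate2)


def _mutate(read: str, n_err: int, rng: np.random.Generator, nt: np.ndarray) -> str:
    arr = np.array(list(read))
    pos = rng.choice(len(arr), size=n_err, replace=False)
    # substitute with one of the three other bases
    for p in pos:
        choices = [b for b in NUCLEOTIDES if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def write_fastq_pair(reads: ReadPairs, path1, path2) -> None:
    """Write mates to two FASTQ files (constant quality, plain text)."""
    for mate, (path, seqs) in enumerate(((path1, reads.mate1), (path2, reads.mate2)), start=1):
        with open(path, "w") as fh:
            for name, seq in zip(reads.names, seqs):
                fh.write(f"@{name}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")


def simulate_annotation_table(truth: TruthTable, jitter: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Insertion-caller-style annotation rows with noisy frequencies.

    One row per insertion; the reported frequency is the true chromosome
    frequency plus Normal(0, jitter) noise, clipped to (0, 1].
    """
    rng = np.random.default_rng(spawn_seed(seed, "annotation", truth.strain_id))
    rows = []
    for ins in truth.insertions:
        freq = ins.frequency
        if jitter > 0:
            freq = float(np.clip(freq + rng.normal(0.0, jitter), 1e-6, 1.0))
        rows.append((truth.strain_id, ins.insertion_id, ins.family, freq))
    return pd.DataFrame(rows, columns=["strain", "insertion_id", "family", "frequency"])


@dataclass
class PhenotypeSimConfig:
    """Generative model for F1 ovarian atrophy.

    atrophy ~ Bernoulli(logit^-1(beta0 + beta_P*CN_P + beta_H*CN_hobo
    + u_block + u_strain)), with block and strain intercepts drawn once
    per level from Normal(0, sigma^2). Defaults mirror a study design of
    ~33 strains scored in 2 of 9 blocks, ~30 females per strain x block.
    """

    beta0: float = -3.0
    beta_P: float = 0.15
    beta_H: float = 0.1
    sigma_block: float = 0.5
    sigma_strain: float = 1.0
    n_blocks: int = 9
    blocks_per_strain: int = 2
    females_per_strain_block: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.sigma_block < 0 or self.sigma_strain < 0:
            raise ValueError("random-intercept SDs must be >= 0")
        if self.females_per_strain_block < 1:
            raise ValueError("females_per_strain_block must be >= 1")
        if not (1 <= self.blocks_per_strain <= self.n_blocks):
            raise ValueError("blocks_per_strain must be in [1, n_blocks]")


@dataclass
class TrueEffects:
    beta0: float
    beta_P: float
    beta_H: float
    block_effects: dict[str, float]
    strain_effects: dict[str, float]


def simulate_phenotypes(
    config: PhenotypeSimConfig,
    dosages: dict[str, tuple[float, float]],
) -> tuple[pd.DataFrame, TrueEffects]:
    """Per-female atrophy records for strains with given (CN_P, CN_hobo).

    Returns a table with one row per F1 female (strain, block,
    atrophied in {0,1}); each strain is scored in exactly
    ``blocks_per_strain`` randomly assigned blocks.
    """
    rng = np.random.default_rng(spawn_seed(config.seed, "phenotypes"))
    blocks = [f"B{i + 1}" for i in range(config.n_blocks)]
    u_block = {b: rng.normal(0.0, config.sigma_block) if config.sigma_block else 0.0 for b in blocks}
    strains = list(dosages)
    u_strain = {s: rng.normal(0.0, config.sigma_strain) if config.sigma_strain else 0.0 for s in strains}

    rows = []
    for strain in strains:
        cn_p, cn_h = dosages[strain]
        eta_fixed = config.beta0 + config.beta_P * cn_p + config.beta_H * cn_h
        if not np.isfinite(eta_fixed):
            raise ValueError(f"non-finite linear predictor for strain {strain!r}")
        chosen = rng.choice(config.n_blocks, size=config.blocks_per_strain, replace=False)
        for b_idx in chosen:
            block = blocks[int(b_idx)]
            eta = eta_fixed + u_block[block] + u_strain[strain]
            p = 1.0 / (1.0 + np.exp(-eta))
            y = rng.random(config.females_per_strain_block) < p
            rows.extend((strain, block, int(v)) for v in y)
    table = pd.DataFrame(rows, columns=["strain", "block", "atrophied"])
    effects = TrueEffects(config.beta0, config.beta_P, config.beta_H, u_block, u_strain)
    return table, effects
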
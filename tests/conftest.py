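import numpy as np
import pytest

from tedosage.synthetic_data import (
    StrainSimConfig,
    TECopySpec,
    TEConsensus,
    build_strain_haplotypes,
    default_variants,
    simulate_reads,
    synthetic_consensus,
)

NT = np.array(list("ACGT"))


def random_seq(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(NT[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def p_consensus():
    return synthetic_consensus("P")


@pytest.fixture(scope="session")
def hobo_consensus():
    return synthetic_consensus("hobo")


@pytest.fixture(scope="session")
def toy_consensus():
    """Small consensus for brute-force alignment oracles."""
    return TEConsensus("toy", random_seq(200, seed=42))


def simulate_strain(consensi, copies, seed, background_length=15_000, depth=30.0, **kw):
    """Build one strain's genome and reads; returns (haps, truth, reads, cfg)."""
    variants = {c.family_name: default_variants(c) for c in consensi}
    cfg = StrainSimConfig(
        strain_id=f"t{seed}",
        te_copies=[TECopySpec(*c) if isinstance(c, tuple) else c for c in copies],
        background_length=background_length,
        depth=depth,
        seed=seed,
        **kw,
    )
    haps, truth = build_strain_haplotypes(cfg, list(consensi), variants)
    reads = simulate_reads(haps, cfg)
    return haps, truth, reads, cfg
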
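"""Small shared helpers: sequence byte views, RNG spawning, checksums."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

NUCLEOTIDES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seq_to_bytes(seq: str) -> np.ndarray:
    """ASCII byte view of a nucleotide string (uint8, read-only copy)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def spawn_seed(seed: int, *tags: object) -> int:
    """Derive a stable sub-seed (< 2**31) from a master seed and tags.

    Stages of a run draw from independently derived streams so each stage
    is reproducible in isolation.
    """
    h = hashlib.sha256(repr((int(seed),) + tags).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
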
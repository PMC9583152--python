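"""Named deterministic RNG streams.

Every stochastic stage draws from a stream derived from (master seed, stage
name, entity names), so per-drug / per-repeat results do not depend on
iteration order and a rerun with the same master seed is bit-identical.
"""
from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["named_seed", "named_rng"]


def _name_digest(names: tuple) -> int:
    payload = "/".join(str(n) for n in names).encode("utf-8")
    digest = hashlib.sha256(payload).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def named_seed(master_seed: int, *names) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``names`` under ``master_seed``."""
    entropy = [int(master_seed) % (2**31)]
    if names:
        entropy.append(_name_digest(names))
    return np.random.SeedSequence(entropy)


def named_rng(master_seed: int, *names) -> np.random.Generator:
    """Generator for the named stream (see :func:`named_seed`)."""
    return np.random.default_rng(named_seed(master_seed, *names))
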
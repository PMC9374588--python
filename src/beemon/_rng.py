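"""Seed management: one master seed fans out to named substreams.

Changing how many draws one stage makes can never perturb another stage's
stream, because each stage derives its generator from (master_seed, name).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return an independent, reproducible generator for a named stage.

    Parameters
    ----------
    master_seed : int
        The run-level seed.
    name : str
        Stage label (e.g. ``"specimens"``, ``"grafting"``, ``"nulls"``).
    """
    tag = zlib.crc32(name.encode("utf-8"))
    seq = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(tag,))
    return np.random.default_rng(seq)
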
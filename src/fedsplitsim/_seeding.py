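"""Deterministic child-seed derivation.

Every stochastic component in the simulator (waveform noise, partitioning,
weight initialisation, data shuffling, DP noise, fleet heterogeneity) draws
from its own ``numpy.random.Generator``.  Child generators are derived from a
single master seed through ``numpy.random.SeedSequence`` spawn keys, so each
module is independently reproducible: changing, say, the number of clients
never perturbs the waveform noise stream.
"""

from __future__ import annotations

import numpy as np

# Fixed stream labels.  Each (label, index) pair maps to a unique child
# SeedSequence, so streams never collide across modules.
STREAM_WAVEFORM = 0
STREAM_PARTITION = 1
STREAM_INIT = 2
STREAM_SHUFFLE = 3
STREAM_DP = 4
STREAM_FLEET = 5


def child_rng(master_seed: int, stream: int, index: int = 0) -> np.random.Generator:
    """Return the generator for stream ``stream``, sub-index ``index``."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, index))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, stream: int, index: int = 0) -> int:
    """A 31-bit integer seed derived from the same scheme (for configs)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(stream, index))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
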
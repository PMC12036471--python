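"""Named random substreams derived from one global seed.

Each stochastic stage draws from its own generator, keyed by a stable name,
so that adding or reordering stages never perturbs another stage's stream.
"""

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a PCG64 generator for stream *name* under the global *seed*.

    The stream key is the CRC32 of the name, which is stable across
    platforms and Python versions.
    """
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    key = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(key,))
    return np.random.Generator(np.random.PCG64(ss))
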
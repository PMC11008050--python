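"""Deterministic seed derivation.

Every stochastic stage derives its own integer seed from a master seed plus a
stage name, so that pipelines are reproducible end to end and independent
stages never share RNG streams. All derived seeds are < 2**31.
"""

from __future__ import annotations

import zlib


def derive_seed(master: int, *tags: object) -> int:
    """Derive a stable 31-bit seed from a master seed and context tags.

    The same (master, tags) pair always maps to the same seed; distinct tags
    give (with overwhelming probability) distinct streams.
    """
    key = ":".join([str(int(master))] + [str(t) for t in tags])
    return zlib.crc32(key.encode("utf-8")) & 0x7FFFFFFF
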
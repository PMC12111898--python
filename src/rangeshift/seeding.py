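"""Deterministic per-stage seed derivation.

All randomness in the pipeline flows from one master seed.  Each stage
derives its own substream seed by hashing (master_seed, stage_name), so any
stage can be re-run independently and reproducibly, and adding a stage
never perturbs the streams of the others.
"""

from __future__ import annotations

import hashlib


def derive_seed(master_seed: int, *stage: object) -> int:
    """A 31-bit seed unique to (master_seed, stage path)."""
    key = ":".join([str(int(master_seed))] + [str(s) for s in stage])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
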
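"""Seed plumbing: named substreams derived from one root seed."""

import hashlib

import numpy as np


def substream_seed(root_seed: int, stream: str) -> int:
    """Derive a stable 32-bit seed for a named stage from the root seed."""
    digest = hashlib.sha256(f"{root_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def substream(root_seed: int, stream: str) -> np.random.Generator:
    """A generator whose stream is a pure function of (root_seed, stream)."""
    return np.random.default_rng(substream_seed(root_seed, stream))
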
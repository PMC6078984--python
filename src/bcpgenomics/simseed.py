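"""Deterministic, label-keyed random streams.

A single root seed fans out into independent child generators keyed by a
stable string label, so adding a new stochastic component never perturbs the
draws of existing ones and the same (seed, label) pair always reproduces the
same stream.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_seed_sequence(root_seed: int, label: str) -> np.random.SeedSequence:
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.SeedSequence(entropy=[int(root_seed) & 0x7FFFFFFF, key])


def child_rng(root_seed: int, label: str) -> np.random.Generator:
    """A generator for the stream named *label* under *root_seed*."""
    return np.random.default_rng(child_seed_sequence(root_seed, label))
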
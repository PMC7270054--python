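"""Deterministic random-number substreams.

A single user-facing seed is fanned out into named, collision-free
substreams via :class:`numpy.random.SeedSequence`, so that e.g. the
Poisson draw for (subject 3, session 1) never shares a stream with the
voxel-jitter draw, and adding subjects never perturbs existing ones.
"""

from __future__ import annotations

import numpy as np

# Fixed stream identifiers; never reorder or reuse.
STREAM_TARGETS = 101
STREAM_SUBJECT = 102
STREAM_SESSION = 103
STREAM_COUNTS = 104
STREAM_TERMS = 105
STREAM_BOOTSTRAP = 106


def substream(seed: int, *key: int) -> np.random.Generator:
    """Return a Generator for the substream identified by ``key``.

    Parameters
    ----------
    seed : base seed (non-negative integer).
    key : further non-negative integers naming the substream.
    """
    parts = [int(seed)] + [int(k) for k in key]
    if any(p < 0 for p in parts):
        raise ValueError(f"seed-sequence keys must be non-negative, got {parts}")
    return np.random.default_rng(np.random.SeedSequence(parts))
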
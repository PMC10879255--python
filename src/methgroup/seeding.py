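"""Deterministic per-stage seeding.

One master seed drives the whole pipeline.  Each stage draws from its own
child stream, derived from the master seed and a fixed stage offset, so a
stage re-run from intermediate files reproduces the monolithic run exactly.
"""

from __future__ import annotations

import numpy as np

# Fixed offsets; never renumber (would silently change all outputs).
STAGE_OFFSETS = {
    "cpg_positions": 0,
    "hmr_blocks": 1,
    "baseline_beta": 2,
    "sequencing": 3,
    "expression": 4,
    "metadata": 5,
    "gene_track": 6,
    "consensus": 7,
    "gap": 8,
    "embed": 9,
    "assign": 10,
    "kmeans": 11,
}


def child_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Generator for one named stage of a run with the given master seed."""
    offset = STAGE_OFFSETS[stage]
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(offset,))
    )


def stage_seed(master_seed: int, stage: str) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    offset = STAGE_OFFSETS[stage]
    ss = np.random.SeedSequence(master_seed, spawn_key=(offset,))
    return int(ss.generate_state(1)[0] % (2**31))
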
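"""Deterministic seed derivation.

Every stochastic stage receives a child seed derived from a master seed and
a fixed stage key, so that enabling or disabling one stage never shifts the
random stream of another.
"""

from __future__ import annotations

import zlib

import numpy as np

# fixed registry: stage key -> stream index; append-only
_STAGE_INDEX = {
    "synth_chem": 1,
    "synth_popgen": 2,
    "synth_pref": 3,
    "synth_survival": 4,
    "synth_protein": 5,
    "nmds": 6,
    "lda_validation": 7,
    "lda_null": 8,
    "pref_mcmc": 9,
    "survival_mcmc": 10,
    "banova_mcmc": 11,
    "fst_bootstrap": 12,
    "mantel": 13,
    "ibd": 14,
    "diversity_bootstrap": 15,
}


def child_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for a named stage."""
    idx = _STAGE_INDEX.get(stage)
    if idx is None:
        # unknown stages hash their name; stable across runs and platforms
        idx = 1000 + zlib.crc32(stage.encode())
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, idx])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def rng_for(master_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, stage))
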
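"""Deterministic seed-stream derivation.

A run is driven by one master seed.  Every stochastic component draws from
its own named substream so that components can be re-run in isolation and
results do not depend on evaluation order or batching.
"""

from __future__ import annotations

import numpy as np

# fixed stream labels; the integers are part of the on-disk reproducibility
# contract and must never be renumbered
STREAMS = {
    "split": 0,
    "generative_fit": 1,
    "posterior_cache": 2,
    "null_draws": 3,
    "predictor_fit": 4,
    "simulation": 5,
    "weights": 6,
    "response_noise": 7,
}


def seed_seq(master_seed: int, stream: str, *extra: int) -> np.random.SeedSequence:
    """SeedSequence for a named substream, optionally keyed further.

    ``extra`` keys (e.g. a gene index for null draws) make the stream
    independent of the order in which hypotheses are evaluated.
    """
    if stream not in STREAMS:
        raise KeyError(f"unknown seed stream {stream!r}")
    return np.random.SeedSequence(entropy=int(master_seed) & 0x7FFFFFFF,
                                  spawn_key=(STREAMS[stream], *map(int, extra)))


def rng_for(master_seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(seed_seq(master_seed, stream, *extra))


def small_int_seed(master_seed: int, stream: str, *extra: int) -> int:
    """A plain integer seed (< 2**31) for libraries that take one (sklearn)."""
    return int(seed_seq(master_seed, stream, *extra).generate_state(1)[0] % (2**31 - 1))
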
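"""Shared helpers: reporting-precision rounding and seed derivation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np

MAX_SEED = 2**31 - 1


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero, as classification tables are printed.

    Rounds the shortest decimal representation that round-trips to ``x``, so
    a nominal tie like 0.9 * 82.85 = 74.565 (stored as 74.56499...) reports
    as 74.57 the way a printed table would.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(quantum,
                                                  rounding=ROUND_HALF_UP))


def derive_seed(master_seed: int, *key: int) -> int:
    """Derive an independent 31-bit integer seed from a master seed and a key path.

    Uses numpy's SeedSequence spawning so components (fold splitting, per-fold
    forests, sweep evaluators) get decorrelated streams that are a pure function
    of (master_seed, key).
    """
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=key)
    return int(ss.generate_state(1)[0]) % MAX_SEED
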
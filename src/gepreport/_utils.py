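"""Small shared helpers: rounding, percentages, seed derivation."""

from __future__ import annotations

import hashlib
import json
from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties going away from zero (half-up), as printed reports do.

    Python's built-in ``round`` uses banker's rounding, which would turn
    94.95 into 94.9 rather than 95.0.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded half-up to ``ndigits`` decimals."""
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_up(100.0 * numerator / denominator, ndigits)


def child_seed(seed: int, index: int) -> int:
    """Derive a reproducible 31-bit sub-seed from a master seed.

    Sub-seed ``index`` is the ``index``-th spawn of
    ``numpy.random.SeedSequence(seed)``; all pipeline stages that need
    independent randomness draw their seeds through this rule.
    """
    ss = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serialisable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
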
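"""Shared helpers: RNG handling and input validation."""

from __future__ import annotations

import numpy as np

MISSING = "NA"


class ValidationError(ValueError):
    """Raised when an input table or parameter set violates a contract."""


def check_rng(seed_or_rng) -> np.random.Generator:
    """Return a Generator from a seed, Generator, or None."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def sklearn_seed(rng: np.random.Generator) -> int:
    """Draw an integer seed suitable for scikit-learn's random_state."""
    return int(rng.integers(0, 2**31 - 1))
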
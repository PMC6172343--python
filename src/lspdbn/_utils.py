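"""Small shared helpers: seed derivation and argument checks."""

from __future__ import annotations

import numpy as np

__all__ = ["derive_seed", "check_positive", "check_fraction"]


def derive_seed(*components: int) -> int:
    """Deterministically derive a child seed from integer components.

    Every stochastic stage of the package draws its seed through this
    function so that a single master seed makes a whole run reproducible.
    The result is kept below 2**31 so it is portable as a plain int seed.
    """
    ss = np.random.SeedSequence([int(c) & 0x7FFFFFFF for c in components])
    return int(ss.generate_state(1)[0] % (2**31))


def check_positive(name: str, value: float) -> None:
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be positive and finite, got {value!r}")


def check_fraction(name: str, value: float, *, allow_zero: bool = True,
                   allow_one: bool = True) -> None:
    lo_ok = value > 0 or (allow_zero and value == 0)
    hi_ok = value < 1 or (allow_one and value == 1)
    if not (np.isfinite(value) and lo_ok and hi_ok):
        raise ValueError(f"{name} must lie in the unit interval, got {value!r}")
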
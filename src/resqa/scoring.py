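"""Local-to-global quality conversion.

A vector of per-residue distance deviations d_i (Å) is summarised into one
global quality score by the Levitt–Gerstein / S-score form

    global = (1/L) * sum_i 1 / (1 + (d_i / c)^2),

with c = 5 Å by default. Each term lies in (0, 1], so the global score does
too; it is 1 exactly when every deviation is zero and strictly decreasing
in every d_i.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

DEFAULT_C = 5.0


def local_to_global(deviations, c: float = DEFAULT_C) -> float:
    """Global quality score in (0, 1] from per-residue deviations (Å)."""
    d = np.asarray(deviations, dtype=float)
    if d.ndim != 1 or d.size == 0:
        raise InputError("deviation vector must be non-empty and 1-D")
    if (d < 0).any():
        raise InputError("deviations must be non-negative")
    if c <= 0:
        raise InputError("c must be positive")
    return float(np.mean(1.0 / (1.0 + (d / c) ** 2)))
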
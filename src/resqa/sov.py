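"""Segment-overlap (SOV) score between two secondary-structure strings.

Implements the 1999 revision of the segment-overlap measure (Zemla et al.,
Proteins 34:220-223): for each state, every pair of overlapping segments
(s1 from the observed string, s2 from the predicted string) contributes
len(s1) * (minov + delta) / maxov, where minov is the length of their
intersection, maxov the length of their union span, and

    delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2).

The normalisation for a state sums len(s1) over all overlapping pairs plus
len(s1) over observed segments with no predicted counterpart; the total
score combines the three states over the summed normalisations. Scores are
returned as fractions in [0, 1].

SOV is asymmetric: the observed string (here, the structure parsed from
the model) plays the reference role. All arithmetic is exact (rational),
with a single float conversion at the end, so independent enumerations of
the same definition agree bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .errors import InputError

STATES = "HEC"


@dataclass
class SovResult:
    sov_total: float
    per_state: dict[str, float]
    n_normalization: int


def segments(s: str, state: str) -> list[tuple[int, int]]:
    """Maximal runs of ``state`` in ``s`` as inclusive 0-based (start, end)."""
    out = []
    start = None
    for i, ch in enumerate(s):
        if ch == state and start is None:
            start = i
        elif ch != state and start is not None:
            out.append((start, i - 1))
            start = None
    if start is not None:
        out.append((start, len(s) - 1))
    return out


def _validate(observed: str, predicted: str) -> None:
    if not observed or not predicted:
        raise InputError("SOV inputs must be non-empty")
    if len(observed) != len(predicted):
        raise InputError(
            f"SOV inputs differ in length ({len(observed)} vs {len(predicted)})"
        )
    for name, s in (("observed", observed), ("predicted", predicted)):
        bad = set(s) - set(STATES)
        if bad:
            raise InputError(f"{name} string contains non-HEC letters {bad}")


def sov_score(observed: str, predicted: str) -> SovResult:
    """SOV'99 of ``predicted`` against the reference ``observed`` string.

    Per-state scores with an empty normalisation (state absent from the
    observed string) are reported as 1.0 — there was nothing to miss.
    """
    _validate(observed, predicted)
    total_num = Fraction(0)
    total_n = 0
    per_state: dict[str, float] = {}
    for state in STATES:
        segs_obs = segments(observed, state)
        segs_pred = segments(predicted, state)
        num = Fraction(0)
        n = 0
        for b1, e1 in segs_obs:
            len1 = e1 - b1 + 1
            overlapped = False
            for b2, e2 in segs_pred:
                minov = min(e1, e2) - max(b1, b2) + 1
                if minov <= 0:
                    continue
                overlapped = True
                maxov = max(e1, e2) - min(b1, b2) + 1
                len2 = e2 - b2 + 1
                delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                num += Fraction(len1 * (minov + delta), maxov)
                n += len1
            if not overlapped:
                n += len1
        per_state[state] = float(num / n) if n > 0 else 1.0
        total_num += num
        total_n += n
    total = float(total_num / total_n) if total_n > 0 else 1.0
    return SovResult(sov_total=total, per_state=per_state, n_normalization=total_n)
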
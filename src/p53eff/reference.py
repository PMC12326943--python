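"""Literal, step-by-step biweight midcorrelation for cross-checking.

This is a deliberately naive transcription of the bicor definition —
explicit medians, deviations, weights and sums computed with plain Python
loops — kept independent of the optimized :func:`p53eff.bicor.bicor` so the
two can be compared against each other. It is used by the test suite and by
the acceptance script as the in-repo oracle; it is not meant to be fast.
"""

from __future__ import annotations

import math
from typing import Sequence


def _median(values: Sequence[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2 == 1:
        return float(s[mid])
    return 0.5 * (s[mid - 1] + s[mid])


def _standardize(v: Sequence[float]) -> list[float]:
    v = [float(a) for a in v]
    med = _median(v)
    deviations = [a - med for a in v]
    mad = _median([abs(d) for d in deviations])
    if mad == 0.0:
        # degenerate robust scale: uniform weights around the mean
        mean = sum(v) / len(v)
        weighted = [a - mean for a in v]
    else:
        weighted = []
        for d in deviations:
            u = d / (9.0 * mad)
            if abs(u) < 1.0:
                w = (1.0 - u * u) ** 2
            else:
                w = 0.0
            weighted.append(d * w)
    norm = math.sqrt(sum(a * a for a in weighted))
    if norm == 0.0:
        raise ValueError("constant vector: correlation undefined")
    return [a / norm for a in weighted]


def bicor_reference(x: Sequence[float], y: Sequence[float]) -> float:
    """Biweight midcorrelation computed term by term from its definition."""
    if len(x) != len(y):
        raise ValueError("length mismatch")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    xt = _standardize(x)
    yt = _standardize(y)
    r = sum(a * b for a, b in zip(xt, yt))
    return max(-1.0, min(1.0, r))
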
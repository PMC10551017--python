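"""Independently coded brute-force reference implementations.

Plain Python loops, no shared code with the package: these are the oracles
the trace-processing and correlation stages are checked against.
"""

from __future__ import annotations

import math
from statistics import median
from typing import List, Sequence, Tuple


def dff_bf(trace: Sequence[float], f0_frames: int = 10) -> List[float]:
    f0 = sum(trace[:f0_frames]) / f0_frames
    return [(v - f0) / f0 for v in trace]


def smooth_bf(
    x: Sequence[float], before: int = 2, after: int = 3, boundary: str = "truncate"
) -> List[float]:
    t = len(x)
    if boundary == "reflect":
        # mirror-pad without repeating the edge sample (numpy 'reflect')
        padded = list(x[before:0:-1]) + list(x) + list(x[t - 2 : t - 2 - after : -1])
        return [
            sum(padded[i : i + before + after + 1]) / (before + after + 1)
            for i in range(t)
        ]
    out = []
    for i in range(t):
        lo = max(0, i - before)
        hi = min(t - 1, i + after)
        out.append(sum(x[lo : hi + 1]) / (hi - lo + 1))
    return out


def remove_background_bf(x: Sequence[float], offset: float, subtract: bool = False) -> List[float]:
    theta = median(x) + offset
    if subtract:
        return [v - theta if v >= theta else 0.0 for v in x]
    return [v if v >= theta else 0.0 for v in x]


def minmax_bf(x: Sequence[float]) -> Tuple[List[float], bool]:
    lo, hi = min(x), max(x)
    if hi == lo:
        return [0.0] * len(x), True
    return [(v - lo) / (hi - lo) for v in x], False


def pearson_bf(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
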
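"""Independent brute-force reference implementations used as test oracles.

These deliberately work second-by-second with explicit loops, sharing no
code with the interval-based implementations they check.
"""

from __future__ import annotations

import numpy as np


def brute_interpolate(raster: np.ndarray, max_gap: int) -> np.ndarray:
    """Fill every zero-run of length <= max_gap that is flanked by ones."""
    out = raster.astype(bool).copy()
    for row in out:
        ones = np.flatnonzero(row)
        if len(ones) < 2:
            continue
        for a, b in zip(ones[:-1], ones[1:]):
            gap = b - a - 1
            if 0 < gap <= max_gap:
                row[a + 1 : b] = True
    return out


def brute_close_triads(raster: np.ndarray, pairs: list[tuple[int, int]], n: int, iterations: int) -> np.ndarray:
    """Per-second synchronous triadic closure by explicit triple loops."""
    S = raster.shape[1]
    out = raster.astype(bool).copy()
    for _ in range(iterations):
        new = out.copy()
        for t in range(S):
            adj = np.zeros((n, n), dtype=bool)
            for d, (i, j) in enumerate(pairs):
                adj[i, j] = adj[j, i] = out[d, t]
            for d, (i, j) in enumerate(pairs):
                if new[d, t]:
                    continue
                for k in range(n):
                    if k != i and k != j and adj[k, i] and adj[k, j]:
                        new[d, t] = True
                        break
        out = new
    return out


def brute_confusion(observed: np.ndarray, truth: np.ndarray) -> tuple[int, int, int, int]:
    """Double-loop dyad-second tally of TP, FP, FN, TN."""
    tp = fp = fn = tn = 0
    for d in range(observed.shape[0]):
        for i in range(observed.shape[1]):
            o, t = bool(observed[d, i]), bool(truth[d, i])
            if o and t:
                tp += 1
            elif o and not t:
                fp += 1
            elif not o and t:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn
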
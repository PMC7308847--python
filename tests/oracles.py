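"""Independent brute-force oracles used to verify the fast implementations.

Deliberately written as plain double loops over pixels so they share no
code path with the package internals.
"""

import numpy as np


def naive_candidates(data: np.ndarray) -> np.ndarray:
    """Per-pixel, per-channel descending sort by explicit loops."""
    n, h, w, c = data.shape
    out = np.empty_like(data, dtype=float)
    for y in range(h):
        for x in range(w):
            for ch in range(c):
                out[:, y, x, ch] = sorted(data[:, y, x, ch], reverse=True)
    return out


def naive_lcov(img: np.ndarray, window: int, epsilon: float) -> np.ndarray:
    """Windowed sigma/(mu+eps), population sigma, edge-duplicating reflect
    padding (numpy's 'symmetric': a b c -> a | a b c | c)."""
    pad = window // 2
    padded = np.pad(img.astype(float), pad, mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            win = padded[y : y + window, x : x + window]
            mu = win.mean()
            sd = win.std()  # population (ddof=0)
            denom = mu + epsilon
            out[y, x] = sd / denom if denom != 0 else 0.0
    return out


def naive_smoothness(img: np.ndarray, window: int, epsilon: float) -> float:
    return float(naive_lcov(img, window, epsilon).sum())
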
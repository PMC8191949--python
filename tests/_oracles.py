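"""Independent brute-force oracles used to pin down expected values."""

from __future__ import annotations

import numpy as np


def brute_otsu(pixels: np.ndarray, n_bins: int = 256) -> tuple[float, np.ndarray]:
    """O(n_bins^2) Otsu: recompute class stats from scratch for every split.

    Same conventions as the implementation under test (class 0 = bins <= t,
    threshold = upper edge of the argmax bin, ties -> floor of the mean
    argmax index) but with none of its cumulative-sum machinery.
    """
    pixels = np.asarray(pixels, dtype=float).ravel()
    hist, edges = np.histogram(pixels, bins=n_bins, range=(pixels.min(), pixels.max()))
    total = hist.sum()
    idx = np.arange(n_bins)
    sigma = np.empty(n_bins - 1)
    for t in range(n_bins - 1):
        h0, h1 = hist[: t + 1], hist[t + 1 :]
        i0, i1 = idx[: t + 1], idx[t + 1 :]
        w0 = h0.sum() / total
        w1 = h1.sum() / total
        mu0 = (h0 * i0).sum() / h0.sum() if h0.sum() > 0 else 0.0
        mu1 = (h1 * i1).sum() / h1.sum() if h1.sum() > 0 else 0.0
        sigma[t] = w0 * w1 * (mu0 - mu1) ** 2
    top = sigma.max()
    ties = np.flatnonzero(sigma >= top * (1.0 - 1e-12))
    t_star = int(np.floor(ties.mean()))
    return float(edges[t_star + 1]), sigma
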
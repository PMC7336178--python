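"""Independent brute-force oracles used by the test suite.

Each function re-derives a quantity by direct enumeration or quadrature,
deliberately sharing no code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate


def bradley_mask_bruteforce(image, window_fraction, sensitivity):
    """Bright-foreground adaptive threshold via explicit sliding windows."""
    img = np.asarray(image, dtype=float)
    n, m = img.shape
    side = int(round(window_fraction * max(n, m)))
    side = max(side | 1, 3)
    half = side // 2
    out = np.zeros((n, m), dtype=bool)
    for i in range(n):
        for j in range(m):
            r0, r1 = max(i - half, 0), min(i + half + 1, n)
            c0, c1 = max(j - half, 0), min(j + half + 1, m)
            out[i, j] = img[i, j] > (1.0 + sensitivity) * img[r0:r1, c0:c1].mean()
    return out


def otsu_threshold_bruteforce(values):
    """Exhaustive between-class-variance maximizer over 256 histogram bins.

    Returns the threshold on the original intensity scale (upper edge of the
    argmax bin after min-max rescaling), matching the package convention.
    """
    values = np.asarray(values, dtype=float).ravel()
    vmin, vmax = values.min(), values.max()
    scaled = (values - vmin) / (vmax - vmin)
    hist, _ = np.histogram(scaled, bins=256, range=(0.0, 1.0))
    total = hist.sum()
    best_t, best_var = 0, -1.0
    for t in range(255):  # t = 255 would leave the upper class empty
        w0 = hist[: t + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            var = -1.0
        else:
            mu0 = (hist[: t + 1] * np.arange(t + 1)).sum() / w0
            mu1 = (hist[t + 1 :] * np.arange(t + 1, 256)).sum() / w1
            var = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return vmin + (best_t + 1) / 256.0 * (vmax - vmin)


def ks_statistic_bruteforce(x, y):
    """sup |ECDF_x - ECDF_y| by evaluating both ECDFs at every pooled point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    best = 0.0
    for v in np.concatenate([x, y]):
        fx = np.mean(x <= v)
        fy = np.mean(y <= v)
        best = max(best, abs(fx - fy))
    return best


def ks_pvalue_permutation(x, y, n_perm=50000, seed=0, chunk=5000):
    """Permutation estimate of the KS p-value (D recomputed per shuffle)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx = x.size
    pooled = np.concatenate([x, y])
    grid = np.sort(pooled)
    d_obs = ks_statistic_bruteforce(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for start in range(0, n_perm, chunk):
        k = min(chunk, n_perm - start)
        order = rng.random((k, pooled.size)).argsort(axis=1)
        perm = pooled[order]
        cx = (np.sort(perm[:, :nx], axis=1)[:, :, None] <= grid[None, None, :]).sum(1) / nx
        cy = (np.sort(perm[:, nx:], axis=1)[:, :, None] <= grid[None, None, :]).sum(1) / (
            pooled.size - nx
        )
        d_perm = np.abs(cx - cy).max(axis=1)
        hits += int((d_perm >= d_obs - 1e-12).sum())
    return hits / n_perm


def rod_form_factor_quadrature(q, L):
    """Orientation average of the thin-rod scattering amplitude squared."""

    def integrand(beta, qq):
        arg = qq * L * np.cos(beta) / 2.0
        amp = np.sinc(arg / np.pi)  # sin(arg)/arg
        return amp**2 * np.sin(beta)

    q = np.atleast_1d(q)
    return np.array(
        [integrate.quad(integrand, 0.0, np.pi / 2.0, args=(qq,), limit=200)[0] for qq in q]
    )
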
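"""Brute-force per-pixel reference implementations of the windowed filters.

Deliberately slow and simple: explicit Python loops over pixels, each
window materialised from an edge-repeating mirror padded copy of the
image (np.pad mode='symmetric', the same convention the filters use).
"""

import numpy as np


def _pad(img, r):
    return np.pad(img, r, mode="symmetric")


def _window(p, i, j, r):
    return p[i : i + 2 * r + 1, j : j + 2 * r + 1]


def lsmv_once(img, sigma_n2, window=5):
    r = window // 2
    p = _pad(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = _window(p, i, j, r)
            mean, var = w.mean(), w.var()
            if var > 0:
                k = (var - mean * mean * sigma_n2) / (var * (1.0 + sigma_n2))
            else:
                k = 0.0
            k = min(max(k, 0.0), 1.0)
            out[i, j] = mean + k * (img[i, j] - mean)
    return out


def wiener_once(img, sigma_n2, window=5):
    r = window // 2
    p = _pad(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = _window(p, i, j, r)
            mean, var = w.mean(), w.var()
            k = (var - sigma_n2) / var if var > 0 else 0.0
            k = min(max(k, 0.0), 1.0)
            out[i, j] = mean + k * (img[i, j] - mean)
    return out


def kuhawara_once(img, window=5):
    r = window // 2
    p = _pad(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = _window(p, i, j, r)
            segments = [
                w[r, :],                      # horizontal
                w[:, r],                      # vertical
                np.diagonal(w),               # main diagonal
                np.diagonal(np.fliplr(w)),    # anti-diagonal
            ]
            variances = [s.var() for s in segments]
            best = int(np.argmin(variances))  # ties -> first (h, v, d1, d2)
            out[i, j] = np.median(segments[best])
    return out


def lsminsc_once(img, window=5, sub=3):
    rw, rs = window // 2, sub // 2
    p = _pad(img, rw)
    plog = np.log1p(np.maximum(p, 0.0))
    out = np.empty_like(img, dtype=float)
    offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)]  # row-major
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            best_c, best_mean = np.inf, img[i, j]
            for dr, dc in offs:
                ci, cj = i + rw + dr, j + rw + dc
                wl = plog[ci - rs : ci + rs + 1, cj - rs : cj + rs + 1]
                wi = p[ci - rs : ci + rs + 1, cj - rs : cj + rs + 1]
                if wl.mean() > 0:
                    c = wl.var() / wl.mean()
                    if c < best_c:
                        best_c, best_mean = c, wi.mean()
            out[i, j] = best_mean if np.isfinite(best_c) else img[i, j]
    return out


def median_once(img, window=5):
    r = window // 2
    p = _pad(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(_window(p, i, j, r))
    return out


def hybrid_median_once(img, window=5):
    r = window // 2
    p = _pad(img, r)
    out = np.empty_like(img, dtype=float)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            w = _window(p, i, j, r)
            plus = np.concatenate([w[r, :], w[:r, r], w[r + 1 :, r]])
            cross = np.concatenate(
                [np.diagonal(w), np.delete(np.diagonal(np.fliplr(w)), r)]
            )
            out[i, j] = (np.median(plus) + np.median(cross) + np.median(w)) / 3.0
    return out


def srad_step(g, eta_s=4.0):
    """One explicit diffusion step with the documented stencil."""
    h, w = g.shape
    p = _pad(g, 1)
    out = np.empty_like(g, dtype=float)
    c = np.empty_like(g, dtype=float)
    for i in range(h):
        for j in range(w):
            gc = p[i + 1, j + 1]
            gn, gs = p[i, j + 1], p[i + 2, j + 1]
            gw, ge = p[i + 1, j], p[i + 1, j + 2]
            gx = (gs - gn) / 2.0
            gy = (ge - gw) / 2.0
            lap = gn + gs + gw + ge - 4.0 * gc
            num = 0.5 * (gx * gx + gy * gy) - lap * lap / 16.0
            den = (gc + 0.25 * lap) ** 2
            c2 = num / den if den > 0 else 0.0
            c[i, j] = np.sqrt(min(max(c2, 0.0), 1.0))
    cp = _pad(c, 1)
    for i in range(h):
        for j in range(w):
            gc = p[i + 1, j + 1]
            div = (
                cp[i + 2, j + 1] * (p[i + 2, j + 1] - gc)
                - cp[i + 1, j + 1] * (gc - p[i, j + 1])
                + cp[i + 1, j + 2] * (p[i + 1, j + 2] - gc)
                - cp[i + 1, j + 1] * (gc - p[i + 1, j])
            )
            out[i, j] = gc + div / eta_s
    return out
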
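"""Despeckle filters for B-mode ultrasound.

Eight filters spanning four families:

* local first-order statistics (``dsf_lsmv``, ``dsf_wiener``) — adaptive
  weighting between the 5x5 local mean and the raw pixel,
* homogeneous-mask selection (``dsf_kuhawara``, ``dsf_lsminsc``) — replace
  the pixel with a statistic of the most homogeneous sub-neighbourhood,
* order statistics (``dsf_median``, ``dsf_hybrid_median``),
* anisotropic diffusion (``dsf_srad``, ``dsf_nldif``).

All filters take a 2D float array and a :class:`FilterConfig` and return a
new array; none modify their input.  Window reads use reflect padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "FilterConfig",
    "SradParams",
    "NldifParams",
    "estimate_noise_variance",
    "dsf_lsmv",
    "dsf_wiener",
    "dsf_kuhawara",
    "dsf_lsminsc",
    "dsf_median",
    "dsf_hybrid_median",
    "dsf_srad",
    "dsf_nldif",
    "srad_coefficient",
    "diffusion_tensor",
    "nldif_step",
    "FILTERS",
    "apply_filter",
]


@dataclass(frozen=True)
class SradParams:
    """Speckle-reducing anisotropic diffusion: update f <- g + div(c grad g)/eta_s."""

    eta_s: float = 4.0
    steps: int = 100


@dataclass(frozen=True)
class NldifParams:
    """Coherence-enhancing diffusion: tensor eigenvalues from local coherence.

    ``s2`` is the coherence threshold (mu1-mu2)^2 above which diffusion
    across the structure stops, ``alpha`` the along-contour conductivity,
    ``m`` the explicit time step.  The structure tensor is built from the
    gradient of the image smoothed at ``sigma_grad`` and smoothed
    componentwise at ``sigma_tensor``.
    """

    s2: float = 2.0
    alpha: float = 0.9
    m: float = 0.2
    steps: int = 10
    sigma_grad: float = 1.0
    sigma_tensor: float = 2.0


@dataclass(frozen=True)
class FilterConfig:
    window: int = 5
    iterations: int | None = None  # None -> per-filter default
    noise_variance: float | None = None  # None -> estimate from the image
    srad: SradParams = field(default_factory=SradParams)
    nldif: NldifParams = field(default_factory=NldifParams)

    def validate(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.iterations is not None and self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0 < self.nldif.alpha <= 1):
            raise ValueError("nldif.alpha must be in (0, 1]")
        if self.nldif.s2 <= 0:
            raise ValueError("nldif.s2 must be > 0")


def _check_image(image: np.ndarray, min_size: int = 5) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale image")
    if min(img.shape) < min_size:
        raise ValueError(f"image must be at least {min_size}x{min_size}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def _local_mean_var(img: np.ndarray, size: int) -> tuple[np.ndarray, np.ndarray]:
    mean = ndimage.uniform_filter(img, size=size, mode="reflect")
    mean_sq = ndimage.uniform_filter(img * img, size=size, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return mean, var


def estimate_noise_variance(image: np.ndarray, tile: int = 21, window: int = 5) -> float:
    """Estimate the speckle noise variance in the log-compressed domain.

    The image is log-compressed (``log(1+g)``, where multiplicative noise
    becomes approximately additive) and partitioned into non-overlapping
    ``tile`` x ``tile`` blocks; the estimate is the average of the per-block
    sample variances.  The tile must be substantially larger than the
    filtering window so block variances reflect noise rather than structure.
    """
    img = _check_image(image)
    if tile < 4 * window:
        raise ValueError(
            f"tile ({tile}) must be at least 4x the filter window ({window})"
        )
    h, w = img.shape
    nr, nc = h // tile, w // tile
    if nr < 1 or nc < 1:
        raise ValueError(f"image {img.shape} smaller than one {tile}x{tile} tile")
    log_img = np.log1p(np.maximum(img, -0.999999))
    blocks = log_img[: nr * tile, : nc * tile].reshape(nr, tile, nc, tile)
    variances = blocks.var(axis=(1, 3), ddof=1)
    return float(variances.mean())


def _noise_variance(img: np.ndarray, cfg: FilterConfig) -> float:
    if cfg.noise_variance is not None:
        if cfg.noise_variance < 0:
            raise ValueError("noise variance must be >= 0")
        return cfg.noise_variance
    return estimate_noise_variance(img, window=cfg.window)


def _adaptive_mean_weight(image: np.ndarray, cfg: FilterConfig, kind: str) -> np.ndarray:
    img = _check_image(image, cfg.window)
    sigma_n2 = _noise_variance(img, cfg)
    iters = cfg.iterations if cfg.iterations is not None else 2
    out = img
    for _ in range(iters):
        mean, var = _local_mean_var(out, cfg.window)
        with np.errstate(divide="ignore", invalid="ignore"):
            if kind == "lsmv":
                k = (var - mean * mean * sigma_n2) / (var * (1.0 + sigma_n2))
            else:  # wiener
                k = (var - sigma_n2) / var
        k = np.where(var > 0, k, 0.0)
        k = np.clip(np.nan_to_num(k, nan=0.0), 0.0, 1.0)
        out = mean + k * (out - mean)
    return out


def dsf_lsmv(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Lee-style local statistics filter, f = mean + k (g - mean).

    The weight ``k = (var - mean^2 sn2) / (var (1 + sn2))`` derives from the
    multiplicative noise model: homogeneous windows (variance explained by
    noise) pull toward the local mean, structured windows keep the pixel.
    Two passes of a 5x5 window by default.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    return _adaptive_mean_weight(image, cfg, "lsmv")


def dsf_wiener(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Pixel-wise adaptive Wiener filter with weight k = (var - sn2)/var."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    return _adaptive_mean_weight(image, cfg, "wiener")


def _kuhawara_footprints(window: int) -> list[np.ndarray]:
    # four 1xN segments through the center: horizontal, vertical, two diagonals
    c = window // 2
    fps = []
    for name in ("h", "v", "d1", "d2"):
        fp = np.zeros((window, window), dtype=bool)
        if name == "h":
            fp[c, :] = True
        elif name == "v":
            fp[:, c] = True
        elif name == "d1":
            np.fill_diagonal(fp, True)
        else:
            np.fill_diagonal(np.fliplr(fp), True)
        fps.append(fp)
    return fps


def dsf_kuhawara(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Directional homogeneous-mask filter.

    Considers the four 1x5 line segments through each pixel (horizontal,
    vertical, both diagonals), picks the most homogeneous one (minimum
    sample variance, ties resolved in that fixed order) and substitutes the
    segment's median.  Applied twice by default.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    img = _check_image(image, cfg.window)
    iters = cfg.iterations if cfg.iterations is not None else 2
    fps = _kuhawara_footprints(cfg.window)
    out = img
    for _ in range(iters):
        variances = []
        medians = []
        for fp in fps:
            weights = fp.astype(float) / fp.sum()
            mean = ndimage.correlate(out, weights, mode="reflect")
            mean_sq = ndimage.correlate(out * out, weights, mode="reflect")
            variances.append(np.maximum(mean_sq - mean * mean, 0.0))
            medians.append(ndimage.median_filter(out, footprint=fp, mode="reflect"))
        choice = np.argmin(np.stack(variances), axis=0)
        out = np.take_along_axis(np.stack(medians), choice[np.newaxis], axis=0)[0]
    return out


def _shift_reflect(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    p = np.pad(a, 1, mode="symmetric")
    return p[1 + dr : 1 + dr + a.shape[0], 1 + dc : 1 + dc + a.shape[1]]


def dsf_lsminsc(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Minimum-speckle-index homogeneous mask filter.

    Within each 5x5 neighbourhood, the nine 3x3 subwindows are scored by the
    speckle index ``C = var/mean`` computed on the log-compressed image; the
    pixel is replaced by the intensity-domain mean of the subwindow with the
    smallest ``C`` (row-major scan order breaks ties).  Single pass.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    img = _check_image(image, cfg.window)
    iters = cfg.iterations if cfg.iterations is not None else 1
    sub = 3
    out = img
    for _ in range(iters):
        log_img = np.log1p(np.maximum(out, 0.0))
        mean_log, var_log = _local_mean_var(log_img, sub)
        mean_int = ndimage.uniform_filter(out, size=sub, mode="reflect")
        c_stack, m_stack = [], []
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                ml = _shift_reflect(mean_log, dr, dc)
                vl = _shift_reflect(var_log, dr, dc)
                with np.errstate(divide="ignore", invalid="ignore"):
                    c = np.where(ml > 0, vl / ml, np.inf)
                c_stack.append(c)
                m_stack.append(_shift_reflect(mean_int, dr, dc))
        c_stack = np.stack(c_stack)
        m_stack = np.stack(m_stack)
        choice = np.argmin(c_stack, axis=0)
        best = np.take_along_axis(m_stack, choice[np.newaxis], axis=0)[0]
        all_skipped = np.isinf(np.min(c_stack, axis=0))
        out = np.where(all_skipped, out, best)
    return out


def dsf_median(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Plain 5x5 median filter."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    img = _check_image(image, cfg.window)
    iters = cfg.iterations if cfg.iterations is not None else 1
    out = img
    for _ in range(iters):
        out = ndimage.median_filter(out, size=cfg.window, mode="reflect")
    return out


def _hybrid_footprints(window: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = window // 2
    plus = np.zeros((window, window), dtype=bool)
    plus[c, :] = True
    plus[:, c] = True
    cross = np.zeros((window, window), dtype=bool)
    np.fill_diagonal(cross, True)
    np.fill_diagonal(np.fliplr(cross), True)
    square = np.ones((window, window), dtype=bool)
    return plus, cross, square


def dsf_hybrid_median(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Hybrid median: average of '+'-cross, 'x'-cross and full-square medians."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    img = _check_image(image, cfg.window)
    iters = cfg.iterations if cfg.iterations is not None else 1
    out = img
    for _ in range(iters):
        parts = [
            ndimage.median_filter(out, footprint=fp, mode="reflect")
            for fp in _hybrid_footprints(cfg.window)
        ]
        out = (parts[0] + parts[1] + parts[2]) / 3.0
    return out


def _gradients_reflect(g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p = np.pad(g, 1, mode="symmetric")
    gx = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    gy = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    return gx, gy


def _laplacian_reflect(g: np.ndarray) -> np.ndarray:
    p = np.pad(g, 1, mode="symmetric")
    return p[2:, 1:-1] + p[:-2, 1:-1] + p[1:-1, 2:] + p[1:-1, :-2] - 4.0 * g


def srad_coefficient(g: np.ndarray) -> np.ndarray:
    """Instantaneous-coefficient-of-variation conduction, clipped to [0, 1].

    ``c^2 = [0.5 |grad g|^2 - (1/16)(lap g)^2] / (g + 0.25 lap g)^2``; high
    relative gradient with low relative Laplacian marks an edge (c -> 1),
    speckle yields small or negative numerators (c -> 0).
    """
    gx, gy = _gradients_reflect(g)
    lap = _laplacian_reflect(g)
    num = 0.5 * (gx * gx + gy * gy) - (lap * lap) / 16.0
    den = (g + 0.25 * lap) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        c2 = np.where(den > 0, num / den, 0.0)
    return np.sqrt(np.clip(np.nan_to_num(c2, nan=0.0), 0.0, 1.0))


def dsf_srad(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Speckle-reducing anisotropic diffusion.

    Explicit iteration ``g <- g + div(c grad g) / eta_s`` with the
    conduction coefficient of :func:`srad_coefficient`.  The divergence is
    discretised as ``c_{i+1,j}(g_{i+1,j}-g_{i,j}) - c_{i,j}(g_{i,j}-g_{i-1,j})``
    plus the analogous column term, with reflect boundaries.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    g = _check_image(image)
    if np.any(g < 0):
        g = g - g.min()
    for _ in range(cfg.srad.steps):
        c = srad_coefficient(g)
        gp = np.pad(g, 1, mode="symmetric")
        cp = np.pad(c, 1, mode="symmetric")
        div = (
            cp[2:, 1:-1] * (gp[2:, 1:-1] - g)
            - c * (g - gp[:-2, 1:-1])
            + cp[1:-1, 2:] * (gp[1:-1, 2:] - g)
            - c * (g - gp[1:-1, :-2])
        )
        g = g + div / cfg.srad.eta_s
    return g


def diffusion_tensor(
    g: np.ndarray, params: NldifParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Coherence-driven diffusion tensor (d11, d12, d22) per pixel.

    Eigenvectors follow the smoothed structure tensor; the across-structure
    eigenvalue is ``alpha (1 - (mu1-mu2)^2/s2)`` while coherence is below
    the ``s2`` threshold and 0 beyond it; the along-contour eigenvalue is
    ``alpha``.  In noisy, incoherent regions mu1 ~ mu2 and diffusion is
    isotropic with strength alpha.
    """
    gs = ndimage.gaussian_filter(g, params.sigma_grad, mode="reflect")
    gx, gy = _gradients_reflect(gs)
    j11 = ndimage.gaussian_filter(gx * gx, params.sigma_tensor, mode="reflect")
    j12 = ndimage.gaussian_filter(gx * gy, params.sigma_tensor, mode="reflect")
    j22 = ndimage.gaussian_filter(gy * gy, params.sigma_tensor, mode="reflect")
    if not (np.all(np.isfinite(j11)) and np.all(np.isfinite(j12)) and np.all(np.isfinite(j22))):
        raise ValueError("non-finite structure tensor entries")
    disc = np.sqrt((j11 - j22) ** 2 + 4.0 * j12 * j12)
    mu1 = 0.5 * (j11 + j22 + disc)
    mu2 = 0.5 * (j11 + j22 - disc)
    coh = (mu1 - mu2) ** 2
    lam1 = np.where(coh <= params.s2, params.alpha * (1.0 - coh / params.s2), 0.0)
    lam2 = np.full_like(g, params.alpha)
    theta = 0.5 * np.arctan2(2.0 * j12, j11 - j22)
    ct, st = np.cos(theta), np.sin(theta)
    d11 = lam1 * ct * ct + lam2 * st * st
    d12 = (lam1 - lam2) * ct * st
    d22 = lam1 * st * st + lam2 * ct * ct
    return d11, d12, d22


def nldif_step(g: np.ndarray, params: NldifParams) -> np.ndarray:
    """One explicit step of dg/dt = div(D grad g), conservative discretisation.

    Fluxes live on half-point faces (tensor entries and tangential
    gradients averaged onto faces); the divergence is the net face flux
    with zero-flux (Neumann) boundaries.  Unlike a twice-central-difference
    form, this damps checkerboard modes.
    """
    d11, d12, d22 = diffusion_tensor(g, params)
    gx_c, gy_c = _gradients_reflect(g)
    # vertical faces (between rows i and i+1)
    gx_f = g[1:, :] - g[:-1, :]
    gy_f = 0.5 * (gy_c[1:, :] + gy_c[:-1, :])
    j1 = 0.5 * (d11[1:, :] + d11[:-1, :]) * gx_f + 0.5 * (d12[1:, :] + d12[:-1, :]) * gy_f
    # horizontal faces (between columns j and j+1)
    gy_g = g[:, 1:] - g[:, :-1]
    gx_g = 0.5 * (gx_c[:, 1:] + gx_c[:, :-1])
    j2 = 0.5 * (d12[:, 1:] + d12[:, :-1]) * gx_g + 0.5 * (d22[:, 1:] + d22[:, :-1]) * gy_g
    div = np.zeros_like(g)
    div[:-1, :] += j1
    div[1:, :] -= j1
    div[:, :-1] += j2
    div[:, 1:] -= j2
    return g + params.m * div


def dsf_nldif(image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Coherence-enhancing nonlinear anisotropic diffusion, dg/dt = div(D grad g)."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    g = _check_image(image)
    for _ in range(cfg.nldif.steps):
        g = nldif_step(g, cfg.nldif)
    return g


FILTERS = {
    "lsmv": dsf_lsmv,
    "wiener": dsf_wiener,
    "kuhawara": dsf_kuhawara,
    "lsminsc": dsf_lsminsc,
    "median": dsf_median,
    "hybridmedian": dsf_hybrid_median,
    "srad": dsf_srad,
    "nldif": dsf_nldif,
}


def apply_filter(name: str, image: np.ndarray, cfg: FilterConfig | None = None) -> np.ndarray:
    """Run a despeckle filter by name; unknown names list the valid choices."""
    try:
        fn = FILTERS[name]
    except KeyError:
        raise ValueError(
            f"unknown filter {name!r}; valid filters: {', '.join(sorted(FILTERS))}"
        ) from None
    return fn(image, cfg)
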
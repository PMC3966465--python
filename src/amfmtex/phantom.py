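"""Synthetic carotid-artery phantom with known AM-FM structure.

The phantom mimics a longitudinal B-mode view of the common carotid artery:
three dark "background" bands (lumen / tissue) separated by two bright,
narrow horizontal strips standing in for the intima-media complex.  Every
band is a chirped FM texture with piecewise-constant instantaneous
amplitude, so the per-pixel instantaneous amplitude (IA) and instantaneous
frequency (IF) are known exactly and can serve as ground truth when
benchmarking despeckle filters and demodulation accuracy.

Speckle is modelled as zero-mean multiplicative noise,
``g = f + n * f`` with ``n`` i.i.d. uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "PhantomSpec",
    "SpeckleSpec",
    "PhantomTruth",
    "default_phantom_spec",
    "generate_phantom",
    "add_speckle",
]


@dataclass(frozen=True)
class Band:
    """One horizontal band of the phantom.

    Rows ``row_start..row_end`` (inclusive) share a constant amplitude and a
    vertical instantaneous frequency that sweeps linearly across the image
    width from ``ifx_min`` to ``ifx_max`` (rad/pixel).  The horizontal IF is
    ``ify_sign * ifx``, which orients the texture along one of the two image
    diagonals.
    """

    row_start: int
    row_end: int
    amplitude: float
    ifx_min: float
    ifx_max: float
    ify_sign: int
    label: str = "background"


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 1024
    width: int = 1024
    bands: tuple[Band, ...] = ()
    sweep_axis: int = 1  # axis along which ifx sweeps (1 = columns)

    def validate(self) -> None:
        if not self.bands:
            raise ValueError("phantom spec has no bands")
        rows_covered = 0
        expected_start = 0
        for b in sorted(self.bands, key=lambda b: b.row_start):
            if b.row_start != expected_start:
                raise ValueError(
                    f"bands must partition rows: gap/overlap at row {b.row_start}"
                )
            if b.row_end < b.row_start:
                raise ValueError("band with row_end < row_start")
            if not (0 < b.ifx_min <= b.ifx_max < np.pi):
                raise ValueError("band IF range must satisfy 0 < ifx_min <= ifx_max < pi")
            if b.ify_sign not in (-1, 1):
                raise ValueError("ify_sign must be +1 or -1")
            rows_covered += b.row_end - b.row_start + 1
            expected_start = b.row_end + 1
        if rows_covered != self.height:
            raise ValueError(
                f"bands cover {rows_covered} rows but phantom height is {self.height}"
            )
        if self.sweep_axis not in (0, 1):
            raise ValueError("sweep_axis must be 0 or 1")


@dataclass(frozen=True)
class SpeckleSpec:
    """Zero-mean uniform multiplicative noise; half-width a = sqrt(3*variance)."""

    variance: float = 0.07
    seed: int = 0

    def validate(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")


@dataclass
class PhantomTruth:
    """Noise-free phantom image together with its generating IA/IF fields."""

    image: np.ndarray
    ia_true: np.ndarray
    ifx_true: np.ndarray
    ify_true: np.ndarray
    masks: dict[str, np.ndarray] = field(default_factory=dict)


def default_phantom_spec(height: int = 1024, width: int = 1024) -> PhantomSpec:
    """Five-band layout: three dark backgrounds and two bright strips.

    Backgrounds sweep the vertical IF over [pi/7.5, pi/4.5] with the texture
    oriented along the anti-diagonal (ify = -ifx); the strips sweep
    [pi/6.5, pi/5.5] along the main diagonal (ify = +ifx).  Row extents scale
    proportionally when a non-default height is requested.
    """
    base = [
        (0, 272, 158.0, np.pi / 7.5, np.pi / 4.5, -1, "background"),
        (273, 306, 250.0, np.pi / 6.5, np.pi / 5.5, +1, "strip"),
        (307, 702, 102.0, np.pi / 7.5, np.pi / 4.5, -1, "background"),
        (703, 750, 250.0, np.pi / 6.5, np.pi / 5.5, +1, "strip"),
        (751, 1023, 182.0, np.pi / 7.5, np.pi / 4.5, -1, "background"),
    ]
    if height != 1024:
        scale = height / 1024.0
        scaled = []
        prev_end = -1
        for i, (r0, r1, a, fmin, fmax, s, lab) in enumerate(base):
            r0s = prev_end + 1
            r1s = int(round((r1 + 1) * scale)) - 1 if i < len(base) - 1 else height - 1
            r1s = max(r1s, r0s)
            scaled.append((r0s, r1s, a, fmin, fmax, s, lab))
            prev_end = r1s
        base = scaled
    bands = tuple(Band(*row) for row in base)
    return PhantomSpec(height=height, width=width, bands=bands)


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Render the phantom image ``f = A * cos(phi)`` and its ground truth.

    Within each band the vertical IF (``d(phi)/d(row)``) is constant down
    every column and sweeps linearly across the sweep axis; the phase is
    synthesized as ``phi(r, c) = r * ifx(c) + sign * Psi(c)`` with ``Psi``
    the running sum of ``ifx`` along the sweep axis.  The row derivative of
    ``phi`` therefore equals the stated ``ifx`` exactly, while the column
    derivative equals ``sign * ifx`` up to a residual ``r * ifx'(c)`` that a
    prescribed non-conservative IF field cannot avoid.
    """
    if spec is None:
        spec = default_phantom_spec()
    spec.validate()
    h, w = spec.height, spec.width

    ia = np.zeros((h, w))
    ifx = np.zeros((h, w))
    ify = np.zeros((h, w))
    phase = np.zeros((h, w))
    masks = {
        "backgrounds": np.zeros((h, w), dtype=bool),
        "strips": np.zeros((h, w), dtype=bool),
    }

    n_sweep = w if spec.sweep_axis == 1 else h
    ramp = np.arange(n_sweep) / max(n_sweep - 1, 1)
    rows = np.arange(h)

    for band in spec.bands:
        sl = slice(band.row_start, band.row_end + 1)
        f_line = band.ifx_min + (band.ifx_max - band.ifx_min) * ramp  # per column
        psi = np.concatenate(([0.0], np.cumsum(f_line[:-1])))
        ia[sl] = band.amplitude
        ifx[sl] = f_line[np.newaxis, :]
        ify[sl] = band.ify_sign * f_line[np.newaxis, :]
        phase[sl] = rows[sl, np.newaxis] * f_line[np.newaxis, :] + band.ify_sign * psi
        key = "strips" if band.label == "strip" else "backgrounds"
        masks[key][sl] = True

    masks["combined"] = masks["backgrounds"] | masks["strips"]
    image = ia * np.cos(phase)
    return PhantomTruth(image=image, ia_true=ia, ifx_true=ifx, ify_true=ify, masks=masks)


def add_speckle(truth: PhantomTruth | np.ndarray, noise: SpeckleSpec | None = None) -> np.ndarray:
    """Corrupt an image with multiplicative uniform speckle, ``g = f + n f``.

    ``n`` is i.i.d. uniform on ``[-a, a]`` with ``a = sqrt(3 * variance)``
    so that it has zero mean and the requested variance.  Reproducible for a
    fixed seed.
    """
    if noise is None:
        noise = SpeckleSpec()
    noise.validate()
    f = truth.image if isinstance(truth, PhantomTruth) else np.asarray(truth, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("input image must be finite")
    if noise.variance == 0:
        return f.copy()
    a = np.sqrt(3.0 * noise.variance)
    rng = np.random.default_rng(noise.seed)
    n = rng.uniform(-a, a, size=f.shape)
    return f + n * f
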
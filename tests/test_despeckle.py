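"""Despeckle filters: closed-form limits, oracle equivalence, diffusion stencils."""

import numpy as np
import pytest
from scipy import ndimage

import oracles
from amfmtex.despeckle import (
    FilterConfig,
    NldifParams,
    SradParams,
    diffusion_tensor,
    dsf_hybrid_median,
    dsf_kuhawara,
    dsf_lsminsc,
    dsf_lsmv,
    dsf_median,
    dsf_nldif,
    dsf_srad,
    dsf_wiener,
    apply_filter,
    estimate_noise_variance,
    srad_coefficient,
)

ALL_FILTERS = [
    dsf_lsmv, dsf_wiener, dsf_kuhawara, dsf_lsminsc,
    dsf_median, dsf_hybrid_median, dsf_srad, dsf_nldif,
]


class TestNoiseVarianceEstimator:
    def test_constant_image_gives_zero(self):
        assert estimate_noise_variance(np.full((64, 64), 42.0)) == pytest.approx(0.0, abs=1e-15)

    def test_recovers_injected_log_domain_variance(self, rng):
        v = 0.03
        a = np.sqrt(3.0 * v)
        logdom = 2.0 + rng.uniform(-a, a, size=(210, 210))
        img = np.expm1(logdom)  # so log1p(img) == logdom exactly
        est = estimate_noise_variance(img, tile=21)
        assert abs(est / v - 1) < 0.1

    def test_tile_not_much_larger_than_window_rejected(self):
        with pytest.raises(ValueError, match="4x"):
            estimate_noise_variance(np.zeros((64, 64)), tile=5, window=5)

    def test_image_smaller_than_tile_rejected(self):
        with pytest.raises(ValueError, match="tile"):
            estimate_noise_variance(np.zeros((10, 10)), tile=21, window=5)


class TestAdaptiveMeanFilters:
    def test_zero_noise_variance_is_identity(self, random_16x16):
        cfg = FilterConfig(noise_variance=0.0, iterations=1)
        np.testing.assert_allclose(dsf_lsmv(random_16x16, cfg), random_16x16, atol=1e-10)
        np.testing.assert_allclose(dsf_wiener(random_16x16, cfg), random_16x16, atol=1e-10)

    def test_huge_noise_variance_reduces_to_box_mean(self, random_16x16):
        """k clipped to 0 everywhere -> output equals the 5x5 mean."""
        box = np.array([
            [np.pad(random_16x16, 2, mode="symmetric")[i : i + 5, j : j + 5].mean()
             for j in range(16)] for i in range(16)
        ])
        cfg = FilterConfig(noise_variance=1e9, iterations=1)
        np.testing.assert_allclose(dsf_wiener(random_16x16, cfg), box, atol=1e-9)

    def test_lsmv_center_matches_direct_evaluation(self, rng):
        patch = rng.uniform(0, 255, size=(7, 7))
        cfg = FilterConfig(noise_variance=0.05, iterations=1)
        out = dsf_lsmv(patch, cfg)
        w = patch[1:6, 1:6]
        mean, var = w.mean(), w.var()
        k = np.clip((var - mean**2 * 0.05) / (var * 1.05), 0, 1)
        assert out[3, 3] == pytest.approx(mean + k * (patch[3, 3] - mean), abs=1e-10)


class TestHomogeneousMaskFilters:
    def test_kuhawara_vertical_edge_uses_vertical_segment(self):
        """On a vertical edge the vertical segment is flat; its median wins."""
        img = np.full((9, 9), 10.0)
        img[:, 5:] = 200.0
        img[4, 4] = 50.0  # center pixel deviates; its column stays at 10 elsewhere
        out = dsf_kuhawara(img, FilterConfig(iterations=1))
        assert out[4, 4] == 10.0  # median of the homogeneous vertical segment

    def test_lsminsc_flat_corner_wins(self):
        """A zero-variance 3x3 subwindow has C=0 and provides the output mean."""
        rng = np.random.default_rng(7)
        img = rng.uniform(100.0, 200.0, size=(9, 9))
        img[2:5, 2:5] = 77.0  # flat 3x3 block, upper-left corner of (4,4)'s window
        out = dsf_lsminsc(img, FilterConfig(iterations=1))
        assert out[4, 4] == pytest.approx(77.0)

    def test_lsminsc_all_zero_neighbourhood_unchanged(self):
        img = np.zeros((8, 8))
        img[6, 6] = 5.0
        out = dsf_lsminsc(img, FilterConfig(iterations=1))
        assert out[1, 1] == 0.0


class TestMedianFilters:
    def test_impulse_removed(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 255.0
        assert dsf_median(img)[4, 4] == 10.0
        assert dsf_hybrid_median(img)[4, 4] == 10.0

    def test_median_preserves_linear_ramp_interior(self):
        img = np.tile(np.arange(16.0), (16, 1))
        out = dsf_median(img)
        np.testing.assert_array_equal(out[2:-2, 2:-2], img[2:-2, 2:-2])

    def test_hybrid_is_mean_of_three_sub_medians(self, random_16x16):
        plus = np.zeros((5, 5), bool); plus[2, :] = True; plus[:, 2] = True
        cross = np.eye(5, dtype=bool) | np.fliplr(np.eye(5, dtype=bool))
        parts = [
            ndimage.median_filter(random_16x16, footprint=fp, mode="reflect")
            for fp in (plus, cross, np.ones((5, 5), bool))
        ]
        np.testing.assert_allclose(
            dsf_hybrid_median(random_16x16), sum(parts) / 3.0, atol=1e-12
        )


class TestDiffusionFilters:
    def test_srad_negative_coefficient_clipped(self):
        # a checkerboard maximises |laplacian| against |gradient|
        img = 100.0 + 50.0 * np.indices((8, 8)).sum(axis=0) % 2
        c = srad_coefficient(img)
        assert np.all(c >= 0)
        center = c[2:-2, 2:-2]
        assert np.all(center == 0)  # (1/16)lap^2 > (1/2)|grad|^2 there

    def test_srad_one_step_matches_stencil_oracle(self, rng):
        img = rng.uniform(50.0, 150.0, size=(12, 12))
        got = dsf_srad(img, FilterConfig(srad=SradParams(eta_s=4.0, steps=1)))
        np.testing.assert_allclose(got, oracles.srad_step(img, 4.0), atol=1e-10)

    def test_srad_one_step_on_ramp(self):
        img = np.tile(np.arange(5.0) + 1.0, (5, 1)) * 10.0
        got = dsf_srad(img, FilterConfig(srad=SradParams(eta_s=4.0, steps=1)))
        np.testing.assert_allclose(got, oracles.srad_step(img, 4.0), atol=1e-12)

    def test_nldif_incoherent_region_is_isotropic(self):
        params = NldifParams()
        d11, d12, d22 = diffusion_tensor(np.full((16, 16), 9.0), params)
        np.testing.assert_allclose(d11, params.alpha, atol=1e-12)
        np.testing.assert_allclose(d22, params.alpha, atol=1e-12)
        np.testing.assert_allclose(d12, 0.0, atol=1e-12)

    def test_nldif_high_coherence_stops_cross_diffusion(self):
        # strong vertical edge -> (mu1-mu2)^2 > s2 -> lambda_1 = 0
        img = np.zeros((32, 32))
        img[:, 16:] = 400.0
        d11, d12, d22 = diffusion_tensor(img, NldifParams())
        # at the edge, the across-edge direction is the column axis (d22 -> 0)
        assert d22[16, 16] == pytest.approx(0.0, abs=1e-9)
        assert d11[16, 16] == pytest.approx(0.9, abs=1e-9)

    def test_nldif_one_step_matches_divergence_oracle(self, rng):
        """Explicit per-cell face-flux bookkeeping reproduces one step."""
        img = rng.uniform(0.0, 10.0, size=(10, 10))
        p = NldifParams(steps=1)
        got = dsf_nldif(img, FilterConfig(nldif=p))

        d11, d12, d22 = diffusion_tensor(img, p)
        pad = np.pad(img, 1, mode="symmetric")
        gx = (pad[2:, 1:-1] - pad[:-2, 1:-1]) / 2
        gy = (pad[1:-1, 2:] - pad[1:-1, :-2]) / 2
        h, w = img.shape
        want = img.copy()
        for i in range(h):
            for j in range(w):
                div = 0.0
                if i + 1 < h:  # face below
                    div += (d11[i, j] + d11[i + 1, j]) / 2 * (img[i + 1, j] - img[i, j]) \
                        + (d12[i, j] + d12[i + 1, j]) / 2 * (gy[i, j] + gy[i + 1, j]) / 2
                if i - 1 >= 0:  # face above
                    div -= (d11[i - 1, j] + d11[i, j]) / 2 * (img[i, j] - img[i - 1, j]) \
                        + (d12[i - 1, j] + d12[i, j]) / 2 * (gy[i - 1, j] + gy[i, j]) / 2
                if j + 1 < w:  # face right
                    div += (d22[i, j] + d22[i, j + 1]) / 2 * (img[i, j + 1] - img[i, j]) \
                        + (d12[i, j] + d12[i, j + 1]) / 2 * (gx[i, j] + gx[i, j + 1]) / 2
                if j - 1 >= 0:  # face left
                    div -= (d22[i, j - 1] + d22[i, j]) / 2 * (img[i, j] - img[i, j - 1]) \
                        + (d12[i, j - 1] + d12[i, j]) / 2 * (gx[i, j - 1] + gx[i, j]) / 2
                want[i, j] += p.m * div
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_diffusion_respects_range_at_small_step(self, rng):
        img = rng.uniform(10.0, 90.0, size=(24, 24))
        lo, hi = img.min(), img.max()
        eps = 1e-9
        out = dsf_srad(img, FilterConfig(srad=SradParams(steps=5)))
        assert out.min() >= lo - eps and out.max() <= hi + eps
        out = dsf_nldif(img, FilterConfig(nldif=NldifParams(steps=5)))
        assert out.min() >= lo - eps and out.max() <= hi + eps


@pytest.mark.parametrize(
    "name,oracle,kwargs",
    [
        ("lsmv", oracles.lsmv_once, {"sigma_n2": 0.05}),
        ("wiener", oracles.wiener_once, {"sigma_n2": 0.05}),
        ("kuhawara", oracles.kuhawara_once, {}),
        ("lsminsc", oracles.lsminsc_once, {}),
        ("median", oracles.median_once, {}),
        ("hybridmedian", oracles.hybrid_median_once, {}),
    ],
)
def test_windowed_filters_match_bruteforce_oracle(name, oracle, kwargs, random_16x16):
    cfg = FilterConfig(iterations=1, noise_variance=kwargs.get("sigma_n2"))
    got = apply_filter(name, random_16x16, cfg)
    want = oracle(random_16x16, **kwargs)
    np.testing.assert_allclose(got, want, atol=1e-9)


def test_range_preserved_by_order_statistic_filters(rng):
    img = rng.uniform(5.0, 250.0, size=(20, 20))
    for fn in (dsf_median, dsf_hybrid_median, dsf_kuhawara):
        out = fn(img)
        assert out.min() >= img.min() - 1e-12
        assert out.max() <= img.max() + 1e-12


def test_unknown_filter_name_lists_choices(random_16x16):
    with pytest.raises(ValueError, match="hybridmedian"):
        apply_filter("boxcar", random_16x16)


def test_filters_do_not_mutate_input(random_16x16):
    snapshot = random_16x16.copy()
    for fn in ALL_FILTERS:
        cfg = FilterConfig(noise_variance=0.05)
        fn(random_16x16, cfg)
        np.testing.assert_array_equal(random_16x16, snapshot)
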
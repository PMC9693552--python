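import math

import numpy as np
import pytest

from saxsfibril import (
    DetectorImage,
    anisotropy_score,
    azimuthal_average,
    fold_half_quadrant,
    radial_integrate,
    subtract_isotropic_floor,
)
from saxsfibril.reduction import AzimuthalProfile, ReductionError

from helpers import brute_force_radial_profile

TWO_PI = 2 * math.pi


def constant_image(qmap, value=3.5):
    return DetectorImage(counts=np.full(qmap.shape, value))


class TestAzimuthalAverage:
    def test_constant_image_gives_constant_profile(self, small_qmap):
        q_edges = np.linspace(0.05, 0.35, 13)
        prof = azimuthal_average(constant_image(small_qmap), small_qmap, q_edges)
        assert np.allclose(prof.intensity[prof.nonempty], 3.5)

    def test_sector_disjoint_from_signal_sees_zero(self, small_qmap):
        counts = np.zeros(small_qmap.shape)
        wedge = ((small_qmap.chi > 0.1) & (small_qmap.chi < 0.4))
        counts[wedge] = 7.0
        prof = azimuthal_average(
            DetectorImage(counts=counts), small_qmap,
            np.linspace(0.05, 0.35, 9), sector=[(1.0, 2.0)],
        )
        assert np.all(prof.intensity[prof.nonempty] == 0.0)

    def test_matches_brute_force_pixel_grouping(self, small_qmap, rng):
        counts = rng.gamma(2.0, 50.0, size=small_qmap.shape)
        mask = rng.random(small_qmap.shape) > 0.1
        image = DetectorImage(counts=counts, mask=mask)
        q_edges = np.linspace(0.03, 0.4, 11)
        sector = [(5.8, 0.7), (2.6, 3.9)]  # one wedge wraps through zero
        prof = azimuthal_average(image, small_qmap, q_edges, sector=sector)
        means, n = brute_force_radial_profile(image, small_qmap, q_edges, sector=sector)
        assert np.array_equal(prof.n_pixels, n)
        both = prof.nonempty
        np.testing.assert_allclose(prof.intensity[both], means[both], rtol=1e-12)

    def test_zero_measure_sector_rejected(self, small_qmap):
        with pytest.raises(ReductionError):
            azimuthal_average(
                constant_image(small_qmap), small_qmap,
                np.linspace(0.05, 0.3, 5), sector=[],
            )

    def test_fully_masked_image_rejected(self, small_qmap):
        img = DetectorImage(counts=np.ones(small_qmap.shape), mask=np.zeros(small_qmap.shape, bool))
        with pytest.raises(ReductionError):
            azimuthal_average(img, small_qmap, np.linspace(0.05, 0.3, 5))

    def test_pixel_conservation(self, small_qmap):
        q_edges = np.linspace(0.0, 1.0, 30)  # covers the whole detector q range
        prof = azimuthal_average(constant_image(small_qmap), small_qmap, q_edges)
        assert prof.n_pixels.sum() == small_qmap.valid.sum()


class TestRadialIntegrate:
    def test_constant_intensity_integrates_to_c_times_band(self, small_qmap):
        c, q_range = 2.25, (0.05, 0.30)
        prof = radial_integrate(
            constant_image(small_qmap, c), small_qmap,
            np.linspace(0, TWO_PI, 37), q_range,
        )
        expect = c * (q_range[1] - q_range[0])
        np.testing.assert_allclose(prof.H[prof.nonempty], expect, rtol=1e-12)

    def test_two_symmetric_streaks_give_two_peaks(self, small_qmap):
        counts = np.zeros(small_qmap.shape)
        chi = small_qmap.chi
        chi0 = 0.9
        near = (np.abs(np.mod(chi - chi0 + math.pi, TWO_PI) - math.pi) < 0.15) | (
            np.abs(np.mod(chi - chi0, TWO_PI) - math.pi) < 0.15
        )
        counts[near] = 10.0
        prof = radial_integrate(
            DetectorImage(counts=counts), small_qmap, np.linspace(0, TWO_PI, 25), (0.05, 0.3)
        )
        hot = prof.nonempty & (prof.H > 0.5 * np.nanmax(prof.H))
        centers = prof.chi_centers[hot]
        # every hot bin sits near chi0 or chi0 + pi
        d0 = np.abs(np.mod(centers - chi0 + math.pi, TWO_PI) - math.pi)
        d1 = np.abs(np.mod(centers - chi0, TWO_PI) - math.pi)
        assert np.all(np.minimum(d0, d1) < 0.4)
        assert (d0 < 0.4).any() and (d1 < 0.4).any()

    def test_matches_refined_radial_grid(self, desk_qmap):
        # smooth streak-like intensity: the 64-sub-bin integral should agree
        # with the same rule on a 4x finer radial grid to better than 2%
        chi_f = np.minimum(np.mod(desk_qmap.chi, math.pi), math.pi - np.mod(desk_qmap.chi, math.pi))
        q = np.where(desk_qmap.q_r > 0.05, desk_qmap.q_r, 0.05)
        counts = 1e3 * q**-2.0 * np.exp(-0.5 * (chi_f / 0.12) ** 2)
        image = DetectorImage(counts=counts)
        chi_edges = np.linspace(0, TWO_PI, 73)
        coarse = radial_integrate(image, desk_qmap, chi_edges, (0.3, 2.0), n_radial_subbins=64)
        fine = radial_integrate(image, desk_qmap, chi_edges, (0.3, 2.0), n_radial_subbins=256)
        both = coarse.nonempty & fine.nonempty
        scale = np.nanmax(fine.H)
        assert np.max(np.abs(coarse.H[both] - fine.H[both])) / scale < 0.02

    def test_empty_annulus_bins_are_nan_not_zero(self, small_qmap):
        counts = np.ones(small_qmap.shape)
        mask = np.ones(small_qmap.shape, bool)
        mask[:, 33:] = False  # kill half the detector
        mask[:20, :] = False
        prof = radial_integrate(
            DetectorImage(counts=counts, mask=mask), small_qmap,
            np.linspace(0, TWO_PI, 73), (0.05, 0.3),
        )
        assert np.isnan(prof.H[~prof.nonempty]).all()
        assert (~prof.nonempty).any()

    def test_centrosymmetric_image_has_pi_periodic_H(self, desk_qmap):
        chi_f = np.minimum(np.mod(desk_qmap.chi, math.pi), math.pi - np.mod(desk_qmap.chi, math.pi))
        q = np.where(desk_qmap.q_r > 0.05, desk_qmap.q_r, 0.05)
        counts = 1e3 * q**-2.0 * np.exp(-0.5 * (chi_f / 0.2) ** 2)
        prof = radial_integrate(
            DetectorImage(counts=counts), desk_qmap, np.linspace(0, TWO_PI, 181), (0.3, 2.0)
        )
        n = len(prof.H) // 2
        a, b = prof.H[:n], prof.H[n:]
        both = np.isfinite(a) & np.isfinite(b)
        assert np.max(np.abs(a[both] - b[both])) / np.nanmax(prof.H) < 0.05

    def test_doubling_counts_doubles_H(self, small_qmap):
        img1 = constant_image(small_qmap, 2.0)
        img2 = constant_image(small_qmap, 4.0)
        edges = np.linspace(0, TWO_PI, 37)
        H1 = radial_integrate(img1, small_qmap, edges, (0.05, 0.3))
        H2 = radial_integrate(img2, small_qmap, edges, (0.05, 0.3))
        both = H1.nonempty & H2.nonempty
        np.testing.assert_allclose(H2.H[both], 2 * H1.H[both], rtol=1e-12)


class TestFoldHalfQuadrant:
    def test_constant_profile_folds_to_constant(self):
        chi = np.linspace(0, TWO_PI, 72, endpoint=False) + TWO_PI / 144
        prof = AzimuthalProfile(chi_centers=chi, H=np.full(72, 5.0), q_range=(0.1, 1.0),
                                n_pixels=np.ones(72))
        folded = fold_half_quadrant(prof)
        assert np.allclose(folded.H[folded.nonempty], 5.0)
        assert folded.chi_centers[-1] <= math.pi / 2 + 1e-12

    def test_symmetric_peaks_fold_to_origin(self):
        chi = np.linspace(0, TWO_PI, 360, endpoint=False) + TWO_PI / 720
        chi0 = 1.1
        H = np.exp(-0.5 * ((np.mod(chi - chi0 + math.pi, TWO_PI) - math.pi) / 0.1) ** 2)
        H += np.exp(-0.5 * ((np.mod(chi - chi0, TWO_PI) - math.pi) / 0.1) ** 2)
        prof = AzimuthalProfile(chi_centers=chi, H=H, q_range=None, n_pixels=np.ones(360))
        folded = fold_half_quadrant(prof)
        imax = np.nanargmax(folded.H)
        assert folded.chi_centers[imax] < math.radians(2.0)

    def test_folded_mean_recomputes_from_contributing_bins(self, rng):
        chi = np.linspace(0, TWO_PI, 144, endpoint=False) + TWO_PI / 288
        H = rng.random(144)
        prof = AzimuthalProfile(chi_centers=chi, H=H, q_range=None, n_pixels=np.ones(144))
        folded = fold_half_quadrant(prof)
        chi0 = chi[np.argmax(H)]
        delta = np.mod(chi - chi0, math.pi)
        fold_vals = np.minimum(delta, math.pi - delta)
        edges = np.linspace(0, math.pi / 2, len(folded.H) + 1)
        # recompute each folded bin directly
        for b, target in enumerate(folded.H):
            members = (np.clip(np.digitize(fold_vals, edges) - 1, 0, len(folded.H) - 1) == b)
            if members.any():
                assert target == pytest.approx(H[members].mean())


class TestAnisotropyScore:
    def test_constant_profile_scores_zero(self):
        chi = np.linspace(0, TWO_PI, 16, endpoint=False)
        prof = AzimuthalProfile(chi_centers=chi, H=np.full(16, 2.0), q_range=None)
        assert anisotropy_score(prof) == 0.0

    def test_alternating_profile_scores_two(self):
        chi = np.linspace(0, TWO_PI, 16, endpoint=False)
        H = np.tile([1.0, 0.0], 8)
        prof = AzimuthalProfile(chi_centers=chi, H=H, q_range=None)
        assert anisotropy_score(prof) == pytest.approx(2.0)

    def test_score_invariant_under_count_scaling(self, rng):
        chi = np.linspace(0, TWO_PI, 32, endpoint=False)
        H = rng.random(32) + 0.1
        s1 = anisotropy_score(AzimuthalProfile(chi_centers=chi, H=H, q_range=None))
        s2 = anisotropy_score(AzimuthalProfile(chi_centers=chi, H=7.0 * H, q_range=None))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_degenerate_profiles_rejected(self):
        chi = np.linspace(0, TWO_PI, 6, endpoint=False)
        with pytest.raises(ReductionError):
            anisotropy_score(AzimuthalProfile(chi_centers=chi, H=np.ones(6), q_range=None))
        chi = np.linspace(0, TWO_PI, 16, endpoint=False)
        with pytest.raises(ReductionError):
            anisotropy_score(AzimuthalProfile(chi_centers=chi, H=np.zeros(16), q_range=None))


class TestSubtractIsotropicFloor:
    def test_floor_is_percentile_and_values_shift(self):
        chi = np.linspace(0, math.pi / 2, 40, endpoint=False)
        H = np.concatenate([np.full(20, 1.0), np.full(20, 11.0)])
        out = subtract_isotropic_floor(AzimuthalProfile(chi_centers=chi, H=H, q_range=None))
        assert out.H[0] == pytest.approx(0.0)
        assert out.H[-1] == pytest.approx(10.0)
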
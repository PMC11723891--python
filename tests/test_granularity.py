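"""Scale bank construction and the pattern-energy spectrum."""

import math

import numpy as np
import pytest

from camophylo.colorimetry import ReflectanceImage
from camophylo.granularity import (
    _spectral_power,
    band_energy,
    build_scale_bank,
    check_pixel_scale,
    granularity_spectrum,
    pattern_channel,
)


class TestScaleBank:
    def test_default_bank_shape(self, default_bank):
        assert len(default_bank) == 15
        assert default_bank.scales_px[0] == 2.0
        assert default_bank.scales_px[-1] == pytest.approx(256.0)
        ratios = np.diff(np.log(default_bank.scales_px))
        np.testing.assert_allclose(np.exp(ratios), math.sqrt(2), atol=1e-9)

    def test_first_three_scales(self, default_bank):
        np.testing.assert_allclose(
            default_bank.scales_px[:3], [2.0, 2.828427, 4.0], atol=1e-6
        )

    def test_degenerate_single_scale(self):
        bank = build_scale_bank(8, 8)
        assert bank.scales_px == (8.0,)

    @pytest.mark.parametrize("kwargs", [dict(min_px=-1), dict(ratio=1.0),
                                        dict(min_px=10, max_px=5)])
    def test_invalid_arguments(self, kwargs):
        with pytest.raises(ValueError):
            build_scale_bank(**kwargs)


class TestPatternChannel:
    def _img(self, r, g, mask):
        pix = np.zeros((*mask.shape, 3))
        pix[..., 0], pix[..., 1] = r, g
        return ReflectanceImage(pix, 20.0, {"animal": mask})

    def test_red_green_average(self):
        img = self._img(0.4, 0.6, np.ones((4, 4), bool))
        chan, _ = pattern_channel(img, "animal")
        np.testing.assert_allclose(chan, 0.5)

    def test_bounding_box_crop_and_fill(self):
        mask = np.zeros((6, 6), bool)
        mask[2:4, 1:5] = True
        img = self._img(0.2, 0.2, mask)
        chan, msub = pattern_channel(img, "animal")
        assert chan.shape == (2, 4)
        assert msub.all()

    def test_single_pixel_mask(self):
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        img = self._img(0.4, 0.8, mask)
        chan, _ = pattern_channel(img, "animal")
        assert chan.shape == (1, 1)
        assert chan[0, 0] == pytest.approx(0.6)


class TestBandEnergy:
    def test_constant_raster_has_no_energy(self, default_bank):
        assert band_energy(np.full((32, 32), 0.7), default_bank.band(5)) == 0.0

    def test_pure_sinusoid_lands_in_its_band(self, default_bank):
        x = np.arange(256)
        ras = np.tile(np.sin(2 * np.pi * x / 16.0), (256, 1))
        energies = [band_energy(ras, default_bank.band(i)) for i in range(15)]
        k = int(np.argmax(energies))
        assert default_bank.scales_px[k] == pytest.approx(16.0)
        # a pure sinusoid has variance amp^2/2, all of it at one wavelength
        assert energies[k] == pytest.approx(0.5, rel=1e-9)
        rest = sum(energies) - energies[k]
        assert rest == pytest.approx(0.0, abs=1e-12)

    def test_seeded_noise_fills_every_band(self, default_bank, rng):
        ras = rng.standard_normal((256, 256))
        for i in range(15):
            assert band_energy(ras, default_bank.band(i)) > 0.0

    def test_band_outside_raster_rejected(self, default_bank):
        with pytest.raises(ValueError):
            band_energy(np.zeros((16, 16)), (100.0, 140.0))


class TestSpectrumInvariants:
    def test_parseval_with_padding(self, default_bank, rng):
        ras = rng.standard_normal((256, 300))  # padded to 256 x 512
        power, wl, var = _spectral_power(ras)
        total = sum(
            band_energy(ras, default_bank.band(i)) for i in range(15)
        )
        lo = default_bank.band_edges_px[0] * (1 - 1e-12)
        hi = default_bank.band_edges_px[-1]
        residual = power[(wl < lo) | (wl >= hi)].sum()
        assert abs(total + residual - var) / var < 1e-6

    def test_rotation_leaves_band_energies_unchanged(self, default_bank, rng):
        ras = rng.standard_normal((64, 64))
        for i in range(10):
            e = band_energy(ras, default_bank.band(i))
            e90 = band_energy(np.rot90(ras), default_bank.band(i))
            assert e90 == pytest.approx(e, rel=1e-9)

    def test_contrast_doubling_quadruples_energy(self, default_bank, rng):
        ras = rng.standard_normal((128, 128))
        doubled = ras.mean() + 2.0 * (ras - ras.mean())
        s1 = granularity_spectrum(ras, default_bank)
        s2 = granularity_spectrum(doubled, default_bank)
        np.testing.assert_allclose(
            np.asarray(s2.energy), 4.0 * np.asarray(s1.energy), rtol=1e-9
        )
        assert s2.dominant_size_px == s1.dominant_size_px
        assert s2.diversity == pytest.approx(s1.diversity)


class TestDescriptors:
    def test_sinusoid_descriptors(self, default_bank):
        x = np.arange(256)
        ras = np.tile(np.sin(2 * np.pi * x / 16.0), (256, 1))
        spec = granularity_spectrum(ras, default_bank)
        assert spec.dominant_size_px == pytest.approx(16.0)
        assert spec.overall_contrast == pytest.approx(0.5, rel=1e-9)
        assert spec.diversity == pytest.approx(1.0)
        assert not spec.undefined

    def test_constant_region_flagged_undefined(self, default_bank):
        spec = granularity_spectrum(np.full((64, 64), 0.3), default_bank)
        assert spec.undefined
        assert math.isnan(spec.dominant_size_px)
        assert math.isnan(spec.diversity)

    def test_diversity_of_rest_convention(self, default_bank, rng):
        ras = rng.standard_normal((64, 64))
        s_tot = granularity_spectrum(ras, default_bank, diversity="of_total")
        s_rest = granularity_spectrum(ras, default_bank, diversity="of_rest")
        d = s_tot.diversity
        assert s_rest.diversity == pytest.approx(d / (1.0 - d))

    def test_sd_energy_is_sqrt_of_power(self, default_bank, rng):
        ras = rng.standard_normal((64, 64))
        sp = granularity_spectrum(ras, default_bank, energy="power")
        sd = granularity_spectrum(ras, default_bank, energy="sd")
        np.testing.assert_allclose(
            np.asarray(sd.energy), np.sqrt(np.asarray(sp.energy)), rtol=1e-9
        )


@pytest.mark.parametrize(
    "px_per_mm,expected", [(15.0, True), (14.9, False), (300.0, True)]
)
def test_pixel_scale_threshold(px_per_mm, expected):
    assert check_pixel_scale(px_per_mm) is expected


def test_pixel_scale_rejects_nonpositive():
    with pytest.raises(ValueError):
        check_pixel_scale(0.0)
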
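"""Phantom generator: geometry, ground truth, simulation, CT mixture."""

import numpy as np
import pytest

from lungadc import (
    Lesion,
    PhantomSpec,
    generate_ct_phantom,
    generate_lung_phantom,
    relative_area,
    simulate_dw_pair,
)
from lungadc.errors import PhantomError


class TestLungGeometry:
    def test_two_lungs_at_plausible_volume_fraction(self, flat_phantom):
        from scipy import ndimage
        mask, _ = flat_phantom
        frac = mask.data.mean()
        assert 0.2 <= frac <= 0.6
        _, n = ndimage.label(mask.data)
        assert n == 2
        assert (mask.per_slice_counts > 0).all()

    def test_grid_too_small_is_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(shape=(2, 64, 64))
        with pytest.raises(PhantomError, match="two lung regions"):
            generate_lung_phantom(PhantomSpec(shape=(3, 3, 3)))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(baseline_adc=0.0)
        with pytest.raises(PhantomError):
            PhantomSpec(noise_sigma=-1.0)
        with pytest.raises(PhantomError, match="ceiling"):
            PhantomSpec(gas="129Xe", baseline_adc=0.05,
                        lesions=(Lesion((3, 32, 16), 3, 0.5),))


class TestGroundTruthField:
    def test_uniform_spec_gives_constant_field(self, flat_spec):
        mask, truth = generate_lung_phantom(flat_spec)
        vals = truth.adc[mask.data]
        assert np.allclose(vals, 0.23)
        assert truth.whole_lung_mean == pytest.approx(0.23)
        assert truth.ap_slope == pytest.approx(0.0, abs=1e-15)

    def test_ap_slope_shifts_per_slice_means_by_slope_times_pitch(self):
        # slope -0.00667 cm^2/s/cm at 3.0 cm pitch: each slice mean drops
        # by 0.02001 cm^2/s relative to its anterior neighbour
        spec = PhantomSpec(shape=(7, 64, 64), spacing=(30.0, 6.25, 6.25),
                           baseline_adc=0.30, ap_slope=-0.00667)
        mask, truth = generate_lung_phantom(spec)
        means = [truth.adc[i][mask.data[i]].mean() for i in range(7)]
        diffs = np.diff(means)
        assert np.allclose(diffs, -0.00667 * 3.0, atol=1e-12)
        assert truth.ap_slope == pytest.approx(-0.00667, rel=1e-9)

    def test_region_means_match_arithmetic_means_of_field(self):
        spec = PhantomSpec(shape=(7, 64, 64), spacing=(30.0, 6.25, 6.25),
                           baseline_adc=0.23, si_offset=0.1)
        mask, truth = generate_lung_phantom(spec)
        assert truth.whole_lung_mean == pytest.approx(
            truth.adc[mask.data].mean(), rel=1e-14)
        sup, _, inf = truth.region_means
        assert sup - inf == pytest.approx(0.1, abs=1e-12)

    def test_lesion_bounds_whole_lung_mean(self):
        spec = PhantomSpec(shape=(7, 64, 64), spacing=(30.0, 6.25, 6.25),
                           baseline_adc=0.2,
                           lesions=(Lesion((3, 32, 17), 6, 0.6),))
        mask, truth = generate_lung_phantom(spec)
        assert 0.2 < truth.whole_lung_mean < 0.6
        assert np.nanmax(truth.adc) == pytest.approx(0.6)

    def test_field_clipped_to_free_diffusion_ceiling(self):
        spec = PhantomSpec(shape=(7, 64, 64), spacing=(30.0, 6.25, 6.25),
                           baseline_adc=0.8, ap_slope=0.01)  # exceeds 0.826 posteriorly
        mask, truth = generate_lung_phantom(spec)
        assert np.nanmax(truth.adc) <= 0.826 + 1e-15


class TestDWSimulation:
    def test_noiseless_attenuation_matches_closed_form(self):
        # S/S0 = exp(-b * ADC) = exp(-12 * 0.080) = exp(-0.96)
        spec = PhantomSpec(shape=(7, 64, 64), spacing=(30.0, 6.25, 6.25),
                           baseline_adc=0.080, gas="129Xe")
        mask, truth = generate_lung_phantom(spec)
        acq = simulate_dw_pair(truth, b=12.0, s0_level=100.0, gas="129Xe")
        ratio = acq.dw.data[mask.data] / acq.ndw.data[mask.data]
        assert np.allclose(ratio, np.exp(-0.96))
        assert np.exp(-0.96) == pytest.approx(0.3829, abs=5e-5)

    def test_b_zero_reproduces_ndw_exactly(self, flat_phantom):
        _, truth = flat_phantom
        acq = simulate_dw_pair(truth, b=0.0, s0_level=50.0)
        np.testing.assert_array_equal(acq.dw.data, acq.ndw.data)

    def test_same_seed_gives_bit_identical_volumes(self, flat_phantom):
        _, truth = flat_phantom
        a = simulate_dw_pair(truth, 1.6, 100.0, noise_sigma=3.0, seed=11)
        b = simulate_dw_pair(truth, 1.6, 100.0, noise_sigma=3.0, seed=11)
        np.testing.assert_array_equal(a.ndw.data, b.ndw.data)
        np.testing.assert_array_equal(a.dw.data, b.dw.data)
        c = simulate_dw_pair(truth, 1.6, 100.0, noise_sigma=3.0, seed=12)
        assert not np.array_equal(a.dw.data, c.dw.data)

    def test_rician_noise_is_nonnegative_and_positive_biased_in_background(
            self, flat_phantom):
        _, truth = flat_phantom
        acq = simulate_dw_pair(truth, 1.6, 100.0, noise_sigma=3.0, seed=0)
        assert (acq.ndw.data >= 0).all()
        bg = acq.ndw.data[~truth.mask.data]
        # background magnitude noise has Rayleigh mean sigma*sqrt(pi/2)
        assert bg.mean() == pytest.approx(3.0 * np.sqrt(np.pi / 2), rel=0.05)

    def test_negative_inputs_rejected(self, flat_phantom):
        _, truth = flat_phantom
        with pytest.raises(PhantomError):
            simulate_dw_pair(truth, 1.6, s0_level=-1.0)
        with pytest.raises(PhantomError):
            simulate_dw_pair(truth, 1.6, 100.0, noise_sigma=-0.1)


class TestCTPhantom:
    def test_degenerate_fractions_are_exact(self):
        hu, mask = generate_ct_phantom(1.0, 1000, seed=0)
        assert relative_area(hu, mask, -950) == 100.0
        hu, mask = generate_ct_phantom(0.0, 1000, seed=0)
        assert relative_area(hu, mask, -950) == 0.0

    def test_realized_fraction_within_binomial_error(self):
        n = 100_000
        hu, mask = generate_ct_phantom(0.25, n, seed=3)
        ra = relative_area(hu, mask, -950)
        sd = 100 * np.sqrt(0.25 * 0.75 / n)
        assert abs(ra - 25.0) <= 3 * sd

    def test_small_volumes_rejected(self):
        with pytest.raises(PhantomError, match="meaningless"):
            generate_ct_phantom(0.5, 99)
        with pytest.raises(PhantomError):
            generate_ct_phantom(1.5, 1000)
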
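"""Window partitioning, Gaussian peak fitting, and shift computation."""

import numpy as np
import pytest

from fbgpalp import (
    BraggChannel,
    ChannelConfigError,
    ChannelWindow,
    NoiseModel,
    PeakFit,
    ShiftError,
    Spectrum,
    compute_shifts,
    extract_peaks,
    fit_gaussian_peak,
    partition_windows,
    synth_spectrum,
)
from fbgpalp.spectra import PM_PER_NM, fwhm_to_sigma


def log_parabola_oracle(center_nm, fwhm_pm, lo_nm, hi_nm, step_nm):
    """Brute-force center locator, independent of the fitting code path.

    Renders the same Gaussian on a 100x oversampled grid, takes the log of
    the (baseline-free) intensity, and interpolates a parabola through the
    three samples around the argmax; the parabola vertex is the center.
    """
    sigma_nm = fwhm_to_sigma(fwhm_pm) / PM_PER_NM
    x = np.arange(lo_nm, hi_nm, step_nm / 100.0)
    with np.errstate(divide="ignore"):
        y = np.log(np.exp(-0.5 * ((x - center_nm) / sigma_nm) ** 2))
    i = int(np.argmax(y))
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    delta = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
    return x[i] + delta * (step_nm / 100.0)


class TestPartitionWindows:
    def test_midpoint_boundaries_on_default_layout(self):
        from fbgpalp import default_channels, default_grid
        chans = default_channels()
        spec = synth_spectrum(chans, [c.nominal_center_nm for c in chans],
                              default_grid())
        wins = partition_windows(spec, chans)
        assert [w.channel_id for w in wins] == [1, 2, 3, 4]
        assert [w.lo_nm for w in wins] == [1510.0, 1530.0, 1550.0, 1570.0]
        assert [w.hi_nm for w in wins] == [1530.0, 1550.0, 1570.0, 1590.0]

    def test_translation_equivariance(self, small_grid, small_channels, quiet):
        centers = [c.nominal_center_nm for c in small_channels]
        spec = synth_spectrum(small_channels, centers, small_grid, noise=quiet)
        base = partition_windows(spec, small_channels)
        shifted = [
            BraggChannel(channel_id=c.channel_id,
                         nominal_center_nm=c.nominal_center_nm + 1.0,
                         azimuth_deg=c.azimuth_deg)
            for c in small_channels
        ]
        moved = partition_windows(spec, shifted)
        for a, b in zip(base[:-1], moved[:-1]):
            assert b.hi_nm == pytest.approx(a.hi_nm + 1.0)

    def test_duplicate_centers_is_a_configuration_error(self, small_grid, small_channels, quiet):
        centers = [c.nominal_center_nm for c in small_channels]
        spec = synth_spectrum(small_channels, centers, small_grid, noise=quiet)
        bad = list(small_channels)
        bad[1] = BraggChannel(channel_id=2, nominal_center_nm=1530.0,
                              azimuth_deg=90.0)
        with pytest.raises(ChannelConfigError):
            partition_windows(spec, bad)

    def test_wrong_channel_count_rejected(self, small_grid, small_channels, quiet):
        centers = [c.nominal_center_nm for c in small_channels]
        spec = synth_spectrum(small_channels, centers, small_grid, noise=quiet)
        with pytest.raises(ChannelConfigError, match="expected 4"):
            partition_windows(spec, small_channels[:3])


class TestGaussianFit:
    def test_off_grid_center_recovered_below_hundredth_pm(self, small_grid, quiet):
        # noiseless, exact model: the 2 pm sampling should not limit accuracy
        true = 1536.0005
        ch = [BraggChannel(channel_id=1, nominal_center_nm=1536.0, azimuth_deg=0.0)]
        spec = synth_spectrum(ch, [true], small_grid, noise=quiet)
        fit = fit_gaussian_peak(spec, ChannelWindow(1, 1534.0, 1538.0))
        assert fit.converged
        assert abs(fit.center_nm - true) * PM_PER_NM < 0.01

    def test_matches_log_parabola_oracle(self, small_grid, quiet):
        rng = np.random.default_rng(11)
        ch = [BraggChannel(channel_id=1, nominal_center_nm=1536.0, azimuth_deg=0.0)]
        for _ in range(10):
            true = 1536.0 + rng.uniform(-1, 1) * 0.01
            spec = synth_spectrum(ch, [true], small_grid, noise=quiet)
            fit = fit_gaussian_peak(spec, ChannelWindow(1, 1534.0, 1538.0))
            oracle = log_parabola_oracle(true, 60.0, 1534.0, 1538.0,
                                         small_grid.step_nm)
            assert abs(fit.center_nm - oracle) * PM_PER_NM < 0.01

    def test_all_zero_window_flagged_not_fitted(self, small_grid):
        spec = Spectrum(grid=small_grid, intensity=np.zeros(small_grid.n_points))
        fit = fit_gaussian_peak(spec, ChannelWindow(1, 1534.0, 1538.0))
        assert not fit.converged
        assert "flat" in fit.message

    def test_scale_invariance_of_center(self, small_grid, quiet):
        true = 1536.0007
        ch = [BraggChannel(channel_id=1, nominal_center_nm=1536.0, azimuth_deg=0.0)]
        spec = synth_spectrum(ch, [true], small_grid, noise=quiet)
        win = ChannelWindow(1, 1534.0, 1538.0)
        f1 = fit_gaussian_peak(spec, win)
        scaled = Spectrum(grid=small_grid, intensity=spec.intensity * 37.5)
        f2 = fit_gaussian_peak(scaled, win)
        assert abs(f1.center_nm - f2.center_nm) * PM_PER_NM < 0.001

    def test_tiny_window_refused(self, small_grid, small_channels, quiet):
        centers = [c.nominal_center_nm for c in small_channels]
        spec = synth_spectrum(small_channels, centers, small_grid, noise=quiet)
        fit = fit_gaussian_peak(spec, ChannelWindow(1, 1530.000, 1530.010))
        assert not fit.converged
        assert "8 samples" in fit.message


class TestExtractPeaks:
    def test_four_peak_round_trip_with_simulator(self, small_grid, small_channels, quiet):
        rng = np.random.default_rng(5)
        true = [c.nominal_center_nm + rng.uniform(-0.05, 0.05)
                for c in small_channels]
        spec = synth_spectrum(small_channels, true, small_grid, noise=quiet)
        fits = extract_peaks(spec, small_channels)
        assert all(f.converged for f in fits)
        for f, t in zip(fits, true):
            assert abs(f.center_nm - t) * PM_PER_NM < 0.05

    def test_missing_peak_flags_only_that_channel(self, small_grid, small_channels, quiet):
        # remove channel 3's peak by synthesizing without it, keeping windows
        present = [c for c in small_channels if c.channel_id != 3]
        spec = synth_spectrum(present, [c.nominal_center_nm for c in present],
                              small_grid, noise=quiet)
        fits = extract_peaks(spec, small_channels)
        status = {f.channel_id: f.converged for f in fits}
        assert status[1] and status[2] and status[4]
        assert not status[3]

    def test_center_errors_not_biased_by_amplitude_rank(self, small_grid, small_channels, quiet):
        # unequal amplitudes from the source envelope must not degrade the
        # noiseless localization of the dimmer channels
        from fbgpalp import linear_ramp_envelope
        rng = np.random.default_rng(9)
        true = [c.nominal_center_nm + rng.uniform(-0.02, 0.02)
                for c in small_channels]
        spec = synth_spectrum(small_channels, true, small_grid,
                              source_envelope=linear_ramp_envelope(small_grid),
                              noise=quiet)
        fits = extract_peaks(spec, small_channels)
        errs = [abs(f.center_nm - t) * PM_PER_NM for f, t in zip(fits, true)]
        assert max(errs) < 0.01


class TestComputeShifts:
    @staticmethod
    def _fits(centers):
        return [PeakFit(channel_id=i + 1, center_nm=c, sigma_nm=0.025,
                        amplitude=1.0, baseline=0.0, converged=True, rss=0.0)
                for i, c in enumerate(centers)]

    def test_identity_and_arithmetic(self):
        ref = self._fits([1530.0, 1534.0, 1538.0, 1542.0])
        assert compute_shifts(ref, ref).as_array() == pytest.approx([0, 0, 0, 0])
        pressed = self._fits([1530.0, 1534.050, 1538.0, 1542.0])
        shifts = compute_shifts(ref, pressed)
        assert shifts.shifts_pm[1] == pytest.approx(50.0)

    def test_blue_shift_is_negative(self):
        ref = self._fits([1530.0, 1534.0, 1538.0, 1542.0])
        pressed = self._fits([1529.980, 1534.0, 1538.0, 1542.0])
        assert compute_shifts(ref, pressed).shifts_pm[0] == pytest.approx(-20.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a = self._fits(1530.0 + rng.uniform(-0.1, 0.1, 4) + np.arange(4) * 4)
        b = self._fits(1530.0 + rng.uniform(-0.1, 0.1, 4) + np.arange(4) * 4)
        ab = compute_shifts(a, b).as_array()
        ba = compute_shifts(b, a).as_array()
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_unconverged_channel_refuses_whole_point(self):
        ref = self._fits([1530.0, 1534.0, 1538.0, 1542.0])
        pressed = self._fits([1530.0, 1534.0, 1538.0, 1542.0])
        pressed[2].converged = False
        with pytest.raises(ShiftError, match=r"channel\(s\) \[3\]"):
            compute_shifts(ref, pressed)

    def test_mismatched_channels_refused(self):
        ref = self._fits([1530.0, 1534.0, 1538.0, 1542.0])
        pressed = self._fits([1530.0, 1534.0, 1538.0, 1542.0])
        pressed[0].channel_id = 9
        with pytest.raises(ShiftError, match="do not match"):
            compute_shifts(ref, pressed)
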
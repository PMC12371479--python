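import numpy as np
import pytest

from mesopipe.preprocess import (DEFAULT_SPECTRA, SpectraConfig, beer_lambert,
                                 global_signal_regression, normalize_dff,
                                 ratiometric_correction, regress_hemodynamics,
                                 temporal_filter)
from .conftest import make_stack


class TestRegressHemodynamics:
    def test_exact_linear_dependence_gives_flat_residual(self, rng):
        green = make_stack(rng.normal(1.0, 0.05, (40, 3, 3)), channel="green")
        fluo = make_stack(0.5 * green.data + 2.0)
        res = regress_hemodynamics(fluo, [green])
        np.testing.assert_allclose(res.coefficients[:, :, 0], 0.5, atol=1e-9)
        np.testing.assert_allclose(res.coefficients[:, :, 1], 2.0, atol=1e-9)
        np.testing.assert_allclose(res.r_squared, 1.0, atol=1e-9)
        # corrected trace is flat at the pixel mean
        np.testing.assert_allclose(
            res.corrected.data,
            np.broadcast_to(fluo.data.mean(axis=0), fluo.shape), atol=1e-9)

    def test_two_channel_recovery_matches_ols_oracle(self, rng):
        T, H, W = 60, 2, 2
        green = make_stack(rng.normal(1.0, 0.05, (T, H, W)), channel="green")
        red = make_stack(rng.normal(1.0, 0.03, (T, H, W)), channel="red")
        s = np.sin(np.linspace(0, 6 * np.pi, T))[:, None, None] * 0.02
        fluo = make_stack(0.6 * green.data + 0.3 * red.data + s)
        res = regress_hemodynamics(fluo, [green, red])
        # independent closed-form OLS per pixel via lstsq
        for r in range(H):
            for c in range(W):
                X = np.column_stack([np.ones(T), green.data[:, r, c],
                                     red.data[:, r, c]])
                beta = np.linalg.lstsq(X, fluo.data[:, r, c], rcond=None)[0]
                np.testing.assert_allclose(
                    res.coefficients[r, c], [beta[1], beta[2], beta[0]], atol=1e-9)

    def test_residual_orthogonal_to_regressors(self, rng):
        green = make_stack(rng.normal(1.0, 0.05, (50, 4, 4)), channel="green")
        fluo = make_stack(rng.normal(2.0, 0.1, (50, 4, 4)))
        res = regress_hemodynamics(fluo, [green])
        resid = res.corrected.data - res.corrected.data.mean(axis=0)
        reg = green.data - green.data.mean(axis=0)
        dots = np.abs((resid * reg).sum(axis=0))
        norms = np.linalg.norm(resid, axis=0) * np.linalg.norm(reg, axis=0)
        assert (dots <= 1e-6 * norms).all()

    def test_empty_reflectance_rejected(self, random_stack):
        with pytest.raises(ValueError, match="at least one"):
            regress_hemodynamics(random_stack, [])

    def test_constant_reflectance_degrades_to_intercept_only(self, random_stack):
        const = make_stack(np.ones_like(random_stack.data), channel="green")
        with pytest.warns(RuntimeWarning, match="constant reflectance"):
            res = regress_hemodynamics(random_stack, [const])
        np.testing.assert_allclose(res.corrected.data, random_stack.data, atol=1e-9)

    def test_missing_frames_excluded_from_fit(self, rng):
        green = make_stack(rng.normal(1.0, 0.05, (60, 2, 2)), channel="green")
        fluo_data = 0.4 * green.data + 1.0
        fluo_data[5, 0, 0] = np.nan          # one missing frame at one pixel
        res = regress_hemodynamics(make_stack(fluo_data), [green])
        assert abs(res.coefficients[0, 0, 0] - 0.4) < 1e-9

    def test_shape_mismatch_rejected(self, random_stack):
        other = make_stack(np.ones((10, 8, 8)), channel="green")
        with pytest.raises(ValueError, match="shape mismatch"):
            regress_hemodynamics(random_stack, [other])


class TestRatiometric:
    def test_identical_stacks_give_unity(self, random_stack):
        out = ratiometric_correction(random_stack, random_stack)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_constant_reflectance_is_plain_normalisation(self, random_stack):
        const = make_stack(np.full_like(random_stack.data, 3.0), channel="green")
        out = ratiometric_correction(random_stack, const)
        np.testing.assert_allclose(
            out.data, random_stack.data / random_stack.data.mean(axis=0), atol=1e-12)

    def test_shared_multiplicative_artifact_cancels(self, rng):
        a = 0.1 * np.sin(np.linspace(0, 4 * np.pi, 80))[:, None, None]
        base_f = rng.uniform(50, 150, (1, 4, 4))
        base_r = rng.uniform(0.5, 1.5, (1, 4, 4))
        fluo = make_stack(base_f * (1 + a))
        refl = make_stack(base_r * (1 + a), channel="green")
        out = ratiometric_correction(fluo, refl)
        np.testing.assert_allclose(out.data, 1.0, atol=1e-12)

    def test_nonpositive_values_rejected(self, random_stack):
        bad = make_stack(random_stack.data - 10.0, channel="green")
        with pytest.raises(ValueError, match="positive"):
            ratiometric_correction(random_stack, bad)


class TestBeerLambert:
    def _stacks(self, dhbo, dhbr, wavelengths=(525.0, 590.0)):
        """Forward-generate reflectance from known concentration changes."""
        T, H, W = dhbo.shape
        stacks = []
        for wl in wavelengths:
            E = DEFAULT_SPECTRA.design([wl])[0]
            dod = E[0] * dhbo + E[1] * dhbr
            R = 1.0 * np.exp(-dod)
            stacks.append(make_stack(R, channel=f"r{int(wl)}", wavelength_nm=wl))
        return stacks

    def test_constant_reflectance_gives_zero_change(self):
        zero = np.zeros((20, 3, 3))
        out = beer_lambert(self._stacks(zero, zero))
        np.testing.assert_allclose(out.delta_hbo.data, 0.0, atol=1e-12)
        np.testing.assert_allclose(out.delta_hbr.data, 0.0, atol=1e-12)

    def test_two_wavelength_inversion_exact(self):
        T, H, W = 30, 3, 3
        dhbo = np.full((T, H, W), 5.0)
        dhbr = np.full((T, H, W), -2.0)
        dhbo[:10] = 0.0
        dhbr[:10] = 0.0
        out = beer_lambert(self._stacks(dhbo, dhbr), baseline_frames=(0, 10))
        np.testing.assert_allclose(out.delta_hbo.data, dhbo, atol=1e-9)
        np.testing.assert_allclose(out.delta_hbr.data, dhbr, atol=1e-9)

    def test_three_wavelengths_match_pseudoinverse_oracle(self, rng):
        wavelengths = (525.0, 590.0, 625.0)
        T, H, W = 10, 2, 2
        stacks = self._stacks(rng.normal(0, 2, (T, H, W)),
                              rng.normal(0, 1, (T, H, W)), wavelengths)
        # perturb one channel so the system is inconsistent
        stacks[2] = make_stack(stacks[2].data * (1 + 0.01), channel="r625",
                               wavelength_nm=625.0)
        out = beer_lambert(stacks, baseline_frames=None)
        E = DEFAULT_SPECTRA.design(list(wavelengths))
        dod = np.stack([-np.log(s.data / s.data.mean(axis=0)) for s in stacks])
        oracle = np.linalg.pinv(E) @ dod.reshape(3, -1)
        np.testing.assert_allclose(out.delta_hbo.data.ravel(), oracle[0], atol=1e-9)
        np.testing.assert_allclose(out.delta_hbr.data.ravel(), oracle[1], atol=1e-9)

    def test_fewer_than_two_wavelengths_rejected(self):
        stacks = self._stacks(np.zeros((5, 2, 2)), np.zeros((5, 2, 2)))
        with pytest.raises(ValueError, match="two wavelengths"):
            beer_lambert(stacks[:1])

    def test_proportional_extinction_columns_rejected(self):
        cfg = SpectraConfig(wavelengths_nm=(500.0, 600.0),
                            extinction_hbo=(1.0, 2.0),
                            extinction_hbr=(2.0, 4.0),
                            pathlength_cm=(1.0, 1.0))
        with pytest.raises(ValueError, match="singular"):
            cfg.design([500.0, 600.0])


class TestGlobalSignalRegression:
    def test_shared_trace_removed_entirely(self, rng):
        trace = rng.normal(0, 1, 40)
        offsets = rng.uniform(1, 2, (4, 4))
        stack = make_stack(trace[:, None, None] + offsets[None])
        out = global_signal_regression(stack)
        # flat at each pixel's temporal mean
        expected = np.broadcast_to(stack.data.mean(axis=0), (40, 4, 4))
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_common_sinusoid_uncorrelated_after(self, rng):
        T = 400
        sinus = np.sin(np.linspace(0, 20 * np.pi, T))
        noise = rng.normal(0, 1, (T, 12, 12))
        stack = make_stack(noise + 2.0 * sinus[:, None, None])
        out = global_signal_regression(stack)
        for r in range(12):
            for c in range(12):
                assert abs(np.corrcoef(out.data[:, r, c], sinus)[0, 1]) <= 0.01

    def test_single_pixel_stack_flattens(self, rng):
        stack = make_stack(rng.normal(5, 1, (30, 1, 1)))
        out = global_signal_regression(stack)
        np.testing.assert_allclose(out.data, stack.data.mean(), atol=1e-9)

    def test_empty_mask_rejected(self, random_stack):
        with pytest.raises(ValueError, match="empty"):
            global_signal_regression(random_stack, mask=np.zeros((8, 8), bool))

    def test_subtract_mode(self, rng):
        trace = rng.normal(0, 1, 40)
        stack = make_stack(trace[:, None, None] + np.zeros((40, 2, 2)))
        out = global_signal_regression(stack, mode="subtract")
        np.testing.assert_allclose(out.data, trace.mean(), atol=1e-9)


class TestTemporalFilter:
    def _amplitude(self, trace, freq, rate):
        """FFT amplitude oracle at the requested frequency."""
        spectrum = np.abs(np.fft.rfft(trace - trace.mean())) * 2 / len(trace)
        freqs = np.fft.rfftfreq(len(trace), d=1 / rate)
        return spectrum[np.argmin(np.abs(freqs - freq))]

    def test_band_center_preserved(self):
        T, rate, f = 1000, 10.0, 0.5
        t = np.arange(T) / rate
        stack = make_stack(np.sin(2 * np.pi * f * t)[:, None, None]
                           * np.ones((T, 2, 2)))
        out = temporal_filter(stack, low_hz=0.1, high_hz=1.0)
        a_in = self._amplitude(stack.data[:, 0, 0], f, rate)
        a_out = self._amplitude(out.data[:, 0, 0], f, rate)
        assert abs(a_out - a_in) / a_in < 0.05

    def test_out_of_band_attenuated(self):
        T, rate, f = 1000, 10.0, 4.0
        t = np.arange(T) / rate
        stack = make_stack(np.sin(2 * np.pi * f * t)[:, None, None]
                           * np.ones((T, 1, 1)))
        out = temporal_filter(stack, low_hz=0.1, high_hz=1.0)
        a_in = self._amplitude(stack.data[:, 0, 0], f, rate)
        a_out = self._amplitude(out.data[:, 0, 0], f, rate)
        assert a_out <= 0.1 * a_in

    def test_lowpass_preserves_dc(self):
        stack = make_stack(np.full((100, 2, 2), 7.0))
        out = temporal_filter(stack, high_hz=1.0)
        np.testing.assert_allclose(out.data, 7.0, atol=1e-9)

    def test_highpass_restores_pixel_mean(self, rng):
        stack = make_stack(rng.normal(3.0, 0.2, (200, 2, 2)))
        out = temporal_filter(stack, low_hz=0.5)
        np.testing.assert_allclose(out.data.mean(axis=0),
                                   stack.data.mean(axis=0), atol=1e-9)

    @pytest.mark.parametrize("kwargs", [
        {"low_hz": -0.1}, {"high_hz": 6.0}, {"low_hz": 2.0, "high_hz": 1.0},
        {},
    ])
    def test_invalid_cutoffs_rejected(self, random_stack, kwargs):
        with pytest.raises(ValueError):
            temporal_filter(random_stack, **kwargs)


class TestNormalizeDff:
    def test_constant_stack_is_zero(self):
        out = normalize_dff(make_stack(np.full((10, 2, 2), 5.0)))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_five_percent_step(self):
        data = np.full((10, 1, 1), 100.0)
        data[4] = 105.0
        out = normalize_dff(make_stack(data), baseline="frame_range",
                            frame_range=(0, 4))
        assert abs(out.data[4, 0, 0] - 0.05) < 1e-12

    def test_frame_range_baseline_zeroes_pre_step(self):
        data = np.full((20, 3, 3), 10.0)
        data[10:] = 12.0
        out = normalize_dff(make_stack(data), baseline="frame_range",
                            frame_range=(0, 10))
        np.testing.assert_allclose(out.data[:10], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data[10:], 0.2, atol=1e-12)

    @pytest.mark.parametrize("c", [0.5, 2.0, 117.0])
    def test_scale_invariance(self, random_stack, c):
        a = normalize_dff(random_stack)
        b = normalize_dff(random_stack.with_data(c * random_stack.data))
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_nonpositive_baseline_rejected_with_count(self):
        data = np.ones((5, 2, 2))
        data[:, 0, :] = -1.0
        with pytest.raises(ValueError, match="2 pixel"):
            normalize_dff(make_stack(data))


def test_stages_append_audit_trail(random_stack):
    out = normalize_dff(temporal_filter(random_stack, high_hz=2.0))
    stages = [h["stage"] for h in out.history]
    assert stages == ["temporal_filter", "normalize_dff"]
    assert out.history[0]["params"]["high_hz"] == 2.0
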
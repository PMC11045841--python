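"""Population decay fits, sinusoid fits and spectral frequencies."""

import numpy as np
import pytest

from rotordyn.errors import FitFailureError
from rotordyn.kinetics_fit import (
    PopulationCurve,
    decompose_alpha,
    dominant_frequency,
    fit_lifetime,
    fit_sinusoid,
    lifetime_model,
    s1_population,
)


class TestS1Population:
    def _ensemble_with_hops(self, hop_frames, n_frames=40):
        from rotordyn.synthetic_data import embed_xyz
        from rotordyn.trajectory_io import Ensemble, Trajectory

        t = np.arange(float(n_frames))
        trajs = []
        for i, h in enumerate(hop_frames):
            states = np.ones(n_frames, dtype=int)
            if h is not None:
                states[h:] = 0
            trajs.append(
                Trajectory(
                    id=f"t{i}", atom_labels=["C"] * 4 + ["H"] * 2,
                    times=t.copy(), coords=embed_xyz(np.zeros(n_frames), np.zeros(n_frames)),
                    states=states,
                )
            )
        return Ensemble(trajectories=trajs)

    def test_two_hops_step_curve(self):
        curve = s1_population(self._ensemble_with_hops([10, 20]))
        assert curve.s1_fraction[9] == 1.0
        assert curve.s1_fraction[10] == 0.5
        assert curve.s1_fraction[20] == 0.0

    def test_no_hops_constant_one(self):
        curve = s1_population(self._ensemble_with_hops([None, None]))
        np.testing.assert_array_equal(curve.s1_fraction, 1.0)

    def test_matches_empirical_cdf_of_hops(self, rng):
        hops = rng.integers(5, 195, size=200)
        curve = s1_population(self._ensemble_with_hops(hops, n_frames=200))
        # survival = 1 - empirical CDF of hop frames (hop frame = first S0)
        for k in (0, 50, 120, 199):
            expected = 1.0 - np.mean(hops <= k)
            assert curve.s1_fraction[k] == pytest.approx(expected, abs=1e-12)


class TestLifetimeFit:
    def test_noiseless_self_recovery_within_one_percent(self):
        t = np.arange(0.0, 400.0)
        true = dict(a1=0.3, t1=50.0, t2=80.0, y0=0.02)
        curve = PopulationCurve(t, lifetime_model(t, **true))
        fit = fit_lifetime(curve)
        for name, val in true.items():
            assert getattr(fit, name) == pytest.approx(val, rel=0.01), name
        assert fit.lifetime == pytest.approx(true["t1"] + true["t2"], rel=0.01)

    def test_step_curve_recovers_onset(self):
        t = np.arange(0.0, 300.0)
        y = np.where(t < 100, 1.0, 0.0)
        fit = fit_lifetime(PopulationCurve(t, y))
        assert fit.t1 == pytest.approx(100.0, abs=5.0)
        assert fit.t2 < 10.0

    def test_constant_curve_fails(self):
        t = np.arange(0.0, 100.0)
        with pytest.raises(FitFailureError):
            fit_lifetime(PopulationCurve(t, np.ones_like(t)))

    def test_preset_population_fit_is_close(self, small_rh_ensemble):
        ensemble, _ = small_rh_ensemble
        curve = s1_population(ensemble)
        fit = fit_lifetime(curve)
        assert fit.rms_residual < 0.05
        assert 0 < fit.t1 < 150 and 0 < fit.t2 < 200


class TestSinusoidFit:
    def test_exact_sinusoid_period_recovery(self):
        t = np.arange(0.0, 200.0)
        y = 2.5 * np.sin(2 * np.pi * t / 40.0 + 0.7) + 1.0
        fit = fit_sinusoid(t, y)
        assert fit.period == pytest.approx(40.0, abs=0.1)
        assert fit.amplitude == pytest.approx(2.5, rel=1e-3)
        assert fit.offset == pytest.approx(1.0, abs=1e-3)

    def test_noisy_long_period_within_two_percent(self):
        t = np.arange(0.0, 600.0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = 3.0 * np.sin(2 * np.pi * t / 250.0 + 0.3)
            y = y + rng.normal(0, 0.05 * 3.0, size=len(t))  # 5% white noise
            fit = fit_sinusoid(t, y)
            assert fit.period == pytest.approx(250.0, rel=0.02), f"seed {seed}"

    def test_flat_series_flagged(self):
        fit = fit_sinusoid(np.arange(50.0), np.full(50, 3.3))
        assert fit.flat and fit.amplitude == 0.0


class TestDecomposeAlpha:
    def test_composite_recovery(self):
        t = np.arange(0.0, 200.0)
        y = -0.5 * t + 3.0 * np.sin(2 * np.pi * t / 40.0)
        dec = decompose_alpha(t, y, promoter_period_hint=40.0)
        assert dec.slope == pytest.approx(-0.5, rel=0.02)
        assert dec.oscillation.period == pytest.approx(40.0, rel=0.02)
        assert dec.oscillation.amplitude == pytest.approx(3.0, rel=0.02)
        np.testing.assert_allclose(dec.reconstruct(t), y, atol=0.2)

    def test_pure_linear_has_negligible_oscillation(self):
        t = np.arange(0.0, 100.0)
        dec = decompose_alpha(t, -1.2 * t + 5.0, promoter_period_hint=40.0)
        assert dec.oscillation.amplitude < 1e-6 or dec.oscillation.flat

    def test_pure_sinusoid_has_negligible_slope(self):
        t = np.arange(0.0, 400.0)
        dec = decompose_alpha(t, 4.0 * np.sin(2 * np.pi * t / 50.0), promoter_period_hint=50.0)
        assert abs(dec.slope) < 0.01


class TestDominantFrequency:
    def test_unit_conversion_identity(self):
        # T = 33.356 fs corresponds to 1 THz, i.e. ~1000 1/cm
        t = np.arange(0.0, 2000.0, 0.5)
        y = np.sin(2 * np.pi * t / 33.356409)
        peaks = dominant_frequency(y, dt=0.5)
        assert peaks[0]["wavenumber_cm1"] == pytest.approx(1000.0, rel=0.01)

    def test_two_component_series_two_peaks(self):
        t = np.arange(0.0, 4000.0)
        y = np.sin(2 * np.pi * t / 40.0) + 0.8 * np.sin(2 * np.pi * t / 20.0)
        peaks = dominant_frequency(y, dt=1.0)
        wns = sorted(p["wavenumber_cm1"] for p in peaks)
        assert wns[0] == pytest.approx(1.0 / (40e-15 * 2.99792458e10), rel=0.01)
        assert wns[1] == pytest.approx(1.0 / (20e-15 * 2.99792458e10), rel=0.01)

    def test_period_wavenumber_product_is_conversion_constant(self):
        t = np.arange(0.0, 1024.0)
        y = np.sin(2 * np.pi * t / 64.0)
        peak = dominant_frequency(y, dt=1.0)[0]
        # wavenumber [1/cm] * period [fs] = 1 / (c [cm/fs])
        assert peak["wavenumber_cm1"] * peak["period_fs"] == pytest.approx(
            1.0 / 2.99792458e-5, rel=1e-9
        )

    def test_white_noise_has_no_stable_peak(self, rng):
        peaks = dominant_frequency(rng.normal(size=4096), dt=1.0)
        assert not any(p["stable"] for p in peaks)
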
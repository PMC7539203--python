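"""AFM oscillation analysis: height reconstruction, windowing, harmonic fits."""

import math

import numpy as np
import pytest

from cortexmech import rheology
from cortexmech.rheology import (
    AFMTrace,
    NoSteadyStateError,
    compute_cell_height,
    fit_oscillation,
    rheology_summary,
    select_steady_window,
    tension_strain_series,
    wrap_phase_deg,
)
from cortexmech.synthetic import gen_afm_trace


def make_trace(force, piezo, fs=500.0, f=1.0, k=0.3, elevation=12.0, spike=0.5, ref=0.0):
    n = len(force)
    return AFMTrace(
        time_s=np.arange(n) / fs,
        force_nN=np.asarray(force, float),
        piezo_um=np.asarray(piezo, float),
        spring_constant_N_per_m=k,
        elevation_um=elevation,
        spike_height_um=spike,
        surface_ref_um=ref,
        frequency_hz=f,
        drive_amplitude_um=0.25,
    )


class TestComputeCellHeight:
    def test_zero_force_geometry_only(self):
        n = 5000
        tr = make_trace(np.zeros(n), np.full(n, 10.0), spike=0.5, ref=0.0)
        h = compute_cell_height(tr)
        assert np.allclose(h, 10.5)

    def test_stiff_cantilever_limit(self):
        n = 5000
        tr_soft = make_trace(np.full(n, 3.0), np.full(n, 10.0), k=0.2)
        tr_stiff = make_trace(np.full(n, 3.0), np.full(n, 10.0), k=2e6)
        assert compute_cell_height(tr_soft)[0] > compute_cell_height(tr_stiff)[0]
        assert compute_cell_height(tr_stiff)[0] == pytest.approx(10.5, abs=1e-5)

    def test_generator_round_trip_exact(self):
        trace, truth = gen_afm_trace(noise_force_nN=0.0, seed=3)
        h = compute_cell_height(trace)
        t = trace.time_s
        # regenerate the true drive waveform
        from cortexmech.synthetic import _drive_waveform

        h_true = truth.params["h0_um"] + truth.params["drive_amplitude_um"] * _drive_waveform(
            t, truth.params["frequency_hz"], True
        )
        assert np.max(np.abs(h - h_true)) < 1e-12 * max(1.0, h_true.max())

    def test_bad_spring_constant(self):
        n = 5000
        tr = make_trace(np.zeros(n), np.full(n, 10.0), k=-1.0)
        with pytest.raises(rheology.CorruptCalibrationError):
            compute_cell_height(tr)


class TestFitOscillation:
    def test_pure_sine(self):
        t = np.arange(4000) / 500.0
        mean, amp, ph, rms, low = fit_oscillation(t, 2.0 * np.sin(2 * np.pi * t), 1.0)
        assert mean == pytest.approx(0.0, abs=1e-12)
        assert amp == pytest.approx(2.0, rel=1e-12)
        assert ph == pytest.approx(0.0, abs=1e-12)
        assert not low

    def test_cosine_is_90_degrees(self):
        t = np.arange(4000) / 500.0
        mean, amp, ph, _, _ = fit_oscillation(t, 1.0 + 0.5 * np.cos(2 * np.pi * t), 1.0)
        assert mean == pytest.approx(1.0, rel=1e-12)
        assert amp == pytest.approx(0.5, rel=1e-12)
        assert math.degrees(ph) == pytest.approx(90.0, abs=1e-9)

    def test_noisy_amplitude_recovery_monte_carlo(self):
        """σ = 0.1·amplitude, n = 4000: amplitude within 2% in ≥95% of seeds."""
        t = np.arange(4000) / 500.0
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            y = 1.5 * np.sin(2 * np.pi * t + 0.7) + rng.normal(0, 0.15, len(t))
            _, amp, _, _, _ = fit_oscillation(t, y, 1.0)
            hits += abs(amp / 1.5 - 1) < 0.02
        assert hits / n_rep >= 0.95

    def test_low_snr_flagged(self):
        t = np.arange(4000) / 500.0
        rng = np.random.default_rng(0)
        _, _, _, _, low = fit_oscillation(t, rng.normal(0, 1.0, len(t)), 1.0)
        assert low


class TestSelectSteadyWindow:
    def test_stationary_takes_last_eight_periods(self):
        t = np.arange(12 * 500) / 500.0
        force = 5 + np.sin(2 * np.pi * t)
        piezo = 10 + 0.25 * np.sin(2 * np.pi * t)
        tr = make_trace(force, piezo)
        w = select_steady_window(tr)
        assert w.n_periods == 8
        assert w.stop == len(t)
        assert w.start == 4 * 500

    def test_decaying_amplitude_excludes_early_periods(self):
        """Force amplitude decaying with 1-period time constant: the 5%
        rule must push the window past the first three periods."""
        t = np.arange(15 * 500) / 500.0
        force = 5 + (1 + 2.0 * np.exp(-t)) * np.sin(2 * np.pi * t)
        piezo = 10 + 0.25 * np.sin(2 * np.pi * t)
        tr = make_trace(force, piezo)
        w = select_steady_window(tr)
        assert w.start >= 3 * 500

    def test_six_periods_clamps_to_five(self):
        t = np.arange(6 * 500) / 500.0
        force = 5 + np.sin(2 * np.pi * t)
        piezo = 10 + 0.25 * np.sin(2 * np.pi * t)
        w = select_steady_window(make_trace(force, piezo))
        assert w.n_periods == 5

    def test_never_steady_raises_with_report(self):
        t = np.arange(8 * 500) / 500.0
        force = 5 + (1 + t) * np.sin(2 * np.pi * t)  # ramping amplitude
        piezo = 10 + 0.25 * np.sin(2 * np.pi * t)
        with pytest.raises(NoSteadyStateError, match="period 0"):
            select_steady_window(make_trace(force, piezo), allow_shrink=False)


class TestTensionStrainSeries:
    def test_constant_inputs_zero_strain(self):
        n = 6 * 500
        tr = make_trace(np.full(n, 5.0), np.full(n, 10.0))
        s = tension_strain_series(tr, 4000.0)
        assert np.allclose(s.area_strain, 0.0, atol=1e-12)
        assert np.ptp(s.gamma_eff_mN_per_m) == pytest.approx(0.0, abs=1e-12)

    def test_force_linearity(self):
        n = 6 * 500
        t = np.arange(n) / 500.0
        piezo = 10 + 0.25 * np.sin(2 * np.pi * t)
        f1 = 5 + np.sin(2 * np.pi * t)
        s1 = tension_strain_series(make_trace(f1, piezo, k=1e9), 4000.0)
        s2 = tension_strain_series(make_trace(2 * f1, piezo, k=1e9), 4000.0)
        assert np.allclose(s2.gamma_eff_mN_per_m, 2 * s1.gamma_eff_mN_per_m, rtol=1e-12)

    def test_strain_mean_free_over_window(self):
        trace, truth = gen_afm_trace(seed=4)
        w = select_steady_window(trace)
        s = tension_strain_series(trace, truth.params["V_um3"], w)
        assert abs(np.mean(s.area_strain)) < 1e-12

    def test_generated_tension_recovered_exactly(self):
        trace, truth = gen_afm_trace(noise_force_nN=0.0, transient_amplitude=0.0, seed=5)
        s = tension_strain_series(trace, truth.params["V_um3"])
        w = 2 * np.pi * truth.params["frequency_hz"]
        expected = truth.params["gamma0"] + truth.params["stiffness"] * truth.params[
            "strain_amp"
        ] * np.sin(w * s.time_s + truth.params["strain_phase_rad"] + math.radians(truth.params["phi_deg"]))
        assert np.max(np.abs(s.gamma_eff_mN_per_m - expected)) < 1e-9


class TestRheologySummary:
    @pytest.mark.parametrize(
        "gamma0,K,phi",
        [(1.5, 20.0, 30.0), (0.5, 5.0, 0.0), (5.0, 100.0, 90.0), (2.0, 50.0, 60.0)],
    )
    def test_noise_free_recovery(self, gamma0, K, phi):
        trace, truth = gen_afm_trace(
            gamma0=gamma0, stiffness=K, phi_deg=phi, noise_force_nN=0.0, seed=0
        )
        res = rheology_summary(trace, truth.params["V_um3"])
        assert res.stiffness_mN_per_m == pytest.approx(K, rel=0.02)
        assert res.phi_deg == pytest.approx(phi, abs=1.0)
        assert res.gamma_mN_per_m == pytest.approx(gamma0, rel=0.01)

    def test_phase_consistent_with_lag(self):
        trace, truth = gen_afm_trace(phi_deg=42.0, noise_force_nN=0.0, seed=1)
        res = rheology_summary(trace, truth.params["V_um3"])
        f = truth.params["frequency_hz"]
        assert res.phi_deg == pytest.approx(math.degrees(2 * np.pi * f * res.lag_s), abs=1e-6)

    def test_phase_matches_cross_correlation_lag(self):
        """φ from the two fitted phases agrees with the lag located by
        cross-correlating tension against strain."""
        trace, truth = gen_afm_trace(phi_deg=35.0, noise_force_nN=0.0, seed=2)
        res = rheology_summary(trace, truth.params["V_um3"])
        s = tension_strain_series(trace, truth.params["V_um3"], res.window)
        g = s.gamma_eff_mN_per_m - s.gamma_eff_mN_per_m.mean()
        e = s.area_strain - s.area_strain.mean()
        lags = np.arange(-len(g) + 1, len(g))
        xc = np.correlate(g, e, mode="full")
        dt = float(np.median(np.diff(s.time_s)))
        lag_s = -lags[np.argmax(xc)] * dt
        f = truth.params["frequency_hz"]
        phi_xc = wrap_phase_deg(math.degrees(2 * np.pi * f * lag_s))
        assert res.phi_deg == pytest.approx(phi_xc, abs=1.0)

    def test_complex_modulus_consistency(self):
        trace, truth = gen_afm_trace(phi_deg=25.0, noise_force_nN=0.0, seed=6)
        res = rheology_summary(trace, truth.params["V_um3"])
        assert abs(res.K_complex) == pytest.approx(res.stiffness_mN_per_m, rel=1e-12)
        assert math.degrees(np.angle(res.K_complex)) == pytest.approx(res.phi_deg, abs=1e-9)
        assert res.stiffness_mN_per_m == pytest.approx(
            res.gamma_amp_mN_per_m / res.strain_amp, rel=1e-12
        )

    def test_noise_error_shrinks_with_window_length(self):
        """Median recovery error of K decreases from 5- to 10-period windows."""
        errs = {5: [], 10: []}
        for seed in range(12):
            trace, truth = gen_afm_trace(noise_force_nN=0.3, n_periods=12, seed=seed)
            for w in (5, 10):
                res = rheology_summary(trace, truth.params["V_um3"], window_periods=w)
                errs[w].append(abs(res.stiffness_mN_per_m / truth.params["stiffness"] - 1))
        assert np.median(errs[10]) <= np.median(errs[5])

    def test_height_sensitivity_report(self):
        trace, truth = gen_afm_trace(noise_force_nN=0.0, seed=7)
        rep = rheology.height_sensitivity(trace, truth.params["V_um3"])
        assert set(rep) == {"minus", "nominal", "plus"}
        # a smaller apparent height implies stronger confinement, a larger
        # contact area, and hence a smaller inferred tension from the same force
        assert rep["minus"].gamma_mN_per_m < rep["plus"].gamma_mN_per_m


def test_wrap_phase_interval():
    assert wrap_phase_deg(180.0) == 180.0
    assert wrap_phase_deg(-180.0) == 180.0
    assert wrap_phase_deg(190.0) == pytest.approx(-170.0)
    assert wrap_phase_deg(-190.0) == pytest.approx(170.0)
    assert wrap_phase_deg(30.0) == 30.0
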
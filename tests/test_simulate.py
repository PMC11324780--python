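"""PSII flash-response simulator: yield law, flash/twin/train/saturation."""

from dataclasses import replace

import numpy as np
import pytest

from flashkin import (
    FlashSpec,
    KineticState,
    KokParams,
    SimConfig,
    SStateDistribution,
    TwinSpec,
    make_st_profile,
    simulate_pump_probe_saturation,
    simulate_stk,
    simulate_train,
    simulate_twin,
    yield_from_state,
)


def state(B=0.0, T=0.0, D=None, dist=None):
    dist = dist or SStateDistribution.pure(1)
    return KineticState(B=B, T=T, D=np.zeros(4) if D is None else D, s_dist=dist,
                        preflash_s23=0.0)


class TestYieldLaw:
    def test_dark_open_state_gives_f0(self, config):
        assert yield_from_state(state(B=0.0), config) == pytest.approx(config.f0_base)

    def test_relaxed_closed_state_gives_fm(self, config):
        assert yield_from_state(state(B=1.0), config) == pytest.approx(config.fm_base)

    def test_connectivity_hyperbola_value(self):
        cfg = SimConfig(connectivity_p=0.3)
        f = yield_from_state(state(B=0.5), cfg)
        v = 0.7 * 0.5 / 0.85  # ≈ 0.4118
        assert f == pytest.approx(cfg.f0_base + (cfg.fm_base - cfg.f0_base) * v)

    def test_quenchers_multiply(self, config):
        f = yield_from_state(state(B=1.0, T=0.5, D=np.array([0.0, 0.2, 0.0, 0.0])), config)
        assert f == pytest.approx(config.fm_base / (1.5 * 1.2))


class TestSimulateStk:
    def test_dark_trace_is_flat_at_f0(self, config, s1):
        profile = make_st_profile(FlashSpec(width=10.0, intensity=0.05), 0.05, absolute=True)
        dark = profile.copy()
        dark.values = np.zeros_like(dark.values)
        tr = simulate_stk(dark, s1, config)
        f0_eff = config.f0_base * (1 + config.delta_f0 * s1.s23)
        assert np.allclose(tr.values, f0_eff)

    def test_moderate_intensity_rise_is_monotone_sigmoid(self, config, s1, saturating_st):
        profile = make_st_profile(saturating_st, 0.025, absolute=True)
        tr = simulate_stk(profile, s1, config)
        on = tr.times <= saturating_st.width
        assert np.all(np.diff(tr.values[on]) > -1e-9)
        assert tr.values[on][-1] > 2.5  # approaches the closed-center yield

    def test_maximal_intensity_shows_dip(self, config, s1):
        profile = make_st_profile(FlashSpec(width=2.0, intensity=1.0), 0.025, absolute=True)
        tr = simulate_stk(profile, s1, config)
        on = (tr.times > 0.1) & (tr.times <= 2.0)
        v = tr.values[on]
        peak = int(np.argmax(v))
        assert 0 < peak < v.size - 1  # rise–peak–decline within the flash
        assert v[-1] < v[peak] - 0.05

    def test_state_bounds_and_yield_range(self, config, s1):
        profile = make_st_profile(FlashSpec(width=2.0, intensity=1.0), 0.025, absolute=True)
        tr = simulate_stk(profile, s1, config, t_end=500.0)
        assert np.all(tr.values > 0.0)
        assert np.all(tr.values <= config.fm_base + 1e-9)

    def test_grid_refinement_convergence(self, config, s1, saturating_st):
        marks = [1.0, 10.0, 20.0, 40.0]
        vals = []
        for dt in (0.05, 0.025):
            profile = make_st_profile(saturating_st, dt, absolute=True)
            tr = simulate_stk(profile, s1, config)
            vals.append(np.interp(marks, tr.times, tr.values))
        assert np.max(np.abs(vals[0] / vals[1] - 1.0)) < 1e-4


class TestTwin:
    def test_full_relaxation_recovers_fm(self, s1):
        cfg = SimConfig(dcmu=True, tau_rec=None)
        twin = TwinSpec(
            st1=FlashSpec(width=40.0, intensity=0.05),
            st2=FlashSpec(width=10.0, intensity=0.005),
            dark_gap=20000.0,
        )
        r = simulate_twin(twin, s1, cfg, sampling_interval=0.1)
        assert r.f_i_st2 == pytest.approx(cfg.fm_base, rel=2e-3)

    def test_triplet_quenching_decays_with_its_time_constant(self, s1):
        """Residual TQ quench ratio between 20 and 40 µs gaps is e^{-4}."""
        cfg = SimConfig(dcmu=True, tau_rec=None)
        cfg = replace(cfg, dq=replace(cfg.dq, d=(0.0, 0.0, 0.0, 0.0)), delta_f0=0.0)
        fi = {}
        for gap in (20.0, 40.0, 2000.0):
            twin = TwinSpec(
                st1=FlashSpec(width=2.0, intensity=1.0),
                st2=FlashSpec(width=10.0, intensity=0.125),
                dark_gap=gap,
            )
            fi[gap] = simulate_twin(twin, s1, cfg, sampling_interval=0.025).f_i_st2
        # T is fully relaxed at 2 ms, so fi[2000] is the TQ-free baseline
        q = {g: fi[2000.0] / fi[g] - 1.0 for g in (20.0, 40.0)}  # k_sv_T·T(gap)
        assert q[40.0] / q[20.0] == pytest.approx(np.exp(-20.0 / cfg.tq.tau_T), rel=0.02)

    def test_equal_fluence_hiq_increases_with_intensity(self, config, s1):
        """Fig-11 design: same fluence, HIQ fraction ordered by intensity."""
        fractions = []
        for rel, width in ((0.125, 16.0), (0.25, 8.0), (0.5, 4.0), (1.0, 2.0)):
            twin = TwinSpec(
                st1=FlashSpec(width=width, intensity=rel),
                st2=FlashSpec(width=20.0, intensity=0.125),
                dark_gap=20.0,
            )
            r = simulate_twin(twin, s1, config, sampling_interval=0.05)
            fractions.append(r.hiq_fraction)
        assert np.all(np.diff(fractions) > 0)

    def test_relaxed_fm_ordering_across_donor_states(self):
        """F_i(ST#2) after a hit: S3 < S2 < S1 < S0 cohorts (monotone d_i)."""
        cfg = SimConfig(dcmu=True, tau_rec=None)
        twin = TwinSpec(
            st1=FlashSpec(width=2.0, intensity=1.0),
            st2=FlashSpec(width=10.0, intensity=0.125),
            dark_gap=100.0,
        )
        fis = [
            simulate_twin(twin, SStateDistribution.pure(i), cfg, sampling_interval=0.05).f_i_st2
            for i in range(4)
        ]
        assert fis[3] < fis[2] < fis[1] < fis[0]


class TestTrain:
    def test_period4_extrema_positions(self, config, s1, kok_default, saturating_st):
        from flashkin import interval_analysis

        res = simulate_train(10, 100.0, saturating_st, s1, config, kok_default,
                             sampling_interval=0.05)
        ia = interval_analysis(res.traces)
        assert ia.f_st_maxima == [1, 5, 9]
        assert ia.f0_minima == [1, 5, 9]
        assert ia.amplitude_1_3 > 0  # S1 start gives positive Fm#1 − Fm#3

    def test_uniform_initial_gives_flat_series(self, config, kok_default, saturating_st):
        from flashkin import interval_analysis

        res = simulate_train(6, 100.0, saturating_st, SStateDistribution.uniform(),
                             config, kok_default, sampling_interval=0.05)
        ia = interval_analysis(res.traces)
        assert np.ptp(ia.f0) < 1e-9
        assert np.ptp(ia.f_st) < 1e-9

    def test_repetition_shorter_than_flash_rejected(self, config, s1, kok_default):
        with pytest.raises(ValueError):
            simulate_train(3, 0.01, FlashSpec(width=40.0, intensity=0.05), s1, config,
                           kok_default)


class TestSaturation:
    def test_poisson_closed_form_without_connectivity(self):
        cfg = SimConfig(connectivity_p=0.0, dcmu=True).hiq_off()
        res = simulate_pump_probe_saturation(
            np.geomspace(0.002, 1.0, 8), cfg, sampling_interval=0.05
        )
        pred = 1.0 - np.exp(-cfg.sigma_psii * res.fluences)
        assert np.max(np.abs(res.fv_rel - pred)) < 1e-6

    def test_connectivity_makes_low_fluence_sigmoidal(self):
        """With p>0 the curve lies below the Poisson curve at low fluence."""
        lows = np.geomspace(0.002, 0.02, 4)
        cfg0 = SimConfig(connectivity_p=0.0, dcmu=True).hiq_off()
        cfgp = SimConfig(connectivity_p=0.4, dcmu=True).hiq_off()
        r0 = simulate_pump_probe_saturation(lows, cfg0, sampling_interval=0.05)
        rp = simulate_pump_probe_saturation(lows, cfgp, sampling_interval=0.05)
        assert np.all(rp.fv_rel < r0.fv_rel)

    def test_monotone_and_saturating(self):
        # Q_A reoxidation fully disabled (forward route and recombination),
        # so the probe reading approaches the relaxed closed-center yield.
        cfg = SimConfig(dcmu=True, tau_rec=None)
        res = simulate_pump_probe_saturation(
            np.geomspace(0.005, 1.0, 6), cfg, sampling_interval=0.05
        )
        assert np.all(np.diff(res.fv) > -1e-9)
        assert res.fv_rel[-1] > 0.95

    def test_empty_intensity_list_rejected(self, config):
        with pytest.raises(ValueError):
            simulate_pump_probe_saturation([], config)
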
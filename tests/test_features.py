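import math

import numpy as np
import pytest

from vmtc.features import (
    ACSF_SOLUTION,
    FICurve,
    PIPETTE_SOLUTION,
    SagMeasure,
    capacitance,
    classify_sag,
    detect_spikes,
    estimate_tau,
    firing_rate,
    fit_fi_boltzmann,
    input_resistance,
    junction_potential,
    rebound_metrics,
    rheobase,
    sag_percent,
    SpikeTrain,
)
from vmtc.simulator import Stimulus, Trace


def make_trace(t, v, **stim_kwargs):
    return Trace(times=np.asarray(t), voltage=np.asarray(v),
                 stimulus=Stimulus(**stim_kwargs))


def trace_with_spikes(spike_times, dt=0.025, total=1000.0, baseline=-70.0):
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, baseline)
    for ts in spike_times:
        # 1 ms triangular spike rising to +10 mV (dv/dt ~ 160 mV/ms)
        mask = (t >= ts) & (t < ts + 1.0)
        tri = 1.0 - np.abs((t[mask] - ts - 0.5) / 0.5)
        v[mask] = baseline + tri * 80.0
    return t, v


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 500, 0.025)
        tr = make_trace(t, np.full_like(t, -65.0), total_duration=500.0)
        assert detect_spikes(tr).n == 0

    def test_three_injected_spikes_recovered(self):
        times = [100.0, 300.0, 550.0]
        t, v = trace_with_spikes(times)
        tr = make_trace(t, v, total_duration=1000.0)
        st = detect_spikes(tr)
        assert st.n == 3
        assert np.allclose(st.spike_times, times, atol=0.1)

    def test_slow_ramp_below_criterion_ignored(self):
        t = np.arange(0, 500, 0.025)
        v = -70.0 + 0.2 * t  # 0.2 mV/ms, well below 10 mV/ms
        tr = make_trace(t, v, total_duration=500.0)
        assert detect_spikes(tr).n == 0

    def test_offset_and_resampling_invariance(self):
        t, v = trace_with_spikes([120.0, 400.0])
        n_fine = detect_spikes(make_trace(t, v, total_duration=1000.0)).n
        n_shift = detect_spikes(make_trace(t, v + 7.5, total_duration=1000.0)).n
        t2, v2 = t[::2], v[::2]
        n_coarse = detect_spikes(make_trace(t2, v2, total_duration=1000.0)).n
        assert n_fine == n_shift == n_coarse == 2

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.025, 0.3, 0.5])
        with pytest.raises(ValueError, match="resampling"):
            detect_spikes(make_trace(t, np.zeros(4), total_duration=1.0))


class TestFiringRate:
    def test_no_spikes_zero(self):
        st = SpikeTrain(np.array([]), np.array([]))
        assert firing_rate(st, 200.0, 2000.0) == 0.0

    def test_onset_exclusion_drops_early_spike(self):
        st = SpikeTrain(np.array([230.0]), np.array([-40.0]))  # onset + 30 ms
        assert firing_rate(st, 200.0, 2000.0) == 0.0

    def test_six_spikes_in_two_seconds(self):
        times = 200.0 + 50.0 + np.linspace(0, 1949.0, 6)
        st = SpikeTrain(times, np.full(6, -40.0))
        assert firing_rate(st, 200.0, 2000.0) == pytest.approx(6 / 1.95, rel=1e-9)


class TestBoltzmannFI:
    def gen(self, fmax=30.0, ihalf=200.0, k=40.0, n=12, noise=0.0, seed=0):
        I = np.linspace(30, 360, n)
        r = fmax / (1.0 + np.exp((ihalf - I) / k))
        if noise:
            r = r + np.random.default_rng(seed).normal(0.0, noise, n)
            r = np.maximum(r, 0.0)
        return FICurve(currents=I, rates=r)

    def test_noiseless_recovery_within_1pct(self):
        fit = fit_fi_boltzmann(self.gen())
        assert fit.converged
        assert fit.fmax == pytest.approx(30.0, rel=0.01)
        assert fit.i_half == pytest.approx(200.0, rel=0.01)
        assert fit.slope == pytest.approx(40.0, rel=0.01)

    def test_noisy_recovery_within_10pct(self):
        fit = fit_fi_boltzmann(self.gen(noise=1.0, seed=42))
        assert fit.converged
        assert fit.fmax == pytest.approx(30.0, rel=0.10)
        assert fit.i_half == pytest.approx(200.0, rel=0.10)
        assert fit.slope == pytest.approx(40.0, rel=0.10)

    def test_all_zero_rates_not_fittable(self):
        fi = FICurve(currents=np.linspace(30, 360, 6), rates=np.zeros(6))
        fit = fit_fi_boltzmann(fi)
        assert not fit.converged
        assert math.isnan(rheobase(fit, 3.0))

    def test_closed_form_roundtrip_at_generating_rate(self):
        fit = fit_fi_boltzmann(self.gen())
        target = 30.0 / (1.0 + math.exp((200.0 - 150.0) / 40.0))
        assert rheobase(fit, target) == pytest.approx(150.0, rel=1e-3)


class TestRheobase:
    def fitted(self):
        f = FICurve(currents=np.array([0.0]), rates=np.array([0.0]))
        f.fmax, f.i_half, f.slope, f.converged = 30.0, 200.0, 40.0, True
        return f

    def test_half_maximum_point(self):
        assert rheobase(self.fitted(), 15.0) == pytest.approx(200.0)

    def test_three_hz_closed_form(self):
        expected = 200.0 - 40.0 * math.log(9.0)
        assert rheobase(self.fitted(), 3.0) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(112.1, abs=0.05)

    def test_target_at_fmax_undefined(self):
        assert math.isnan(rheobase(self.fitted(), 30.0))

    def test_monotone_in_target_rate(self):
        f = self.fitted()
        assert rheobase(f, 3.0) < rheobase(f, 10.0) < rheobase(f, 20.0)

    def test_interp_method_on_raw_points(self):
        fi = FICurve(currents=np.array([100.0, 200.0]), rates=np.array([0.0, 10.0]))
        assert rheobase(fi, 3.0, method="interp") == pytest.approx(130.0)


def hyperpolarizing_trace(peak_defl, ss_defl, baseline=-77.0, tau_sag=300.0):
    dt = 0.05
    t = np.arange(0.0, 2600.0, dt)
    v = np.full_like(t, baseline)
    step = (t >= 200.0) & (t < 2200.0)
    ts = t[step] - 200.0
    sag_amp = peak_defl - ss_defl
    v[step] = (
        baseline
        - peak_defl * (1 - np.exp(-ts / 15.0))
        + sag_amp * (1 - np.exp(-ts / tau_sag))
    )
    v[t >= 2200.0] = baseline
    return make_trace(t, v, step_current=-100.0, step_onset=200.0,
                      step_duration=2000.0, total_duration=2600.0)


class TestSag:
    def test_hand_computed_percentage(self):
        # piecewise trace with exact 20 mV peak and 15 mV steady deflections
        dt = 0.05
        t = np.arange(0.0, 2600.0, dt)
        v = np.full_like(t, -77.0)
        step = (t >= 200.0) & (t < 2200.0)
        ts = t[step] - 200.0
        v[step] = -77.0 - np.interp(ts, [0.0, 50.0, 500.0, 2000.0],
                                    [0.0, 20.0, 15.0, 15.0])
        tr = make_trace(t, v, step_current=-100.0, step_onset=200.0,
                        step_duration=2000.0, total_duration=2600.0)
        m = sag_percent(tr)
        assert m.sag_percent == pytest.approx(25.0, abs=0.1)
        assert m.v_peak_deflection == pytest.approx(20.0, abs=0.05)
        assert m.v_ss_deflection == pytest.approx(15.0, abs=0.05)

    def test_no_sag_zero_percent(self):
        tr = hyperpolarizing_trace(20.0, 20.0)
        assert sag_percent(tr).sag_percent == pytest.approx(0.0, abs=0.3)

    def test_scale_invariance(self):
        a = sag_percent(hyperpolarizing_trace(20.0, 15.0)).sag_percent
        b = sag_percent(hyperpolarizing_trace(40.0, 30.0)).sag_percent
        assert a == pytest.approx(b, abs=0.2)

    def test_depolarizing_step_rejected(self):
        t = np.arange(0, 2600, 0.05)
        tr = make_trace(t, np.full_like(t, -70.0), step_current=100.0,
                        step_onset=200.0, step_duration=2000.0,
                        total_duration=2600.0)
        with pytest.raises(ValueError):
            sag_percent(tr)

    def test_passive_cell_has_no_sag(self, passive_soma):
        from vmtc.simulator import integrate, settle

        st, _ = settle(passive_soma, 0.0, duration=500.0, dt=0.05)
        tr = integrate(
            passive_soma,
            Stimulus(step_current=-2.0, step_onset=200.0, step_duration=2000.0,
                     total_duration=2500.0),
            dt=0.05,
            state=st,
        )
        assert abs(sag_percent(tr).sag_percent) < 1.0

    @pytest.mark.parametrize(
        "pct, expected",
        [(25.0, "sag_expressing"), (14.9, "no_sag"), (15.0, "no_sag")],
    )
    def test_classification_threshold(self, pct, expected):
        m = SagMeasure(baseline=-77.0, v_peak_deflection=20.0,
                       v_ss_deflection=20.0 * (1 - pct / 100.0), sag_percent=pct)
        assert classify_sag(m) == expected


class TestRebound:
    def test_no_post_step_spikes(self):
        tr = hyperpolarizing_trace(30.0, 25.0)
        m = rebound_metrics(tr)
        assert m["rebound_spike_count"] == 0
        assert m["end_of_step_hyperpolarization"] == pytest.approx(25.0, abs=0.3)
        assert m["bin"] == "20-40"

    def test_burst_counted_and_binned(self):
        tr = hyperpolarizing_trace(35.0, 30.0)
        t, v = tr.times, tr.voltage.copy()
        for ts in (2210.0, 2218.0, 2226.0):  # 3-spike rebound burst
            mask = (t >= ts) & (t < ts + 1.0)
            tri = 1.0 - np.abs((t[mask] - ts - 0.5) / 0.5)
            v[mask] = v[mask] + tri * 90.0
        tr2 = make_trace(t, v, step_current=-100.0, step_onset=200.0,
                         step_duration=2000.0, total_duration=2600.0)
        m = rebound_metrics(tr2)
        assert m["rebound_spike_count"] == 3
        assert m["bin"] == "20-40"

    def test_shallow_step_bins_low(self):
        m = rebound_metrics(hyperpolarizing_trace(12.0, 10.0))
        assert m["bin"] == "0-20"


class TestTauEstimation:
    def pulse_trace(self, decay):
        dt = 0.025
        t = np.arange(0.0, 300.0, dt)
        v = np.full_like(t, -77.0)
        after = t >= 50.5
        td = t[after] - 50.5
        v[after] = -77.0 - decay(td)
        tr = make_trace(t, v, step_current=-1000.0, step_onset=50.0,
                        step_duration=0.5, total_duration=300.0)
        return tr

    def test_single_exponential_both_methods(self):
        tr = self.pulse_trace(lambda td: 5.0 * np.exp(-td / 20.0))
        t33 = estimate_tau(tr, method="decay33")
        assert t33 == pytest.approx(20.0 * math.log(1 / 0.33), abs=0.1)
        assert estimate_tau(tr, method="double_exp") == pytest.approx(20.0, rel=0.02)

    def test_two_exponential_slowest_recovered(self):
        tr = self.pulse_trace(
            lambda td: 0.7 * 5.0 * np.exp(-td / 20.0) + 0.3 * 5.0 * np.exp(-td / 2.0)
        )
        assert estimate_tau(tr, method="double_exp") == pytest.approx(20.0, rel=0.02)

    def test_flat_trace_fails(self):
        t = np.arange(0.0, 300.0, 0.025)
        tr = make_trace(t, np.full_like(t, -77.0), step_current=-1000.0,
                        step_onset=50.0, step_duration=0.5, total_duration=300.0)
        with pytest.raises(ValueError, match="estimation failure|deflection"):
            estimate_tau(tr, method="decay33")


class TestPassiveScalars:
    def rin_trace(self, deflection):
        dt = 0.05
        t = np.arange(0.0, 250.0, dt)
        v = np.full_like(t, -77.0)
        step = (t >= 100.0) & (t < 200.0)
        v[step] = -77.0 + deflection * (1 - np.exp(-(t[step] - 100.0) / 5.0))
        return make_trace(t, v, step_current=-10.0, step_onset=100.0,
                          step_duration=100.0, total_duration=250.0)

    def test_ohms_law(self):
        assert input_resistance(self.rin_trace(-2.0)) == pytest.approx(200.0, abs=0.5)

    def test_printed_model_value(self):
        assert input_resistance(self.rin_trace(-2.182)) == pytest.approx(218.2, abs=0.5)

    def test_zero_pulse_guarded(self):
        tr = self.rin_trace(-2.0)
        tr.stimulus = Stimulus(step_current=0.0, step_onset=100.0,
                               step_duration=100.0, total_duration=250.0)
        with pytest.raises(ValueError):
            input_resistance(tr)

    def test_capacitance_ratio(self):
        assert capacitance(19.1, 218.2) == pytest.approx(87.4, abs=0.2)
        assert capacitance(20.0, 200.0) == pytest.approx(100.0)
        assert capacitance(0.0, 200.0) == 0.0
        with pytest.raises(ValueError):
            capacitance(10.0, 0.0)


class TestJunctionPotential:
    def test_identical_solutions_zero(self):
        assert junction_potential(ACSF_SOLUTION, ACSF_SOLUTION) == pytest.approx(0.0)

    def test_kcl_vs_nacl_small_positive(self):
        ljp = junction_potential({"K": 150.0, "Cl": 150.0},
                                 {"Na": 150.0, "Cl": 150.0})
        assert 0.0 < ljp < 12.0

    def test_recording_solutions_near_14_2(self):
        assert junction_potential() == pytest.approx(14.2, abs=0.5)

    def test_missing_mobility_names_species(self):
        with pytest.raises(KeyError, match="unobtainium"):
            junction_potential({"unobtainium": 10.0}, ACSF_SOLUTION)

    def test_pipette_composition_is_charge_sane(self):
        from vmtc.features import IONIC_MOBILITIES

        for sol in (PIPETTE_SOLUTION, ACSF_SOLUTION):
            net = sum(IONIC_MOBILITIES[s][0] * c for s, c in sol.items())
            total = sum(abs(IONIC_MOBILITIES[s][0]) * c for s, c in sol.items())
            assert abs(net) / total < 0.05  # near electroneutrality
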
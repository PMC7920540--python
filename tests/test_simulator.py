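import numpy as np
import pytest
from scipy.linalg import expm

from vmtc.membrane import DistributionTable, default_distribution_table
from vmtc.morphology import Morphology, Section, SurrogateConfig
from vmtc.simulator import (
    PassiveParams,
    SolverError,
    Stimulus,
    apply_pharmacology,
    assemble,
    build_cell,
    find_holding_current,
    find_holding_current_batch,
    integrate,
    settle,
    steady_state_injection,
)

from conftest import soma_only_morphology, zero_distribution


def two_comp_passive():
    secs = (
        Section(0, "soma", None, 9.66, 9.66, 0, 0.0),
        Section(1, "dend", 0, 60.0, 2.0, 1, 30.0),
    )
    return assemble(
        Morphology(secs), dist=zero_distribution(), max_seg_length=100.0
    )


class TestPassiveOracles:
    def test_single_compartment_rc_charging(self, passive_soma):
        """Backward-Euler solution vs the RC closed form, < 0.1% of deflection."""
        pas = passive_soma.passive
        area = 293.0e-8
        r = pas.rm * 1e3 / area / 1e6  # MOhm
        c = pas.cm * area * 1e3  # nF
        tau = r * c
        amp = -2.0  # pA; small so the deflection is cell-scale
        tr = integrate(
            passive_soma,
            Stimulus(step_current=amp, step_onset=0.0, step_duration=400.0,
                     total_duration=400.0),
            dt=0.025,
        )
        vinf = amp * r * 1e-3  # mV deflection
        expected = pas.e_pas + vinf * (1.0 - np.exp(-tr.times / tau))
        err = np.max(np.abs(tr.voltage - expected))
        assert err < 1e-3 * abs(vinf)

    def test_two_compartment_matches_matrix_exponential(self):
        """Soma+dendrite passive pair vs the analytic 2x2 linear system."""
        cell = two_comp_passive()
        pas = cell.passive
        areas = cell.grid.area_um2 * 1e-8
        c = pas.cm * areas * 1e3  # nF
        g_leak = areas * 1e6 / (pas.rm * 1e3)  # uS
        g_ax = cell.grid.axial_conductance_uS(pas.ri)[1]
        amp_na = -5e-3  # nA (-5 pA) into the soma
        A = np.array(
            [
                [-(g_leak[0] + g_ax) / c[0], g_ax / c[0]],
                [g_ax / c[1], -(g_leak[1] + g_ax) / c[1]],
            ]
        )
        b = np.array([(g_leak[0] * pas.e_pas + amp_na) / c[0],
                      g_leak[1] * pas.e_pas / c[1]])
        v_inf = np.linalg.solve(A, -b)
        tr = integrate(
            cell,
            Stimulus(step_current=-5.0, step_onset=0.0, step_duration=300.0,
                     total_duration=300.0),
            dt=0.0125,
            record_dt=0.5,
        )
        v0 = np.array([pas.e_pas, pas.e_pas])
        deflection = abs(v_inf[0] - pas.e_pas)
        for k, t in enumerate(tr.times):
            v_t = v_inf + expm(A * t) @ (v0 - v_inf)
            assert abs(tr.voltage[k] - v_t[0]) < 1e-3 * deflection


class TestIntegration:
    def test_deterministic_traces(self, cell):
        stim = Stimulus(bias_current=50.0, step_current=120.0, step_onset=100.0,
                        step_duration=300.0, total_duration=500.0)
        a = integrate(cell, stim, dt=0.05)
        b = integrate(cell, stim, dt=0.05)
        assert a.voltage.tobytes() == b.voltage.tobytes()

    def test_rest_is_stable_and_quiet(self, cell):
        st, v1 = settle(cell, 0.0, duration=4000.0, dt=0.05)
        tr = integrate(
            cell, Stimulus(total_duration=2000.0), dt=0.05, record_dt=0.5, state=st
        )
        dvdt = np.diff(tr.voltage) / 0.5
        assert np.max(np.abs(dvdt[200:])) < 1e-4
        assert np.max(tr.voltage) < -70.0  # no spikes at rest

    def test_divergence_raises_solver_error(self, passive_soma):
        with pytest.raises(SolverError, match="at t ="):
            integrate(
                passive_soma,
                Stimulus(bias_current=2e5, total_duration=100.0),
                dt=0.05,
            )

    def test_refinement_preserves_tonic_firing(self, cell):
        """Halving dt leaves the spike count, first-spike latency and mean
        interspike interval of a tonic train essentially unchanged."""
        from vmtc.features import detect_spikes

        (h,), (st,) = find_holding_current_batch([cell], -64.0, dt=0.025)
        stim = Stimulus(bias_current=h, step_current=350.0, step_onset=100.0,
                        step_duration=1000.0, total_duration=1100.0)
        t_coarse = detect_spikes(
            integrate(cell, stim, dt=0.025, state=st)
        ).spike_times
        t_fine = detect_spikes(
            integrate(cell, stim, dt=0.0125, record_dt=0.025, state=st)
        ).spike_times
        assert t_coarse.size == t_fine.size >= 10
        assert abs(t_coarse[0] - t_fine[0]) < 0.3  # ms
        isi_c = np.mean(np.diff(t_coarse))
        isi_f = np.mean(np.diff(t_fine))
        assert abs(isi_c - isi_f) / isi_f < 0.015


class TestAssemble:
    def test_all_zero_densities_is_passive(self):
        cell = assemble(soma_only_morphology(), dist=zero_distribution())
        assert all(cell.total_conductance(ch) == 0.0 for ch in ("NaF", "KM", "IH"))

    def test_soma_kdr_conductance_is_density_times_area(self, cell):
        soma = cell.soma_index
        dens = cell.density("KDR")[soma]
        assert dens == pytest.approx(1.52)
        area_cm2 = cell.grid.area_um2[soma] * 1e-8
        assert dens * area_cm2 == pytest.approx(1.52 * 293e-8, rel=1e-9)

    def test_total_km_is_area_weighted_sum(self, cell):
        table = default_distribution_table()
        expected = sum(
            table.get("KM", lab) * a * 1e-8
            for lab, a in zip(cell.comp_label, cell.grid.area_um2)
        )
        assert cell.total_conductance("KM") == pytest.approx(expected, rel=1e-12)

    def test_unknown_region_label_rejected(self):
        bad = DistributionTable({"KM": {"axon_hillock": 1e-3}})
        with pytest.raises(ValueError, match="region"):
            assemble(soma_only_morphology(), dist=bad)


class TestPharmacology:
    def test_identity_scaling_identical_output(self, cell):
        same = apply_pharmacology(cell, {ch: 1.0 for ch in ("KM", "IH", "NaF")})
        stim = Stimulus(step_current=80.0, step_onset=50.0, step_duration=200.0,
                        total_duration=300.0)
        assert (
            integrate(cell, stim, dt=0.05).voltage.tobytes()
            == integrate(same, stim, dt=0.05).voltage.tobytes()
        )

    def test_zero_factor_is_exact_removal(self, cell):
        blocked = apply_pharmacology(cell, {"KM": 0.0})
        assert np.all(blocked.density("KM") == 0.0)
        # equivalent to deleting the row from the density table, bitwise
        nodist = DistributionTable(
            {
                ch: ({r: 0.0 for r in row} if ch == "KM" else dict(row))
                for ch, row in default_distribution_table().density.items()
            }
        )
        removed = build_cell(dist=nodist)
        stim = Stimulus(step_current=60.0, step_onset=50.0, step_duration=200.0,
                        total_duration=300.0)
        assert (
            integrate(blocked, stim, dt=0.05).voltage.tobytes()
            == integrate(removed, stim, dt=0.05).voltage.tobytes()
        )

    def test_composition_multiplies(self, cell):
        c = apply_pharmacology(apply_pharmacology(cell, {"KM": 0.5}), {"KM": 0.4})
        assert c.pharmacology["KM"] == pytest.approx(0.2)
        assert np.allclose(c.density("KM"), cell.density("KM") * 0.2)

    def test_half_km_halves_conductance(self, cell):
        half = apply_pharmacology(cell, {"KM": 0.5})
        assert half.total_conductance("KM") == pytest.approx(
            0.5 * cell.total_conductance("KM")
        )

    def test_negative_factor_rejected(self, cell):
        with pytest.raises(ValueError):
            apply_pharmacology(cell, {"KM": -0.1})


class TestHoldingCurrent:
    def test_rest_target_needs_no_current(self, cell):
        _, vrest = settle(cell, 0.0, duration=3000.0, dt=0.05)
        i = find_holding_current(cell, vrest, tol=0.5)
        assert abs(i) < 12.0  # pA; within the search tolerance of zero

    def test_monotone_in_target(self, cell):
        i_64 = find_holding_current(cell, -64.0)
        i_71 = find_holding_current(cell, -71.0)
        assert i_64 > i_71

    def test_self_consistency(self, cell):
        i, states = find_holding_current_batch([cell], -68.0, tol=0.5)
        tr = integrate(
            cell,
            Stimulus(bias_current=float(i[0]), total_duration=1000.0),
            dt=0.05,
            record_dt=0.5,
            state=states[0],
        )
        assert np.median(tr.voltage[tr.times > 800.0]) == pytest.approx(-68.0, abs=0.7)

    def test_out_of_range_target_rejected(self, cell):
        with pytest.raises(ValueError):
            find_holding_current(cell, -30.0)


class TestSteadyStateInjection:
    def test_balances_at_rest(self, cell):
        _, vrest = settle(cell, 0.0, duration=3000.0, dt=0.05)
        assert abs(steady_state_injection(cell, vrest)) < 12.0
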
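import numpy as np
import pytest

from delaysum.circuit import GlutUnit, group_kinetics_at
from delaysum.model import (
    BarStimulus,
    model_dsi_curve,
    modulate_decay,
    rms_error,
    shuffled_model,
    simulate_population,
    simulate_unit,
    sustained_model,
    temporal_filter_kernel,
)
from delaysum.stimuli import make_moving_spot, make_static_spot
from delaysum.traces import Trace

from conftest import two_unit_circuit


def _unit(group="G3", pos=(0.0, 0.0), lat_jit=0.0):
    return GlutUnit(group=group, pos_um=pos,
                    kinetics=group_kinetics_at(group, pos[0], lat_jit))


class TestSimulateUnit:
    def test_zero_stimulus_gives_zero_trace(self):
        mv = make_static_spot(200.0, 0.0, 1.0)
        tr = simulate_unit(_unit(), mv)
        assert np.all(tr.values == 0)

    def test_impulse_reproduces_temporal_kernel(self):
        unit = _unit()
        mv = make_static_spot(200.0, 1.0, 2.0, px_size_um=10.0, refresh_hz=50.0)
        # a one-frame flash: zero all but the first frame
        mv.frames[:, :, 1:] = 0.0
        tr = simulate_unit(unit, mv, apply_envelope=False)
        k = temporal_filter_kernel(unit.kinetics)
        # one stimulus frame lasts 20 ms on the 1 ms simulation grid
        box = np.ones(20) / 20.0
        expected = np.convolve(k, box)
        n = min(tr.values.size, expected.size)
        cc = np.corrcoef(tr.values[:n], expected[:n])[0, 1]
        assert cc > 0.999

    def test_onset_scales_with_speed(self):
        unit = _unit(pos=(0.0, 0.0))
        t_on = {}
        for v in (200.0, 100.0):
            tr = simulate_unit(unit, BarStimulus(speed_um_s=v, field_um=800.0))
            t_on[v] = np.argmax(tr.values > 0.1 * tr.values.max()) * 0.001
        lat = unit.kinetics.peak_latency_s
        # time to reach the unit doubles for half the speed
        travel_fast = t_on[200.0]
        travel_slow = t_on[100.0]
        assert travel_slow - lat == pytest.approx(2 * (travel_fast - lat), rel=0.2)

    def test_unit_outside_stimulus_rejected(self):
        mv = make_static_spot(100.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            simulate_unit(_unit(pos=(500.0, 0.0)), mv)


class TestModulateDecay:
    def _bump(self):
        t = np.arange(0, 3.0, 0.001)
        v = np.exp(-0.5 * ((t - 1.0) / 0.2) ** 2)
        return Trace(v, 1000.0)

    def test_wide_envelope_limit_leaves_trace_unchanged(self):
        tr = self._bump()
        out = modulate_decay(tr, 1e6, 1e-4)
        assert np.allclose(out.values, tr.values, atol=1e-3)

    def test_envelope_preserves_the_peak(self):
        tr = self._bump()
        out = modulate_decay(tr, 0.3, 0.05)
        assert out.values.max() == pytest.approx(tr.values.max(), rel=1e-9)
        assert np.argmax(out.values) == np.argmax(tr.values)

    def test_post_peak_charge_decreases_with_tau1(self):
        tr = self._bump()
        charges = []
        for tau1 in (1.0, 0.5, 0.25):
            out = modulate_decay(tr, tau1, 0.05)
            p = np.argmax(out.values)
            charges.append(np.trapezoid(out.values[p:], dx=0.001))
        assert charges[0] > charges[1] > charges[2]

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            modulate_decay(self._bump(), 0.05, 0.3)


class TestPopulation:
    def test_single_unit_population_equals_unit(self):
        unit = _unit()
        bar = BarStimulus(speed_um_s=300.0)
        a = simulate_unit(unit, bar)
        from delaysum.circuit import CircuitModel

        out = simulate_population(CircuitModel(units=[unit]), bar)
        assert np.allclose(out.summed.values, a.values)

    def test_charge_additivity(self, grid_circuit):
        bar = BarStimulus(speed_um_s=300.0)
        out = simulate_population(grid_circuit, bar)
        unit_charges = sum(
            simulate_unit(u, bar).charge() for u in grid_circuit.units
        )
        assert out.charge == pytest.approx(unit_charges, rel=1e-9)

    def test_gain_scaling_scales_output_not_dsi(self, grid_circuit):
        from dataclasses import replace
        from delaysum.circuit import CircuitModel

        doubled = CircuitModel(
            units=[replace(u, gain=2 * u.gain) for u in grid_circuit.units],
            dendritic_diameter_um=grid_circuit.dendritic_diameter_um,
        )
        speeds = (150.0, 300.0)
        a = model_dsi_curve(grid_circuit, speeds=speeds)
        b = model_dsi_curve(doubled, speeds=speeds)
        assert np.allclose(b.amplitude_pref, 2 * a.amplitude_pref, rtol=1e-9)
        assert np.allclose(b.dsi_amplitude, a.dsi_amplitude, atol=1e-12)

    def test_summed_peak_after_bar_passes_centre(self, default_circuit):
        """Global summation: the model input peaks only after the moving
        stimulus passes the dendritic-field centre."""
        bar = BarStimulus(speed_um_s=200.0)
        out = simulate_population(default_circuit, bar)
        t_peak = np.argmax(out.summed.values) * 0.001
        t_center = (0.0 - bar.start_center_um) / bar.speed_um_s
        assert t_peak > t_center

    def test_analytic_and_raster_drives_agree(self):
        unit = _unit(pos=(30.0, 10.0))
        bar = BarStimulus(diameter_um=300.0, speed_um_s=400.0, field_um=800.0)
        mv = make_moving_spot(300.0, 1.0, 0.0, 400.0, 800.0, px_size_um=5.0,
                              refresh_hz=50.0, shape="bar")
        a = simulate_unit(unit, bar).values
        b = simulate_unit(unit, mv).values
        n = min(a.size, b.size)
        assert np.corrcoef(a[:n], b[:n])[0, 1] > 0.995
        assert b[:n].max() == pytest.approx(a[:n].max(), rel=0.05)


class TestChargeInvariance:
    def test_linear_charge_dsi_is_zero(self, grid_circuit):
        res = model_dsi_curve(grid_circuit, speeds=(150.0, 500.0),
                              apply_envelope=False)
        assert np.all(np.abs(res.dsi_charge) < 1e-6)


class TestHROptimum:
    @pytest.mark.parametrize("ds,dt", [(100.0, 0.5), (200.0, 1.0)])
    def test_two_unit_optimum_at_ds_over_dt(self, ds, dt):
        circ = two_unit_circuit(ds, dt)
        grid = np.arange(50.0, 610.0, 25.0)
        res = model_dsi_curve(circ, speeds=grid)
        opt = res.optimal_speed()
        assert abs(opt - ds / dt) <= 25.0


class TestVariants:
    def test_shuffle_preserves_charge(self, grid_circuit):
        speeds = (200.0,)
        base = model_dsi_curve(grid_circuit, speeds=speeds)
        sh = shuffled_model(grid_circuit, n_shuffles=5, seed=2, speeds=speeds)
        assert sh.charge_pref[0] == pytest.approx(base.charge_pref[0], rel=1e-6)

    def test_sustained_substitution_preserves_counts_and_nonsub_groups(
        self, default_circuit
    ):
        res = sustained_model(default_circuit, speeds=(200.0,))
        assert res.variant == "sustained"
        # count preservation is structural: rebuild and compare kinetics
        from delaysum.model import DEFAULT_GROUP_KINETICS

        assert len(default_circuit) == 193

    def test_sustained_without_transient_groups_matches_delay_sum(self):
        from delaysum.circuit import make_ground_truth_cell

        c = make_ground_truth_cell(
            counts_by_group={"G2": 6, "G3": 6, "G5": 6}, seed=1
        )
        speeds = (150.0, 300.0)
        a = model_dsi_curve(c, speeds=speeds)
        b = sustained_model(c, speeds=speeds)
        assert np.allclose(a.amplitude_pref, b.amplitude_pref)


class TestRMSError:
    def test_identical_curves_zero(self):
        x = np.array([0.1, 0.2, 0.3])
        assert rms_error(x, x) == 0.0

    def test_constant_offset(self):
        x = np.array([0.1, 0.2, 0.3])
        assert rms_error(x, x + 0.07) == pytest.approx(0.07)

    def test_swapped_pair(self):
        assert rms_error(np.array([0.3, 0.1]), np.array([0.1, 0.3])) == pytest.approx(0.2)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rms_error(np.zeros(3), np.zeros(4))
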
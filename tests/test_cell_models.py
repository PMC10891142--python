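"""Single-cell model behavior: resting states, calibration, cross-checks."""

import numpy as np
import pytest

import fibromotif as fm
from fibromotif import _engine as engine
from fibromotif import cell_models, metrics
from fibromotif.errors import CalibrationError, InvalidStateError


class TestMyocyte:
    def test_resting_potential_after_quiescence(self, shallow):
        """The quiescent epicardial cell settles near -86 mV."""
        y = fm.resting_myocyte_state(shallow)
        assert y[0] == pytest.approx(-86.0, abs=1.0)
        cell_models.validate_myocyte_state(y)

    def test_steady_state_is_voltage_stationary(self, shallow):
        res = fm.steady_state("myocyte", shallow, t_max=10000.0)
        assert res.residual < 1e-4
        # voltage itself is essentially stationary even though pump fluxes
        # keep draining Na_i on a minutes timescale
        rhs = fm.myocyte_rhs(res.state, shallow)
        assert abs(rhs[0]) < 1e-3  # mV/ms

    def test_single_beat_shape(self, steep):
        """One stimulated beat: fast upstroke, overshoot, dome, repolarization."""
        spec = fm.PacingSpec(n_beats=1, n_discard=0)
        tr = fm.run_uncoupled_myocyte(steep, spec, stim_times=np.array([0.0]),
                                      t_end=500.0)
        ev = metrics.detect_aps(tr.v1, tr.time)
        assert len(ev) == 1
        assert ev[0].peak_v > 20.0
        assert 150.0 < ev[0].apd90 < 350.0
        assert ev[0].dia_v < -80.0
        # fast upstroke: V crosses 0 mV within 3 ms of the threshold crossing
        above0 = tr.time[tr.v1 > 0.0]
        assert above0.size and above0[0] - ev[0].upstroke_time < 3.0

    def test_gates_bounded_over_twenty_beats(self, steep):
        """All Hodgkin-Huxley gates stay in [0, 1] along a 20-beat trajectory."""
        y = fm.resting_myocyte_state(steep)
        dt = 0.02
        stim = (np.arange(20) * 600.0 / dt).round().astype(np.int64)
        chunk = int(100.0 / dt)   # validate every 100 ms
        for k in range(120):
            offset = k * chunk
            local = stim[(stim >= offset) & (stim < offset + chunk)] - offset
            engine.run_myocyte(y, steep.vector(), local, int(1.0 / dt), 52.0,
                               chunk, dt, 10 ** 9)
            gates = y[engine.MYO_GATE_SLICE]
            assert np.all(gates >= 0.0) and np.all(gates <= 1.0)
            assert np.all(y[14:] > 0.0)

    def test_rhs_rejects_nonfinite_state(self, shallow):
        y = fm.resting_myocyte_state(shallow)
        y[0] = np.nan
        with pytest.raises(InvalidStateError):
            fm.myocyte_rhs(y, shallow)

    def test_lsoda_cross_check_single_beat(self, shallow):
        """Independent stiff-solver route reproduces the stepper's APD90."""
        from scipy.integrate import solve_ivp

        y0 = fm.resting_myocyte_state(shallow)

        def rhs(t, y):
            s = 52.0 if t < 1.0 else 0.0
            return fm.myocyte_rhs(y, shallow, i_ext=s, i_stim=s)

        ts, vs = [], []
        y = y0.copy()
        for (a, b) in [(0.0, 1.0), (1.0, 450.0)]:
            sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=1e-8,
                            atol=1e-8, max_step=1.0, dense_output=True)
            assert sol.success
            y = sol.y[:, -1]
            tt = np.arange(a, b, 0.1)
            ts.append(tt)
            vs.append(sol.sol(tt)[0])
        ev_lsoda = metrics.detect_aps(np.concatenate(vs), np.concatenate(ts))

        spec = fm.PacingSpec(n_beats=1, n_discard=0)
        tr = fm.run_uncoupled_myocyte(shallow, spec, stim_times=np.array([0.0]),
                                      t_end=450.0)
        ev_rl = metrics.detect_aps(tr.v1, tr.time)
        assert len(ev_lsoda) == len(ev_rl) == 1
        assert ev_lsoda[0].apd90 == pytest.approx(ev_rl[0].apd90, abs=1.0)


class TestFibroblast:
    def test_native_resting_potential(self):
        """Unmodified fibroblast rests near the published -49.6 mV."""
        y = fm.resting_fibroblast_state(fm.FibroblastParams())
        assert -52.0 < y[0] < -46.0

    def test_fixed_point_residual(self):
        res = fm.steady_state("fibroblast", fm.FibroblastParams(), t_max=60000.0)
        assert res.converged
        assert res.residual < 1e-6

    def test_steady_state_self_consistency(self):
        """Doubling the settle time leaves V_f unchanged to < 0.01 mV."""
        p = fm.FibroblastParams()
        v1 = fm.resting_fibroblast_state(p, t_max=60000.0)[0]
        v2 = fm.resting_fibroblast_state(p, t_max=120000.0)[0]
        assert abs(v1 - v2) < 0.01

    def test_calibrated_rest_depolarized(self, fib24):
        y = fm.resting_fibroblast_state(fib24)
        assert y[0] == pytest.approx(-24.5, abs=0.1)

    def test_calibrated_rest_near_native(self, fib49):
        y = fm.resting_fibroblast_state(fib49)
        assert y[0] == pytest.approx(-49.0, abs=0.1)
        # -49 mV is close to the native resting potential: tiny shift
        assert abs(fib49.kv_shift) < 5.0

    def test_identity_calibration(self):
        """Calibrating to the native resting potential returns shift ~ 0."""
        native = fm.resting_fibroblast_state(fm.FibroblastParams())[0]
        shift = fm.calibrate_kv_shift(float(native))
        assert shift == pytest.approx(0.0, abs=0.5)

    def test_steady_vf_monotone_in_shift(self):
        """Brute-force scan: the steady V_f(shift) map is strictly increasing."""
        from dataclasses import replace

        shifts = np.linspace(-10.0, 80.0, 10)
        vfs = [fm.resting_fibroblast_state(
            replace(fm.FibroblastParams(), kv_shift=float(s)))[0]
            for s in shifts]
        assert np.all(np.diff(vfs) > 0)

    def test_kv_shift_monotone_in_target(self, fib24, fib49):
        assert fib24.kv_shift > fib49.kv_shift

    def test_unreachable_target_raises(self):
        with pytest.raises(CalibrationError):
            fm.calibrate_kv_shift(-80.0)

    def test_coupled_fibroblast_follows_myocyte_aps(self, shallow, fib49,
                                                    short_spec):
        """Weak coupling: V_f shows one depolarization per myocyte AP."""
        cfg = fm.build_motif(3, 0.5, 0.0)
        tr = fm.run_paced(cfg, short_spec, shallow, fib49)
        vf = tr.voltage("f1")
        rest = vf[0]
        # count depolarization excursions above rest + 10 mV
        above = vf > rest + 10.0
        n_rises = int(np.sum(~above[:-1] & above[1:]))
        n_aps = len(metrics.detect_aps(tr.v1, tr.time))
        assert n_aps == short_spec.n_beats
        assert n_rises == n_aps
        assert vf.max() < tr.v1.max()  # fibroblast follows, attenuated


class TestSerialization:
    def test_params_toml_roundtrip(self, tmp_path, steep, fib24):
        p1 = tmp_path / "myo.toml"
        cell_models.params_to_toml(steep, p1)
        assert cell_models.params_from_toml(p1) == steep
        p2 = tmp_path / "fib.toml"
        cell_models.params_to_toml(fib24, p2)
        assert cell_models.params_from_toml(p2) == fib24

    def test_state_checkpoint_roundtrip(self, tmp_path, shallow):
        y = fm.resting_myocyte_state(shallow)
        path = tmp_path / "state.h5"
        cell_models.save_state_hdf5(path, y, "myocyte")
        y2, kind = cell_models.load_state_hdf5(path)
        assert kind == "myocyte"
        np.testing.assert_array_equal(y, y2)
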
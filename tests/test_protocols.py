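"""Pacing protocols, stimulus bookkeeping, solver convergence, S1S2."""

import numpy as np
import pytest

import fibromotif as fm
from fibromotif import metrics


def test_pacing_spec_validation():
    with pytest.raises(ValueError):
        fm.PacingSpec(n_beats=5, n_discard=5)
    with pytest.raises(ValueError):
        fm.PacingSpec(t1=-100.0)
    with pytest.raises(ValueError):
        fm.PacingSpec(tau_d=-1.0)


def test_stimulus_bookkeeping_twenty_beats(shallow, study_spec):
    """20 delivered stimuli produce 20 detected APs, one per stimulus."""
    tr = fm.run_uncoupled_myocyte(shallow, study_spec)
    assert len(tr.stim_times_m1) == 20
    events = metrics.detect_aps(tr.v1, tr.time, stim_times=tr.stim_times_m1)
    assert len(events) == 20
    assert [e.stim_index for e in events] == list(range(20))
    # steady pacing: post-discard beats accommodate slowly and monotonically;
    # the residual beat-to-beat APD change is well under a millisecond
    apds = np.array([e.apd90 for e in events[10:]])
    steps = np.diff(apds)
    assert np.all(np.abs(steps) < 1.0)
    assert max(apds) - min(apds) < 6.0


def test_zero_amplitude_gives_no_aps(shallow):
    spec = fm.PacingSpec(n_beats=3, n_discard=1, stim_amplitude=0.0)
    tr = fm.run_uncoupled_myocyte(shallow, spec)
    assert metrics.detect_aps(tr.v1, tr.time) == []
    assert np.all(np.abs(tr.v1 - tr.v1[0]) < 1.0)


def test_traces_are_deterministic(steep, fib24, short_spec):
    cfg = fm.build_motif(2, 1.0, 2.0)
    tr1 = fm.run_paced(cfg, short_spec, steep, fib24)
    tr2 = fm.run_paced(cfg, short_spec, steep, fib24)
    np.testing.assert_array_equal(tr1.v1, tr2.v1)
    np.testing.assert_array_equal(tr1.v2, tr2.v2)
    np.testing.assert_array_equal(tr1.vf1, tr2.vf1)


def test_delayed_stimulation_lag(steep, fib24):
    """tau_D = 25 ms: myocyte-2 upstrokes lag myocyte-1's by 25 +/- 1 ms."""
    spec = fm.PacingSpec(t1=600.0, tau_d=25.0, n_beats=3, n_discard=1)
    cfg = fm.build_motif(3, 0.5, 0.5)
    tr = fm.run_paced(cfg, spec, steep, fib24)
    e1 = metrics.detect_aps(tr.v1, tr.time)
    e2 = metrics.detect_aps(tr.v2, tr.time)
    assert len(e1) == len(e2) == 3
    for a, b in zip(e1, e2):
        assert b.upstroke_time - a.upstroke_time == pytest.approx(25.0, abs=1.0)


def test_infinite_delay_stimulates_one_cell(shallow, fib24, short_spec):
    cfg = fm.build_motif(3, 0.0, 0.0)
    tr, roles = fm.run_pacing_response(cfg, short_spec, shallow, fib24)
    assert roles.pacing == "m1" and roles.response == "m2"
    assert len(tr.stim_times_m1) == short_spec.n_beats
    assert len(tr.stim_times_m2) == 0
    # fully uncoupled: the response cell never leaves rest
    assert np.all(np.abs(tr.v2 - tr.v2[0]) < 5.0)


def test_response_has_positive_latency(shallow, fib24):
    """Response-cell depolarizations trail the pacing-cell upstrokes."""
    spec = fm.PacingSpec(t1=600.0, n_beats=6, n_discard=3)
    cfg = fm.build_motif(3, 2.0, 2.0)
    tr, roles = fm.run_pacing_response(cfg, spec, shallow, fib24)
    e1 = metrics.detect_aps(tr.v1, tr.time)
    e2 = metrics.detect_aps(tr.v2, tr.time)
    assert len(e2) > 0
    for ev in e2:
        pre = [p for p in e1 if p.upstroke_time <= ev.upstroke_time]
        assert pre, "response AP with no preceding pacing AP"
        assert ev.upstroke_time - pre[-1].upstroke_time > 0.0


def test_strong_coupling_gives_one_to_one(shallow, fib24):
    spec = fm.PacingSpec(t1=600.0, n_beats=6, n_discard=3)
    cfg = fm.build_motif(3, 4.0, 4.0)
    tr, roles = fm.run_pacing_response(cfg, spec, shallow, fib24)
    fr = metrics.response_fraction(tr, roles, n_count=3)
    assert fr.response == 1.0 and fr.pacing == 1.0


def test_pace_m2_selects_other_cell(shallow, fib24, short_spec):
    cfg = fm.build_motif(2, 2.0, 2.0)
    tr, roles = fm.run_pacing_response(cfg, short_spec, shallow, fib24,
                                       pace="m2")
    assert roles.pacing == "m2" and roles.response == "m1"
    assert len(tr.stim_times_m2) == short_spec.n_beats
    assert len(tr.stim_times_m1) == 0


class TestS1S2:
    def test_long_di_reaches_full_recovery_plateau(self, restitution_shallow):
        """The curve plateaus at long DI (full recovery limit, within 2 ms)."""
        c = restitution_shallow
        order = np.argsort(c.di)
        di, apd = c.di[order], c.apd[order]
        assert di[-1] >= 1000.0
        assert apd[-1] == pytest.approx(apd[-2], abs=2.0)
        # full-recovery APD exceeds the accommodated steady-pacing APD
        assert apd[-1] > c.s1_apd

    def test_curve_monotone_over_physiological_range(self, restitution_shallow):
        """Away from the capture boundary (DI >= 30 ms) the raw curve rises."""
        di, apd = restitution_shallow.points()
        order = np.argsort(di)
        di, apd = di[order], apd[order]
        sel = di >= 30.0
        assert np.all(np.diff(apd[sel]) > -1.0)
        # the isotonic filter touches only the capture-boundary artifacts
        dm, am = restitution_shallow.monotone_points()
        assert np.all(np.diff(am) > -0.5)
        assert dm.size >= di[sel].size

    def test_steep_slope_exceeds_shallow(self, restitution_steep,
                                         restitution_shallow):
        assert restitution_steep.max_slope() > restitution_shallow.max_slope()

    def test_grid_refinement_stability(self, steep):
        """Halving the DI spacing in the convergence regime moves the max
        slope by < 5% (finite differences converge from below)."""
        coarse = list(np.arange(26.0, 81.0, 4.0)) + [100, 150, 300, 1000]
        fine = list(np.arange(26.0, 81.0, 2.0)) + [100, 150, 300, 1000]
        s_coarse = fm.s1s2_restitution(steep, di_grid=coarse).max_slope()
        s_fine = fm.s1s2_restitution(steep, di_grid=fine).max_slope()
        assert s_fine == pytest.approx(s_coarse, rel=0.05)


def test_apd_converges_under_dt_refinement(steep):
    """10x finer step changes APD90 by < 0.5 ms (solver accuracy contract)."""
    apds = {}
    for dt in (0.01, 0.001):
        spec = fm.PacingSpec(n_beats=1, n_discard=0, dt=dt)
        tr = fm.run_uncoupled_myocyte(steep, spec, stim_times=np.array([0.0]),
                                      t_end=450.0)
        apds[dt] = metrics.detect_aps(tr.v1, tr.time)[0].apd90
    assert abs(apds[0.01] - apds[0.001]) < 0.5
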
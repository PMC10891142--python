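"""Metric operations on analytic and constructed traces."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fibromotif as fm
from fibromotif import metrics
from fibromotif.errors import UndefinedMetricError
from fibromotif.protocols import Roles
from fibromotif.surrogate import make_fixture_trace


def _analytic_triangle_trace(dt=0.1):
    """Flat rest, instantaneous rise -85 -> +35 at t=100, linear fall over 300 ms."""
    t = np.arange(0.0, 600.0 + dt / 2, dt)
    v = np.full_like(t, -85.0)
    rise = t >= 100.0
    fall = (t >= 100.0) & (t <= 400.0)
    v[rise] = -85.0
    v[fall] = 35.0 - (35.0 + 85.0) * (t[fall] - 100.0) / 300.0
    return t, v


class TestDetect:
    def test_flat_series_has_no_events(self):
        t = np.arange(0, 1000, 0.1)
        assert metrics.detect_aps(np.full_like(t, -86.0), t) == []

    def test_analytic_triangle_apd90(self):
        """Linear 120 mV fall over 300 ms: APD90 = 270 ms (crossing at -73 mV)."""
        t, v = _analytic_triangle_trace()
        events = metrics.detect_aps(v, t)
        assert len(events) == 1
        ev = events[0]
        assert ev.peak_v == pytest.approx(35.0)
        assert ev.apd90 == pytest.approx(270.0, abs=0.2)

    def test_refractory_merges_close_excursions(self):
        t = np.arange(0, 300, 0.1)
        v = np.full_like(t, -85.0)
        v[(t >= 50) & (t < 70)] = 30.0    # main excursion
        v[(t >= 75) & (t < 90)] = 25.0    # notch re-crossing within refractory
        v[(t >= 200) & (t < 230)] = 30.0  # separate AP
        events = metrics.detect_aps(v, t, refractory_min=50.0)
        assert len(events) == 2

    def test_trailing_incomplete_ap_dropped(self):
        t = np.arange(0, 200, 0.1)
        v = np.full_like(t, -85.0)
        v[t >= 150] = 30.0  # AP still ongoing at the end of the record
        assert metrics.detect_aps(v, t) == []


class TestMeanApd:
    def test_constant_events(self):
        tr = make_fixture_trace([(k * 500.0, 300.0) for k in range(20)])
        events = metrics.detect_aps(tr.v1, tr.time)
        assert metrics.mean_apd(events, 10) == pytest.approx(300.0, abs=0.1)

    def test_alternating_events_average(self):
        apds = [280.0 if k % 2 else 300.0 for k in range(20)]
        tr = make_fixture_trace([(k * 500.0, a) for k, a in enumerate(apds)])
        events = metrics.detect_aps(tr.v1, tr.time)
        assert metrics.mean_apd(events, 10) == pytest.approx(290.0, abs=0.1)

    def test_too_few_events_is_undefined(self):
        tr = make_fixture_trace([(k * 500.0, 250.0) for k in range(5)])
        events = metrics.detect_aps(tr.v1, tr.time)
        with pytest.raises(UndefinedMetricError):
            metrics.mean_apd(events, 10)


class TestDeltaApd:
    def test_identical_traces_give_exact_zero(self):
        ev = [(k * 500.0, 260.0) for k in range(15)]
        tr = make_fixture_trace(ev, ev)
        assert metrics.delta_apd(tr) == 0.0

    def test_antisymmetry_under_cell_swap(self):
        e1 = [(k * 500.0, 300.0) for k in range(15)]
        e2 = [(k * 500.0 + 10.0, 260.0) for k in range(15)]
        tr = make_fixture_trace(e1, e2)
        tr_swapped = make_fixture_trace(e2, e1)
        d = metrics.delta_apd(tr)
        assert d == pytest.approx(40.0, abs=0.2)
        assert metrics.delta_apd(tr_swapped) == pytest.approx(-d, abs=1e-9)


class TestResponseFraction:
    def _trace(self, captured_every):
        stims = [k * 500.0 for k in range(10)]
        pacing = [(s + 2.0, 250.0) for s in stims]
        resp = [(s + 30.0, 200.0) for i, s in enumerate(stims)
                if i % captured_every == 0]
        tr = make_fixture_trace(pacing, resp, stim_times_m1=stims)
        return tr, Roles(pacing="m1")

    def test_full_capture(self):
        tr, roles = self._trace(1)
        fr = metrics.response_fraction(tr, roles)
        assert fr.response == 1.0 and fr.pacing == 1.0

    def test_no_capture(self):
        stims = [k * 500.0 for k in range(10)]
        tr = make_fixture_trace([(s + 2.0, 250.0) for s in stims], [],
                                stim_times_m1=stims)
        fr = metrics.response_fraction(tr, Roles(pacing="m1"))
        assert fr.response == 0.0 and fr.pacing == 1.0

    def test_alternate_capture_is_half_and_ir(self):
        tr, roles = self._trace(2)
        fr = metrics.response_fraction(tr, roles)
        assert fr.response == 0.5
        assert metrics.classify_regime(fr.response).regime is fm.Regime.IR

    def test_no_stimuli_is_undefined(self):
        tr = make_fixture_trace([(10.0, 200.0)], [])
        with pytest.raises(UndefinedMetricError):
            metrics.response_fraction(tr, Roles(pacing="m1"))


class TestClassify:
    @pytest.mark.parametrize("frac, regime", [
        (0.0, fm.Regime.NR), (1.0, fm.Regime.ONE_TO_ONE),
        (0.3, fm.Regime.IR), (0.999, fm.Regime.IR),
    ])
    def test_mapping(self, frac, regime):
        assert metrics.classify_regime(frac).regime is regime

    @pytest.mark.parametrize("bad", [-0.1, 1.1, 2.0])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            metrics.classify_regime(bad)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0))
    def test_partition_is_exhaustive_and_exclusive(self, frac):
        label = metrics.classify_regime(frac)
        matches = [label.regime is fm.Regime.NR,
                   label.regime is fm.Regime.IR,
                   label.regime is fm.Regime.ONE_TO_ONE]
        assert sum(matches) == 1
        assert (label.regime is fm.Regime.NR) == (frac == 0.0)
        assert (label.regime is fm.Regime.ONE_TO_ONE) == (frac == 1.0)


class TestRestitutionSlope:
    def test_linear_curve(self):
        di = np.arange(20.0, 400.0, 20.0)
        assert metrics.max_restitution_slope(di, 200.0 + 0.5 * di) == \
            pytest.approx(0.5)

    def test_translation_invariance(self):
        di = np.array([20, 40, 60, 100, 150, 300.0])
        apd = 320.0 - 140.0 * np.exp(-di / 80.0)
        s1 = metrics.max_restitution_slope(di, apd)
        s2 = metrics.max_restitution_slope(di + 50.0, apd)
        assert s1 == pytest.approx(s2)

    def test_too_few_points_undefined(self):
        with pytest.raises(UndefinedMetricError):
            metrics.max_restitution_slope([10.0, 20.0], [100.0, 120.0])

    @settings(max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=1.0, max_value=1000.0),
                    min_size=4, max_size=12, unique=True))
    def test_slope_bounds_secants(self, dis):
        """The max centered slope is bounded by the max adjacent secant."""
        di = np.sort(np.array(dis))
        apd = 320.0 - 140.0 * np.exp(-di / 80.0)
        s = metrics.max_restitution_slope(di, apd)
        secants = np.diff(apd) / np.diff(di)
        assert s <= secants.max() + 1e-12
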
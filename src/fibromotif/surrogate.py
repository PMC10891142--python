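"""Closed-form surrogate cells and ground-truth fixture traces.

The surrogate myocyte is a deterministic two-regime excitable unit: below
threshold it relaxes to rest with time constant ``tau_m`` and integrates
external current; on crossing threshold it emits a square action potential
(plateau at ``v_peak`` followed by a short linear repolarization ramp) whose
APD90 equals the prescribed restitution law

    APD(DI) = apd_max - apd_amp * exp(-DI / tau_rest)

evaluated at the true preceding diastolic interval.  Because the law is
closed form, the surrogate doubles as a brute-force oracle for every metric
in the package; it makes no claim of biophysical fidelity and is never used
for quantitative study results.

The surrogate fibroblast stand-in is a passive RC node.  Both plug into the
same motif coupling algebra as the biophysical models, so the whole
motif -> protocol -> metrics -> sweep pipeline can run end-to-end in
milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidStateError
from .motif import MotifConfig
from .protocols import INFINITE, PacingSpec, Roles, SimulationTrace

__all__ = [
    "SurrogateParams", "SurrogatePassiveParams", "SurrogateCell",
    "PassiveCell", "surrogate_rhs", "run_surrogate_paced",
    "run_surrogate_pacing_response", "make_fixture_trace",
]


@dataclass(frozen=True)
class SurrogateParams:
    """Excitable surrogate with prescribed restitution (all mV / ms)."""

    v_rest: float = -85.0
    v_peak: float = 30.0
    apd_max: float = 300.0
    apd_amp: float = 150.0
    tau_rest: float = 100.0
    threshold: float = -55.0
    refractory: float = 50.0
    tau_m: float = 10.0
    ramp: float = 5.0

    def __post_init__(self):
        if not self.v_rest < self.threshold < self.v_peak:
            raise ValueError("need v_rest < threshold < v_peak")
        if self.apd_amp >= self.apd_max:
            raise ValueError("restitution law must keep APD positive")

    def apd(self, di: float) -> float:
        """Prescribed APD90 as a function of the diastolic interval."""
        return self.apd_max - self.apd_amp * math.exp(-di / self.tau_rest)


@dataclass(frozen=True)
class SurrogatePassiveParams:
    """Passive RC stand-in for the fibroblast unit."""

    v_rest: float = -24.5
    tau_m: float = 20.0


class SurrogateCell:
    """Stateful stepper for :class:`SurrogateParams`."""

    def __init__(self, params: SurrogateParams):
        self.p = params
        self.v = params.v_rest
        self.firing = False
        self.t_fire = -1e12
        self.apd_now = params.apd_max
        self.t_last_rep = -1e12
        self.upstrokes: list[float] = []

    def step(self, t: float, i_ext: float, dt: float) -> None:
        p = self.p
        if self.firing:
            t_ramp0 = self.t_fire + self.apd_now - 0.9 * p.ramp
            tn = t + dt
            if tn <= t_ramp0:
                self.v = p.v_peak
            elif tn < t_ramp0 + p.ramp:
                self.v = p.v_peak - (p.v_peak - p.v_rest) * (tn - t_ramp0) / p.ramp
            else:
                self.v = p.v_rest
                self.firing = False
                self.t_last_rep = self.t_fire + self.apd_now
            return
        self.v += dt * ((p.v_rest - self.v) / p.tau_m + i_ext)
        if self.v >= p.threshold and (t + dt) - self.t_last_rep >= p.refractory:
            di = (t + dt) - self.t_last_rep
            self.apd_now = p.apd(di) if self.t_last_rep > -1e11 else p.apd_max
            self.firing = True
            self.t_fire = t + dt
            self.upstrokes.append(t + dt)
            self.v = p.v_peak


class PassiveCell:
    def __init__(self, params: SurrogatePassiveParams):
        self.p = params
        self.v = params.v_rest

    def step(self, t: float, i_ext: float, dt: float) -> None:
        self.v += dt * ((self.p.v_rest - self.v) / self.p.tau_m + i_ext)


def surrogate_rhs(state: float, params: SurrogateParams,
                  i_ext: float = 0.0) -> float:
    """Subthreshold derivative of the surrogate membrane potential.

    The discontinuous firing rule (threshold crossing -> square AP) lives in
    :class:`SurrogateCell`; this is the smooth part only.
    """
    if not math.isfinite(state):
        raise InvalidStateError("non-finite surrogate state")
    return (params.v_rest - state) / params.tau_m + i_ext


def _surrogate_schedules(spec: PacingSpec, pace: str | None):
    k = np.arange(spec.n_beats, dtype=float)
    s1 = k * spec.t1
    s2 = np.empty(0) if math.isinf(spec.tau_d) else k * spec.period2 + spec.tau_d
    if pace == "m1":
        s2 = np.empty(0)
    elif pace == "m2":
        s1, s2 = np.empty(0), k * spec.period2
    return s1, s2


def run_surrogate_paced(config: MotifConfig, spec: PacingSpec,
                        myo_params: SurrogateParams | None = None,
                        fib_params: SurrogatePassiveParams | None = None,
                        pace: str | None = None,
                        c_m: float = 150.0, c_f: float = 50.0) -> SimulationTrace:
    """Surrogate counterpart of :func:`fibromotif.protocols.run_paced`."""
    mp = myo_params or SurrogateParams()
    fp = fib_params or SurrogatePassiveParams()
    m1, m2 = SurrogateCell(mp), SurrogateCell(mp)
    f1, f2 = PassiveCell(fp), PassiveCell(fp)

    s1, s2 = _surrogate_schedules(spec, pace)
    dt = spec.dt
    longest = max(spec.t1, spec.period2)
    t_end = (spec.n_beats - 1) * longest + (
        0.0 if math.isinf(spec.tau_d) else spec.tau_d) + longest
    n_steps = int(round(t_end / dt))
    sample_every = max(1, int(round(spec.sample_dt / dt)))
    dur_steps = max(1, int(round(spec.stim_duration / dt)))
    st1 = set(int(round(x / dt)) for x in s1)
    st2 = set(int(round(x / dt)) for x in s2)
    on1 = on2 = 0

    gl1, gl2, gg1, gg2 = config.conductances()
    nf = config.n_f
    n_out = n_steps // sample_every + 1
    vout = np.empty((4, n_out))
    vout[:, 0] = (m1.v, m2.v, f1.v, f2.v)
    for step in range(n_steps):
        if step in st1:
            on1 = dur_steps
        if step in st2:
            on2 = dur_steps
        stim1 = spec.stim_amplitude if on1 > 0 else 0.0
        stim2 = spec.stim_amplitude if on2 > 0 else 0.0
        on1 = max(0, on1 - 1)
        on2 = max(0, on2 - 1)
        t = step * dt
        v1, v2, vf1, vf2 = m1.v, m2.v, f1.v, f2.v
        i1 = stim1 + nf * (gl1 * (vf1 - v1) + gg1 * (vf2 - v1)) / c_m
        i2 = stim2 + nf * (gl2 * (vf2 - v2) + gg2 * (vf1 - v2)) / c_m
        j1 = (gl1 * (v1 - vf1) + gg2 * (v2 - vf1)) / c_f
        j2 = (gl2 * (v2 - vf2) + gg1 * (v1 - vf2)) / c_f
        m1.step(t, i1, dt)
        m2.step(t, i2, dt)
        f1.step(t, j1, dt)
        f2.step(t, j2, dt)
        if (step + 1) % sample_every == 0:
            vout[:, (step + 1) // sample_every] = (m1.v, m2.v, f1.v, f2.v)

    time = np.arange(n_out) * (sample_every * dt)
    return SimulationTrace(time=time, v1=vout[0], v2=vout[1],
                           vf1=vout[2], vf2=vout[3],
                           stim_times_m1=s1, stim_times_m2=s2,
                           meta={"config": config, "spec": spec, "pace": pace,
                                 "surrogate": True})


def run_surrogate_pacing_response(config: MotifConfig, spec: PacingSpec,
                                  myo_params: SurrogateParams | None = None,
                                  fib_params: SurrogatePassiveParams | None = None,
                                  pace: str = "m1"):
    spec = replace(spec, tau_d=INFINITE)
    trace = run_surrogate_paced(config, spec, myo_params, fib_params, pace=pace)
    return trace, Roles(pacing=pace)


def make_fixture_trace(events_m1, events_m2=None,
                       stim_times_m1=None, stim_times_m2=None,
                       t_end: float | None = None, dt: float = 0.1,
                       v_rest: float = -85.0, v_peak: float = 35.0,
                       ramp: float = 5.0) -> SimulationTrace:
    """Piecewise-linear trace with exactly known AP times and APD90s.

    ``events_m?`` are lists of ``(upstroke_time, apd90)``; each AP rises
    instantaneously to ``v_peak`` and repolarizes linearly such that the 90%
    crossing (relative to the resting baseline) falls exactly at
    ``upstroke_time + apd90``.  Overlapping APs raise ``ValueError``.
    """
    def _series(events):
        events = sorted(events)
        for (u0, a0), (u1, _a1) in zip(events, events[1:]):
            if u0 + a0 + 0.1 * ramp >= u1:
                raise ValueError("overlapping action potentials in fixture spec")
        v = np.full(n, v_rest)
        for u, apd in events:
            if apd <= 0.9 * ramp:
                raise ValueError("APD too short for the repolarization ramp")
            t0 = u + apd - 0.9 * ramp   # ramp start; 90% crossing at u + apd
            i_up = int(np.ceil(u / dt))
            i_r0 = int(np.floor(t0 / dt))
            v[i_up:i_r0 + 1] = v_peak
            i_r1 = int(np.ceil((t0 + ramp) / dt))
            for i in range(i_r0 + 1, min(i_r1, n - 1) + 1):
                frac = (i * dt - t0) / ramp
                v[i] = v_peak - (v_peak - v_rest) * min(1.0, frac)
        return v

    all_ev = list(events_m1) + list(events_m2 or [])
    if t_end is None:
        t_end = max((u + a for u, a in all_ev), default=0.0) + 100.0
        if stim_times_m1 is not None and len(stim_times_m1):
            t_end = max(t_end, float(np.max(stim_times_m1)) + 100.0)
    n = int(round(t_end / dt)) + 1
    time = np.arange(n) * dt
    v1 = _series(events_m1)
    v2 = _series(events_m2) if events_m2 is not None else None
    return SimulationTrace(
        time=time, v1=v1, v2=v2,
        stim_times_m1=np.asarray(stim_times_m1 if stim_times_m1 is not None else [], float),
        stim_times_m2=np.asarray(stim_times_m2 if stim_times_m2 is not None else [], float),
        meta={"fixture": True})
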
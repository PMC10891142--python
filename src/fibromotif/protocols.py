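"""Stimulation protocols: periodic pacing, pacing/response, S1S2 restitution.

All protocols start from uncoupled resting states (quiescence-equilibrated
myocytes; calibration-settled fibroblasts), stimulate with 1-ms pulses of
52 pA/pF (positive-depolarizing), and integrate with the fixed-step
Rush-Larsen/Euler scheme at dt = 0.01 ms, sampling output every 0.1 ms.
Stimulus onsets are snapped to the integration grid (exact to < dt).

The infinite-delay protocol stimulates exactly one myocyte (the *pacing
cell*); the other (*response cell*) can only be excited through the
fibroblast pathway.  S1S2 restitution preconditions with an S1 train and
delivers one S2 per requested diastolic interval, measured from the 90%
repolarization of the last S1 beat (DI-controlled S2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import _engine as engine
from . import metrics
from .cell_models import (
    FibroblastParams,
    MyocyteParams,
    resting_fibroblast_state,
    resting_myocyte_state,
)
from .errors import SolverError
from .motif import MotifConfig, pack_state

__all__ = [
    "INFINITE", "PacingSpec", "SimulationTrace", "Roles",
    "run_paced", "run_pacing_response", "run_uncoupled_myocyte",
    "s1s2_restitution", "RestitutionCurve",
]

#: Sentinel pacing delay: the second myocyte is never stimulated.
INFINITE = math.inf


@dataclass(frozen=True)
class PacingSpec:
    """Pacing periods, delay, beat counts and stimulus/solver settings."""

    t1: float = 600.0            # ms, pacing period of myocyte-1
    t2: float | None = None      # ms, myocyte-2 period (defaults to t1)
    tau_d: float = 0.0           # ms delay of myocyte-2 stimuli, or INFINITE
    n_beats: int = 20
    n_discard: int = 10
    stim_amplitude: float = 52.0  # pA/pF, positive depolarizes
    stim_duration: float = 1.0    # ms
    dt: float = 0.01              # ms, integration step
    sample_dt: float = 0.1        # ms, output sampling

    def __post_init__(self):
        if self.n_discard >= self.n_beats:
            raise ValueError("n_discard must be smaller than n_beats")
        if self.t1 <= 0 or (self.t2 is not None and self.t2 <= 0):
            raise ValueError("pacing periods must be positive")
        if self.tau_d < 0:
            raise ValueError("tau_d must be non-negative (or INFINITE)")

    @property
    def period2(self) -> float:
        return self.t1 if self.t2 is None else self.t2


@dataclass
class SimulationTrace:
    """Uniformly sampled voltages for the four cells plus stimulus times."""

    time: np.ndarray
    v1: np.ndarray
    v2: np.ndarray | None = None
    vf1: np.ndarray | None = None
    vf2: np.ndarray | None = None
    stim_times_m1: np.ndarray = field(default_factory=lambda: np.empty(0))
    stim_times_m2: np.ndarray = field(default_factory=lambda: np.empty(0))
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("trace time grid must be strictly increasing")
        for v in (self.v1, self.v2, self.vf1, self.vf2):
            if v is not None and len(v) != len(self.time):
                raise ValueError("trace series lengths must match the time grid")

    def voltage(self, cell: str) -> np.ndarray:
        v = {"m1": self.v1, "m2": self.v2, "f1": self.vf1, "f2": self.vf2}[cell]
        if v is None:
            raise KeyError(f"trace holds no series for cell {cell!r}")
        return v

    def stim_times(self, cell: str) -> np.ndarray:
        return {"m1": self.stim_times_m1, "m2": self.stim_times_m2}[cell]

    def to_frame(self):
        import pandas as pd

        data = {"time": self.time, "v1": self.v1}
        for name in ("v2", "vf1", "vf2"):
            v = getattr(self, name)
            if v is not None:
                data[name] = v
        return pd.DataFrame(data)


@dataclass(frozen=True)
class Roles:
    """Role assignment of the infinite-delay protocol."""

    pacing: str   # "m1" or "m2"

    @property
    def response(self) -> str:
        return "m2" if self.pacing == "m1" else "m1"


def _stim_steps(times_ms: np.ndarray, dt: float) -> np.ndarray:
    return np.asarray(np.round(np.asarray(times_ms, float) / dt), dtype=np.int64)


def _schedules(spec: PacingSpec, pace: str | None = None):
    """Stimulus onset times (ms) for both myocytes.

    ``pace`` restricts stimulation to one myocyte (infinite-delay protocol).
    """
    k = np.arange(spec.n_beats, dtype=float)
    s1 = k * spec.t1
    if math.isinf(spec.tau_d):
        s2 = np.empty(0)
    else:
        s2 = k * spec.period2 + spec.tau_d
    if pace == "m1":
        s2 = np.empty(0)
    elif pace == "m2":
        s1, s2 = np.empty(0), k * spec.period2
    return s1, s2


def run_paced(config: MotifConfig, spec: PacingSpec,
              myo_params: MyocyteParams, fib_params: FibroblastParams,
              initial_state: np.ndarray | None = None,
              pace: str | None = None,
              t_extra: float | None = None) -> SimulationTrace:
    """Periodically paced motif simulation from uncoupled resting states.

    Myocyte-1 is stimulated at k*T1, myocyte-2 at k*T2 + tau_D (never, if
    tau_D is INFINITE).  The trace extends one pacing period past the last
    stimulus so the final action potential repolarizes on record.
    """
    if initial_state is None:
        m0 = resting_myocyte_state(myo_params)
        f0 = resting_fibroblast_state(fib_params)
        y = pack_state(m0, m0, f0, f0)
    else:
        y = np.array(initial_state, dtype=float)

    s1, s2 = _schedules(spec, pace)
    dt = spec.dt
    longest = max(spec.t1, spec.period2)
    t_end = (spec.n_beats - 1) * longest + (
        0.0 if math.isinf(spec.tau_d) else spec.tau_d)
    t_end += longest if t_extra is None else t_extra
    n_steps = int(round(t_end / dt))
    sample_every = max(1, int(round(spec.sample_dt / dt)))
    dur_steps = max(1, int(round(spec.stim_duration / dt)))

    try:
        vout = engine.run_motif(
            y, myo_params.vector(), fib_params.vector(),
            config.g_loc1, config.g_loc2, config.g_long1, config.g_long2,
            float(config.n_f), myo_params.c_m, fib_params.c_f,
            _stim_steps(s1, dt), _stim_steps(s2, dt), dur_steps,
            spec.stim_amplitude, n_steps, dt, sample_every)
    except ValueError as exc:
        raise SolverError(str(exc), last_state=y) from exc

    t = np.arange(vout.shape[1]) * (sample_every * dt)
    return SimulationTrace(
        time=t, v1=vout[0], v2=vout[1], vf1=vout[2], vf2=vout[3],
        stim_times_m1=s1, stim_times_m2=s2,
        meta={"config": config, "spec": spec,
              "final_state": y, "pace": pace})


def run_pacing_response(config: MotifConfig, spec: PacingSpec,
                        myo_params: MyocyteParams,
                        fib_params: FibroblastParams,
                        pace: str = "m1") -> tuple[SimulationTrace, Roles]:
    """Infinite-delay protocol: stimulate one myocyte, observe the other."""
    if pace not in ("m1", "m2"):
        raise ValueError("pace must be 'm1' or 'm2'")
    spec = replace(spec, tau_d=INFINITE)
    trace = run_paced(config, spec, myo_params, fib_params, pace=pace)
    return trace, Roles(pacing=pace)


def run_uncoupled_myocyte(myo_params: MyocyteParams, spec: PacingSpec,
                          initial_state: np.ndarray | None = None,
                          stim_times: np.ndarray | None = None,
                          t_end: float | None = None) -> SimulationTrace:
    """Single uncoupled myocyte paced at T1 (reference / restitution runs)."""
    y = (resting_myocyte_state(myo_params) if initial_state is None
         else np.array(initial_state, dtype=float))
    if stim_times is None:
        stim_times = np.arange(spec.n_beats, dtype=float) * spec.t1
    if t_end is None:
        t_end = (spec.n_beats) * spec.t1 + spec.t1
    dt = spec.dt
    sample_every = max(1, int(round(spec.sample_dt / dt)))
    dur_steps = max(1, int(round(spec.stim_duration / dt)))
    try:
        v = engine.run_myocyte(y, myo_params.vector(),
                               _stim_steps(stim_times, dt), dur_steps,
                               spec.stim_amplitude, int(round(t_end / dt)),
                               dt, sample_every)
    except ValueError as exc:
        raise SolverError(str(exc), last_state=y) from exc
    t = np.arange(v.size) * (sample_every * dt)
    return SimulationTrace(time=t, v1=v, stim_times_m1=np.asarray(stim_times, float),
                           meta={"spec": spec, "final_state": y})


# ---------------------------------------------------------------------------
# S1S2 restitution
# ---------------------------------------------------------------------------

# 2.5 ms spacing over the short-DI limb (where the slope peaks and the
# finite-difference estimate converges from below), sparser beyond.
_DEFAULT_DI_GRID = tuple(
    [5.0 + 2.5 * k for k in range(31)]     # 5 .. 80 ms
    + [85, 90, 95, 100, 115, 130, 150, 175, 200, 250, 300, 400, 500, 700, 1000])


@dataclass
class RestitutionCurve:
    """S2 APD90 versus preceding diastolic interval.

    ``captured`` marks S2 beats whose AP amplitude reached the capture
    fraction of the steady S1 amplitude; graded near-refractory responses
    are kept in the record but excluded from slope computation.
    """

    di: np.ndarray
    apd: np.ndarray
    amp_frac: np.ndarray
    captured: np.ndarray
    s1_apd: float
    t_s1: float

    def points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.di[self.captured], self.apd[self.captured]

    def monotone_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Captured points with all-or-none boundary artifacts removed.

        APD restitution is non-decreasing in DI over the physiological
        range; isolated dips (all-or-none loss of the dome near a capture
        boundary) would otherwise inject spurious rebound slopes.  A point
        below the running maximum of the curve is such an artifact and is
        dropped (isotonic filter).
        """
        di, apd = self.points()
        order = np.argsort(di)
        di, apd = di[order], apd[order]
        keep = np.ones(di.size, dtype=bool)
        running = -np.inf
        for i, a in enumerate(apd):
            if a < running - 0.5:   # 0.5 ms tolerance for sampling noise
                keep[i] = False
            else:
                running = max(running, a)
        return di[keep], apd[keep]

    def max_slope(self) -> float:
        return metrics.max_restitution_slope(*self.monotone_points())


def s1s2_restitution(myo_params: MyocyteParams, t_s1: float = 600.0,
                     di_grid=None, n_s1: int = 10,
                     capture_fraction: float = 0.7,
                     spec: PacingSpec | None = None) -> RestitutionCurve:
    """S1S2 restitution of the uncoupled myocyte at S1 period ``t_s1``.

    After ``n_s1`` preconditioning S1 beats the S2 stimulus is delivered at
    the 90% repolarization time of the last S1 beat plus the requested DI;
    the recorded DI is re-measured from the trace (S2 upstroke minus S1
    repolarization), so it reflects the true recovery time.
    """
    if di_grid is None:
        di_grid = _DEFAULT_DI_GRID
    base = spec or PacingSpec(t1=t_s1, n_beats=max(n_s1, 2), n_discard=1)
    base = replace(base, t1=t_s1, n_beats=max(n_s1, 2), n_discard=1)
    s1_times = np.arange(n_s1, dtype=float) * t_s1

    pre = run_uncoupled_myocyte(myo_params, base, stim_times=s1_times,
                                t_end=n_s1 * t_s1)
    events = metrics.detect_aps(pre.v1, pre.time)
    if len(events) < n_s1:
        raise SolverError("S1 preconditioning lost capture")
    last = events[-1]
    s1_apd = last.apd90
    s1_amp = last.peak_v - last.dia_v
    rep_last = last.rep90_time

    di_out, apd_out, frac_out, cap_out = [], [], [], []
    for di in di_grid:
        t_s2 = rep_last + float(di)
        stim = np.append(s1_times, t_s2)
        tr = run_uncoupled_myocyte(myo_params, base, stim_times=stim,
                                   t_end=t_s2 + 800.0)
        evs = [e for e in metrics.detect_aps(tr.v1, tr.time)
               if e.upstroke_time >= t_s2 - 1.0]
        if not evs:
            di_out.append(float(di))
            apd_out.append(np.nan)
            frac_out.append(0.0)
            cap_out.append(False)
            continue
        ev = evs[0]
        di_out.append(ev.upstroke_time - rep_last)
        apd_out.append(ev.apd90)
        frac = (ev.peak_v - ev.dia_v) / s1_amp
        frac_out.append(frac)
        cap_out.append(bool(frac >= capture_fraction))

    return RestitutionCurve(
        di=np.array(di_out), apd=np.array(apd_out),
        amp_frac=np.array(frac_out), captured=np.array(cap_out, dtype=bool),
        s1_apd=s1_apd, t_s1=t_s1)
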
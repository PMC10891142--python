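"""Trace analysis: AP detection, APD90, delta-APD, response fractions, regimes.

An action potential is a contiguous supra-threshold excursion of the
membrane potential (threshold -20 mV by default — fibroblast-mediated
subthreshold depolarizations never count as APs).  APD90 runs from the
interpolated threshold crossing of the upstroke to the 90% repolarization
level, where the AP amplitude is measured from the event's own peak down to
the preceding diastolic minimum (robust when coupling elevates diastolic V).

Regimes of the infinite-delay protocol are classified from the fraction of
pacing-cell stimuli that elicit a response-cell AP within one pacing period:
NR (fraction 0), 1:1 (fraction 1) and IR (anything in between).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import UndefinedMetricError

__all__ = [
    "APEvent", "Regime", "RegimeLabel", "ResponseFractions",
    "detect_aps", "mean_apd", "delta_apd", "response_fraction",
    "classify_regime", "max_restitution_slope",
    "DEFAULT_THRESHOLD", "DEFAULT_REFRACTORY",
]

DEFAULT_THRESHOLD = -20.0   # mV
DEFAULT_REFRACTORY = 50.0   # ms minimum event separation


@dataclass(frozen=True)
class APEvent:
    """One detected action potential."""

    upstroke_time: float
    peak_time: float
    peak_v: float
    dia_v: float
    rep90_time: float
    apd90: float
    stim_index: int | None = None

    def __post_init__(self):
        if self.apd90 <= 0:
            raise ValueError("APD90 must be positive")


class Regime(str, Enum):
    NR = "NR"
    IR = "IR"
    ONE_TO_ONE = "1:1"


@dataclass(frozen=True)
class RegimeLabel:
    regime: Regime
    response_fraction: float


def _interp_crossing(t0, t1, v0, v1, level):
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def detect_aps(v: np.ndarray, time: np.ndarray,
               threshold_v: float = DEFAULT_THRESHOLD,
               refractory_min: float = DEFAULT_REFRACTORY,
               stim_times: np.ndarray | None = None) -> list[APEvent]:
    """Action potentials in a uniformly sampled voltage series.

    One event per supra-threshold excursion separated by at least
    ``refractory_min`` ms; events whose repolarization is not on record
    (trace ends mid-AP) are dropped.  When ``stim_times`` is given each
    event is attributed to the latest stimulus at or before its upstroke.
    """
    v = np.asarray(v, float)
    time = np.asarray(time, float)
    if v.size != time.size:
        raise ValueError("series lengths differ")
    if v.size < 2:
        return []

    above = v > threshold_v
    rises = np.flatnonzero(~above[:-1] & above[1:])
    if above[0]:
        rises = np.concatenate([[0], rises])
    events: list[APEvent] = []
    last_up = -np.inf
    prev_rep_idx = 0
    for n, i in enumerate(rises):
        up_t = (time[0] if i == 0 and above[0] else
                _interp_crossing(time[i], time[i + 1], v[i], v[i + 1], threshold_v))
        if up_t - last_up < refractory_min:
            continue
        j_end = rises[n + 1] if n + 1 < len(rises) else v.size - 1
        seg = v[i:j_end + 1]
        ipk = int(np.argmax(seg))
        peak_v = float(seg[ipk])
        peak_idx = i + ipk
        dia_v = float(np.min(v[prev_rep_idx:i + 1])) if i > prev_rep_idx else float(v[i])
        v90 = peak_v - 0.9 * (peak_v - dia_v)
        post = v[peak_idx:j_end + 1]
        below = np.flatnonzero(post < v90)
        if below.size == 0:
            continue  # repolarization not on record
        k = peak_idx + below[0]
        rep_t = _interp_crossing(time[k - 1], time[k], v[k - 1], v[k], v90)
        stim_index = None
        if stim_times is not None and len(stim_times):
            idx = int(np.searchsorted(stim_times, up_t, side="right")) - 1
            stim_index = idx if idx >= 0 else None
        events.append(APEvent(upstroke_time=float(up_t),
                              peak_time=float(time[peak_idx]),
                              peak_v=peak_v, dia_v=dia_v,
                              rep90_time=float(rep_t),
                              apd90=float(rep_t - up_t),
                              stim_index=stim_index))
        last_up = up_t
        prev_rep_idx = k
    return events


def mean_apd(events: list[APEvent], n_discard: int = 10) -> float:
    """Mean APD90 over the events after the first ``n_discard``."""
    if len(events) < n_discard + 1:
        raise UndefinedMetricError(
            f"need more than {n_discard} APs to average, got {len(events)}")
    return float(np.mean([e.apd90 for e in events[n_discard:]]))


def delta_apd(trace, n_discard: int = 10,
              threshold_v: float = DEFAULT_THRESHOLD,
              refractory_min: float = DEFAULT_REFRACTORY) -> float:
    """Mean APD90 of myocyte-1 minus mean APD90 of myocyte-2."""
    e1 = detect_aps(trace.voltage("m1"), trace.time, threshold_v, refractory_min)
    e2 = detect_aps(trace.voltage("m2"), trace.time, threshold_v, refractory_min)
    return mean_apd(e1, n_discard) - mean_apd(e2, n_discard)


@dataclass(frozen=True)
class ResponseFractions:
    """Per-stimulus capture fractions of the infinite-delay protocol."""

    pacing: float
    response: float
    n_stimuli: int


def response_fraction(trace, roles, capture_window: float | None = None,
                      n_count: int = 10,
                      threshold_v: float = DEFAULT_THRESHOLD,
                      refractory_min: float = DEFAULT_REFRACTORY) -> ResponseFractions:
    """Fractions of pacing stimuli answered by an AP within the window.

    Only the last ``n_count`` pacing stimuli are scored (the transient is
    discarded).  ``capture_window`` defaults to the pacing period, so each
    response is attributed to the most recent stimulus.  The pacing cell is
    scored the same way against its own APs (at rapid pacing it, too, can
    drop beats).
    """
    stims = np.asarray(trace.stim_times(roles.pacing), float)
    if stims.size == 0:
        raise UndefinedMetricError("no stimuli delivered to the pacing cell")
    if capture_window is None:
        if stims.size < 2:
            raise UndefinedMetricError("capture window underdetermined")
        capture_window = float(stims[1] - stims[0])
    stims = stims[-n_count:]

    def _frac(cell: str) -> float:
        ups = np.array([e.upstroke_time for e in
                        detect_aps(trace.voltage(cell), trace.time,
                                   threshold_v, refractory_min)])
        hits = 0
        for s in stims:
            if ups.size and np.any((ups > s) & (ups <= s + capture_window)):
                hits += 1
        return hits / stims.size

    return ResponseFractions(pacing=_frac(roles.pacing),
                             response=_frac(roles.response),
                             n_stimuli=int(stims.size))


def classify_regime(fraction: float) -> RegimeLabel:
    """Exact regime mapping: 0 -> NR, 1 -> 1:1, in between -> IR."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"response fraction {fraction} outside [0, 1]")
    if fraction == 0.0:
        regime = Regime.NR
    elif fraction == 1.0:
        regime = Regime.ONE_TO_ONE
    else:
        regime = Regime.IR
    return RegimeLabel(regime=regime, response_fraction=float(fraction))


def max_restitution_slope(di: np.ndarray, apd: np.ndarray) -> float:
    """Maximum centered finite-difference slope dAPD/dDI of a curve."""
    di = np.asarray(di, float)
    apd = np.asarray(apd, float)
    ok = np.isfinite(di) & np.isfinite(apd)
    di, apd = di[ok], apd[ok]
    if di.size < 3:
        raise UndefinedMetricError("need at least 3 captured points for a slope")
    order = np.argsort(di)
    di, apd = di[order], apd[order]
    slopes = (apd[2:] - apd[:-2]) / (di[2:] - di[:-2])
    return float(np.max(slopes))
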
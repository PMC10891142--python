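"""Single-cell electrophysiology: ventricular myocyte and active fibroblast.

The myocyte is the ten Tusscher-Panfilov 2006 (TP06) epicardial human
ventricular cell: 19 state variables (membrane potential, 12 Hodgkin-Huxley
gates, the ryanodine-receptor adaptation variable and intracellular
Na+/K+/Ca2+ concentrations) and 12 sarcolemmal currents.  Two parameter
variants are provided, ``Shallow`` and ``Steep``, which differ in the
plateau-current conductances G_pCa and G_pK and correspond to the published
shallow (slope 0.7) and steep (slope 1.8) restitution parameter sets of the
source model.

The fibroblast is the MacCannell "active" fibroblast: membrane potential
plus activation/inactivation gates of the time- and voltage-dependent K+
current I_fKv, with I_fK1, an Na+/K+ pump and a background Na+ current.
Its resting potential is tuned by rigidly shifting the I_fKv gating curves
along the voltage axis (``kv_shift``); :func:`calibrate_kv_shift` solves for
the shift that yields a requested resting potential V_FR.

Units: mV, ms, mM; ionic currents are densities in pA/pF so dV/dt = -I_ion
+ I_ext is in mV/ms.  External currents ``I_ext`` are positive-depolarizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from enum import Enum
from functools import lru_cache

import numpy as np

from . import _engine as engine
from ._engine import (
    FIB_STATE_NAMES,
    MYO_STATE_NAMES,
    N_FIB,
    N_MYO,
    STATE_LAYOUT_VERSION,
)
from .errors import CalibrationError, InvalidStateError

__all__ = [
    "Variant",
    "MyocyteParams",
    "FibroblastParams",
    "myocyte_rhs",
    "fibroblast_rhs",
    "validate_myocyte_state",
    "validate_fibroblast_state",
    "resting_myocyte_state",
    "resting_fibroblast_state",
    "steady_state",
    "SteadyStateResult",
    "calibrate_kv_shift",
    "fibroblast_params_for_vfr",
    "MYO_STATE_NAMES",
    "FIB_STATE_NAMES",
    "STATE_LAYOUT_VERSION",
]


class Variant(str, Enum):
    """Restitution variant of the ventricular parameter set."""

    SHALLOW = "shallow"
    STEEP = "steep"


@dataclass(frozen=True)
class MyocyteParams:
    """Maximal conductances / scaling factors of the 12 TP06 currents.

    Conductances are in nS/pF (the model's native densities); ``c_m`` is the
    whole-cell capacitance used for the gap-junctional coupling terms.
    ``tau_f_scale`` multiplies the ICaL f-gate time constant for V > 0 and is
    1 for both study variants (kept as an explicit kinetics knob).
    """

    g_na: float = 14.838
    g_k1: float = 5.405
    g_to: float = 0.294
    g_kr: float = 0.153
    g_ks: float = 0.392
    g_cal: float = 3.98e-5
    k_naca: float = 1000.0
    p_nak: float = 2.724
    g_pca: float = 0.1238
    g_pk: float = 0.0146
    g_bna: float = 0.00029
    g_bca: float = 0.000592
    tau_f_scale: float = 1.0
    c_m: float = 150.0  # pF, fixed by the study
    variant: Variant | None = None

    @classmethod
    def shallow(cls) -> "MyocyteParams":
        return cls(g_pca=0.0619, g_pk=0.0730, variant=Variant.SHALLOW)

    @classmethod
    def steep(cls) -> "MyocyteParams":
        return cls(g_pca=0.8666, g_pk=0.00073, variant=Variant.STEEP)

    @classmethod
    def from_variant(cls, variant: "Variant | str") -> "MyocyteParams":
        variant = Variant(variant)
        return cls.shallow() if variant is Variant.SHALLOW else cls.steep()

    def vector(self) -> np.ndarray:
        """Engine parameter vector (see ``_engine`` layout)."""
        return np.array([
            self.g_na, self.g_k1, self.g_to, self.g_kr, self.g_ks,
            self.g_cal, self.k_naca, self.p_nak, self.g_pca, self.g_pk,
            self.g_bna, self.g_bca, self.tau_f_scale,
        ])

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["variant"] = self.variant.value if self.variant else None
        return d


@dataclass(frozen=True)
class FibroblastParams:
    """MacCannell active-fibroblast parameters (conductances in nS/pF).

    ``kv_shift`` rigidly displaces the I_fKv activation/inactivation
    steady-state curves *and* time constants along V (a positive shift
    closes the current at rest and depolarizes V_FR).  ``c_f`` = 50 pF is
    the myofibroblast whole-cell capacitance used in the coupling terms.
    """

    g_k1: float = 0.4822
    g_kv: float = 0.25
    g_bna: float = 0.0095
    i_nak_max: float = 2.002
    kv_shift: float = 0.0
    c_f: float = 50.0  # pF
    v_fr_target: float | None = None

    def vector(self) -> np.ndarray:
        return np.array([self.g_k1, self.g_kv, self.g_bna, self.i_nak_max,
                         self.kv_shift])

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


# ---------------------------------------------------------------------------
# Right-hand sides and state validation
# ---------------------------------------------------------------------------

def _check_finite(state: np.ndarray, n: int, what: str) -> np.ndarray:
    state = np.asarray(state, dtype=float)
    if state.shape != (n,):
        raise InvalidStateError(f"{what} state must have shape ({n},), got {state.shape}")
    if not np.all(np.isfinite(state)):
        raise InvalidStateError(f"{what} state contains non-finite values")
    return state


def myocyte_rhs(state: np.ndarray, params: MyocyteParams,
                i_ext: float = 0.0, i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the TP06 state.

    ``i_ext`` is the signed total external current density (stimulus plus
    coupling, pA/pF, positive depolarizes); ``i_stim`` is the stimulus part
    alone, which also enters the K+ mass balance as in the source model.
    """
    state = _check_finite(state, N_MYO, "myocyte")
    d = np.empty(N_MYO)
    ginf = np.empty(engine.N_MYO_GATES)
    gtau = np.empty(engine.N_MYO_GATES)
    engine.myo_eval(state, params.vector(), float(i_ext), float(i_stim),
                    d, ginf, gtau)
    return d


def fibroblast_rhs(state: np.ndarray, params: FibroblastParams,
                   i_ext: float = 0.0) -> np.ndarray:
    """Time derivative of the MacCannell fibroblast state."""
    state = _check_finite(state, N_FIB, "fibroblast")
    d = np.empty(N_FIB)
    ginf = np.empty(engine.N_FIB_GATES)
    gtau = np.empty(engine.N_FIB_GATES)
    engine.fib_eval(state, params.vector(), float(i_ext), d, ginf, gtau)
    return d


def validate_myocyte_state(state: np.ndarray) -> None:
    """Raise :class:`InvalidStateError` if physiological invariants fail."""
    state = _check_finite(state, N_MYO, "myocyte")
    v = state[0]
    if not -120.0 <= v <= 80.0:
        raise InvalidStateError(f"membrane potential {v:.1f} mV outside [-120, 80]")
    gates = state[engine.MYO_GATE_SLICE]
    if np.any(gates < -1e-12) or np.any(gates > 1.0 + 1e-12):
        raise InvalidStateError("gating variable outside [0, 1]")
    if np.any(state[14:] <= 0.0):
        raise InvalidStateError("non-positive ionic concentration")


def validate_fibroblast_state(state: np.ndarray) -> None:
    state = _check_finite(state, N_FIB, "fibroblast")
    if np.any(state[1:] < -1e-12) or np.any(state[1:] > 1.0 + 1e-12):
        raise InvalidStateError("gating variable outside [0, 1]")


# ---------------------------------------------------------------------------
# Resting states and steady-state search
# ---------------------------------------------------------------------------

@dataclass
class SteadyStateResult:
    state: np.ndarray
    residual: float
    converged: bool
    t_max: float


def _state_scale(state: np.ndarray) -> np.ndarray:
    return np.maximum(np.abs(state), 1.0)


def steady_state(kind: str, params, t_max: float = 20000.0,
                 dt: float = 0.01, residual_tol: float = 1e-4) -> SteadyStateResult:
    """Unstimulated long-time state of a single cell.

    Integrates the quiescent cell for ``t_max`` ms from the model's default
    initial values and reports the relative fixed-point residual
    ``max_i |dy_i/dt| / max(|y_i|, 1)``.  A residual above ``residual_tol``
    raises a warning (non-convergence is flagged, not fatal).

    The fibroblast settles to a genuine fixed point (residual ~1e-8).  The
    ventricular myocyte's voltage and gates equilibrate within seconds, but
    its Na+/K+ pump fluxes keep draining Na_i on a minutes timescale when
    the cell is never stimulated; the default tolerance of 1e-4 accepts the
    voltage-stationary state without requiring that unphysiological limit.
    """
    if t_max < 10000.0:
        raise ValueError("t_max must be at least 10000 ms")
    no_stim = np.empty(0, dtype=np.int64)
    if kind == "myocyte":
        y = engine.MYO_INIT.copy()
        engine.run_myocyte(y, params.vector(), no_stim, 0, 0.0,
                           int(round(t_max / dt)), dt, 10 ** 9)
        resid = float(np.max(np.abs(myocyte_rhs(y, params)) / _state_scale(y)))
    elif kind == "fibroblast":
        y = engine.FIB_INIT.copy()
        engine.run_fibroblast(y, params.vector(), 0.0,
                              int(round(t_max / dt)), dt, 10 ** 9)
        resid = float(np.max(np.abs(fibroblast_rhs(y, params)) / _state_scale(y)))
    else:
        raise ValueError(f"unknown cell kind {kind!r}")
    converged = resid <= residual_tol
    if not converged:
        warnings.warn(
            f"{kind} steady state not converged after {t_max:g} ms "
            f"(residual {resid:.2e} > {residual_tol:.0e})",
            RuntimeWarning, stacklevel=2)
    return SteadyStateResult(y, resid, converged, t_max)


@lru_cache(maxsize=16)
def _resting_myocyte_cached(param_key: tuple, t_max: float, dt: float) -> np.ndarray:
    params = MyocyteParams(*param_key[:-1],
                           variant=Variant(param_key[-1]) if param_key[-1] else None)
    return steady_state("myocyte", params, t_max=t_max, dt=dt).state


def resting_myocyte_state(params: MyocyteParams, t_max: float = 10000.0,
                          dt: float = 0.01) -> np.ndarray:
    """Uncoupled resting state after ``t_max`` ms of quiescence (cached)."""
    key = tuple(getattr(params, f.name) for f in fields(params)[:-1])
    key = key + (params.variant.value if params.variant else None,)
    return _resting_myocyte_cached(key, t_max, dt).copy()


def _fib_settle(params: FibroblastParams, t_max: float = 60000.0,
                dt: float = 0.05) -> np.ndarray:
    y = engine.FIB_INIT.copy()
    engine.run_fibroblast(y, params.vector(), 0.0, int(round(t_max / dt)),
                          dt, 10 ** 9)
    return y


@lru_cache(maxsize=32)
def _resting_fibroblast_cached(param_key: tuple, t_max: float) -> np.ndarray:
    params = FibroblastParams(*param_key)
    return _fib_settle(params, t_max=t_max)


def resting_fibroblast_state(params: FibroblastParams,
                             t_max: float = 60000.0) -> np.ndarray:
    """Uncoupled fibroblast resting state (slow I_fKv inactivation settled)."""
    key = (params.g_k1, params.g_kv, params.g_bna, params.i_nak_max,
           params.kv_shift, params.c_f, params.v_fr_target)
    return _resting_fibroblast_cached(key, t_max).copy()


# ---------------------------------------------------------------------------
# Resting-potential calibration of the fibroblast
# ---------------------------------------------------------------------------

# Monotone range of the steady V_f(shift) map: beyond it the shifted
# activation/inactivation window detaches from the resting potential and
# I_fKv vanishes at rest in either direction.
_SHIFT_BRACKET = (-20.0, 100.0)


def _vf_at_shift(shift: float, base: FibroblastParams, t_max: float) -> float:
    return float(_fib_settle(replace(base, kv_shift=float(shift)), t_max=t_max)[0])


def calibrate_kv_shift(target_vfr: float, tolerance: float = 0.05,
                       base: FibroblastParams | None = None,
                       t_settle: float = 60000.0) -> float:
    """Voltage shift of the I_fKv gating curves giving resting V_f = target.

    Deterministic root bracketing (Brent) on the unstimulated long-time
    membrane potential as a function of the shift; the map is monotone over
    the bracket.  Raises :class:`CalibrationError` with the achievable range
    if the target lies outside it.
    """
    from scipy.optimize import brentq

    if not -60.0 <= target_vfr <= -10.0:
        raise CalibrationError(
            f"target V_FR {target_vfr:g} mV outside the supported [-60, -10] mV")
    base = base or FibroblastParams()
    lo, hi = _SHIFT_BRACKET
    v_lo = _vf_at_shift(lo, base, t_settle)
    v_hi = _vf_at_shift(hi, base, t_settle)
    if not (v_lo <= target_vfr <= v_hi):
        raise CalibrationError(
            f"target V_FR {target_vfr:g} mV unreachable; achievable range is "
            f"[{v_lo:.1f}, {v_hi:.1f}] mV for shifts in {_SHIFT_BRACKET}")
    shift = brentq(lambda s: _vf_at_shift(s, base, t_settle) - target_vfr,
                   lo, hi, xtol=1e-3)
    achieved = _vf_at_shift(shift, base, t_settle)
    if abs(achieved - target_vfr) > tolerance:
        raise CalibrationError(
            f"calibration landed at {achieved:.3f} mV, outside +/-{tolerance:g} "
            f"of {target_vfr:g} mV")
    return float(shift)


@lru_cache(maxsize=8)
def _shift_for_target(target_vfr: float) -> float:
    return calibrate_kv_shift(target_vfr)


def fibroblast_params_for_vfr(target_vfr: float = -24.5) -> FibroblastParams:
    """Fibroblast parameter set calibrated to the requested resting potential."""
    shift = _shift_for_target(float(target_vfr))
    return FibroblastParams(kv_shift=shift, v_fr_target=float(target_vfr))


# ---------------------------------------------------------------------------
# TOML round-trip for parameter sets
# ---------------------------------------------------------------------------

def _toml_scalar(v):
    if v is None:
        return '""'
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(float(v)) if isinstance(v, float) else str(v)
    return '"' + str(v) + '"'


def params_to_toml(params, path) -> None:
    """Serialize a parameter dataclass as a flat TOML table."""
    name = type(params).__name__
    lines = [f"[{name}]"]
    for k, v in params.to_dict().items():
        lines.append(f"{k} = {_toml_scalar(v)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def params_from_toml(path):
    """Load a parameter set written by :func:`params_to_toml`."""
    import tomllib

    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    if "MyocyteParams" in data:
        d = data["MyocyteParams"]
        variant = d.pop("variant", None) or None
        return MyocyteParams(**d, variant=Variant(variant) if variant else None)
    if "FibroblastParams" in data:
        d = data["FibroblastParams"]
        if d.get("v_fr_target") == "":
            d["v_fr_target"] = None
        return FibroblastParams(**d)
    raise ValueError(f"no recognised parameter table in {path}")


def save_state_hdf5(path, state: np.ndarray, kind: str) -> None:
    """Checkpoint a state vector (layout-versioned) to HDF5."""
    import h5py

    names = {"myocyte": MYO_STATE_NAMES, "fibroblast": FIB_STATE_NAMES}[kind]
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("state", data=np.asarray(state, dtype=float))
        ds.attrs["kind"] = kind
        ds.attrs["names"] = list(names)
        ds.attrs["layout_version"] = STATE_LAYOUT_VERSION


def load_state_hdf5(path) -> tuple[np.ndarray, str]:
    import h5py

    with h5py.File(path, "r") as fh:
        ds = fh["state"]
        if int(ds.attrs["layout_version"]) != STATE_LAYOUT_VERSION:
            raise InvalidStateError("state checkpoint from an incompatible layout version")
        return np.array(ds), str(ds.attrs["kind"])
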
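"""Coupling topologies: 2 myocytes + 2 fibroblast units, three motifs.

The two myocytes are never coupled to each other; every pathway runs through
a fibroblast unit (N_f identical fibroblasts in parallel, sharing one state
vector).  Two conductance classes exist: ``G_Loc`` couples a fibroblast to
its proximal myocyte, ``G_Long`` to the distal one.  With i != j,

    C_m dV_i/dt  = -I_ion_i + N_f [G_Loc_i (Vf_i - V_i) + G_Long_i (Vf_j - V_i)]
    C_f dVf_i/dt = -I_fib_i +      G_Loc_i (V_i - Vf_i) + G_Long_j (V_j - Vf_i)

so the link M1-F2 carries G_Long1 and M2-F1 carries G_Long2; N_f scales the
myocyte side only (each of the N_f parallel fibroblasts sources the same
current).  The motifs zero specific conductances:

* Motif-1: G_Loc1 = G_Long2 = 0 — one fibroblast (F2) bridges both myocytes;
* Motif-2: G_Long2 = 0 — M1 sees both fibroblasts, M2 only F2;
* Motif-3: all four links present (fully symmetric).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from . import _engine as engine
from .cell_models import (
    FibroblastParams,
    MyocyteParams,
    fibroblast_rhs,
    myocyte_rhs,
)
from .errors import InvalidStateError

__all__ = [
    "MotifKind", "MotifConfig", "build_motif", "CoupledState",
    "coupling_currents", "coupled_rhs", "pack_state", "unpack_state",
]

_NM = engine.N_MYO
_NF = engine.N_FIB


class MotifKind(IntEnum):
    MOTIF1 = 1
    MOTIF2 = 2
    MOTIF3 = 3


@dataclass(frozen=True)
class MotifConfig:
    """Topology kind plus the effective per-link conductances (nS)."""

    kind: MotifKind
    g_loc: float
    g_long: float
    n_f: int = 4

    @property
    def g_loc1(self) -> float:
        return 0.0 if self.kind is MotifKind.MOTIF1 else self.g_loc

    @property
    def g_loc2(self) -> float:
        return self.g_loc

    @property
    def g_long1(self) -> float:
        return self.g_long

    @property
    def g_long2(self) -> float:
        return self.g_long if self.kind is MotifKind.MOTIF3 else 0.0

    def conductances(self) -> tuple[float, float, float, float]:
        return (self.g_loc1, self.g_loc2, self.g_long1, self.g_long2)


def build_motif(kind: MotifKind | int, g_loc: float, g_long: float,
                n_f: int = 4) -> MotifConfig:
    """Motif configuration with the kind-specific conductance zeroing."""
    kind = MotifKind(kind)
    if g_loc < 0 or g_long < 0:
        raise ValueError("gap-junctional conductances must be non-negative")
    if n_f < 1:
        raise ValueError("n_f must be a positive count")
    return MotifConfig(kind=kind, g_loc=float(g_loc), g_long=float(g_long),
                       n_f=int(n_f))


@dataclass
class CoupledState:
    """States of (M1, M2, F1, F2) at one instant."""

    m1: np.ndarray
    m2: np.ndarray
    f1: np.ndarray
    f2: np.ndarray
    time: float = 0.0

    def pack(self) -> np.ndarray:
        return np.concatenate([self.m1, self.m2, self.f1, self.f2])


def pack_state(m1, m2, f1, f2) -> np.ndarray:
    y = np.concatenate([np.asarray(m1, float), np.asarray(m2, float),
                        np.asarray(f1, float), np.asarray(f2, float)])
    if y.shape != (engine.N_MOTIF,):
        raise InvalidStateError(f"packed motif state must have {engine.N_MOTIF} entries")
    return y


def unpack_state(y: np.ndarray, time: float = 0.0) -> CoupledState:
    y = np.asarray(y, float)
    if y.shape != (engine.N_MOTIF,):
        raise InvalidStateError(f"motif state must have shape ({engine.N_MOTIF},)")
    return CoupledState(m1=y[:_NM].copy(), m2=y[_NM:2 * _NM].copy(),
                        f1=y[2 * _NM:2 * _NM + _NF].copy(),
                        f2=y[2 * _NM + _NF:].copy(), time=time)


def coupling_currents(config: MotifConfig, v1: float, v2: float,
                      vf1: float, vf2: float,
                      c_m: float = 150.0, c_f: float = 50.0):
    """Per-cell gap-junctional current densities (pA/pF, depolarizing > 0).

    Returns ``(i_m1, i_m2, i_f1, i_f2)``.  Term-level antisymmetry holds by
    construction: the whole-cell charge entering a myocyte through one link
    equals N_f times the charge leaving each fibroblast of the unit.
    """
    gl1, gl2, gg1, gg2 = config.conductances()
    nf = config.n_f
    i_m1 = nf * (gl1 * (vf1 - v1) + gg1 * (vf2 - v1)) / c_m
    i_m2 = nf * (gl2 * (vf2 - v2) + gg2 * (vf1 - v2)) / c_m
    i_f1 = (gl1 * (v1 - vf1) + gg2 * (v2 - vf1)) / c_f
    i_f2 = (gl2 * (v2 - vf2) + gg1 * (v1 - vf2)) / c_f
    return i_m1, i_m2, i_f1, i_f2


def coupled_rhs(y: np.ndarray, config: MotifConfig,
                myo_params: MyocyteParams, fib_params: FibroblastParams,
                i_stim1: float = 0.0, i_stim2: float = 0.0) -> np.ndarray:
    """Derivative of the packed 44-variable motif state."""
    y = np.asarray(y, float)
    if not np.all(np.isfinite(y)):
        raise InvalidStateError("motif state contains non-finite values")
    s = unpack_state(y)
    i_m1, i_m2, i_f1, i_f2 = coupling_currents(
        config, s.m1[0], s.m2[0], s.f1[0], s.f2[0],
        c_m=myo_params.c_m, c_f=fib_params.c_f)
    return np.concatenate([
        myocyte_rhs(s.m1, myo_params, i_ext=i_stim1 + i_m1, i_stim=i_stim1),
        myocyte_rhs(s.m2, myo_params, i_ext=i_stim2 + i_m2, i_stim=i_stim2),
        fibroblast_rhs(s.f1, fib_params, i_ext=i_f1),
        fibroblast_rhs(s.f2, fib_params, i_ext=i_f2),
    ])
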
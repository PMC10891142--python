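"""Conductance-grid sweeps and regime-fraction summaries.

A sweep runs one simulation per (feature combination x grid point) with the
grid spanning G_Loc, G_Long in [0, 4] nS at 0.5 nS steps (81 points) by
default, and collects tidy records: mean APD per myocyte and delta-APD in
both-paced mode; per-cell response fractions and NR/IR/1:1 regime labels in
pacing-response mode.  Execution order never affects results (each point
starts from the same resting initial conditions); per-point failures are
isolated into flagged rows.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import metrics
from .cell_models import MyocyteParams, fibroblast_params_for_vfr
from .errors import FibromotifError, UndefinedMetricError
from .motif import build_motif
from .protocols import PacingSpec, run_paced, run_pacing_response
from .surrogate import (
    SurrogateParams,
    SurrogatePassiveParams,
    run_surrogate_paced,
    run_surrogate_pacing_response,
)

__all__ = ["SweepSpec", "run_sweep", "marginal_regime_fractions",
            "DEFAULT_G_GRID"]

DEFAULT_G_GRID = tuple(np.arange(0.0, 4.01, 0.5))


@dataclass(frozen=True)
class SweepSpec:
    """Feature levels and grid of a sweep."""

    motifs: tuple = (1, 2, 3)
    variants: tuple = ("shallow", "steep")
    periods: tuple = (600.0,)
    v_fr: tuple = (-24.5,)
    tau_d: float = 0.0
    mode: str = "both-paced"          # or "pacing-response"
    pacing_cells: tuple = ("m1",)     # scored roles in pacing-response mode
    g_values: tuple = DEFAULT_G_GRID  # identical axis for G_Loc and G_Long
    n_f: int = 4
    n_beats: int = 20
    n_discard: int = 10
    cells: str = "biophysical"        # or "surrogate"
    dt: float | None = None           # default: 0.01 biophysical, 0.25 surrogate

    def __post_init__(self):
        if self.mode not in ("both-paced", "pacing-response"):
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if self.cells not in ("biophysical", "surrogate"):
            raise ValueError(f"unknown cell kind {self.cells!r}")

    @property
    def step_dt(self) -> float:
        if self.dt is not None:
            return self.dt
        return 0.01 if self.cells == "biophysical" else 0.25

    def combos(self):
        """Deterministically ordered feature/grid combinations."""
        pacing = self.pacing_cells if self.mode == "pacing-response" else (None,)
        return itertools.product(
            self.motifs, self.variants, self.periods, self.v_fr, pacing,
            self.g_values, self.g_values)


def _point_key(spec: SweepSpec, combo) -> str:
    payload = {"spec": {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in spec.__dict__.items()},
               "combo": list(combo)}
    return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                     default=str).encode()).hexdigest()


def _run_point(spec: SweepSpec, combo) -> dict:
    motif, variant, period, v_fr, pacing, g_loc, g_long = combo
    config = build_motif(motif, g_loc, g_long, n_f=spec.n_f)
    pspec = PacingSpec(t1=period, tau_d=spec.tau_d, n_beats=spec.n_beats,
                       n_discard=spec.n_discard, dt=spec.step_dt)
    rec = {"motif": motif, "variant": variant, "T": period, "v_fr": v_fr,
           "tau_d": spec.tau_d, "mode": spec.mode, "pacing_cell": pacing,
           "g_loc": g_loc, "g_long": g_long,
           "apd_m1": np.nan, "apd_m2": np.nan, "delta_apd": np.nan,
           "frac_pacing": np.nan, "frac_response": np.nan,
           "regime_pacing": pd.NA, "regime_response": pd.NA, "error": pd.NA}

    if spec.cells == "biophysical":
        myo = MyocyteParams.from_variant(variant)
        fib = fibroblast_params_for_vfr(v_fr)
        paced = lambda: run_paced(config, pspec, myo, fib)
        pr = lambda: run_pacing_response(config, pspec, myo, fib, pace=pacing)
    else:
        myo = SurrogateParams()
        fib = SurrogatePassiveParams()
        paced = lambda: run_surrogate_paced(config, pspec, myo, fib)
        pr = lambda: run_surrogate_pacing_response(config, pspec, myo, fib,
                                                   pace=pacing)

    if spec.mode == "both-paced":
        trace = paced()
        e1 = metrics.detect_aps(trace.v1, trace.time)
        e2 = metrics.detect_aps(trace.v2, trace.time)
        rec["apd_m1"] = metrics.mean_apd(e1, spec.n_discard)
        rec["apd_m2"] = metrics.mean_apd(e2, spec.n_discard)
        rec["delta_apd"] = rec["apd_m1"] - rec["apd_m2"]
    else:
        trace, roles = pr()
        fr = metrics.response_fraction(trace, roles,
                                       n_count=spec.n_beats - spec.n_discard)
        rec["frac_pacing"] = fr.pacing
        rec["frac_response"] = fr.response
        rec["regime_pacing"] = metrics.classify_regime(fr.pacing).regime.value
        rec["regime_response"] = metrics.classify_regime(fr.response).regime.value
    return rec


def run_sweep(spec: SweepSpec, cache_dir=None, progress: bool = False) -> pd.DataFrame:
    """Run every grid point of the sweep; failures become flagged NA rows."""
    rows = []
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    combos = list(spec.combos())
    for i, combo in enumerate(combos):
        cfile = cache / f"{_point_key(spec, combo)}.json" if cache else None
        if cfile is not None and cfile.exists():
            rows.append(json.loads(cfile.read_text()))
            continue
        try:
            rec = _run_point(spec, combo)
        except FibromotifError as exc:
            motif, variant, period, v_fr, pacing, g_loc, g_long = combo
            rec = {"motif": motif, "variant": variant, "T": period,
                   "v_fr": v_fr, "tau_d": spec.tau_d, "mode": spec.mode,
                   "pacing_cell": pacing, "g_loc": g_loc, "g_long": g_long,
                   "apd_m1": np.nan, "apd_m2": np.nan, "delta_apd": np.nan,
                   "frac_pacing": np.nan, "frac_response": np.nan,
                   "regime_pacing": pd.NA, "regime_response": pd.NA,
                   "error": f"{type(exc).__name__}: {exc}"}
        if cfile is not None:
            clean = {k: (None if v is pd.NA else v) for k, v in rec.items()}
            cfile.write_text(json.dumps(clean, sort_keys=True))
        rows.append(rec)
        if progress and (i + 1) % 10 == 0:
            print(f"  sweep {i + 1}/{len(combos)}", flush=True)
    df = pd.DataFrame(rows)
    df["error"] = df["error"].astype("object")
    return df


_FEATURES = {
    "variant": ["variant"],
    "T": ["T"],
    "motif": ["motif", "pacing_cell"],   # topology + stimulated-cell role
}


def marginal_regime_fractions(df: pd.DataFrame, fix_feature: str) -> pd.DataFrame:
    """Regime occurrence fractions with one feature fixed at a time.

    For each level of ``fix_feature`` ("variant", "T" or "motif", the last
    jointly with the stimulated cell), returns the fraction of all pooled
    (grid x remaining-feature) instances classified NR / IR / 1:1,
    separately for the pacing and response cells.  Fractions sum to one per
    (level, cell).
    """
    if fix_feature not in _FEATURES:
        raise ValueError(f"fix_feature must be one of {sorted(_FEATURES)}")
    sel = df[df["mode"] == "pacing-response"].dropna(subset=["regime_pacing"])
    if sel.empty:
        raise UndefinedMetricError("no pacing-response records to summarise")
    keys = _FEATURES[fix_feature]
    out = []
    for level, grp in sel.groupby(keys, dropna=False):
        level = level if len(keys) > 1 else (level,)
        for cell, col in (("pacing", "regime_pacing"),
                          ("response", "regime_response")):
            counts = grp[col].value_counts()
            total = int(counts.sum())
            for regime in (metrics.Regime.NR, metrics.Regime.IR,
                           metrics.Regime.ONE_TO_ONE):
                out.append({
                    "feature": fix_feature,
                    "level": "/".join(str(x) for x in level),
                    "cell": cell,
                    "regime": regime.value,
                    "fraction": counts.get(regime.value, 0) / total,
                    "n": total,
                })
    return pd.DataFrame(out)
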
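"""Run configuration: validated schema, TOML loading, provenance hashing."""

from __future__ import annotations

import hashlib
from pathlib import Path

from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .cell_models import MyocyteParams, fibroblast_params_for_vfr
from .errors import ConfigError
from .motif import MotifConfig, build_motif
from .protocols import INFINITE, PacingSpec

__all__ = ["RunConfig", "SweepSection", "load_config", "save_config",
           "config_hash", "SCHEMA_VERSION"]

SCHEMA_VERSION = 1


class RunConfig(BaseModel):
    """Everything needed to reproduce one motif simulation."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    motif: int = 3
    variant: str = "steep"
    g_loc: float = 0.0
    g_long: float = 0.0
    n_f: int = 4
    v_fr: float = -24.5
    t1: float = 600.0
    t2: float | None = None
    tau_d: float | str = 0.0          # ms, or "inf" for the pacing-response protocol
    pace: str | None = None           # stimulate one cell only: "m1" / "m2"
    n_beats: int = 20
    n_discard: int = 10
    stim_amplitude: float = 52.0
    stim_duration: float = 1.0
    dt: float = 0.01
    sample_dt: float = 0.1
    schema_version: int = SCHEMA_VERSION

    @field_validator("motif")
    @classmethod
    def _motif_range(cls, v):
        if v not in (1, 2, 3):
            raise ValueError("motif must be 1, 2 or 3")
        return v

    @field_validator("variant")
    @classmethod
    def _variant_known(cls, v):
        if v not in ("shallow", "steep"):
            raise ValueError("variant must be 'shallow' or 'steep'")
        return v

    @field_validator("g_loc", "g_long")
    @classmethod
    def _g_nonneg(cls, v):
        if v < 0:
            raise ValueError("conductances must be non-negative")
        return v

    @field_validator("tau_d")
    @classmethod
    def _tau_ok(cls, v):
        if isinstance(v, str):
            if v not in ("inf", "INF", "infinite"):
                raise ValueError("tau_d must be a number or 'inf'")
            return "inf"
        if v < 0:
            raise ValueError("tau_d must be non-negative")
        return v

    @property
    def tau_d_value(self) -> float:
        return INFINITE if isinstance(self.tau_d, str) else float(self.tau_d)

    def motif_config(self) -> MotifConfig:
        return build_motif(self.motif, self.g_loc, self.g_long, n_f=self.n_f)

    def pacing_spec(self) -> PacingSpec:
        return PacingSpec(t1=self.t1, t2=self.t2, tau_d=self.tau_d_value,
                          n_beats=self.n_beats, n_discard=self.n_discard,
                          stim_amplitude=self.stim_amplitude,
                          stim_duration=self.stim_duration,
                          dt=self.dt, sample_dt=self.sample_dt)

    def myo_params(self) -> MyocyteParams:
        return MyocyteParams.from_variant(self.variant)

    def fib_params(self):
        return fibroblast_params_for_vfr(self.v_fr)


class SweepSection(BaseModel):
    """TOML section describing a sweep grid (see :mod:`fibromotif.sweeps`)."""

    model_config = ConfigDict(extra="forbid")

    motifs: list[int] = [1, 2, 3]
    variants: list[str] = ["shallow", "steep"]
    periods: list[float] = [600.0]
    v_fr: list[float] = [-24.5]
    tau_d: float = 0.0
    mode: str = "both-paced"
    pacing_cells: list[str] = ["m1"]
    g_min: float = 0.0
    g_max: float = 4.0
    g_step: float = 0.5
    n_f: int = 4
    n_beats: int = 20
    n_discard: int = 10
    cells: str = "biophysical"

    def sweep_spec(self):
        from .sweeps import SweepSpec

        n = int(round((self.g_max - self.g_min) / self.g_step)) + 1
        grid = tuple(self.g_min + i * self.g_step for i in range(n))
        return SweepSpec(motifs=tuple(self.motifs),
                         variants=tuple(self.variants),
                         periods=tuple(self.periods), v_fr=tuple(self.v_fr),
                         tau_d=self.tau_d, mode=self.mode,
                         pacing_cells=tuple(self.pacing_cells),
                         g_values=grid, n_f=self.n_f, n_beats=self.n_beats,
                         n_discard=self.n_discard, cells=self.cells)


def _format_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path) -> RunConfig:
    """Load and validate a TOML run configuration; records its file hash."""
    import tomllib

    path = Path(path)
    raw = path.read_bytes()
    data = tomllib.loads(raw.decode())
    section = data.get("run", data)
    try:
        cfg = RunConfig(**section)
    except ValidationError as exc:
        raise ConfigError(f"invalid configuration {path}: {_format_error(exc)}") from exc
    object.__setattr__(cfg, "_provenance",
                       {"path": str(path),
                        "sha256": hashlib.sha256(raw).hexdigest()})
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    lines = ["[run]"]
    for key, value in cfg.model_dump().items():
        if value is None:
            continue
        if isinstance(value, bool):
            sval = "true" if value else "false"
        elif isinstance(value, (int, float)):
            sval = repr(value)
        else:
            sval = '"' + str(value) + '"'
        lines.append(f"{key} = {sval}")
    Path(path).write_text("\n".join(lines) + "\n")


def config_hash(cfg) -> str:
    """Stable hash of a configuration (pydantic model or plain dict)."""
    import json

    payload = cfg.model_dump() if hasattr(cfg, "model_dump") else dict(cfg)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()
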
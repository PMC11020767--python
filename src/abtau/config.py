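"""Run-configuration schema and reproducibility manifest.

A run is described by a YAML document with sections ``params``,
``inflammation``, ``solver``, ``drug`` and ``output``; the schema is the
pydantic model :class:`RunConfig`, so violations are reported with
field paths.  Every run emits a JSON manifest (config hash, seed,
package version) sufficient to reproduce it bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import __version__ as _pkg_version

__all__ = ["RunConfig", "load_config", "config_hash", "write_manifest"]


class ParamsBlock(BaseModel):
    table: Optional[str] = None          # path to a delimited parameter table
    overrides: dict[str, float] = Field(default_factory=dict)


class MapSpec(BaseModel):
    n_x: int = Field(10, ge=1)
    n_y: int = Field(10, ge=1)
    fractions: tuple[float, float, float, float] = (0.40, 0.40, 0.15, 0.05)
    N1: float = 1.5
    N2: float = 0.5
    block: int = Field(1, ge=1)
    mask: Optional[str] = None           # CSV of 0/1 active cells


class InflammationBlock(BaseModel):
    R_star: float = Field(1.85e-6, ge=0)
    Rbar_star: float = Field(4.13e-10, ge=0)
    K: float = Field(100.0, gt=0)
    gamma: float = Field(1.0, gt=0)
    # either uniform multipliers or a pixel map
    uniform_multipliers: Optional[tuple[float, float]] = (1.0, 1.0)
    map: Optional[MapSpec] = None


class SolverBlock(BaseModel):
    t_end: float = Field(3650.0, gt=0)
    sample_interval: float = Field(10.0, gt=0)
    rtol: float = Field(1e-9, gt=0)
    grid_nx: int = Field(50, ge=2)
    grid_ny: int = Field(50, ge=2)
    cell_size: float = Field(0.02, gt=0)
    dt: float = Field(0.25, gt=0)
    snapshot_times: list[float] = Field(default_factory=lambda: [500.0])


class DrugBlock(BaseModel):
    t0: float = Field(ge=0)
    D_star: float = Field(0.07429, ge=0)
    K_D: float = Field(1797.0, gt=0)
    mu: float = Field(0.1499, ge=0)
    mu_star: float = Field(11.89, ge=0)


class OutputBlock(BaseModel):
    directory: str = "out"
    cadence: float = Field(100.0, gt=0)


class RunConfig(BaseModel):
    mode: Literal["ode", "pde", "treatment"] = "ode"
    seed: int = 0
    params: ParamsBlock = Field(default_factory=ParamsBlock)
    inflammation: InflammationBlock = Field(default_factory=InflammationBlock)
    solver: SolverBlock = Field(default_factory=SolverBlock)
    drug: Optional[DrugBlock] = None
    output: OutputBlock = Field(default_factory=OutputBlock)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.mode == "treatment" and self.drug is None:
            raise ValueError("treatment mode requires a [drug] block")
        if self.drug is not None and self.drug.t0 >= self.solver.t_end:
            raise ValueError("drug.t0 must lie before solver.t_end")
        if (
            self.mode == "pde"
            and max(self.solver.snapshot_times, default=0.0) > self.solver.t_end
        ):
            raise ValueError("solver.snapshot_times must not exceed solver.t_end")
        return self


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Schema violations are re-raised as ``ValueError`` listing the
    offending field paths.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as err:
        lines = [
            f"  {'.'.join(str(x) for x in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ValueError("invalid run configuration:\n" + "\n".join(lines)) from None


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(cfg: RunConfig, outdir: str | Path, extra: dict | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "abtau",
        "version": _pkg_version,
        "config": cfg.model_dump(mode="json"),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
    }
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
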
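"""Run configuration: schema validation, presets and scan writers.

Configs are JSON (optionally YAML when PyYAML is importable) and validated
with pydantic before any computation; unknown keys are rejected.  Presets
expand to the parameter sets of the two pathway size classes and of the
whole-cell model; explicit fields override preset values (override wins,
logged).  Writers emit deterministic CSV/JSON with a provenance header.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .pathway import PathwayParams, metabolic_preset, ribosomal_preset
from .wholecell import METABOLIC_ENZYME_PRESETS, WholeCellParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config", "write_scan", "PRESETS"]

#: Named parameter presets; N-presets select the active-enzyme counts
#: estimated for different nutritional environments.
PRESETS = ("metabolic-pathway", "ribosomal-pathway",
           "wholecell-default", "wholecell-theta46")


class RunConfig(BaseModel):
    """Validated description of one run."""

    model_config = ConfigDict(extra="forbid")

    model: Literal["pathway", "wholecell", "vazquez", "convert"]
    preset: Optional[str] = None
    N: Optional[int] = Field(default=None, ge=1)
    theta_metabolic: Optional[float] = Field(default=None, ge=0)
    theta_ribosomal: Optional[float] = Field(default=None, ge=0)
    s_ext: Optional[float] = Field(default=None, gt=0)
    objective: Literal["mu", "flux"] = "mu"
    regime: Literal["saturated", "diffusion"] = "saturated"
    rho_values: Optional[list[float]] = None
    substrate_share_values: Optional[list[float]] = None
    n_restarts: int = Field(default=20, ge=1)
    seed: int = 0
    rho_dm: Optional[float] = Field(default=None, ge=0)
    r: Optional[float] = Field(default=None, ge=0)
    mu: Optional[float] = Field(default=None, ge=0)
    law: Literal["scott", "table"] = "scott"
    out: Optional[str] = None
    format: Literal["csv", "json"] = "csv"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_preset(self):
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {PRESETS}")
        if self.model == "convert" and self.rho_dm is None:
            raise ValueError("model='convert' requires rho_dm")
        return self

    # -- parameter expansion -------------------------------------------

    def pathway_params(self) -> PathwayParams:
        theta = self.theta_metabolic if self.theta_metabolic is not None else 2.3
        n = self.N if self.N is not None else 20
        if self.preset == "ribosomal-pathway":
            return ribosomal_preset(N=n, theta=self.theta_ribosomal or 2.3)
        if self.preset in (None, "metabolic-pathway"):
            return metabolic_preset(N=n, theta=theta)
        raise ValueError(f"preset {self.preset!r} is not a pathway preset")

    def wholecell_params(self) -> WholeCellParams:
        from dataclasses import replace
        base = WholeCellParams()
        if self.preset == "wholecell-theta46":
            base = replace(base, metabolic=replace(base.metabolic, theta=4.6))
        elif self.preset not in (None, "wholecell-default"):
            raise ValueError(f"preset {self.preset!r} is not a whole-cell preset")
        overrides = {}
        if self.N is not None:
            if self.preset in ("wholecell-default", "wholecell-theta46") \
                    and self.N not in METABOLIC_ENZYME_PRESETS:
                logger.info("N=%d is not one of the shipped presets %s",
                            self.N, METABOLIC_ENZYME_PRESETS)
            overrides["N"] = self.N
        if self.s_ext is not None:
            overrides["s_ext"] = self.s_ext
        if self.theta_metabolic is not None:
            overrides["metabolic"] = replace(base.metabolic,
                                             theta=self.theta_metabolic)
            logger.info("override: theta_metabolic=%s", self.theta_metabolic)
        if self.theta_ribosomal is not None:
            overrides["ribosomal"] = replace(base.ribosomal,
                                             theta=self.theta_ribosomal)
        return replace(base, **overrides) if overrides else base

    def provenance(self) -> dict:
        # hash the scientific parameters only, not output plumbing
        payload = self.model_dump(exclude_none=True,
                                  exclude={"out", "format", "log_level"})
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
        return dict(version=__version__, config_hash=digest, seed=self.seed)


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a JSON (or YAML) config file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return RunConfig.model_validate(data)


def write_scan(result, path: str | Path, format: str = "csv",
               provenance: dict | None = None) -> Path:
    """Write a ScanResult table with a provenance header.

    CSV files carry '#'-prefixed key=value comment lines followed by the
    table at 12 significant digits; JSON files embed the provenance.
    Identical inputs produce byte-identical files.
    """
    if result is None or len(result.table) == 0:
        raise ValueError("refusing to write an empty scan result")
    path = Path(path)
    prov = dict(provenance or {})
    prov.setdefault("objective", result.objective)
    for k, v in result.optimum.items():
        prov[f"optimum_{k}"] = v
    table = result.table
    if format == "csv":
        lines = [f"# {k}={v}" for k, v in prov.items()]
        body = table.to_csv(index=False, float_format="%.12g")
        path.write_text("\n".join(lines) + "\n" + body)
    elif format == "json":
        payload = dict(provenance=prov,
                       optimum=result.optimum,
                       table=json.loads(table.to_json(orient="records",
                                                      double_precision=12)))
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path
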
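"""Run configuration: YAML schema, validation and defaults.

Validation is all-at-once: every schema violation and every missing input
path is collected and reported together, so a configuration can be fixed in
one pass. Unknown keys warn (forward compatibility) rather than fail.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError
from .metnet import EnvironmentSpec

__all__ = ["EnvConfig", "ConditionConfig", "RunConfig", "validate_config"]

logger = logging.getLogger(__name__)


class EnvConfig(BaseModel):
    model_config = ConfigDict(extra="allow")

    exchange_bounds: dict[str, tuple[Optional[float], Optional[float]]] = Field(
        default_factory=dict
    )
    oxygen_allowed: bool = True
    oxygen_exchange: str = "EX_o2_e"
    nutrient_pools: dict[str, float] = Field(default_factory=dict)
    atp_maintenance: float = Field(default=0.0, ge=0.0)
    atp_maintenance_reaction: str = "ATPM"

    def to_spec(self) -> EnvironmentSpec:
        return EnvironmentSpec(
            exchange_bounds=dict(self.exchange_bounds),
            oxygen_allowed=self.oxygen_allowed,
            oxygen_exchange=self.oxygen_exchange,
            nutrient_pools=dict(self.nutrient_pools),
            atp_maintenance=self.atp_maintenance,
            atp_maintenance_reaction=self.atp_maintenance_reaction,
        )


class ConditionConfig(BaseModel):
    model_config = ConfigDict(extra="allow")

    de_table: Path
    label: str


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="allow", protected_namespaces=())

    counts: Path
    design: Path
    annotation: Optional[Path] = None
    model: Optional[Path] = None
    model_format: Optional[Literal["model-json", "sbml-fbc"]] = None
    pathway_map: Optional[Path] = None
    conditions: list[ConditionConfig] = Field(default_factory=list)

    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    fdr: bool = False
    trim_m: float = Field(default=0.3, ge=0.0, lt=0.5)
    trim_a: float = Field(default=0.05, ge=0.0, lt=0.5)
    dispersion: Optional[float] = Field(default=None, ge=0.0)
    n_mapped: Optional[int] = Field(default=None, ge=1)
    multi_count_categories: bool = True

    epsilon: float = Field(default=1e-6, gt=0.0)
    gpr_and: Literal["min", "max", "mean"] = "min"
    gpr_or: Literal["min", "max", "mean"] = "max"
    cap_relaxation: float = Field(default=1.0, ge=1.0)
    reference_env: EnvConfig = Field(default_factory=EnvConfig)
    stress_env: EnvConfig = Field(default_factory=EnvConfig)

    seed: int = 0
    outdir: Path = Path("results")

    def input_paths(self) -> dict[str, Path]:
        paths = {"counts": self.counts, "design": self.design}
        for name in ("annotation", "model", "pathway_map"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        for cond in self.conditions:
            paths[f"condition '{cond.label}'"] = cond.de_table
        return paths


def _warn_unknown(model: BaseModel, context: str) -> None:
    extra = getattr(model, "model_extra", None) or {}
    for key in extra:
        logger.warning("unknown configuration key %r in %s ignored", key, context)


def validate_config(path: str | Path, check_paths: bool = True) -> RunConfig:
    """Load + validate a YAML run configuration.

    Raises :class:`ConfigurationError` listing *all* schema violations and
    *all* missing input paths at once. Applied defaults are logged.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path} does not contain a configuration mapping")
    try:
        cfg = RunConfig(**doc)
    except ValidationError as exc:
        lines = [
            f"  {'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors()
        ]
        raise ConfigurationError(
            f"invalid configuration {path}:\n" + "\n".join(lines)
        ) from exc

    _warn_unknown(cfg, str(path))
    for sub, label in ((cfg.reference_env, "reference_env"), (cfg.stress_env, "stress_env")):
        _warn_unknown(sub, label)
    for name in sorted(set(RunConfig.model_fields) - set(doc)):
        logger.info(
            "configuration default applied: %s = %r", name, getattr(cfg, name)
        )

    if check_paths:
        missing = [
            f"  {name}: {p}" for name, p in cfg.input_paths().items() if not Path(p).exists()
        ]
        if missing:
            raise ConfigurationError(
                f"configuration {path} references missing inputs:\n" + "\n".join(missing)
            )
    return cfg
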
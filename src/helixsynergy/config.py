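"""Validated run configuration (pydantic models, unknown keys rejected)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .exceptions import ConfigError
from .helix_geometry import (
    DEFAULT_EVEN_TOLERANCE,
    DEFAULT_FACE_BOUNDARY,
    BindingSite,
    HelixParameters,
    SiteArrangement,
)
from .simulator import DEFAULT_MODEL_PARAMS, SynergyModelParams
from .synthetic import GelParams, NoiseSpec

__all__ = ["RunConfig", "load_config", "default_config", "config_hash"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HelixConfig(_Strict):
    twist_per_bp: float = 36.0
    rise_per_bp: float = 3.4
    reference_azimuth: float = 0.0

    def build(self) -> HelixParameters:
        return HelixParameters(**self.model_dump())


class SiteConfig(_Strict):
    name: str
    start: int = Field(ge=1)
    length: int = Field(ge=1)
    factor: str = ""

    def build(self) -> BindingSite:
        return BindingSite(**self.model_dump())


class ModelConfig(_Strict):
    K: float = DEFAULT_MODEL_PARAMS.K
    w: float = DEFAULT_MODEL_PARAMS.w
    xi: float = DEFAULT_MODEL_PARAMS.xi
    r: float = DEFAULT_MODEL_PARAMS.r
    rho: float = DEFAULT_MODEL_PARAMS.rho
    sharpness: float = DEFAULT_MODEL_PARAMS.sharpness
    xi_recruit: float = DEFAULT_MODEL_PARAMS.xi_recruit
    R50: float = DEFAULT_MODEL_PARAMS.R50
    m: float = DEFAULT_MODEL_PARAMS.m
    A_basal: float = DEFAULT_MODEL_PARAMS.A_basal
    A_max: float = DEFAULT_MODEL_PARAMS.A_max

    def build(self) -> SynergyModelParams:
        return SynergyModelParams(**self.model_dump())


class NoiseConfig(_Strict):
    cv: float = 0.10
    n_replicates: int = 3
    seed: int = 0

    def build(self) -> NoiseSpec:
        return NoiseSpec(**self.model_dump())


class GelConfig(_Strict):
    log_intercept: float = 5.0
    length_slope: float = 0.004
    extent_coeff: float = 0.002
    radial_distance: float = 30.0
    cluster_radius: float = 15.0
    probe_flank: int = 80

    def build(self) -> GelParams:
        return GelParams(**self.model_dump())


class RunConfig(_Strict):
    """Top-level configuration for CLI runs.

    Precedence elsewhere: explicit CLI flags > this file > defaults.
    """

    helix: HelixConfig = HelixConfig()
    model: ModelConfig = ModelConfig()
    noise: NoiseConfig = NoiseConfig()
    gel: GelConfig = GelConfig()
    sites: list[SiteConfig] | None = None
    boundary: float = DEFAULT_FACE_BOUNDARY
    even_tolerance: float = DEFAULT_EVEN_TOLERANCE

    def arrangement(self) -> SiteArrangement:
        if not self.sites:
            raise ConfigError("config defines no sites")
        return SiteArrangement(
            sites=tuple(s.build() for s in self.sites), params=self.helix.build()
        )


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path: str | Path | None) -> RunConfig:
    """Load JSON (or YAML) config; None gives all defaults.

    Unknown keys and out-of-range values raise :class:`ConfigError`
    with the offending field path.
    """
    if path is None:
        return default_config()
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        loc = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"config field {loc!r}: {first['msg']}") from exc


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a config (for run logs)."""
    payload = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
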
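"""Schema-validated run configuration (JSON, with YAML accepted).

A :class:`RunConfig` fully determines a simulation: model parameters,
network options, initial counts, horizon/grid, ensemble size and seed.
Unknown keys are rejected.  Every command writes a manifest echoing the
resolved configuration plus seeds and package version, sufficient to
reproduce the run exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .engine import COMPLETION_FORMS, TEMPLATE_MODES, RateParams
from .network import (
    ReactionNetwork,
    annotate_templates,
    assign_base_constants,
    default_network,
    enumerate_reactions,
    enumerate_species,
    extend_with_inhibitor,
)


class ConfigError(ValueError):
    """Invalid run configuration."""


class RateParamsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    k_uni_default: float = Field(1.0, gt=0)
    k_bi_base: float = Field(5.0, gt=0)
    D: float = Field(1.0, gt=0)
    k_nano: float = Field(1000.0, ge=0)
    template_factor: float = Field(10.0, ge=1)
    k_d: float = Field(0.05, ge=0)
    temperature: float = Field(1.0, gt=0)
    volume: float = Field(1.0, gt=0)
    mass_per_mo: float = Field(1.0, gt=0)
    template_mode: str = "presence"
    completion_form: str = "hyperbolic"

    def to_params(self) -> RateParams:
        if self.template_mode not in TEMPLATE_MODES:
            raise ConfigError(f"template_mode must be one of {TEMPLATE_MODES}")
        if self.completion_form not in COMPLETION_FORMS:
            raise ConfigError(f"completion_form must be one of {COMPLETION_FORMS}")
        return RateParams(**self.model_dump())


class InhibitorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    binding_k: float = Field(ge=0)
    release_k: float = Field(ge=0)
    bound_targets: list[str] = ["Mo6", "Mo36"]


class NetworkConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    max_nuclearity: int = Field(154, ge=1)
    targets: list[int] = [36, 132, 154]
    mixing_threshold: int = Field(6, ge=2)
    growth_mode: str = "auto"
    template_rules: str = "default"  # "default" | "none"
    slow_degrade: list[str] | None = None
    inhibitor: InhibitorConfig | None = None


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    params: RateParamsConfig = RateParamsConfig()
    network: NetworkConfig = NetworkConfig()
    init_counts: dict[str, int] = {"Mo1": 2000}
    horizon: float = Field(8.0, gt=0)
    grid_points: int = Field(201, ge=2)
    n_replicates: int = Field(1, ge=1)
    seed: int = 0
    window: float = Field(0.5, gt=0, le=1)

    def build(self) -> tuple[ReactionNetwork, RateParams]:
        params = self.params.to_params()
        nc = self.network
        if nc.template_rules not in ("default", "none"):
            raise ConfigError("template_rules must be 'default' or 'none'")
        species = enumerate_species(nc.max_nuclearity, nc.targets, nc.mixing_threshold)
        net = enumerate_reactions(
            species, nc.max_nuclearity, nc.growth_mode, nc.mixing_threshold
        )
        net = annotate_templates(net, [] if nc.template_rules == "none" else None)
        net = assign_base_constants(net, params, nc.slow_degrade)
        if nc.inhibitor is not None:
            net = extend_with_inhibitor(
                net,
                nc.inhibitor.binding_k,
                nc.inhibitor.release_k,
                nc.inhibitor.bound_targets,
            )
            net = _reassign_plain(net)
        unknown = set(self.init_counts) - set(net.species_by_id)
        if unknown:
            raise ConfigError(f"init_counts name unknown species {sorted(unknown)}")
        return net, params


def _reassign_plain(net: ReactionNetwork) -> ReactionNetwork:
    return net  # inhibitor reactions carry their own constants already


def load_config(path) -> RunConfig:
    """Load a JSON (or YAML) run configuration with schema validation."""
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError:
        payload = yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    return RunConfig.model_validate(payload)


def write_manifest(out_dir, config: RunConfig, seeds: list[int], extra: dict | None = None) -> Path:
    """Write the reproducibility manifest for one output directory."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.model_dump(),
        "seeds": seeds,
    }
    if extra:
        manifest.update(extra)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
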
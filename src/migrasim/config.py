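"""YAML run configuration shared by the CLI subcommands.

A run config names the input/output paths, the model parameters, the
simulation horizon and date origin, and the generator / calibration /
scenario settings. Every command writes a manifest (config hash + seed) next
to its outputs so any run can be replayed from its logged config alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .calibration import CalibrationSpec
from .dynamics import ModelParameters
from .events import ScenarioComponent, ScenarioSpec
from .population import ConfigurationError, PopulationConfig, Region, default_config

DEFAULT_RISK_GROUPS = {"child": 1.2, "adult": 1.0, "elderly": 1.2}


@dataclass
class RunConfig:
    seed: int = 0
    date_origin: str = "2022-03-01"
    horizon: int = 30
    paths: dict[str, str] = field(default_factory=dict)
    population: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=lambda: {"radius_km": 1.0, "max_neighbors": 20})
    risk_proneness: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RISK_GROUPS))
    params: dict[str, Any] = field(default_factory=dict)
    calibration: dict[str, Any] = field(default_factory=dict)
    scenario: dict[str, Any] = field(default_factory=dict)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    # -- derived objects ----------------------------------------------------

    def model_parameters(self) -> ModelParameters:
        return ModelParameters(**self.params)

    def population_config(self) -> PopulationConfig:
        pop = dict(self.population)
        seed = pop.pop("seed", self.seed)
        if not pop:
            return default_config(seed=seed)
        if "regions" in pop:
            pop["regions"] = [Region(**r) for r in pop["regions"]]
            pop.setdefault("n_households", 1000)
            base = default_config(pop.pop("n_households"), seed)
            return PopulationConfig(
                n_households=base.n_households,
                household_size_probs=pop.get("household_size_probs", base.household_size_probs),
                age_pyramid=[tuple(b) for b in pop["age_pyramid"]] if "age_pyramid" in pop else base.age_pyramid,
                female_fraction=pop.get("female_fraction", base.female_fraction),
                regions=pop["regions"],
                seed=seed,
            )
        base = default_config(pop.pop("n_households", 1000), seed)
        if "household_size_probs" in pop or "age_pyramid" in pop or "female_fraction" in pop:
            return PopulationConfig(
                n_households=base.n_households,
                household_size_probs=pop.get("household_size_probs", base.household_size_probs),
                age_pyramid=[tuple(b) for b in pop.get("age_pyramid", base.age_pyramid)],
                female_fraction=pop.get("female_fraction", base.female_fraction),
                regions=base.regions,
                seed=seed,
            )
        return base

    def calibration_spec(self) -> CalibrationSpec:
        cal = dict(self.calibration)
        if "bounds" in cal:
            cal["bounds"] = {k: tuple(v) for k, v in cal["bounds"].items()}
        if "free_parameters" in cal:
            cal["free_parameters"] = tuple(cal["free_parameters"])
        cal.setdefault("seed", self.seed)
        return CalibrationSpec(**cal)

    def scenario_spec(self) -> ScenarioSpec:
        sc = dict(self.scenario)
        if "components" not in sc:
            raise ConfigurationError("scenario config requires a 'components' list")
        components = [ScenarioComponent(**c) for c in sc.pop("components")]
        sc.setdefault("seed", self.seed)
        return ScenarioSpec(components=components, **sc)

    # -- provenance ---------------------------------------------------------

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def write_manifest(self, out_dir, command: str, extra: Mapping[str, Any] | None = None) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest = {
            "command": command,
            "seed": self.seed,
            "config_hash": self.config_hash(),
            "config": asdict(self),
        }
        if extra:
            manifest.update(extra)
        path = out_dir / f"{command}_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, default=str))
        return path
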
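"""Flat, versioned run configuration.

Every default that has a standard-parameterisation value uses it
(S = 30, C = 0.15, Z = 100, K = 540 µgC/L, y = 10/d, h = 1.2,
f_a = 0.4, f_m = 0.1, e = 0.45/0.85, extinction threshold 1e-6 µgC/L,
100-day season, 300 years = 200 burn-in + 100 analysis, 500 webs).
Configs round-trip losslessly through YAML/JSON and unknown keys are
rejected by name, so parameter provenance stays auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import DynamicsParams
from .experiment import EnsembleConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Configuration schema violation, naming the offending key."""


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    # structure
    S: int = 30
    C: float = 0.15
    Z: float = 100.0
    connectance_tol: float = 0.05
    # life history
    t_max: int = 3
    leslie_stay: float = 0.1
    leslie_advance: float = 0.9
    allow_conspecific_predation: bool = True
    permissive_empty_diet: bool = False
    # dynamics
    K_cap: float = 540.0
    r_mean: float = 0.9
    r_sd: float = 0.2
    r_min: float = 0.6
    r_max: float = 1.2
    y_max: float = 10.0
    e_autotroph: float = 0.45
    e_heterotroph: float = 0.85
    hill: float = 1.2
    f_a: float = 0.4
    f_m: float = 0.1
    B0: float = 80.0
    c_interference: float = 0.0
    extinction_threshold: float = 1e-6
    season_days: float = 100.0
    samples_per_season: int = 100
    loss_efficiency_form: str = "multiply"
    init_biomass_min: float = 5.0
    init_biomass_max: float = 500.0
    rtol: float = 1e-6
    atol: float = 1e-9
    solver: str = "LSODA"
    # ensemble
    n_webs: int = 500
    years: int = 300
    burn_in: int = 200
    model_types: list[str] = field(
        default_factory=lambda: ["original", "unlinked", "linked"]
    )
    blowup_ceiling: float = 1e10
    seed: int = 0
    out_dir: str = "."

    def to_dynamics_params(self) -> DynamicsParams:
        return DynamicsParams(
            K_cap=self.K_cap, r_mean=self.r_mean, r_sd=self.r_sd,
            r_bounds=(self.r_min, self.r_max), y_max=self.y_max,
            e_autotroph=self.e_autotroph, e_heterotroph=self.e_heterotroph,
            hill=self.hill, f_a=self.f_a, f_m=self.f_m, B0=self.B0,
            c_interference=self.c_interference,
            extinction_threshold=self.extinction_threshold,
            season_days=self.season_days,
            samples_per_season=self.samples_per_season,
            loss_efficiency_form=self.loss_efficiency_form,
            leslie_stay=self.leslie_stay, leslie_advance=self.leslie_advance,
            init_biomass_range=(self.init_biomass_min, self.init_biomass_max),
            rtol=self.rtol, atol=self.atol, solver=self.solver,
        )

    def to_ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            n_webs=self.n_webs, years=self.years, burn_in=self.burn_in,
            S=self.S, C=self.C, Z=self.Z, seed=self.seed,
            model_types=tuple(self.model_types),
            connectance_tol=self.connectance_tol,
            blowup_ceiling=self.blowup_ceiling,
            dynamics=self.to_dynamics_params(),
            allow_conspecific_predation=self.allow_conspecific_predation,
            reject_empty_diet=not self.permissive_empty_diet,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON, a YAML subset) config; defaults fill
    missing keys, unknown keys raise :class:`ConfigError`."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config key: {key!r}")
    if data.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ConfigError(
            f"unsupported schema_version: {data['schema_version']!r}"
        )
    try:
        return RunConfig(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc))


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
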
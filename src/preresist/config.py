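"""Strict configuration loading (YAML or JSON).

Unknown keys are an error — for a one-formula model a silently ignored
parameter is the most dangerous failure mode.  Missing keys take the package
defaults; an explicit ``u`` overrides the per-base-rate times
number-of-positions product.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .model import (
    ModelParameters,
    TumorGeometry,
    DEFAULT_MUTATION_RATE_PER_BASE,
    DEFAULT_N_RESISTANCE_POSITIONS,
)

__all__ = ["ConfigError", "ModelConfig", "load_config", "CONFIG_KEYS"]

CONFIG_KEYS = frozenset({
    "mutation_rate_per_base",
    "n_resistance_positions",
    "u",
    "l",
    "d",
    "a",
    "b",
    "cell_density_per_cm3",
    "tumor_purity",
    "stem_fraction",
    "limit_threshold",
})


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Merged model + geometry configuration with its raw echo."""

    params: ModelParameters
    geometry_template: TumorGeometry  # diameter_cm = 0; use .with_diameter()
    raw: dict

    def echo(self) -> dict:
        """Full effective parameter set for provenance blocks."""
        return {
            "u": self.params.u,
            "l": self.params.l,
            "d": self.params.d,
            "a": self.params.a,
            "b": self.params.b,
            "limit_threshold": self.params.limit_threshold,
            "cell_density_per_cm3": self.geometry_template.cell_density_per_cm3,
            "tumor_purity": self.geometry_template.tumor_purity,
            "stem_fraction": self.geometry_template.stem_fraction,
        }


def _build(values: dict) -> ModelConfig:
    rate = values.get("mutation_rate_per_base", DEFAULT_MUTATION_RATE_PER_BASE)
    n_pos = values.get("n_resistance_positions", DEFAULT_N_RESISTANCE_POSITIONS)
    u = values.get("u", rate * n_pos)
    params = ModelParameters(
        u=u,
        l=values.get("l", 1.0),
        d=values.get("d", 0.0),
        a=values.get("a", 0.0),
        b=values.get("b", 0.0),
        limit_threshold=values.get("limit_threshold", 1e-12),
    )
    geometry = TumorGeometry(
        diameter_cm=0.0,
        cell_density_per_cm3=values.get("cell_density_per_cm3", 1e9),
        tumor_purity=values.get("tumor_purity", 0.5),
        stem_fraction=values.get("stem_fraction", 6.2e-3),
    )
    return ModelConfig(params=params, geometry_template=geometry, raw=dict(values))


def default_config() -> ModelConfig:
    return _build({})


def load_config(path: str | Path | None, overrides: dict | None = None) -> ModelConfig:
    """Load a YAML/JSON config file and apply flag overrides on top.

    ``path=None`` gives the full default configuration.  Unknown keys raise
    :class:`ConfigError` naming them; parse failures name the file.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        try:
            if path.suffix.lower() == ".json":
                loaded = json.loads(text) if text.strip() else {}
            else:
                loaded = yaml.safe_load(text)
        except (yaml.YAMLError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping, got {type(loaded).__name__}")
        unknown = sorted(set(loaded) - CONFIG_KEYS)
        if unknown:
            raise ConfigError(f"unknown config keys in {path}: {', '.join(unknown)}")
        values.update(loaded)
    if overrides:
        unknown = sorted(set(overrides) - CONFIG_KEYS)
        if unknown:
            raise ConfigError(f"unknown override keys: {', '.join(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
    return _build(values)
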
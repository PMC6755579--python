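"""YAML configuration: override any swarm or scoring parameter.

Layout::

    chaos:
      map: singer        # logistic|singer|sinusoidal|tent|zaslavskii|none
      seed: 1
    pso:
      n_particles: 8
      inertia: 0.36
      cognitive: 0.99
      social: 0.99
      ls_ratio: 0.1
      stall_generations: 18
      max_generations: 200
    scoring:
      gauss1: -0.035579
      cutoff: 8.0
      vdw_radii: {C: 1.9}
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

import yaml

from .optimizer import SwarmConfig
from .scoring import ScoringParams

__all__ = ["load_config", "swarm_config_from_dict", "scoring_params_from_dict"]


def _apply(instance, overrides: dict, label: str):
    valid = {f.name for f in fields(instance)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown {label} config keys: {sorted(unknown)}")
    return replace(instance, **overrides)


def swarm_config_from_dict(cfg: dict, base: SwarmConfig | None = None) -> SwarmConfig:
    base = base or SwarmConfig()
    pso = dict(cfg.get("pso", {}))
    chaos = cfg.get("chaos", {})
    if "map" in chaos:
        pso["chaos_map"] = None if chaos["map"] in (None, "none") else chaos["map"]
    if "seed" in chaos:
        pso["seed"] = int(chaos["seed"])
    return _apply(base, pso, "pso")


def scoring_params_from_dict(cfg: dict,
                             base: ScoringParams | None = None) -> ScoringParams:
    return _apply(base or ScoringParams(), dict(cfg.get("scoring", {})), "scoring")


def load_config(path) -> dict:
    """Read a YAML config file into a plain dict (empty file -> {})."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return data
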
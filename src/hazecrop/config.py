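"""YAML configuration for the pipeline.

A config file may carry any of the blocks ``rt`` (radiative-transfer optics),
``impact`` (response betas, diffuse multipliers, cloud fraction) and
``synthetic`` (AOD generator parameters); absent keys fall back to package
defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .crop_impact import (
    DEFAULT_CLOUD_FRACTION,
    DEFAULT_DIFFUSE_CASES,
    DiffuseCase,
    YieldResponseModel,
)
from .radiative_transfer import RTConfig

# default response coefficients, calibrated with scripts/calibrate_beta.py on
# the default synthetic reference run (seed 0); see docs/methods.md
DEFAULT_BETAS: dict[str, float] = {"wheat": 0.4267, "rice": 0.2189}


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def rt_config_from(config: dict) -> RTConfig:
    return RTConfig.from_mapping(config.get("rt", {}))


def impact_config_from(config: dict):
    """Returns (response models, diffuse cases, cloud fraction)."""
    block = config.get("impact", {})
    betas = {**DEFAULT_BETAS, **block.get("betas", {})}
    models = {crop: YieldResponseModel(crop, beta) for crop, beta in betas.items()}
    if "diffuse_k" in block:
        cases = tuple(DiffuseCase(label, k) for label, k in block["diffuse_k"].items())
    else:
        cases = DEFAULT_DIFFUSE_CASES
    cloud = block.get("cloud_fraction", DEFAULT_CLOUD_FRACTION)
    return models, cases, cloud
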
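"""Study configuration: one validated document driving the whole pipeline."""

from __future__ import annotations

from typing import List, Optional, Tuple, Union

import yaml
from pydantic import BaseModel, field_validator

from .exceptions import ConfigError
from .group_analysis import DEFAULT_VENTRICLE_LABELS

__all__ = ["StudyConfig"]

KNOWN_MODELS = ("LP", "1TC", "2TC", "LR", "SRTM", "SUV", "1TC-mAIF")


class StudyConfig(BaseModel):
    """Paths, model selection and analysis conventions for one study run."""

    tac_table: str
    sessions_table: str
    blood_table: Optional[str] = None
    output_dir: str = "petkin_out"
    models: List[str] = ["LP", "1TC", "LR", "SRTM", "SUV"]
    reference_region: str = "brainstem"
    suv_convention: str = "as-printed"
    logan_t_star_min: float = 15.0
    # k2' policy for the Logan reference plot: a number fixes it, the string
    # "srtm-median" takes the session median over the reference region's
    # contralateral SRTM fits, None drops the C_ref/k2' term.
    lr_k2_prime: Union[float, str, None] = "srtm-median"
    suv_window_min: Tuple[float, float] = (0.0, 60.0)
    alpha: float = 0.05
    aggregation: str = "mean-of-sides"
    exclusions: List[str] = list(DEFAULT_VENTRICLE_LABELS)
    seed: int = 0

    @field_validator("models")
    @classmethod
    def _check_models(cls, models):
        if not models:
            raise ValueError("model list must be non-empty")
        unknown = [m for m in models if m not in KNOWN_MODELS]
        if unknown:
            raise ValueError(f"unknown model(s): {', '.join(unknown)}; "
                             f"choose from {', '.join(KNOWN_MODELS)}")
        return models

    @field_validator("alpha")
    @classmethod
    def _check_alpha(cls, alpha):
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        return alpha

    @field_validator("suv_convention")
    @classmethod
    def _check_convention(cls, conv):
        if conv not in ("as-printed", "conventional"):
            raise ValueError("suv_convention must be 'as-printed' or 'conventional'")
        return conv

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        try:
            with open(path) as fh:
                payload = yaml.safe_load(fh)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        if not isinstance(payload, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        try:
            return cls(**payload)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)
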
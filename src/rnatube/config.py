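"""Run configuration and provenance manifests.

Configurations are YAML/JSON files validated against a strict schema
(unknown keys rejected); every stochastic stage carries an explicit seed.
A run manifest echoes every effective parameter and seed so each output
file is traceable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

__all__ = ["RunConfig", "ConfigError", "load_config", "write_manifest", "manifest_hash"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AFMSimConfig(_Strict):
    preset: str = "WT_AFM"
    n_filaments: int = Field(100, ge=1)
    pixel_size_nm: float | None = Field(None, gt=0)
    noise_sd_nm: float | None = Field(None, ge=0)
    seed: int = 0


class GUVSimConfig(_Strict):
    image_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = Field(0.2, gt=0)
    n_vesicles: int = Field(3, ge=0)
    radius_um_range: tuple[float, float] = (5.0, 20.0)
    rna_mode: str = "cortex"
    noise_sd: float = Field(0.0, ge=0)
    seed: int = 0


class TrajSimConfig(_Strict):
    n_layers: int = Field(20, ge=1)
    tiles_per_layer: int = Field(3, ge=1)
    nt_per_tile: int = Field(72, ge=48)
    bend_P_nm: float = Field(2000.0, gt=0)
    n_frames: int = Field(200, ge=1)
    save_every_steps: int = Field(500_000, ge=1)
    seed: int = 0


class TraceConfig(_Strict):
    pixel_size_nm: float = Field(4.0, gt=0)
    use_otsu: bool = False  # threshold the height image instead of a given mask
    level_rows: bool = False
    exclude_cycles: bool = True


class FitConfig(_Strict):
    min_length_nm: float = Field(200.0, ge=0)
    s: float = Field(1.0, gt=0)
    fix_s: bool = True
    mask_residuals: bool = True
    final_fraction: float = Field(0.1, gt=0, le=1)
    middle_fraction: float = Field(0.8, gt=0, le=1)


class GUVAnalyzeConfig(_Strict):
    pixel_size_um: float = Field(0.2, gt=0)
    min_fraction_pct: float = Field(1.0, ge=0)
    hough_radius_range_px: tuple[int, int] = (20, 80)
    circularity_estimator: str = "contour"


class RunConfig(_Strict):
    """Top-level configuration; each stage section is optional."""

    simulate_afm: AFMSimConfig | None = None
    simulate_guv: GUVSimConfig | None = None
    simulate_traj: TrajSimConfig | None = None
    trace: TraceConfig | None = None
    fit: FitConfig | None = None
    guv_analyze: GUVAnalyzeConfig | None = None
    output_dir: str = "results"


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as e:
        missing = [
            ".".join(str(p) for p in err["loc"])
            for err in e.errors()
            if err["type"] == "missing"
        ]
        detail = f"; missing keys: {missing}" if missing else ""
        raise ConfigError(f"invalid configuration {path}: {e}{detail}") from e


def manifest_hash(manifest: dict) -> str:
    return hashlib.sha256(
        json.dumps(manifest, sort_keys=True, default=str).encode()
    ).hexdigest()


def write_manifest(path, config: RunConfig | dict, extra: dict | None = None) -> dict:
    """Write a JSON manifest echoing every effective parameter and seed."""
    params = config.model_dump() if isinstance(config, RunConfig) else dict(config)
    manifest = {"parameters": params, **(extra or {})}
    manifest["hash"] = manifest_hash(manifest)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str, sort_keys=True))
    return manifest
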
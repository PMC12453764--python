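"""Run configuration: nested YAML sections with strict key checking.

Every pipeline run resolves its configuration (defaults, then YAML file,
then CLI overrides), writes the resolved copy and a timestamped log into the
output directory, and derives per-stage seeds from the single global seed by
fixed offsets, so any run is reproducible from the saved config alone.
"""

from __future__ import annotations

import copy
import datetime
from pathlib import Path

import yaml

DEFAULTS: dict = {
    "seed": 0,
    "output_dir": "runs",
    "log_level": "info",
    "synthdata": {
        "n_images": 200,
        "image_size": [64, 64],
        "prevalence": 0.5,
        "lesion_axes_range": [8.0, 16.0],
        "lesion_intensity_shift": 0.2,
        "lesion_noise_sd": 0.08,
        "background_noise_sd": 0.05,
        "clinical_effect_beta": 1.0,
    },
    "preprocess": {
        "target_size": [256, 256],
        "sanlm_h": 0.1,
        "sanlm_patch_radius": 1,
        "sanlm_search_radius": 2,
        "resample_mode": "nearest",
    },
    "patching": {"patch_size": 32, "stride": None},
    "fcrn": {
        "learning_rate": 0.001,
        "batch_size": 32,
        "epochs": 8,
        "patience": 10,
        "activation": "leaky_relu",
        "per_class_patches": 400,
    },
    "probmap": {"map_stride": 16, "top_n": 8, "threshold": 0.5,
                "reduction": "column_mean"},
    "clinical": {
        "continuous": ["age", "symptom_duration"],
        "categorical": ["gender", "history_flag", "skin_type"],
    },
    "fusion": {"learning_rate": 0.001, "batch_size": 16, "epochs": 10,
               "branch": "conv1d"},
    "evaluate": {"folds": 5, "head_seeds": []},
}

# fixed per-stage seed offsets fanned out from the global seed
SEED_OFFSETS = {"synthdata": 0, "fcrn": 1, "fusion": 2, "split": 3, "augment": 4}


class ConfigError(ValueError):
    pass


def _merge_strict(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        where = f"{path}.{key}" if path else key
        if key not in base:
            raise ConfigError(f"unknown config key: {where}")
        if isinstance(base[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config section {where} must be a mapping")
            out[key] = _merge_strict(base[key], value, where)
        else:
            out[key] = value
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, overlaid by a YAML file, overlaid by explicit overrides."""
    cfg = copy.deepcopy(DEFAULTS)
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _merge_strict(cfg, data)
    if overrides:
        cfg = _merge_strict(cfg, overrides)
    return cfg


def stage_seed(cfg: dict, stage: str) -> int:
    return (int(cfg["seed"]) + SEED_OFFSETS.get(stage, 0)) % (2 ** 31)


def finalize_run(outdir: str | Path, cfg: dict, log_lines: list[str]) -> None:
    """Write the resolved config and a timestamped log into the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with open(outdir / "run.log", "a") as fh:
        for line in log_lines:
            fh.write(f"{stamp} {line}\n")
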
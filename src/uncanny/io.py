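"""Configuration loading, validation and result serialization.

Configs resolve in three layers: built-in defaults (the typical-condition
parameterization), then values from a YAML/JSON file, then explicit
overrides (e.g. CLI ``--set`` flags).  Two presets ship with the package:
``typical`` (human-category mean 1.0) and ``asd`` (mean 1.25).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .experiments import EffectiveInterval, SweepResult
from .learning import LearningConfig, LearningTrace
from .model import Category, Cue, ModelConfig, ResponseCurve

__all__ = [
    "ConfigError",
    "RunManifest",
    "DEFAULT_CONFIG",
    "load_config",
    "preset_path",
    "resolve_config",
    "config_digest",
    "write_outputs",
    "read_curve",
]

log = logging.getLogger("uncanny")


class ConfigError(ValueError):
    """Invalid, unknown or out-of-range configuration input."""


#: The typical-condition defaults.
DEFAULT_CONFIG: dict[str, Any] = {
    "categories": [
        {"mean": 0.5, "sd": 0.5, "prior": 0.5, "label": "background"},
        {"mean": 1.0, "sd": 0.05, "prior": 0.5, "label": "human"},
    ],
    "cues": [
        {"sigma_s": 0.2, "label": "S1"},
        {"sigma_s": 0.05, "label": "S2"},
    ],
    "alpha": 150.0,
    "beta": 0.5,
    "human_index": 1,
    "tension_ddof": 1,
    "learning": {
        "presented_stimulus": 0.4,
        "delta": 0.1,
        "n_trials": 500,
        "variance_floor": 1e-6,
    },
}

_TOP_KEYS = {"categories", "cues", "alpha", "beta", "human_index",
             "tension_ddof", "learning"}
_CATEGORY_KEYS = {"mean", "sd", "prior", "label"}
_CUE_KEYS = {"sigma_s", "label"}
_LEARNING_KEYS = {"presented_stimulus", "delta", "n_trials", "variance_floor",
                  "seed"}

#: Flat override shorthands mapping to nested config paths.
_SHORTHAND = {
    "mu_c1": ("categories", 0, "mean"),
    "sigma_c1": ("categories", 0, "sd"),
    "prior_c1": ("categories", 0, "prior"),
    "mu_c2": ("categories", 1, "mean"),
    "sigma_c2": ("categories", 1, "sd"),
    "prior_c2": ("categories", 1, "prior"),
    "sigma_s1": ("cues", 0, "sigma_s"),
    "sigma_s2": ("cues", 1, "sigma_s"),
    "alpha": ("alpha",),
    "beta": ("beta",),
    "human_index": ("human_index",),
    "tension_ddof": ("tension_ddof",),
    "sp": ("learning", "presented_stimulus"),
    "presented_stimulus": ("learning", "presented_stimulus"),
    "delta": ("learning", "delta"),
    "n_trials": ("learning", "n_trials"),
    "variance_floor": ("learning", "variance_floor"),
}


def preset_path(name: str) -> Path:
    """Path of a shipped preset config (``typical`` or ``asd``)."""
    ref = resources.files("uncanny").joinpath(f"presets/{name}.yaml")
    if not ref.is_file():
        available = sorted(
            p.name[:-5]
            for p in resources.files("uncanny").joinpath("presets").iterdir()
            if p.name.endswith(".yaml")
        )
        raise ConfigError(f"unknown preset {name!r}; available: {available}")
    return Path(str(ref))


def _check_keys(mapping: Mapping, allowed: set, context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown {context} key(s) {sorted(unknown)}; valid keys: "
            f"{sorted(allowed)}"
        )


def _merge(base: dict, update: Mapping) -> dict:
    out = dict(base)
    for key, value in update.items():
        if key in ("categories", "cues") and value is not None:
            items = [dict(d) for d in base[key]]
            for i, entry in enumerate(value):
                allowed = _CATEGORY_KEYS if key == "categories" else _CUE_KEYS
                _check_keys(entry, allowed, key[:-1] if key.endswith("s") else key)
                if i < len(items):
                    items[i].update(entry)
                else:
                    items.append(dict(entry))
            out[key] = items
        elif key == "learning" and value is not None:
            _check_keys(value, _LEARNING_KEYS, "learning")
            out[key] = {**base["learning"], **value}
        else:
            out[key] = value
    return out


def _apply_shorthand(config: dict, overrides: Mapping[str, Any]) -> dict:
    out = json.loads(json.dumps(config))  # deep copy of plain data
    for key, value in overrides.items():
        if key not in _SHORTHAND:
            raise ConfigError(
                f"unknown override {key!r}; valid overrides: "
                f"{sorted(_SHORTHAND)}"
            )
        node = out
        *path, leaf = _SHORTHAND[key]
        for part in path:
            node = node[part]
        node[leaf] = value
    return out


def resolve_config(data: dict) -> tuple[ModelConfig, LearningConfig]:
    """Build validated config objects from a plain mapping."""
    _check_keys(data, _TOP_KEYS, "config")
    try:
        model = ModelConfig(
            categories=tuple(Category(**c) for c in data["categories"]),
            cues=tuple(Cue(**c) for c in data["cues"]),
            alpha=float(data["alpha"]),
            beta=float(data["beta"]),
            human_index=int(data["human_index"]),
            tension_ddof=int(data["tension_ddof"]),
        )
        learn_data = dict(data["learning"])
        learn_data["n_trials"] = int(learn_data["n_trials"])
        learn = LearningConfig(**learn_data)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    return model, learn


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> tuple[ModelConfig, LearningConfig]:
    """Load and validate a model + learning configuration.

    ``path`` may be a YAML/JSON file, a preset name (``typical``/``asd``)
    or None for the built-in defaults.  File values override defaults and
    ``overrides`` (flat shorthand keys such as ``mu_c2`` or ``delta``)
    override both.
    """
    data = json.loads(json.dumps(DEFAULT_CONFIG))
    if path is not None:
        path = Path(path)
        if not path.exists() and path.suffix == "":
            path = preset_path(str(path))
        try:
            raw = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} must contain a mapping at top level")
        _check_keys(raw, _TOP_KEYS, "config")
        data = _merge(data, raw)
    if overrides:
        data = _apply_shorthand(data, overrides)
    model, learn = resolve_config(data)
    log.info("resolved config digest=%s alpha=%s beta=%s mu_h=%s sd_h=%s",
             config_digest(model, learn), model.alpha, model.beta,
             model.human.mean, model.human.sd)
    return model, learn


def config_digest(model: ModelConfig, learn: LearningConfig | None = None) -> str:
    """Short content hash identifying a resolved configuration."""
    payload = {
        "categories": [
            {"mean": c.mean, "sd": c.sd, "prior": c.prior}
            for c in model.categories
        ],
        "cues": [{"sigma_s": c.sigma_s} for c in model.cues],
        "alpha": model.alpha,
        "beta": model.beta,
        "human_index": model.human_index,
        "tension_ddof": model.tension_ddof,
    }
    if learn is not None:
        payload["learning"] = {
            "presented_stimulus": learn.presented_stimulus,
            "delta": learn.delta,
            "n_trials": learn.n_trials,
            "variance_floor": learn.variance_floor,
        }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class RunManifest:
    """Record of one CLI or scripted run."""

    command: str
    config_digest: str
    output_paths: tuple[str, ...]
    tool_version: str = __version__

    def as_dict(self) -> dict:
        return {
            "command": self.command,
            "config_digest": self.config_digest,
            "output_paths": list(self.output_paths),
            "tool_version": self.tool_version,
        }


# -- serialization -----------------------------------------------------------

CURVE_COLUMNS = ["h", "V", "F_S1", "F_S2", "Y"]


def _curve_frame(curve: ResponseCurve) -> pd.DataFrame:
    data = {"h": curve.grid, "V": curve.V}
    for i in range(curve.per_cue_F.shape[0]):
        data[f"F_S{i + 1}"] = curve.per_cue_F[i]
    data["Y"] = curve.Y
    return pd.DataFrame(data)


def _write_one(result, out_dir: Path, stem: str) -> list[Path]:
    if isinstance(result, ResponseCurve):
        path = out_dir / f"{stem}.csv"
        _curve_frame(result).to_csv(path, index=False)
        return [path]
    if isinstance(result, LearningTrace):
        path = out_dir / f"{stem}.csv"
        result.as_frame().to_csv(path, index=False)
        return [path]
    if isinstance(result, EffectiveInterval):
        path = out_dir / f"{stem}.json"
        path.write_text(json.dumps(result.as_dict(), indent=2) + "\n")
        return [path]
    if isinstance(result, SweepResult):
        paths = []
        for value, output in zip(result.sweep_values, result.outputs):
            tag = f"{result.parameter or 'value'}_{value:g}".replace(".", "p")
            paths.extend(_write_one(output, out_dir, f"{stem}_{tag}"))
        if result.outputs and isinstance(result.outputs[0], LearningTrace):
            summary = out_dir / f"{stem}_terminal.json"
            summary.write_text(
                json.dumps(
                    {
                        "sweep_values": [float(v) for v in result.sweep_values],
                        "terminal_variance": [
                            float(v) for v in result.terminal_variances
                        ],
                        "initial_variance": result.initial_variance,
                        "condition": result.condition_label,
                    },
                    indent=2,
                )
                + "\n"
            )
            paths.append(summary)
        return paths
    raise TypeError(f"cannot serialize {type(result).__name__}")


def write_outputs(
    result,
    out_dir: str | Path,
    *,
    stem: str = "result",
    command: str = "library",
    digest: str = "",
) -> RunManifest:
    """Serialize a result (curve, trace, sweep or interval) under ``out_dir``.

    Tabular series go to CSV, scalar summaries to JSON; the manifest is
    written last so its listed paths are guaranteed to exist.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = _write_one(result, out_dir, stem)
    manifest = RunManifest(
        command=command,
        config_digest=digest,
        output_paths=tuple(str(p) for p in paths),
    )
    (out_dir / f"{stem}_manifest.json").write_text(
        json.dumps(manifest.as_dict(), indent=2) + "\n"
    )
    return manifest


def read_curve(path: str | Path) -> ResponseCurve:
    """Re-read a serialized response curve (round-trips ``write_outputs``)."""
    frame = pd.read_csv(path)
    cue_cols = [c for c in frame.columns if c.startswith("F_S")]
    return ResponseCurve(
        grid=frame["h"].to_numpy(),
        Y=frame["Y"].to_numpy(),
        per_cue_F=np.stack([frame[c].to_numpy() for c in cue_cols]),
        V=frame["V"].to_numpy(),
    )
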
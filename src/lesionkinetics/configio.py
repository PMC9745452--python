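"""YAML/JSON (de)serialisation of :class:`ExperimentConfig`."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import ExperimentConfig, PopModel, ResponseTruth

__all__ = ["config_to_dict", "config_from_dict", "load_config", "save_config"]


def config_to_dict(config: ExperimentConfig) -> dict:
    return {
        "seed": config.seed,
        "n_per_cell": config.n_per_cell,
        "c_ratio": config.c_ratio,
        "d_ratio": config.d_ratio,
        "design": {
            f"{power:g}": list(times)
            for power, times in sorted(config.times_by_power.items())
        },
        "forces": list(config.forces),
        "truths": [
            {
                "power_w": power, "cf_g": cf, "response": resp,
                "ymax": truth.ymax, "k": truth.k,
                **(
                    {"noise_sd": truth.noise_sd}
                    if truth.noise_sd is not None
                    else {"noise_cv": truth.noise_cv}
                ),
            }
            for (power, cf, resp), truth in sorted(config.truths.items())
        ],
        "pop_models": {
            f"{power:g}": {"intercept": m.intercept, "slope": m.slope}
            for power, m in sorted(config.pop_models.items())
        },
    }


def config_from_dict(data: dict) -> ExperimentConfig:
    try:
        truths = {
            (float(row["power_w"]), float(row["cf_g"]), str(row["response"])):
            ResponseTruth(
                ymax=float(row["ymax"]), k=float(row["k"]),
                noise_sd=float(row["noise_sd"]) if "noise_sd" in row else None,
                noise_cv=float(row["noise_cv"]) if "noise_cv" in row else None,
            )
            for row in data["truths"]
        }
        return ExperimentConfig(
            times_by_power={
                float(p): tuple(float(t) for t in times)
                for p, times in data["design"].items()
            },
            forces=tuple(float(f) for f in data["forces"]),
            n_per_cell=int(data["n_per_cell"]),
            truths=truths,
            pop_models={
                float(p): PopModel(
                    intercept=float(m["intercept"]), slope=float(m["slope"])
                )
                for p, m in data["pop_models"].items()
            },
            seed=int(data.get("seed", 0)),
            c_ratio=float(data.get("c_ratio", 0.5)),
            d_ratio=float(data.get("d_ratio", 0.8)),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"malformed config: {exc}") from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a config from a .yaml/.yml or .json file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    path = Path(path)
    data = config_to_dict(config)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))
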
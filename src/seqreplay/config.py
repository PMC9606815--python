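"""Experiment configuration: YAML parsing, validation, serialization,
run manifests and result-bundle output.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .params import ModelParams
from .plasticity import PlasticityGates
from .protocol import (DaySpec, ExperimentSpec, ResultBundle, TestSpec,
                       TrainBlock)
from . import presets as _presets

__all__ = [
    "ConfigError", "load_experiment_config", "parse_experiment_config",
    "serialize_experiment_config", "load_preset", "RunManifest",
    "write_result_bundle",
]


class ConfigError(ValueError):
    """Raised for malformed experiment configuration."""


_TOP_KEYS = {"name", "seed", "days", "nights", "params", "gates",
             "hc_to_ctx_enabled", "trace_weights", "trace_interval"}


def _as_sequence(value: Any, where: str) -> tuple[str, ...]:
    if isinstance(value, str):
        return tuple(value)
    if isinstance(value, (list, tuple)) and all(isinstance(v, str) for v in value):
        return tuple(value)
    raise ConfigError(f"{where}: a sequence must be a string like 'ABCDE' "
                      "or a list of labels")


def _check_keys(d: Mapping, allowed: set[str], where: str) -> None:
    if not isinstance(d, Mapping):
        raise ConfigError(f"{where}: expected a mapping, got {type(d).__name__}")
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown key(s) {sorted(unknown)}; "
                          f"valid keys: {sorted(allowed)}")


def parse_experiment_config(cfg: Mapping[str, Any]) -> ExperimentSpec:
    """Validate a config mapping and build an :class:`ExperimentSpec`."""
    _check_keys(cfg, _TOP_KEYS, "config")
    if "seed" not in cfg or cfg["seed"] is None:
        raise ConfigError("config: an integer 'seed' is required")
    if "days" not in cfg:
        raise ConfigError("config: 'days' is required")

    try:
        params = ModelParams().override(**(cfg.get("params") or {}))
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"config.params: {exc}") from exc

    gate_fields = {f.name for f in fields(PlasticityGates)}
    gd = cfg.get("gates") or {}
    _check_keys(gd, gate_fields, "config.gates")
    gates = PlasticityGates(**gd)

    days: list[DaySpec] = []
    for i, day in enumerate(cfg["days"], start=1):
        _check_keys(day or {}, {"train", "test"}, f"config.days[{i}]")
        blocks = []
        for j, blk in enumerate(day.get("train") or []):
            _check_keys(blk, {"seq", "trials"}, f"config.days[{i}].train[{j}]")
            trials = blk.get("trials", 1)
            if not isinstance(trials, int) or trials < 0:
                raise ConfigError(
                    f"config.days[{i}].train[{j}]: trials must be a "
                    f"non-negative integer, got {trials!r}")
            blocks.append(TrainBlock(
                sequence=_as_sequence(blk.get("seq"),
                                      f"config.days[{i}].train[{j}]"),
                trials=trials))
        tests = []
        for j, t in enumerate(day.get("test") or []):
            _check_keys(t, {"cue", "target", "when"},
                        f"config.days[{i}].test[{j}]")
            when = t.get("when", "auto")
            if when not in ("auto", "morning", "after_training"):
                raise ConfigError(f"config.days[{i}].test[{j}]: bad 'when'")
            tests.append(TestSpec(
                cue=str(t["cue"]),
                target=_as_sequence(t["target"], f"config.days[{i}].test[{j}]"),
                when=when))
        days.append(DaySpec(train=tuple(blocks), tests=tuple(tests)))

    nights = cfg.get("nights", 0)
    if not isinstance(nights, int) or nights < 0:
        raise ConfigError("config: nights must be a non-negative integer")

    try:
        return ExperimentSpec(
            name=str(cfg.get("name", "experiment")),
            seed=int(cfg["seed"]),
            days=tuple(days),
            nights=nights,
            params=params,
            gates=gates,
            hc_to_ctx_enabled=bool(cfg.get("hc_to_ctx_enabled", True)),
            trace_weights=bool(cfg.get("trace_weights", True)),
            trace_interval=float(cfg.get("trace_interval", 0.1)),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_experiment_config(path: str | Path) -> ExperimentSpec:
    """Read and validate a YAML experiment config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        raise ConfigError(f"{path}: empty config file")
    return parse_experiment_config(cfg)


def load_preset(name: str, seed: int | None = None,
                overrides: Mapping[str, Any] | None = None) -> ExperimentSpec:
    """Load a packaged preset, optionally overriding seed/parameters."""
    with _presets.preset_path(name).open() as fh:
        cfg = yaml.safe_load(fh)
    if seed is not None:
        cfg["seed"] = seed
    if overrides:
        merged = dict(cfg.get("params") or {})
        merged.update(overrides)
        cfg["params"] = merged
    return parse_experiment_config(cfg)


def serialize_experiment_config(spec: ExperimentSpec) -> dict:
    """Round-trippable plain-dict form of an :class:`ExperimentSpec`."""
    default = ModelParams()
    params = {k: v for k, v in asdict(spec.params).items()
              if getattr(default, k) != v}
    gates = {k: v for k, v in asdict(spec.gates).items() if v is not True}
    cfg: dict[str, Any] = {
        "name": spec.name,
        "seed": spec.seed,
        "nights": spec.nights,
        "days": [
            {
                **({"train": [{"seq": "".join(b.sequence), "trials": b.trials}
                              for b in day.train]} if day.train else {}),
                **({"test": [{"cue": t.cue, "target": "".join(t.target),
                              **({"when": t.when} if t.when != "auto" else {})}
                             for t in day.tests]} if day.tests else {}),
            }
            for day in spec.days
        ],
    }
    if params:
        cfg["params"] = params
    if gates:
        cfg["gates"] = gates
    if not spec.hc_to_ctx_enabled:
        cfg["hc_to_ctx_enabled"] = False
    if not spec.trace_weights:
        cfg["trace_weights"] = False
    if spec.trace_interval != 0.1:
        cfg["trace_interval"] = spec.trace_interval
    return cfg


# ----------------------------------------------------------------------
@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    name: str
    seed: int
    params: dict
    config: dict
    version: str = ""
    out_dir: str = ""
    started: str = ""
    finished: str = ""

    @classmethod
    def for_spec(cls, spec: ExperimentSpec, out_dir: str = "") -> "RunManifest":
        from . import __version__
        return cls(
            name=spec.name, seed=spec.seed, params=asdict(spec.params),
            config=serialize_experiment_config(spec), version=__version__,
            out_dir=str(out_dir),
            started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )


def write_result_bundle(bundle: ResultBundle, out_dir: str | Path,
                        manifest: RunManifest | None = None) -> Path:
    """Write recalls/replays/weights/salience CSVs plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = RunManifest.for_spec(bundle.spec, str(out))
    float_fmt = "%.9g"
    bundle.recalls_frame().to_csv(out / "recalls.csv", index=False,
                                  float_format=float_fmt)
    bundle.replays_frame().to_csv(out / "replays.csv", index=False,
                                  float_format=float_fmt)
    bundle.weights.to_csv(out / "weights.csv", index=False,
                          float_format=float_fmt)
    bundle.salience.to_csv(out / "salience.csv", index=False,
                           float_format=float_fmt)
    with open(out / "summary.json", "w") as fh:
        json.dump(bundle.summary, fh, indent=2, sort_keys=True)
    manifest.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
    with open(out / "manifest.json", "w") as fh:
        json.dump(asdict(manifest), fh, indent=2, sort_keys=True)
    return out
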
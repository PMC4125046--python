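"""Configuration loading and tabular output.

Run configurations may come from a YAML or JSON file, from CLI flags, or
both (flags override file values); unspecified fields fall back to the
standard training protocol (learning rate 0.1, 1000 trials, 500 replicates,
100-trial summary window).  Tables are written as CSV or JSON records with
floats at 12 significant digits, accompanied by a sibling manifest recording
the exact configuration, seed and package version, so every run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .experiments import TransitionSpec
from .model import (
    ConfigurationError,
    ConsensusRule,
    EnvironmentConfig,
    LearningConfig,
    VotingRule,
)
from .spatial import SpatialConfig

__all__ = ["RunConfig", "load_config", "write_table"]

EXPERIMENT_KINDS = (
    "train",
    "sweep",
    "optimal",
    "landscape",
    "global-compare",
    "transition",
    "isolated-pooled",
    "spatial-validate",
)

_TOP_LEVEL_KEYS = {
    "experiment",
    "r_low",
    "r_high",
    "n",
    "group_sizes",
    "r_lows",
    "r_highs",
    "alpha",
    "v_init",
    "n_trials",
    "n_reps",
    "window",
    "voting",
    "consensus",
    "transition",
    "spatial",
    "seed",
    "out",
}


@dataclass(frozen=True)
class RunConfig:
    """A fully validated experiment configuration."""

    experiment: str
    env: EnvironmentConfig
    n: int
    group_sizes: tuple[int, ...]
    r_lows: tuple[float, ...]
    r_highs: tuple[float, ...]
    learning: LearningConfig
    voting: VotingRule
    consensus: ConsensusRule
    transition: TransitionSpec | None
    spatial: SpatialConfig | None
    seed: int
    out: str | None

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [convert(v) for v in obj]
            return obj

        return {
            f.name: convert(getattr(self, f.name))
            for f in dataclasses.fields(self)
        }


def _build(cls, data: dict, context: str):
    """Construct a config dataclass, rejecting unknown keys by name."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) in {context}: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid {context} configuration: {exc}") from exc


def _read_file(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return data


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a validated :class:`RunConfig` from an optional YAML/JSON file
    plus keyword overrides (overrides win); defaults fill the rest.

    Raises :class:`ConfigurationError` naming the offending key on unknown
    keys or out-of-range values.
    """
    data: dict = {}
    if path is not None:
        data.update(_read_file(path))
    data.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(sorted(unknown))}"
        )

    experiment = data.get("experiment", "train")
    if experiment not in EXPERIMENT_KINDS:
        raise ConfigurationError(
            f"unknown experiment kind {experiment!r}; expected one of "
            + ", ".join(EXPERIMENT_KINDS)
        )

    env = _build(
        EnvironmentConfig,
        {"r_low": data.get("r_low", 0.7), "r_high": data.get("r_high", 0.8)},
        "environment",
    )
    learning = _build(
        LearningConfig,
        {
            k: data[k]
            for k in ("alpha", "v_init", "n_trials", "n_reps", "window")
            if k in data
        },
        "learning",
    )
    voting = _build(VotingRule, dict(data.get("voting", {})), "voting")
    consensus = _build(ConsensusRule, dict(data.get("consensus", {})), "consensus")

    transition = None
    if "transition" in data:
        tdata = dict(data["transition"])
        n = int(data.get("n", 5))
        tdefaults = {
            "change_trial": tdata.pop("change_trial", learning.n_trials // 2),
            "n_before": tdata.pop("n_before", n),
            "n_after": tdata.pop("n_after", n),
            "env_before": EnvironmentConfig(
                tdata.pop("r_low_before", env.r_low),
                tdata.pop("r_high_before", env.r_high),
            ),
            "env_after": EnvironmentConfig(
                tdata.pop("r_low_after", env.r_low),
                tdata.pop("r_high_after", env.r_high),
            ),
        }
        if tdata:
            raise ConfigurationError(
                f"unknown key(s) in transition: {', '.join(sorted(tdata))}"
            )
        transition = TransitionSpec(**tdefaults)

    spatial = None
    if "spatial" in data or experiment == "spatial-validate":
        spatial = _build(SpatialConfig, dict(data.get("spatial", {})), "spatial")

    return RunConfig(
        experiment=experiment,
        env=env,
        n=int(data.get("n", 5)),
        group_sizes=tuple(data.get("group_sizes", (1, 7, 31))),
        r_lows=tuple(data.get("r_lows", (0.6, 0.7, 0.8, 0.9))),
        r_highs=tuple(data.get("r_highs", (0.6, 0.7, 0.8, 0.9))),
        learning=learning,
        voting=voting,
        consensus=consensus,
        transition=transition,
        spatial=spatial,
        seed=int(data.get("seed", 0)),
        out=data.get("out"),
    )


def _format_value(v):
    if isinstance(v, float):
        return float(f"{v:.12g}")
    return v


def write_table(
    rows,
    path: str | Path,
    fmt: str = "csv",
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write homogeneous records as CSV (with header) or JSON records,
    floats at 12 significant digits, plus a sibling ``<stem>.manifest.json``
    recording config, seed and package version."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if fmt == "csv":
        df.to_csv(path, index=False, float_format="%.12g")
    elif fmt == "json":
        records = [
            {k: _format_value(v) for k, v in rec.items()}
            for rec in df.to_dict(orient="records")
        ]
        path.write_text(json.dumps(records, indent=1) + "\n")
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    manifest = {
        "version": __version__,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": config.to_dict() if config is not None else None,
    }
    manifest_path = path.with_suffix(path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1) + "\n")
    return path
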
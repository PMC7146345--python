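"""Run configuration: one validated document for the whole pipeline.

Defaults ship in ``data/default_config.yaml``; user files are merged over
the defaults and unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import yaml


@dataclass(frozen=True)
class WindowCfg:
    length: int
    step: int


@dataclass(frozen=True)
class SynthCfg:
    n_subjects: int = 5
    reps_per_test: int = 20
    sample_rate: float = 50.0
    subject_scale_jitter: float = 0.1
    classes_file: str | None = None  # None -> shipped default class table


@dataclass(frozen=True)
class PreprocessCfg:
    alpha: float = 0.98
    median_window: int = 3


@dataclass(frozen=True)
class FeaturesCfg:
    window_l1: WindowCfg = field(default_factory=lambda: WindowCfg(10, 5))
    window_l3: WindowCfg = field(default_factory=lambda: WindowCfg(4, 2))
    buffer_samples: int = 155
    chunk_samples: int = 55  # on-line buffering granularity (~one repetition)


@dataclass(frozen=True)
class ModelCfg:
    k1: int = 70
    k2: int = 20
    k3: int = 8
    dbscan_eps: float = 0.2
    dbscan_min_pts: int = 2
    greedy_tol: float = 0.0
    threshold_percentile: float = 99.5
    min_run: int = 2

    def __post_init__(self):
        if self.k1 < self.k2:
            raise ConfigError(f"k1 must be >= k2 (encode levels feed the sub-feature layer), "
                              f"got k1={self.k1}, k2={self.k2}")
        if min(self.k1, self.k2, self.k3) < 2:
            raise ConfigError("k1, k2 and k3 must all be >= 2")
        if self.dbscan_eps <= 0 or self.dbscan_min_pts < 1:
            raise ConfigError("dbscan_eps must be > 0 and dbscan_min_pts >= 1")


@dataclass(frozen=True)
class EvaluateCfg:
    folds: int = 5


@dataclass(frozen=True)
class RunConfig:
    synth: SynthCfg = field(default_factory=SynthCfg)
    preprocess: PreprocessCfg = field(default_factory=PreprocessCfg)
    features: FeaturesCfg = field(default_factory=FeaturesCfg)
    model: ModelCfg = field(default_factory=ModelCfg)
    evaluate: EvaluateCfg = field(default_factory=EvaluateCfg)
    seed: int = 0
    verbosity: int = 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        _check_keys(raw, _SCHEMA, path="")
        synth = SynthCfg(**raw.get("synth", {}))
        pre = PreprocessCfg(**raw.get("preprocess", {}))
        f_raw = dict(raw.get("features", {}))
        for key in ("window_l1", "window_l3"):
            if key in f_raw:
                f_raw[key] = WindowCfg(**f_raw[key])
        feats = FeaturesCfg(**f_raw)
        model = ModelCfg(**raw.get("model", {}))
        ev = EvaluateCfg(**raw.get("evaluate", {}))
        return cls(synth=synth, preprocess=pre, features=feats, model=model, evaluate=ev,
                   seed=int(raw.get("seed", 0)), verbosity=int(raw.get("verbosity", 1)))


_SCHEMA = {
    "synth": {"n_subjects", "reps_per_test", "sample_rate", "subject_scale_jitter", "classes_file"},
    "preprocess": {"alpha", "median_window"},
    "features": {"window_l1": {"length", "step"}, "window_l3": {"length", "step"},
                 "buffer_samples": None, "chunk_samples": None},
    "model": {"k1", "k2", "k3", "dbscan_eps", "dbscan_min_pts", "greedy_tol",
              "threshold_percentile", "min_run"},
    "evaluate": {"folds"},
    "seed": None,
    "verbosity": None,
}


class ConfigError(ValueError):
    """Unknown or malformed configuration key."""


def _check_keys(raw, schema, path: str):
    if not isinstance(raw, dict):
        raise ConfigError(f"config section {path or '<root>'} must be a mapping")
    allowed = set(schema) if isinstance(schema, dict) else set(schema)
    for key, value in raw.items():
        if key not in allowed:
            raise ConfigError(f"unknown config key {path + key!r}")
        sub = schema[key] if isinstance(schema, dict) else None
        if isinstance(sub, (dict, set)) and isinstance(value, dict):
            _check_keys(value, sub, path=f"{path}{key}.")


def default_config(seed: int = 0) -> RunConfig:
    """The shipped defaults (data/default_config.yaml) with the given seed."""
    ref = resources.files("racquetclust").joinpath("data/default_config.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    raw["seed"] = seed
    return RunConfig.from_dict(raw)


def _deep_merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in over.items():
        out[k] = _deep_merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path=None, seed: int | None = None) -> RunConfig:
    """Load a YAML config merged over the shipped defaults; reject unknown keys."""
    ref = resources.files("racquetclust").joinpath("data/default_config.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        _check_keys(user, _SCHEMA, path="")
        raw = _deep_merge(raw, user)
    if seed is not None:
        raw["seed"] = seed
    return RunConfig.from_dict(raw)
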
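"""Run configuration: one YAML file drives the whole workflow.

Sections mirror the component configs (``synthetic``, ``missingness``,
``transformer``, ``knn``, ``lstm``) plus dataset column declarations.
Unknown keys are rejected outright — a silently ignored typo in a
hyperparameter name would invalidate a benchmark.

The global ``seed`` propagates into every section that does not set its
own, so a single integer reproduces an entire run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .baselines import KnnConfig
from .lstm import LstmConfig
from .synthetic import MissingnessSpec, SyntheticConfig
from .transformer import TransformerConfig
from .tabular import DEFAULT_MISSING_MARKERS


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class DatasetConfig:
    target_column: str = "Cognitive_State_Index"
    id_columns: tuple[str, ...] = ("Timestamp",)
    feature_columns: tuple[str, ...] | None = None   # None: all non-id/target
    missing_markers: tuple[str, ...] = DEFAULT_MISSING_MARKERS


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    missingness: MissingnessSpec = field(default_factory=MissingnessSpec)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    knn: KnnConfig = field(default_factory=KnnConfig)
    lstm: LstmConfig = field(default_factory=LstmConfig)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_SECTIONS = {
    "dataset": DatasetConfig,
    "synthetic": SyntheticConfig,
    "missingness": MissingnessSpec,
    "transformer": TransformerConfig,
    "knn": KnnConfig,
    "lstm": LstmConfig,
}
_SEEDED = {"synthetic", "missingness", "transformer", "lstm"}
# stable per-section offsets so sections do not share identical streams
_SEED_OFFSETS = {"synthetic": 0, "missingness": 104729,
                 "transformer": 224737, "lstm": 350377}


def _build_section(name: str, cls, payload: dict, global_seed: int):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - fields
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {name!r}; "
            f"valid keys: {sorted(fields)}")
    kwargs = dict(payload)
    for key in ("exempt_cols", "id_columns", "feature_columns",
                "missing_markers"):
        if key in kwargs and kwargs[key] is not None:
            kwargs[key] = tuple(kwargs[key])
    if name in _SEEDED and "seed" not in kwargs:
        kwargs["seed"] = (global_seed + _SEED_OFFSETS[name]) % (2 ** 31)
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc


def config_from_dict(raw: dict) -> RunConfig:
    raw = dict(raw or {})
    seed = int(raw.pop("seed", 0))
    sections = {}
    for name, payload in list(raw.items()):
        if name not in _SECTIONS:
            raise ConfigError(
                f"unknown section {name!r}; valid sections: "
                f"{sorted(_SECTIONS)} plus top-level 'seed'")
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name] = _build_section(name, _SECTIONS[name], payload, seed)
    for name, cls in _SECTIONS.items():
        if name not in sections:
            sections[name] = _build_section(name, cls, {}, seed)
    return RunConfig(seed=seed, **sections)


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_dict(raw)
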
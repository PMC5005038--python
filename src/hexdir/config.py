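"""Run configuration with strict validation and seeded reproducibility.

A :class:`RunConfig` collects every tunable of the pipeline in nested
parameter blocks mirroring the modules.  Loading from JSON rejects unknown
keys (typos must fail loudly), fills documented defaults -- TR 1.8 s,
searchlight diameter 7 voxels, 10,000 permutations -- and requires every
stochastic stage to carry an explicit seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

__all__ = ["ConfigError", "RunConfig", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class Seeds:
    design: int = 1
    signal: int = 2
    permutation: int = 3


@dataclass
class DesignBlock:
    scale: float = 1.0
    ns_street_column_x: float = 1.0


@dataclass
class SimulateBlock:
    n_subjects: int = 24
    n_voxels: int = 48
    signal_kind: str = "grid"
    signal_region: str = "pmEC-left"
    tr_s: float = 1.8


@dataclass
class RsaBlock:
    scheme: str = "mod60"
    filters: list[str] = field(default_factory=list)


@dataclass
class SearchlightBlock:
    diameter_voxels: int = 7
    min_voxels: int = 31
    smooth_fwhm_mm: float = 4.0


@dataclass
class InferenceBlock:
    n_perm: int = 10_000
    alpha: float = 0.05
    tail: str = "one"
    correction_k: int = 2


@dataclass
class RunConfig:
    seeds: Seeds = field(default_factory=Seeds)
    design: DesignBlock = field(default_factory=DesignBlock)
    simulate: SimulateBlock = field(default_factory=SimulateBlock)
    rsa: RsaBlock = field(default_factory=RsaBlock)
    searchlight: SearchlightBlock = field(default_factory=SearchlightBlock)
    inference: InferenceBlock = field(default_factory=InferenceBlock)
    out_dir: str = "results"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {path or 'config'}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        if dataclasses.is_dataclass(_resolve(ftype)):
            if not isinstance(value, dict):
                raise ConfigError(f"{path}.{name} must be an object")
            kwargs[name] = _build(_resolve(ftype), value, f"{path}.{name}")
        else:
            kwargs[name] = _check_scalar(name, value, f"{path}.{name}")
    return cls(**kwargs)


_BLOCKS = {
    "seeds": Seeds, "design": DesignBlock, "simulate": SimulateBlock,
    "rsa": RsaBlock, "searchlight": SearchlightBlock, "inference": InferenceBlock,
}


def _resolve(ftype):
    if isinstance(ftype, str):
        return {c.__name__: c for c in
                (Seeds, DesignBlock, SimulateBlock, RsaBlock,
                 SearchlightBlock, InferenceBlock)}.get(ftype, str)
    return ftype


def _check_scalar(name, value, path):
    if isinstance(value, dict):
        raise ConfigError(f"{path}: unexpected object")
    return value


def load_config(path) -> RunConfig:
    """Validated config with defaults filled; unknown keys are an error."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"malformed JSON in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config root must be an object")
    cfg = _build(RunConfig, data, "")
    for f in dataclasses.fields(Seeds):
        if getattr(cfg.seeds, f.name) is None:
            raise ConfigError(f"missing seed {f.name!r}")
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        json.dump(cfg.to_dict(), fh, indent=2, sort_keys=True)
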
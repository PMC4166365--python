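"""Run configuration, validation and provenance records.

A :class:`RunConfig` collects everything a command-line run needs: which
model to run, the module parameters (defaults are the reference values of
the simulations), the seed and the output directory.  Configurations load
from YAML, JSON or TOML; unknown keys are rejected so typos fail loudly.

Every run emits a provenance record -- a JSON file with the full effective
configuration, the seed, package version, wall-clock runtime and SHA-256
digests of every output file -- so that bit-identical reproduction can be
checked with two commands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

from gammasnap import __version__

__all__ = ["RunConfig", "load_config", "write_provenance", "config_to_dict"]

_MODELS = ("binary", "spiking", "sweep", "ephys")


@dataclass
class TSInputConfig:
    """TS input generator settings (times in ms)."""

    n_channels: int = 320
    n_prf: int = 100
    t_gamma_ms: float = 30.0
    onset_noise_sd_ms: float = 0.0
    active_fraction: float = 0.3
    rate_noise_hz_per_ms: float = 5.0

    def validate(self) -> None:
        if self.onset_noise_sd_ms < 0:
            raise ValueError("onset_noise_sd_ms must be non-negative")
        if self.t_gamma_ms <= 0:
            raise ValueError("t_gamma_ms must be positive")
        if not 0 <= self.active_fraction <= 1:
            raise ValueError("active_fraction must be in [0, 1]")
        if self.n_prf <= 0 or self.n_channels <= 0:
            raise ValueError("n_prf and n_channels must be positive")


@dataclass
class BinaryConfig:
    """Binary-model settings (dimensionless model time units)."""

    n_ts: int = 100
    module_sizes: tuple[int, ...] = (300, 300, 300)
    module_offsets: tuple[float, ...] = (0.5, 2.5, 4.5)
    dt: float = 0.2
    half_cycle: float = 8.0
    n_cycles: int = 3
    p_ts: float = 0.01
    w_ts: float = 2.0
    p_ex_rec: float = 0.01
    w_ex_rec: float = 0.1
    p_in_rec: float = 0.30
    w_in_rec: float = -1.5
    p_ff: float = 0.01
    w_ff: float = 4.0

    def validate(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if len(self.module_sizes) != len(self.module_offsets):
            raise ValueError("module_sizes and module_offsets must match")
        for p in (self.p_ts, self.p_ex_rec, self.p_in_rec, self.p_ff):
            if not 0 <= p <= 1:
                raise ValueError(f"connection probability {p} outside [0, 1]")


@dataclass
class SweepConfig:
    preset: str = "reduced"
    seeds: int = 2

    def validate(self) -> None:
        if self.preset not in ("reduced", "full"):
            raise ValueError(f"unknown sweep preset {self.preset!r}")
        if self.seeds <= 0:
            raise ValueError("seeds must be positive")


@dataclass
class EphysConfig:
    """Synthetic-session and analysis-chain settings (times in s)."""

    gamma_freq_hz: float = 60.0
    lock_phase_rad: float = -2.3
    lock_concentration: float = 5.0
    n_trials: int = 20
    event_time_s: float = 0.2
    band_low_hz: float = 40.0
    band_high_hz: float = 80.0
    psth_bin_s: float = 0.010
    threshold_sd: float = 4.5
    bootstrap_reps: int = 10000

    def validate(self) -> None:
        if self.lock_concentration < 0:
            raise ValueError("lock_concentration must be non-negative")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if not 0 < self.band_low_hz < self.band_high_hz:
            raise ValueError("invalid gamma band")


@dataclass
class RunConfig:
    """Top-level configuration of one command-line run."""

    model: str = "spiking"
    seed: int = 0
    out_dir: str = "out"
    log_level: str = "INFO"
    ts_input: TSInputConfig = field(default_factory=TSInputConfig)
    binary: BinaryConfig = field(default_factory=BinaryConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    ephys: EphysConfig = field(default_factory=EphysConfig)
    #: overrides applied on top of SpikingParams defaults
    spiking: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}, got {self.model!r}")
        for sub in (self.ts_input, self.binary, self.sweep, self.ephys):
            sub.validate()
        from gammasnap.spiking import SpikingParams

        known = {f.name for f in fields(SpikingParams)}
        unknown = set(self.spiking) - known
        if unknown:
            raise ValueError(f"unknown spiking parameter(s): {sorted(unknown)}")

    def spiking_params(self):
        from gammasnap.spiking import SpikingParams

        return dataclasses.replace(SpikingParams.defaults(), **self.spiking)


def _from_mapping(cls, data: dict, path: str):
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path or 'config'}")
    kwargs = {}
    for key, value in data.items():
        f = known[key]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _from_mapping(f.type, value, f"{path}.{key}")
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


_SUBSECTIONS = {
    "ts_input": TSInputConfig,
    "binary": BinaryConfig,
    "sweep": SweepConfig,
    "ephys": EphysConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a configuration file (YAML, JSON or TOML).

    Unset fields take the package defaults; unknown keys raise
    ``ValueError`` naming the offending key.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file {path} does not exist")
    text = path.read_text()
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        data = yaml.safe_load(text) or {}
    elif path.suffix == ".json":
        data = json.loads(text)
    elif path.suffix == ".toml":
        import tomllib

        data = tomllib.loads(text)
    else:
        raise ValueError(f"unsupported config format {path.suffix!r}")
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")

    top = {}
    for key, value in data.items():
        if key in _SUBSECTIONS:
            top[key] = _from_mapping(_SUBSECTIONS[key], value or {}, key)
        elif key == "spiking":
            if not isinstance(value, dict):
                raise ValueError("spiking section must be a mapping")
            top[key] = value
        elif key in {"model", "seed", "out_dir", "log_level"}:
            top[key] = value
        else:
            raise ValueError(f"unknown key {key!r} in config")
    cfg = RunConfig(**top)
    cfg.validate()
    return cfg


def config_to_dict(cfg: RunConfig) -> dict:
    return dataclasses.asdict(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_dir: str | Path,
    config: RunConfig,
    outputs: list[str | Path],
    started: float,
    failed: bool = False,
    diagnostic: str = "",
) -> Path:
    """Write the provenance JSON for a finished (or aborted) run.

    Records the full effective configuration, seed, package version,
    runtime and a SHA-256 digest of every emitted file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "package": "gammasnap",
        "version": __version__,
        "config": config_to_dict(config),
        "seed": config.seed,
        "runtime_s": time.time() - started,
        "failed": failed,
        "diagnostic": diagnostic,
        "outputs": {
            str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()
        },
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, default=str))
    return path
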
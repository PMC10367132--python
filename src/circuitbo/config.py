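"""Run configuration and result serialization.

A run config (YAML or JSON) resolves every setting of an optimization run —
model, objective, optimizer, sweep/benchmark settings — and is emitted next
to the results so any artifact can be re-run exactly. A single global seed
drives every random stream; per-component child seeds are derived from it
deterministically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .architectures import ConfigurationError
from .models import MODEL_IDS
from .objectives import ObjectiveSpec
from .optimizers import OptimizerConfig, TrialHistory

__all__ = ["RunConfig", "load_config", "save_config", "export_results", "load_results"]

__version__ = "0.1.0"

logger = logging.getLogger("circuitbo")


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings of one run."""

    model: str = "toy"
    overrides: dict = field(default_factory=dict)
    objective: ObjectiveSpec = field(default_factory=ObjectiveSpec)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    sweep: dict = field(default_factory=dict)      # perturbation/benchmark extras
    out: str = "run.json"

    def __post_init__(self) -> None:
        if self.model not in MODEL_IDS:
            raise ConfigurationError(f"unknown model {self.model!r}")

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "overrides": dict(self.overrides),
            "objective": asdict(self.objective),
            "optimizer": asdict(self.optimizer),
            "sweep": dict(self.sweep),
            "out": self.out,
        }

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_section(cls, payload: dict, section: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown keys in {section!r} section: {sorted(unknown)}"
        )
    return cls(**payload)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run config; defaults (Hill n=2, gamma=15,
    uniform priors) fill unspecified fields; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    payload = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(payload, dict):
        raise ConfigurationError(f"config {path} is not a mapping")
    known = {"model", "overrides", "objective", "optimizer", "sweep", "out"}
    unknown = set(payload) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {k: payload[k] for k in ("model", "overrides", "sweep", "out")
                    if k in payload}
    if "objective" in payload:
        kwargs["objective"] = _build_section(ObjectiveSpec, payload["objective"], "objective")
    if "optimizer" in payload:
        kwargs["optimizer"] = _build_section(OptimizerConfig, payload["optimizer"], "optimizer")
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(config.to_dict(), indent=2, sort_keys=True))
    else:
        path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def export_results(
    history: TrialHistory,
    fmt: str,
    path: str | Path,
    config: RunConfig | None = None,
) -> Path:
    """Write a trial history as JSON (full record incl. seed, config hash and
    package version) or CSV (one documented row per trial). Bit-stable for
    fixed inputs."""
    if not history.trials:
        raise ConfigurationError("refusing to export an empty history")
    path = Path(path)
    if fmt == "json":
        payload = history.to_dict()
        payload["package_version"] = __version__
        if config is not None:
            payload["config"] = config.to_dict()
            payload["config_digest"] = config.digest()
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    elif fmt == "csv":
        history.to_dataframe().to_csv(path, index=False)
    else:
        raise ConfigurationError(f"unknown export format {fmt!r}")
    return path


def load_results(path: str | Path) -> TrialHistory:
    payload = json.loads(Path(path).read_text())
    return TrialHistory.from_dict(payload)


def child_seed(seed: int, stream: str) -> int:
    """Deterministic per-component child seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{stream}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)
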
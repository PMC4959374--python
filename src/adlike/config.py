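"""Run configuration: a validated, hashable bundle of pipeline parameters."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class FilterConfig:
    hp_hz: float = 2.0
    lp_hz: float = 47.0
    order: int = 4


@dataclass
class ArtifactConfig:
    enabled: bool = True
    threshold_uv: float = 100.0
    pad_s: float = 0.25


@dataclass
class WindowConfig:
    length_s: float = 10.0
    overlap_s: float = 4.0


@dataclass
class BaselineConfig:
    correct: bool = True


@dataclass
class CVConfig:
    repetitions: int = 10
    seed: int = 0


@dataclass
class RunConfig:
    """Everything the pipeline needs, with the study defaults filled in."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "theta": (3.0, 7.0), "alpha": (8.0, 13.0),
            "beta": (14.0, 29.0), "gamma": (30.0, 47.0),
        }
    )
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    variant: str = "original"
    cv: CVConfig = field(default_factory=CVConfig)
    blocks: tuple[str, ...] = ("stat", "psd", "asym", "z")

    def validate(self) -> "RunConfig":
        f = self.filter
        if not 0 < f.hp_hz < f.lp_hz:
            raise ConfigError("filter.hp_hz: must satisfy 0 < hp_hz < lp_hz")
        if f.order < 1:
            raise ConfigError("filter.order: must be >= 1")
        for name, edges in self.bands.items():
            if len(edges) != 2 or not 0 < edges[0] < edges[1]:
                raise ConfigError(f"bands.{name}: edges must be an increasing positive pair")
        if self.artifact.threshold_uv <= 0:
            raise ConfigError("artifact.threshold_uv: must be positive")
        if self.artifact.pad_s < 0:
            raise ConfigError("artifact.pad_s: must be >= 0")
        if not 0 <= self.window.overlap_s < self.window.length_s:
            raise ConfigError("window.overlap_s: must lie in [0, window.length_s)")
        if self.variant not in ("original", "optimized"):
            raise ConfigError("variant: must be 'original' or 'optimized'")
        if self.cv.repetitions < 1:
            raise ConfigError("cv.repetitions: must be >= 1")
        bad = [b for b in self.blocks if b not in ("stat", "psd", "asym", "z")]
        if bad:
            raise ConfigError(f"blocks: unknown block(s) {bad}")
        return self

    def hash(self) -> str:
        """Short stable digest embedded in every artifact this config produced."""
        doc = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha1(doc.encode()).hexdigest()[:12]


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config file; missing keys keep their defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg.validate()
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from None
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = {"filter", "bands", "artifact", "window", "baseline", "variant", "cv", "blocks"}
    for key in doc:
        if key not in known:
            raise ConfigError(f"{key}: unknown configuration section")
    for section, cls in (
        ("filter", FilterConfig), ("artifact", ArtifactConfig),
        ("window", WindowConfig), ("baseline", BaselineConfig), ("cv", CVConfig),
    ):
        if section in doc:
            sub = doc[section]
            if not isinstance(sub, dict):
                raise ConfigError(f"{section}: must be a mapping")
            current = getattr(cfg, section)
            for k, v in sub.items():
                if not hasattr(current, k):
                    raise ConfigError(f"{section}.{k}: unknown key")
                setattr(current, k, type(getattr(current, k))(v))
    if "bands" in doc:
        cfg.bands = {name: (float(lo), float(hi)) for name, (lo, hi) in doc["bands"].items()}
    if "variant" in doc:
        cfg.variant = str(doc["variant"])
    if "blocks" in doc:
        cfg.blocks = tuple(doc["blocks"])
    return cfg.validate()
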
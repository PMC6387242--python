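"""Layered run configuration: YAML/JSON -> validated dataclasses.

An empty file yields pure defaults (STFT window 64, hop 14, 30 filters of
width 3, VAE hidden sizes 600/300/100/300/600, 10x10 cross-validation).
Unknown keys are rejected with their full key path; cross-section dimension
invariants (CNN feature dim vs VAE input dim) are validated before any
computation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import yaml

from .cnn import CnnConfig
from .evaluation import CvScheme
from .pipeline import PipelineConfig
from .representation import BandSpec, RepresentationConfig, StftParams
from .synth import SynthParams
from .vae import VaeConfig

__all__ = ["RunConfig", "load_config", "dump_config"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    synth: SynthParams = field(default_factory=SynthParams)
    representation: RepresentationConfig = field(default_factory=RepresentationConfig)
    cnn: CnnConfig = field(default_factory=CnnConfig)
    vae: VaeConfig = field(default_factory=VaeConfig)
    evaluation: CvScheme = field(default_factory=CvScheme)
    seed: int = 0
    normalize: bool = True
    out_dir: str = "."
    log_level: str = "INFO"

    def pipeline_config(self) -> PipelineConfig:
        """Build (and thereby dimension-validate) the pipeline config."""
        return PipelineConfig(
            representation=self.representation,
            cnn=self.cnn,
            vae=self.vae,
            seed=self.seed,
            normalize=self.normalize,
        )


def _build(cls, d: dict, path: str):
    """Instantiate dataclass ``cls`` from ``d``, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(d) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under '{path}'; "
            f"valid keys: {sorted(fields)}"
        )
    kwargs = {}
    for key, value in d.items():
        sub = _NESTED.get((cls, key))
        if sub is not None and isinstance(value, dict):
            kwargs[key] = _build(sub, value, f"{path}.{key}")
        elif key == "bands" and cls is RepresentationConfig:
            kwargs[key] = tuple(
                _build(BandSpec, b, f"{path}.bands[{i}]") for i, b in enumerate(value)
            )
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration under '{path}': {exc}") from exc


_NESTED = {(RepresentationConfig, "stft"): StftParams}

_SECTIONS = {
    "synth": SynthParams,
    "representation": RepresentationConfig,
    "cnn": CnnConfig,
    "vae": VaeConfig,
    "evaluation": CvScheme,
}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML (or JSON) config file; missing keys fall back to defaults.

    The fully resolved configuration is echoed to the log.  Validation
    failures report the offending key path; no partially built config is
    ever returned.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config root must be a mapping, got {type(loaded).__name__}")
        raw = loaded
    if overrides:
        raw = {**raw, **overrides}

    unknown = set(raw) - set(_SECTIONS) - {"seed", "normalize", "out_dir", "log_level"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _build(cls, raw[name] or {}, name)
    for scalar in ("seed", "normalize", "out_dir", "log_level"):
        if scalar in raw:
            kwargs[scalar] = raw[scalar]
    cfg = RunConfig(**kwargs)
    cfg.pipeline_config()  # cross-section dimension validation
    logger.info("config %s", dump_config(cfg))
    return cfg


def dump_config(cfg: RunConfig) -> dict:
    """RunConfig -> plain dict (YAML/JSON serializable, load round-trips)."""

    def clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return [clean(v) for v in obj]
        if isinstance(obj, list):
            return [clean(v) for v in obj]
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    return clean(
        {
            "synth": cfg.synth,
            "representation": cfg.representation,
            "cnn": cfg.cnn,
            "vae": cfg.vae,
            "evaluation": cfg.evaluation,
            "seed": cfg.seed,
            "normalize": cfg.normalize,
            "out_dir": cfg.out_dir,
            "log_level": cfg.log_level,
        }
    )
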
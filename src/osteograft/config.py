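"""Run configuration shared by the command-line interface.

Every CLI output embeds the configuration verbatim in its metadata block so
results are traceable to the choices that produced them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Reproducibility-relevant switches for a pipeline run.

    composition_convention:
        ``"rescaled"`` (mass-balance rescaling of the composite grafts,
        default) or ``"nominal"`` (keep printed CaCO3).
    scale_predictors:
        Autoscale predictors/response to unit variance (default) or center
        only.
    correlation_mode:
        Which predicted-vs-measured correlation a report headline uses:
        ``"loo"`` (cross-validated, default) or ``"fitted"``.
    seed:
        Only consulted by the synthetic-data commands.
    """

    composition_convention: str = "rescaled"
    scale_predictors: bool = True
    correlation_mode: str = "loo"
    output_dir: str = "."
    log_level: str = "info"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.composition_convention not in ("rescaled", "nominal"):
            raise ConfigError(f"composition_convention {self.composition_convention!r}")
        if self.correlation_mode not in ("loo", "fitted"):
            raise ConfigError(f"correlation_mode {self.correlation_mode!r}")
        if self.log_level not in ("debug", "info", "warning", "error", "quiet"):
            raise ConfigError(f"log_level {self.log_level!r}")

    def as_dict(self) -> dict:
        return asdict(self)


def load_config(path: str) -> RunConfig:
    """Read a RunConfig from a TOML or JSON file."""
    text = open(path, "rb").read()
    if str(path).lower().endswith(".toml"):
        import tomllib

        try:
            data = tomllib.loads(text.decode("utf-8"))
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"bad TOML config {path}: {exc}") from exc
    else:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"bad JSON config {path}: {exc}") from exc
    known = RunConfig().as_dict().keys()
    unknown = [k for k in data if k not in known]
    if unknown:
        raise ConfigError(f"unknown config keys {unknown}")
    return RunConfig(**data)
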
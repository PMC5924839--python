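"""Experiment configuration: YAML bundles of model, protocol and fit settings.

A configuration file mirrors the dataclass field names of the objects it
configures, e.g.::

    params:
      gbar_Klt: 6.0
      gbar_KA: 8.0
    protocol:
      I_stim: 60.0
    grid:
      step: 0.5
    distribution:
      mu_x: 3.0
      mu_y: 4.0
      rho: 0.6
    fit:
      sigma: [1.0, 1.0]
    seed: 1
    output_dir: results

Every section is optional; omitted fields keep their defaults.  The
resolved configuration is echoed next to any artifacts a run produces,
which together with the package version suffices to reproduce outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .model import NeuronParameters, StimulusProtocol
from .patternmap import GridSpec
from .population import BivariateNormal
from .fit import FitConfig

__all__ = ["ExperimentConfig", "load_config"]


@dataclass
class ExperimentConfig:
    params: NeuronParameters = field(default_factory=NeuronParameters)
    protocol: StimulusProtocol = field(default_factory=StimulusProtocol)
    grid: GridSpec = field(default_factory=GridSpec)
    distribution: BivariateNormal = field(default_factory=BivariateNormal)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTIONS = {
    "params": NeuronParameters,
    "protocol": StimulusProtocol,
    "grid": GridSpec,
    "distribution": BivariateNormal,
    "fit": FitConfig,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file plus flat overrides.

    ``overrides`` maps ``section.field`` (or a top-level key) to a value
    and takes precedence over the file, mirroring CLI flags.  Unknown
    keys raise ``ValueError`` naming the offending key.
    """
    raw: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"config file {path} must contain a mapping")
            raw = loaded
    for key, value in (overrides or {}).items():
        if "." in key:
            section, name = key.split(".", 1)
            raw.setdefault(section, {})[name] = value
        else:
            raw[key] = value

    kwargs: dict = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            try:
                section_value = cls(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()})
            except TypeError as exc:
                raise ValueError(f"config section '{key}': {exc}") from None
            kwargs[key] = section_value
        elif key in ("seed", "output_dir"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown config key '{key}'")
    return ExperimentConfig(**kwargs)
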
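"""Run configuration: defaults, file loading, validation.

A config file may be YAML or simple ``key = value`` lines; CLI flags
override file values, which override the defaults below.  The defaults
describe the package's reference synthetic study: four blends of
increasing plasticizer content degrading over a two-week observation
window in triplicate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthetic import DEFAULT_BLEND_T50

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All knobs of a pipeline run, with their defaults."""

    outdir: str = "phbdeg_out"
    seed: int = 1
    # study design
    blends: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BLEND_T50))
    n_replicates: int = 3
    n_timepoints: int = 13
    t_max_h: float = 336.0  # 14 days
    replicate_t50_cv: float = 0.05  # biological variability between replicates
    # scene rendering (None -> SceneParams defaults)
    image_size: tuple[int, int] | None = None
    n_grains: int | None = None
    grain_radius_range: tuple[float, float] | None = None
    noise_sd: float | None = None
    illumination_gradient: float | None = None
    mycelium_growth_rate: float | None = None
    # thresholding: "auto" or (low, high)
    threshold: str | tuple[float, float] = "auto"
    # t50 fitting
    max_degree: int = 6
    alpha: float = 0.05
    level: float = 50.0
    # NMR integration
    monomer_center: float = 4.20
    polymer_center: float = 5.20
    region_half_width: float = 0.15

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_timepoints < 4:
            raise ValueError("need >= 1 replicate and >= 4 time points")
        if self.t_max_h <= 0:
            raise ValueError("t_max_h must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.max_degree < 1:
            raise ValueError("max_degree must be >= 1")
        if isinstance(self.threshold, str):
            if self.threshold != "auto":
                raise ValueError("threshold must be 'auto' or a (low, high) pair")
        else:
            low, high = self.threshold
            if not 0.0 <= low <= high <= 1.0:
                raise ValueError(f"threshold must satisfy 0 <= low <= high <= 1, got {self.threshold}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if isinstance(d["threshold"], tuple):
            d["threshold"] = list(d["threshold"])
        for key in ("image_size", "grain_radius_range"):
            if isinstance(d[key], tuple):
                d[key] = list(d[key])
        return d


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a config from an optional file plus keyword overrides.

    The file may be a YAML mapping or plain ``key = value`` lines (values
    parsed as YAML scalars).  Overrides with value ``None`` are ignored so
    that unset CLI flags fall through to the file/defaults.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if isinstance(loaded, dict):
            data = loaded
        else:  # key = value lines
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"cannot parse config line: {line!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                data[key] = yaml.safe_load(value)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("threshold", "image_size", "grain_radius_range"):
        if isinstance(data.get(key), list):
            data[key] = tuple(data[key])
    return RunConfig(**data)
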
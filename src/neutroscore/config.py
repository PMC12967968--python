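"""Run configuration: one object bundling every knob of the pipeline.

Configs load from flat YAML. Top-level keys map to model parameters
(``d_max``, ``s_max``, ``d_crit``, ``d_mid``, ``d_range``), band settings
(``band_cuts``, ``band_labels``), the classical cutoff, the seed, alpha,
the rectification mode, grid extents (``grid: {d_min, d_max, d_step,
s_min, s_max, s_step}``) and an optional ``groups`` list overriding the
default cohort specs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import yaml

from .landscape import GridSpec
from .model import BandThresholds, ModelParameters
from .simulate import DEFAULT_GROUP_SPECS, GroupSpec

__all__ = ["RunConfig", "load_config"]

_PARAM_KEYS = ("d_max", "s_max", "d_crit", "d_mid", "d_range")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed for an end-to-end reproduction run."""

    params: ModelParameters = field(default_factory=ModelParameters)
    group_specs: Tuple[GroupSpec, ...] = DEFAULT_GROUP_SPECS
    seed: int = 42
    bands: BandThresholds = field(default_factory=BandThresholds)
    classical_cutoff: float = 2.0
    grid: GridSpec = field(default_factory=GridSpec)
    alpha: float = 0.05
    rectify_mode: str = "truncate"
    s_levels: Tuple[float, ...] = (0.05, 0.15, 0.25)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.classical_cutoff <= 0:
            raise ValueError("classical_cutoff must be positive")
        if self.rectify_mode not in ("truncate", "absolute"):
            raise ValueError(f"unknown rectify_mode {self.rectify_mode!r}")

    def with_overrides(self, **kwargs) -> "RunConfig":
        current = {
            "params": self.params,
            "group_specs": self.group_specs,
            "seed": self.seed,
            "bands": self.bands,
            "classical_cutoff": self.classical_cutoff,
            "grid": self.grid,
            "alpha": self.alpha,
            "rectify_mode": self.rectify_mode,
            "s_levels": self.s_levels,
        }
        current.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**current)


def load_config(path) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file; absent keys keep defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must contain a mapping")

    defaults = ModelParameters()
    params = ModelParameters(
        **{k: float(raw.get(k, getattr(defaults, k))) for k in _PARAM_KEYS}
    )

    band_kwargs = {}
    if "band_cuts" in raw:
        band_kwargs["cuts"] = tuple(raw["band_cuts"])
    if "band_labels" in raw:
        band_kwargs["labels"] = tuple(raw["band_labels"])
    bands = BandThresholds(**band_kwargs)

    grid = GridSpec(**{k: float(v) for k, v in raw.get("grid", {}).items()})

    if "groups" in raw:
        specs = tuple(
            GroupSpec(
                label=str(g["label"]),
                n=int(g["n"]),
                mu_d=float(g["mu_d"]),
                sigma_d=float(g["sigma_d"]),
                mu_s=float(g["mu_s"]),
                sigma_s=float(g["sigma_s"]),
            )
            for g in raw["groups"]
        )
    else:
        specs = DEFAULT_GROUP_SPECS

    return RunConfig(
        params=params,
        group_specs=specs,
        seed=int(raw.get("seed", 42)),
        bands=bands,
        classical_cutoff=float(raw.get("classical_cutoff", 2.0)),
        grid=grid,
        alpha=float(raw.get("alpha", 0.05)),
        rectify_mode=str(raw.get("rectify_mode", "truncate")),
        s_levels=tuple(float(s) for s in raw.get("s_levels", (0.05, 0.15, 0.25))),
    )
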
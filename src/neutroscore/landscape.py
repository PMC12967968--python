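"""Figure-ready numeric grids over the deviation–instability plane.

Everything here is a plain numeric artifact — membership profiles along the
deviation axis, the competence surface S(d, s), crisp decision-region label
matrices and the classical-vs-neutrosophic discordance table — so tests and
downstream analyses never depend on rendering. Plotting lives in
:mod:`neutroscore.plotting` as a thin optional layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    BandThresholds,
    ModelParameters,
    classical_pass,
    classify_band,
    evaluate,
)
from .simulate import CohortDataset

__all__ = [
    "GridSpec",
    "LandscapeGrid",
    "membership_profiles",
    "competence_surface",
    "decision_regions",
    "discordance_table",
]


@dataclass(frozen=True)
class GridSpec:
    """Rectangular evaluation grid over (d, s).

    Defaults cover all three class priors to ±4σ plus the saturation region:
    d ∈ [0, 5] mm in steps of 0.01, s ∈ [0, 0.35] in steps of 0.005.
    """

    d_min: float = 0.0
    d_max: float = 5.0
    d_step: float = 0.01
    s_min: float = 0.0
    s_max: float = 0.35
    s_step: float = 0.005

    def __post_init__(self) -> None:
        if not (self.d_min < self.d_max and self.s_min < self.s_max):
            raise ValueError("grid ranges must satisfy min < max")
        if self.d_step <= 0 or self.s_step <= 0:
            raise ValueError("grid steps must be positive")
        if self.d_min < 0 or self.s_min < 0:
            raise ValueError("grid must lie in the non-negative quadrant")
        if len(self.d_axis()) < 2 or len(self.s_axis()) < 2:
            raise ValueError("grid needs at least 2 points per axis")

    def d_axis(self) -> np.ndarray:
        n = int(round((self.d_max - self.d_min) / self.d_step)) + 1
        return self.d_min + self.d_step * np.arange(n)

    def s_axis(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        return self.s_min + self.s_step * np.arange(n)


@dataclass(frozen=True)
class LandscapeGrid:
    """Evaluated grids: T, I, F, S matrices of shape (len(s), len(d)).

    Rows index the instability axis, columns the deviation axis (image
    orientation: ``S[i, j]`` is the score at ``(d_axis[j], s_axis[i])``).
    """

    d_axis: np.ndarray
    s_axis: np.ndarray
    T: np.ndarray
    I: np.ndarray
    F: np.ndarray
    S: np.ndarray
    bands: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        shape = (len(self.s_axis), len(self.d_axis))
        for name in ("T", "I", "F", "S"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} matrix shape must be {shape}")
        if np.any(self.S < 0) or np.any(self.S > 1):
            raise ValueError("S grid must lie in [0, 1]")

    def superlevel(self, level: float) -> np.ndarray:
        """Boolean mask of the super-level set {S >= level}."""
        return self.S >= level

    def to_csv_dir(self, outdir, prefix: str = "grid") -> list:
        """Export one CSV per quantity, d values as the header row and s as
        the first column."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        quantities = {"T": self.T, "I": self.I, "F": self.F, "S": self.S}
        if self.bands is not None:
            quantities["bands"] = self.bands
        for name, matrix in quantities.items():
            df = pd.DataFrame(matrix, index=self.s_axis, columns=self.d_axis)
            df.index.name = "s\\d"
            path = outdir / f"{prefix}_{name}.csv"
            df.to_csv(path, float_format="%.17g")
            written.append(path)
        return written


def membership_profiles(
    s_levels: Sequence[float],
    d_axis: Sequence[float],
    params: Optional[ModelParameters] = None,
) -> pd.DataFrame:
    """Membership-function profiles T(d), I(d), F(d) at fixed instability.

    Evaluates the three memberships pointwise along ``d_axis`` for each
    instability level (typical levels: 0.05, 0.15, 0.25 — calm, moderate and
    marked tremor). Returns a long-format DataFrame with columns
    ``s_level, d, T, I, F``.
    """
    d = np.asarray(d_axis, dtype=float)
    if d.size < 1 or not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("d_axis must be non-empty, finite and non-negative")
    levels = np.asarray(s_levels, dtype=float)
    if levels.size < 1 or not np.all(np.isfinite(levels)) or np.any(levels < 0):
        raise ValueError("s_levels must be non-empty, finite and non-negative")
    frames = []
    for s in levels:
        T, I, F, _ = evaluate(d, np.full_like(d, s), params)
        frames.append(pd.DataFrame({"s_level": s, "d": d, "T": T, "I": I, "F": F}))
    return pd.concat(frames, ignore_index=True)


def competence_surface(
    grid: Optional[GridSpec] = None,
    params: Optional[ModelParameters] = None,
) -> LandscapeGrid:
    """Evaluate the neutrosophic model at every node of a (d, s) grid."""
    g = grid or GridSpec()
    d_axis, s_axis = g.d_axis(), g.s_axis()
    D, Sg = np.meshgrid(d_axis, s_axis)
    T, I, F, S = evaluate(D, Sg, params)
    return LandscapeGrid(d_axis=d_axis, s_axis=s_axis, T=T, I=I, F=F, S=S)


def decision_regions(
    grid: Optional[GridSpec] = None,
    params: Optional[ModelParameters] = None,
    bands: Optional[BandThresholds] = None,
) -> LandscapeGrid:
    """Crisp decision regions: the band label of every grid cell.

    Returns the evaluated :class:`LandscapeGrid` with its ``bands`` matrix
    filled in (cellwise band classification of the competence surface).
    """
    surface = competence_surface(grid, params)
    labels = classify_band(surface.S, bands)
    return LandscapeGrid(
        d_axis=surface.d_axis,
        s_axis=surface.s_axis,
        T=surface.T,
        I=surface.I,
        F=surface.F,
        S=surface.S,
        bands=labels,
    )


def discordance_table(
    data,
    cutoff: float = 2.0,
    bands: Optional[BandThresholds] = None,
) -> pd.DataFrame:
    """Contrast the classical distance-only rule with the neutrosophic bands.

    A row is *discordant* when the classical rule passes it (d <= cutoff)
    but the neutrosophic score places it below the top band — the
    false-positive competence case the combined (d, s) model is designed to
    expose (typically attempts with acceptable deviation but elevated
    instability).

    Returns the cohort table augmented with ``classical_pass``, ``band`` and
    ``discordant`` columns.
    """
    b = bands or BandThresholds()
    df = (data.data if isinstance(data, CohortDataset) else data).copy()
    for col in ("d", "S"):
        if col not in df.columns:
            raise ValueError(f"dataset has no {col!r} column; evaluate it first")
    passed = classical_pass(df["d"].to_numpy(), cutoff=cutoff)
    band = classify_band(df["S"].to_numpy(), b)
    df["classical_pass"] = passed
    df["band"] = band
    df["discordant"] = passed & (band != b.top_label)
    return df
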
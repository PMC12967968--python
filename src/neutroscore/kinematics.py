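"""Raw-geometry reductions: target deviation and trajectory instability.

These turn simulator kinematics into the two scalar performance variables
the scoring model consumes: the Euclidean tip-to-target deviation ``d`` and
the motor-instability scalar ``s`` (total positional variance of the tracked
instrument tip over a window).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence, Union

import numpy as np
import pandas as pd

__all__ = ["Point3D", "target_deviation", "trajectory_instability", "read_trajectory_csv"]


class Point3D(NamedTuple):
    """A point in the surgical field, coordinates in mm."""

    x: float
    y: float
    z: float


def _as_point(p) -> np.ndarray:
    arr = np.asarray(tuple(p) if isinstance(p, Point3D) else p, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"expected a 3-D point, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"coordinates must be finite, got {arr}")
    return arr


def target_deviation(target, tip) -> float:
    """Euclidean deviation (mm) between the instrument tip and the target.

    ``d = sqrt((xt - xs)^2 + (yt - ys)^2 + (zt - zs)^2)``; symmetric in its
    arguments and non-negative.
    """
    t = _as_point(target)
    s = _as_point(tip)
    return float(np.linalg.norm(t - s))


def trajectory_instability(traj, normalization: str = "population") -> float:
    """Motor instability: total variance of a tip trajectory.

    The trajectory is an ``(n, 2)`` or ``(n, 3)`` array of positions (mm),
    one row per sample. Instability is the trace of the positional
    covariance — the sum of per-axis variances about the trajectory mean —
    a single rotation-invariant dispersion scalar. A perfectly steady
    (constant) trajectory scores 0.

    Parameters
    ----------
    traj : array-like, shape (n, 2) or (n, 3)
        At least two samples, all finite.
    normalization : {"population", "sample"}
        Variance denominator: ``n`` (default) or ``n - 1``.
    """
    if normalization not in ("population", "sample"):
        raise ValueError(f"unknown normalization {normalization!r}")
    arr = np.asarray(traj, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError(f"trajectory must have shape (n, 2) or (n, 3), got {arr.shape}")
    if arr.shape[0] < 2:
        raise ValueError("trajectory variance needs at least 2 samples")
    if not np.all(np.isfinite(arr)):
        raise ValueError("trajectory samples must be finite")
    ddof = 0 if normalization == "population" else 1
    return float(np.sum(np.var(arr, axis=0, ddof=ddof)))


def read_trajectory_csv(path) -> np.ndarray:
    """Read a trajectory from a two- or three-column CSV (x, y[, z] per row)."""
    df = pd.read_csv(path)
    if df.shape[1] not in (2, 3):
        raise ValueError(
            f"trajectory CSV must have 2 or 3 columns, found {df.shape[1]} in {path}"
        )
    return df.to_numpy(dtype=float)
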
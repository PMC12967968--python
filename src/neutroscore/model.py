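"""Neutrosophic scoring of stereotactic surgical performance.

A single attempt is summarised by the behavioural vector ``X = (d, s)``:
``d`` is the Euclidean deviation of the instrument tip from the stereotactic
target (mm) and ``s`` is a scalar motor-instability measure (trajectory
variance, treated as dimensionless "model units"; only the ratio ``s/s_max``
enters the model).

Performance is formalised as a single-valued neutrosophic set (SVNS)
``A = <T(X), I(X), F(X)>`` with three independent memberships in [0, 1]:

* Truth ``T`` — degree of competent performance: a product of rectified
  linear decays, ``T = max(0, 1 - d/d_max) * max(0, 1 - s/s_max)``.
* Indeterminacy ``I`` — borderline/ambiguous performance: a triangular
  kernel in ``d`` centred on the mid-risk distance, scaled by normalised
  instability, ``I = max(0, 1 - |d - d_mid|/d_range) * min(1, s/s_max)``.
* Falsity ``F`` — clinically unsafe performance: the worst case of capped
  linear components, ``F = max(min(1, d/d_crit), min(1, s/s_max))``.

The composite competence score is ``S = (2 + T - I - F) / 3``, a bounded,
order-preserving summary that penalises both active error and unresolved
uncertainty.

All scoring functions are vectorised: ``d`` and ``s`` may be scalars or
broadcastable numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "ModelParameters",
    "PerformanceVector",
    "NeutrosophicResult",
    "BandThresholds",
    "truth",
    "falsity",
    "indeterminacy",
    "competence_score",
    "evaluate",
    "classify_band",
    "classical_pass",
]

ArrayLike = Union[float, Sequence[float], np.ndarray]

#: Absolute tolerance used for internal consistency checks (pure arithmetic,
#: no iterative numerics).
FLOAT_TOL = 1e-9


@dataclass(frozen=True)
class ModelParameters:
    """The five clinical constants governing the membership functions.

    Parameters
    ----------
    d_max : float
        Distance normaliser of the Truth function (mm). Upper bound of
        generally accepted targeting error; Truth vanishes for ``d >= d_max``.
        Default 3.0 mm.
    s_max : float
        Instability normaliser (model units). Conservative upper bound on
        tremor / micromovement variance; Truth vanishes and Falsity saturates
        for ``s >= s_max``. Default 0.30.
    d_crit : float
        Deviation marking unacceptable, unsafe placement (mm); the Falsity
        distance component saturates at 1 there. Default 4.0 mm.
    d_mid : float
        Centre of the ambiguous "mid-risk" zone (mm), the transition between
        high-precision targeting and elevated clinical risk. Default 1.5 mm.
    d_range : float
        Half-width of the triangular indeterminacy kernel (mm). Default 1.5 mm.

    All defaults are illustrative values motivated by deep-brain-stimulation
    accuracy constraints and are meant to be adjusted per procedure.
    """

    d_max: float = 3.0
    s_max: float = 0.30
    d_crit: float = 4.0
    d_mid: float = 1.5
    d_range: float = 1.5

    def __post_init__(self) -> None:
        for name in ("d_max", "s_max", "d_crit", "d_mid", "d_range"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {value!r}")
        if not self.d_mid < self.d_crit:
            raise ValueError(f"d_mid ({self.d_mid}) must be < d_crit ({self.d_crit})")
        if not self.d_mid <= self.d_max:
            raise ValueError(f"d_mid ({self.d_mid}) must be <= d_max ({self.d_max})")

    def as_dict(self) -> dict:
        return {
            "d_max": self.d_max,
            "s_max": self.s_max,
            "d_crit": self.d_crit,
            "d_mid": self.d_mid,
            "d_range": self.d_range,
        }


@dataclass(frozen=True)
class PerformanceVector:
    """One attempt's behavioural vector ``(d, s)`` with an optional group label."""

    d: float
    s: float
    group: Optional[str] = None

    def __post_init__(self) -> None:
        _check_inputs(self.d, self.s)


@dataclass(frozen=True)
class NeutrosophicResult:
    """The ``(T, I, F, S)`` bundle for one attempt.

    Invariants: each membership lies in [0, 1], ``0 <= T + I + F <= 3`` and
    ``S == (2 + T - I - F) / 3``.
    """

    T: float
    I: float
    F: float
    S: float

    def __post_init__(self) -> None:
        for name in ("T", "I", "F", "S"):
            value = getattr(self, name)
            if not 0.0 - FLOAT_TOL <= value <= 1.0 + FLOAT_TOL:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        expected = (2.0 + self.T - self.I - self.F) / 3.0
        if abs(self.S - expected) > FLOAT_TOL:
            raise ValueError(
                f"inconsistent bundle: S={self.S!r} but (2+T-I-F)/3={expected!r}"
            )

    def astuple(self) -> tuple:
        return (self.T, self.I, self.F, self.S)


@dataclass(frozen=True)
class BandThresholds:
    """Ascending cut points on S and the labels of the resulting bands.

    With defaults ``(0.3, 0.5, 0.7)`` the bands are ``unsafe`` [0, 0.3),
    ``at-risk`` [0.3, 0.5), ``indeterminate`` [0.5, 0.7) and ``expert``
    [0.7, 1]. Intervals are left-closed: a score exactly on a cut point is
    assigned to the band above it.
    """

    cuts: tuple = (0.3, 0.5, 0.7)
    labels: tuple = ("unsafe", "at-risk", "indeterminate", "expert")

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        labels = tuple(str(l) for l in self.labels)
        object.__setattr__(self, "cuts", cuts)
        object.__setattr__(self, "labels", labels)
        if any(not 0.0 < c < 1.0 for c in cuts):
            raise ValueError(f"cut points must lie strictly inside (0, 1): {cuts}")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cut points must be strictly increasing: {cuts}")
        if len(labels) != len(cuts) + 1:
            raise ValueError(
                f"need {len(cuts) + 1} labels for {len(cuts)} cut points, got {len(labels)}"
            )

    @property
    def top_label(self) -> str:
        return self.labels[-1]


def _check_inputs(d: ArrayLike, s: ArrayLike) -> tuple:
    d = np.asarray(d, dtype=float)
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(d)) or not np.all(np.isfinite(s)):
        raise ValueError("d and s must be finite")
    if np.any(d < 0) or np.any(s < 0):
        raise ValueError("d and s must be non-negative")
    return d, s


def _coerce(v, s, caller: str):
    """Accept either (PerformanceVector,) or (d, s) leading arguments."""
    if isinstance(v, PerformanceVector):
        if s is not None:
            raise TypeError(f"{caller}: pass either a PerformanceVector or (d, s), not both")
        return v.d, v.s
    if s is None:
        raise TypeError(f"{caller}: missing instability argument s")
    return v, s


def truth(v: ArrayLike, s: ArrayLike = None, params: ModelParameters = None):
    """Truth membership: degree of competent performance.

    ``T(d, s) = max(0, 1 - d/d_max) * max(0, 1 - s/s_max)`` — the product of
    two rectified linear decays; zero whenever ``d >= d_max`` or
    ``s >= s_max``.
    """
    d, s = _coerce(v, s, "truth")
    d, s = _check_inputs(d, s)
    p = params or ModelParameters()
    t = np.maximum(0.0, 1.0 - d / p.d_max) * np.maximum(0.0, 1.0 - s / p.s_max)
    return t if t.ndim else float(t)


def falsity(v: ArrayLike, s: ArrayLike = None, params: ModelParameters = None):
    """Falsity membership: degree of clinically unsafe performance.

    ``F(d, s) = max(min(1, d/d_crit), min(1, s/s_max))`` — a safety-critical
    worst-case criterion over the two capped linear components; saturates at
    1 whenever ``d >= d_crit`` or ``s >= s_max``.
    """
    d, s = _coerce(v, s, "falsity")
    d, s = _check_inputs(d, s)
    p = params or ModelParameters()
    f = np.maximum(np.minimum(1.0, d / p.d_crit), np.minimum(1.0, s / p.s_max))
    return f if f.ndim else float(f)


def indeterminacy(v: ArrayLike, s: ArrayLike = None, params: ModelParameters = None):
    """Indeterminacy membership: degree of borderline/ambiguous performance.

    ``I(d, s) = max(0, 1 - |d - d_mid|/d_range) * min(1, s/s_max)`` — a
    triangular kernel centred on the mid-risk distance, scaled by normalised
    instability. Zero when ``|d - d_mid| >= d_range`` or ``s = 0``; peaks at
    ``d = d_mid`` with saturating instability.
    """
    d, s = _coerce(v, s, "indeterminacy")
    d, s = _check_inputs(d, s)
    p = params or ModelParameters()
    kernel = np.maximum(0.0, 1.0 - np.abs(d - p.d_mid) / p.d_range)
    i = kernel * np.minimum(1.0, s / p.s_max)
    return i if i.ndim else float(i)


def competence_score(T: ArrayLike, I: ArrayLike, F: ArrayLike):
    """Composite competence score ``S = (2 + T - I - F) / 3``.

    Strictly increasing in Truth, strictly decreasing in Indeterminacy and
    Falsity; bounded in [0, 1] for memberships in [0, 1].
    """
    T, I, F = (np.asarray(x, dtype=float) for x in (T, I, F))
    for name, x in (("T", T), ("I", I), ("F", F)):
        if not np.all(np.isfinite(x)) or np.any(x < -FLOAT_TOL) or np.any(x > 1 + FLOAT_TOL):
            raise ValueError(f"{name} must lie in [0, 1]")
    s = (2.0 + T - I - F) / 3.0
    return s if s.ndim else float(s)


def evaluate(v: ArrayLike, s: ArrayLike = None, params: ModelParameters = None):
    """Evaluate the full neutrosophic bundle ``(T, I, F, S)`` for an attempt.

    Accepts a :class:`PerformanceVector` or a ``(d, s)`` pair (scalars or
    arrays). Returns a :class:`NeutrosophicResult` for scalar input, or a
    4-tuple of arrays ``(T, I, F, S)`` for array input.
    """
    d, s = _coerce(v, s, "evaluate")
    d, s = _check_inputs(d, s)
    p = params or ModelParameters()
    T = np.maximum(0.0, 1.0 - d / p.d_max) * np.maximum(0.0, 1.0 - s / p.s_max)
    I = np.maximum(0.0, 1.0 - np.abs(d - p.d_mid) / p.d_range) * np.minimum(1.0, s / p.s_max)
    F = np.maximum(np.minimum(1.0, d / p.d_crit), np.minimum(1.0, s / p.s_max))
    S = (2.0 + T - I - F) / 3.0
    if T.ndim == 0:
        return NeutrosophicResult(float(T), float(I), float(F), float(S))
    return T, I, F, S


def classify_band(S: ArrayLike, bands: BandThresholds = None):
    """Map a competence score to its band label.

    Intervals are left-closed, right-open (the last band is closed at 1), so
    a score exactly equal to a cut point takes the band above it.
    """
    b = bands or BandThresholds()
    s = np.asarray(S, dtype=float)
    if not np.all(np.isfinite(s)) or np.any(s < -FLOAT_TOL) or np.any(s > 1 + FLOAT_TOL):
        raise ValueError(f"S must lie in [0, 1], got {S!r}")
    idx = np.searchsorted(np.asarray(b.cuts), s, side="right")
    labels = np.asarray(b.labels, dtype=object)[idx]
    return labels if s.ndim else str(labels)


def classical_pass(v: ArrayLike, s: ArrayLike = None, cutoff: float = 2.0):
    """Classical threshold verdict: pass iff ``d <= cutoff`` (mm).

    Deliberately ignores instability ``s`` entirely — this is the comparator
    the neutrosophic model is contrasted against. ``s`` is accepted (and
    validated) only so callers can pass the same inputs as to the scoring
    functions; a bare ``d`` works too.
    """
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise ValueError(f"cutoff must be strictly positive, got {cutoff!r}")
    if isinstance(v, PerformanceVector):
        d = np.asarray(v.d, dtype=float)
    else:
        d = np.asarray(v, dtype=float)
        if s is not None:
            _check_inputs(d, s)
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        raise ValueError("d must be finite and non-negative")
    result = d <= cutoff
    return result if result.ndim else bool(result)
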
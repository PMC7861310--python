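"""Synthetic trajectory generators: closed planar curves, prediction pairs,
one-hot augmentation and composite multi-activity sequences.

All generators are deterministic functions of their specs so that fixtures
are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TrajectorySpec",
    "SequencePair",
    "make_circle",
    "make_ellipse",
    "make_trajectory",
    "make_prediction_pair",
    "attach_onehot",
    "make_variable_rate_pairs",
    "make_shifted_circle_pairs",
    "make_composite_sequence",
]


@dataclass(frozen=True)
class TrajectorySpec:
    """Parameters of a closed planar sampling curve.

    ``period_steps`` rows trace exactly one full period; row ``t`` is sampled
    at angle ``phase_offset + 2*pi*t/period_steps``.
    """

    shape_kind: str = "circle"
    period_steps: int = 50
    radius: float = 1.0
    semi_axes: tuple[float, float] = (2.0, 1.0)
    center: tuple[float, float] = (0.0, 0.0)
    phase_offset: float = 0.0
    type_id: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("circle", "ellipse"):
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if self.period_steps < 2:
            raise ValueError("period_steps must be >= 2")
        if self.shape_kind == "circle" and self.radius <= 0:
            raise ValueError("radius must be strictly positive")
        if self.shape_kind == "ellipse" and min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be strictly positive")


@dataclass
class SequencePair:
    """Encoder input ``X`` (Te x M) and target output ``Y`` (Td x M).

    ``type_id`` is an evaluation-only tag, never consumed by training.
    When ``onehot_width`` = w > 0 the last w columns of X and Y are a
    constant one-hot indicator.
    """

    X: np.ndarray
    Y: np.ndarray
    type_id: int = 0
    onehot_width: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValueError("X and Y must be 2-D matrices")
        if self.X.shape[1] != self.Y.shape[1]:
            raise ValueError(
                f"feature mismatch: X has {self.X.shape[1]} columns, "
                f"Y has {self.Y.shape[1]}"
            )

    @property
    def Te(self) -> int:
        return self.X.shape[0]

    @property
    def Td(self) -> int:
        return self.Y.shape[0]

    @property
    def M(self) -> int:
        return self.X.shape[1]


def _angles(spec: TrajectorySpec, n_steps: int) -> np.ndarray:
    t = np.arange(n_steps)
    return spec.phase_offset + 2.0 * np.pi * t / spec.period_steps


def make_circle(spec: TrajectorySpec, n_steps: int | None = None) -> np.ndarray:
    """Sample one full period (or ``n_steps`` rows) of the circle in ``spec``."""
    if spec.shape_kind != "circle":
        raise ValueError("spec.shape_kind must be 'circle'")
    theta = _angles(spec, spec.period_steps if n_steps is None else n_steps)
    out = np.empty((theta.size, 2))
    out[:, 0] = spec.center[0] + spec.radius * np.cos(theta)
    out[:, 1] = spec.center[1] + spec.radius * np.sin(theta)
    return out


def make_ellipse(spec: TrajectorySpec, n_steps: int | None = None) -> np.ndarray:
    """Sample one full period (or ``n_steps`` rows) of the ellipse in ``spec``."""
    if spec.shape_kind != "ellipse":
        raise ValueError("spec.shape_kind must be 'ellipse'")
    a, b = spec.semi_axes
    theta = _angles(spec, spec.period_steps if n_steps is None else n_steps)
    out = np.empty((theta.size, 2))
    out[:, 0] = spec.center[0] + a * np.cos(theta)
    out[:, 1] = spec.center[1] + b * np.sin(theta)
    return out


def make_trajectory(spec: TrajectorySpec, n_steps: int | None = None) -> np.ndarray:
    """Dispatch on ``spec.shape_kind``."""
    if spec.shape_kind == "circle":
        return make_circle(spec, n_steps)
    return make_ellipse(spec, n_steps)


def make_prediction_pair(
    traj: np.ndarray, Td: int | None = None, *, type_id: int = 0,
    allow_truncated: bool = False,
) -> SequencePair:
    """Build a pair whose target is one further full period of the closed curve.

    Because the curve is periodic with period Te, the next period is the
    input itself, so by default Y == X and Td must equal Te. With
    ``allow_truncated`` a shorter Td takes the first Td rows of the next
    period instead.
    """
    traj = np.asarray(traj, dtype=float)
    Te = traj.shape[0]
    if Td is None:
        Td = Te
    if Td != Te and not allow_truncated:
        raise ValueError(
            f"periodic pair requires Td == Te ({Td} != {Te}); "
            "pass allow_truncated=True to take a partial next period"
        )
    if not 1 <= Td <= Te:
        raise ValueError("Td must be in [1, Te]")
    return SequencePair(X=traj.copy(), Y=traj[:Td].copy(), type_id=type_id)


def attach_onehot(pair: SequencePair, type_id: int, n_types: int) -> SequencePair:
    """Append ``n_types`` constant one-hot indicator columns to X and Y."""
    if pair.onehot_width:
        raise ValueError("pair already carries a one-hot block; refusing to stack")
    if not 0 <= type_id < n_types:
        raise ValueError(f"type_id {type_id} out of range [0, {n_types})")
    hot = np.zeros(n_types)
    hot[type_id] = 1.0
    X = np.hstack([pair.X, np.tile(hot, (pair.Te, 1))])
    Y = np.hstack([pair.Y, np.tile(hot, (pair.Td, 1))])
    return SequencePair(X=X, Y=Y, type_id=pair.type_id, onehot_width=n_types)


def make_variable_rate_pairs(
    slow_steps: int = 50, fast_steps: int = 25,
) -> tuple[SequencePair, SequencePair]:
    """Two unit circles sampled at different rates (same x-y support)."""
    slow = TrajectorySpec("circle", period_steps=slow_steps, radius=1.0, type_id=0)
    fast = TrajectorySpec("circle", period_steps=fast_steps, radius=1.0, type_id=1)
    return (
        make_prediction_pair(make_circle(slow), type_id=0),
        make_prediction_pair(make_circle(fast), type_id=1),
    )


def make_shifted_circle_pairs(
    period_steps: int = 50, offset: tuple[float, float] = (2.0, 0.0),
) -> tuple[SequencePair, SequencePair]:
    """A centered unit circle and the same circle translated by ``offset``."""
    centered = TrajectorySpec("circle", period_steps=period_steps, type_id=0)
    shifted = replace(centered, center=offset, type_id=1)
    return (
        make_prediction_pair(make_circle(centered), type_id=0),
        make_prediction_pair(make_circle(shifted), type_id=1),
    )


def make_composite_sequence(
    specs: list[TrajectorySpec],
    durations: list[int],
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate periodic segments into one long multi-activity sequence.

    Returns the T x M sequence and an integer frame-label vector carrying
    each frame's ``type_id``. Segments are butted together with no
    smoothing, so boundaries carry a discontinuity. ``seed`` is accepted
    for interface uniformity; generation is deterministic.
    """
    if len(specs) != len(durations):
        raise ValueError("specs and durations must have equal length")
    if any(d <= 0 for d in durations):
        raise ValueError("durations must be positive")
    segments, labels = [], []
    for spec, dur in zip(specs, durations):
        seg = make_trajectory(spec, n_steps=dur)
        segments.append(seg)
        labels.append(np.full(dur, spec.type_id, dtype=int))
    widths = {s.shape[1] for s in segments}
    if len(widths) != 1:
        raise ValueError(f"segments disagree on feature count: {sorted(widths)}")
    return np.vstack(segments), np.concatenate(labels)
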
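"""Column-centered SVD embedding of state matrices.

The global states matrix stacks every sequence's encoder-over-decoder
state block. Its centered SVD provides orthogonal spatial modes; mode
counts are chosen to retain a stated fraction of the singular-value
energy, and any state matrix can be projected into the shared mode space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seq2seq import StateTrace

__all__ = [
    "ENCODER",
    "DECODER",
    "PODBasis",
    "GlobalStatesMatrix",
    "center_columns",
    "pod",
    "pod_of",
    "sve_mode_count",
    "stack_states",
    "project",
    "origin_projection",
    "save_basis",
    "load_basis",
]

ENCODER = 0
DECODER = 1


@dataclass
class PODBasis:
    """Column means, right singular vectors and singular values of a
    centered state matrix."""

    mu: np.ndarray       # (N,) column means removed before the SVD
    V: np.ndarray        # (N, r) orthonormal mode columns
    sigma: np.ndarray    # (r,) non-increasing singular values
    U: np.ndarray | None = None   # (T, r) time coefficients, optional

    @property
    def n_features(self) -> int:
        return self.V.shape[0]

    @property
    def sve_total(self) -> float:
        """Total singular-value energy, sum of squared singular values."""
        return float(np.sum(self.sigma ** 2))

    def mode_count(self, p: float) -> int:
        return sve_mode_count(self.sigma, p)


@dataclass
class GlobalStatesMatrix:
    """Stack of per-sequence state blocks with row provenance.

    Within each sequence block, encoder rows precede decoder rows. The
    parallel index arrays record, per row: sequence id, phase
    (``ENCODER``/``DECODER``), time step within the phase, and the
    sequence's evaluation-only type id.
    """

    S: np.ndarray
    seq_ids: np.ndarray
    phases: np.ndarray
    steps: np.ndarray
    type_ids: np.ndarray

    def __post_init__(self) -> None:
        n = self.S.shape[0]
        for name in ("seq_ids", "phases", "steps", "type_ids"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"row_index field {name} has wrong length")

    @property
    def encoder_mask(self) -> np.ndarray:
        return self.phases == ENCODER

    @property
    def decoder_mask(self) -> np.ndarray:
        return self.phases == DECODER

    @property
    def encoder_rows(self) -> np.ndarray:
        return self.S[self.encoder_mask]

    @property
    def decoder_rows(self) -> np.ndarray:
        return self.S[self.decoder_mask]


def center_columns(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove column means; returns the centered matrix and the means."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    mu = A.mean(axis=0)
    return A - mu, mu


def pod(Ac: np.ndarray, keep_U: bool = True) -> PODBasis:
    """SVD of a centered matrix with a deterministic sign convention.

    Each mode column is flipped so its largest-magnitude entry is
    positive. A thin SVD is used; for T < N the trailing modes with zero
    energy are simply absent (they never enter mode counts).
    """
    Ac = np.asarray(Ac, dtype=float)
    if Ac.ndim != 2 or Ac.size == 0:
        raise ValueError("expected a non-empty 2-D matrix")
    if not np.all(np.isfinite(Ac)):
        raise ValueError("matrix contains non-finite entries")
    U, sigma, Vt = np.linalg.svd(Ac, full_matrices=False)
    V = Vt.T
    # sign convention: dominant entry of each mode positive
    flip = V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])] < 0
    V[:, flip] *= -1.0
    U[:, flip] *= -1.0
    mu = np.zeros(Ac.shape[1])  # callers center first; means live with the caller
    return PODBasis(mu=mu, V=V, sigma=sigma, U=U if keep_U else None)


def pod_of(A: np.ndarray, keep_U: bool = True) -> PODBasis:
    """Center then decompose; the returned basis carries the removed means."""
    Ac, mu = center_columns(A)
    basis = pod(Ac, keep_U=keep_U)
    basis.mu = mu
    return basis


def sve_mode_count(sigma: np.ndarray, p: float) -> int:
    """Smallest k whose leading singular values retain a fraction >= p of
    the total singular-value energy."""
    sigma = np.asarray(sigma, dtype=float)
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    energy = sigma ** 2
    total = energy.sum()
    if total <= 0.0:
        raise ValueError("all singular values are zero")
    ratio = np.cumsum(energy) / total
    # 1e-12 slack so p=1 is reached as soon as the cumulative sum is
    # complete to machine precision (trailing exact-zero modes excluded)
    return int(np.searchsorted(ratio, p - 1e-12) + 1)


def stack_states(
    traces: Sequence[StateTrace], type_ids: Sequence[int] | None = None,
) -> GlobalStatesMatrix:
    """Assemble the global states matrix from per-sequence traces."""
    if not traces:
        raise ValueError("no traces given")
    widths = {t.E.shape[1] for t in traces} | {t.D.shape[1] for t in traces}
    if len(widths) != 1:
        raise ValueError(f"traces disagree on state width: {sorted(widths)}")
    if type_ids is None:
        type_ids = [0] * len(traces)
    if len(type_ids) != len(traces):
        raise ValueError("type_ids length must match traces")
    blocks, seq_ids, phases, steps, tids = [], [], [], [], []
    for k, (trace, tid) in enumerate(zip(traces, type_ids)):
        Te, Td = trace.E.shape[0], trace.D.shape[0]
        blocks.append(trace.S)
        seq_ids.append(np.full(Te + Td, k))
        phases.append(np.concatenate([np.full(Te, ENCODER), np.full(Td, DECODER)]))
        steps.append(np.concatenate([np.arange(Te), np.arange(Td)]))
        tids.append(np.full(Te + Td, tid))
    return GlobalStatesMatrix(
        S=np.vstack(blocks),
        seq_ids=np.concatenate(seq_ids),
        phases=np.concatenate(phases),
        steps=np.concatenate(steps),
        type_ids=np.concatenate(tids),
    )


def project(A: np.ndarray, basis: PODBasis, n: int) -> np.ndarray:
    """Project rows of A into the first n modes of the basis.

    Centering always uses the basis's own means so that new matrices land
    in the same coordinate frame as the basis source.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    if A.shape[1] != basis.n_features:
        raise ValueError(
            f"matrix has {A.shape[1]} columns, basis expects {basis.n_features}"
        )
    if not 1 <= n <= basis.V.shape[1]:
        raise ValueError(f"n must be in [1, {basis.V.shape[1]}]")
    return (A - basis.mu) @ basis.V[:, :n]


def origin_projection(basis: PODBasis, n: int) -> np.ndarray:
    """Image of the all-zero state under the basis projection (-mu @ V_n).

    Every trajectory started from a zero initial state enters the
    embedding at this shared point.
    """
    return project(np.zeros((1, basis.n_features)), basis, n)[0]


def save_basis(basis: PODBasis, path, provenance: dict | None = None) -> None:
    meta = json.dumps(provenance or {})
    np.savez(
        path, mu=basis.mu, V=basis.V, sigma=basis.sigma,
        provenance=np.frombuffer(meta.encode(), dtype=np.uint8),
    )


def load_basis(path) -> tuple[PODBasis, dict]:
    with np.load(path) as data:
        basis = PODBasis(mu=data["mu"], V=data["V"], sigma=data["sigma"])
        provenance = json.loads(bytes(data["provenance"]).decode() or "{}")
    return basis, provenance
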
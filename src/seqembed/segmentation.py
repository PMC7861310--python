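"""Unsupervised temporal segmentation of long multi-activity sequences.

A trained predictor is slid along the sequence; the decoder states
collected from every window are embedded (centered SVD of the collected
matrix itself), projected, and clustered bottom-up with cosine single
linkage. Cluster votes from all decoder rows covering a frame are
aggregated into per-frame labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import agglomerative_cosine_single, kmeans_pp, matched_accuracy
from .embedding import pod_of, project
from .seq2seq import Seq2Seq

__all__ = [
    "WindowScan",
    "SegmentationResult",
    "sliding_windows",
    "collect_window_states",
    "segment",
    "evaluate_segmentation",
    "segment_table",
]


@dataclass
class WindowScan:
    starts: np.ndarray
    Te: int
    Td: int
    stride: int
    n_frames: int

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def frame_map(self) -> np.ndarray:
        """Frame index covered by each decoder row, window-major then
        decoder-step: step t of the window at s covers frame s + Te + t."""
        return (self.starts[:, None] + self.Te + np.arange(self.Td)[None, :]).ravel()


@dataclass
class SegmentationResult:
    frame_labels: np.ndarray
    k: int
    covered: np.ndarray            # bool per frame: received >= 1 vote
    uncovered_policy: str = "nearest-covered"
    accuracy: float | None = None


def sliding_windows(sequence: np.ndarray, Te: int, Td: int, stride: int = 1) -> WindowScan:
    """Window starts 0, stride, 2*stride, ... while start + Te + Td fits."""
    sequence = np.asarray(sequence)
    T = sequence.shape[0]
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if T < Te + Td:
        raise ValueError(f"sequence length {T} shorter than Te+Td={Te + Td}")
    starts = np.arange(0, T - Te - Td + 1, stride)
    return WindowScan(starts=starts, Te=Te, Td=Td, stride=stride, n_frames=T)


def collect_window_states(
    model: Seq2Seq, scan: WindowScan, sequence: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward every window; returns ((n_windows*Td) x N decoder rows,
    aligned covered-frame indices). All windows share a shape, so the
    forward pass is batched."""
    sequence = np.asarray(sequence, dtype=float)
    X = np.stack([sequence[s:s + scan.Te] for s in scan.starts])
    _, D, _ = model.forward_batch(X, scan.Td)
    rows = D.reshape(-1, D.shape[2])
    return rows, scan.frame_map()


def segment(
    model: Seq2Seq,
    sequence: np.ndarray,
    k: int,
    Te: int,
    Td: int,
    stride: int = 1,
    n_pcs: int = 3,
    granularity: str = "window",
    method: str = "kmeans",
    seed: int = 0,
) -> SegmentationResult:
    """Full unsupervised segmentation pipeline.

    ``granularity`` controls what gets clustered: ``"window"`` clusters one
    summary vector per window (the mean of its projected decoder rows, each
    row then voting with its window's label) and ``"row"`` clusters every
    projected decoder row individually. Windows straddling an activity
    boundary produce transitional states that bridge the attractors; the
    window summary averages them out, so it is the stable default, while
    per-row clustering is kept for inspection. ``method`` selects K-means++
    (``seed``-deterministic) or bottom-up cosine single linkage.

    Frames covered by several windows take the majority cluster of their
    decoder rows (ties toward the lower cluster id); frames never covered
    (the first Te and any tail past the last window) inherit the nearest
    covered frame's label.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if granularity not in ("window", "row"):
        raise ValueError(f"unknown granularity {granularity!r}")
    if method not in ("kmeans", "agglo"):
        raise ValueError(f"unknown method {method!r}")
    sequence = np.asarray(sequence, dtype=float)
    T = sequence.shape[0]
    scan = sliding_windows(sequence, Te, Td, stride)
    rows, frames = collect_window_states(model, scan, sequence)
    if k > rows.shape[0]:
        raise ValueError(f"k={k} exceeds number of collected rows {rows.shape[0]}")

    basis = pod_of(rows, keep_U=False)
    proj = project(rows, basis, min(n_pcs, basis.V.shape[1]))
    if granularity == "window":
        points = proj.reshape(scan.n_windows, scan.Td, -1).mean(axis=1)
        if k > len(points):
            raise ValueError(f"k={k} exceeds number of windows {len(points)}")
    else:
        points = proj
    if method == "kmeans":
        point_labels = kmeans_pp(points, k, seed=seed).labels
    else:
        point_labels = agglomerative_cosine_single(points, k).labels
    if granularity == "window":
        labels = np.repeat(point_labels, scan.Td)
    else:
        labels = point_labels

    votes = np.zeros((T, k), dtype=np.int64)
    np.add.at(votes, (frames, labels), 1)
    covered = votes.sum(axis=1) > 0
    frame_labels = np.full(T, -1, dtype=int)
    frame_labels[covered] = votes[covered].argmax(axis=1)  # lower id wins ties

    if not covered.all():
        cov_idx = np.flatnonzero(covered)
        missing = np.flatnonzero(~covered)
        pos = np.searchsorted(cov_idx, missing)
        left = cov_idx[np.clip(pos - 1, 0, len(cov_idx) - 1)]
        right = cov_idx[np.clip(pos, 0, len(cov_idx) - 1)]
        nearest = np.where(missing - left <= right - missing, left, right)
        # clip above collapses out-of-range sides onto valid covered frames
        nearest[missing < cov_idx[0]] = cov_idx[0]
        nearest[missing > cov_idx[-1]] = cov_idx[-1]
        frame_labels[missing] = frame_labels[nearest]

    return SegmentationResult(frame_labels=frame_labels, k=k, covered=covered)


def evaluate_segmentation(
    result: SegmentationResult, reference_frame_labels: np.ndarray,
) -> float:
    """Frame-level accuracy under optimal cluster-to-class matching."""
    ref = np.asarray(reference_frame_labels).ravel()
    if ref.size != result.frame_labels.size:
        raise ValueError(
            f"frame count mismatch: {result.frame_labels.size} vs {ref.size}"
        )
    acc = matched_accuracy(result.frame_labels, ref)
    result.accuracy = acc
    return acc


def segment_table(frame_labels: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous (start, end_exclusive, label) runs of a frame labeling."""
    labels = np.asarray(frame_labels).ravel()
    if labels.size == 0:
        return []
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(int(s), int(e), int(labels[s])) for s, e in zip(starts, ends)]
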
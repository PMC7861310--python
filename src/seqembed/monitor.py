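"""Training-time observation of the embedding: losses vs. decoder-cluster
quality and dominant-mode counts, plus optimal-fit / overfitting detection.

At each checkpoint the embedding is rebuilt from scratch from that
iteration's probe forward passes; snapshots are pure observations and
never perturb the training stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .clustering import agglomerative_cosine_single, ari, kmeans_pp
from .embedding import PODBasis, pod_of, project, stack_states
from .seq2seq import Seq2Seq, SequencePair, TrainLog, forward_collect, train, validation_loss

__all__ = [
    "TrainingSnapshot",
    "take_snapshot",
    "snapshot_schedule",
    "run_monitoring",
    "detect_optimal_iteration",
]

ENERGY_LEVELS = (0.90, 0.99)


@dataclass
class TrainingSnapshot:
    iteration: int
    train_loss: float | None
    val_loss: float | None
    ari_full: float           # K-means++ on full-width decoder state rows
    ari_pc3: float            # K-means++ on decoder rows projected to n_pcs
    ari_agglo: float          # agglomerative cosine/single on full-width rows
    n_pcs: int
    modes: dict[str, dict[float, int]]   # phase -> {energy level -> k}
    basis: PODBasis | None = field(default=None, repr=False)

    @property
    def ari(self) -> float:
        """Default separability score.

        Interleaved closed-loop attractors are not linearly separable, so
        K-means row partitions can stay near chance even when the loops are
        cleanly separated; the bottom-up cosine merge is the score that
        tracks separability on the synthetic tasks.
        """
        return self.ari_agglo


def take_snapshot(
    model: Seq2Seq,
    probe_pairs: Sequence[SequencePair],
    iteration: int,
    *,
    n_pcs: int = 3,
    cluster_seed: int = 0,
    train_loss: float | None = None,
    val_pairs: Sequence[SequencePair] | None = None,
    keep_basis: bool = False,
) -> TrainingSnapshot:
    """Forward every probe pair, rebuild the embedding, cluster decoder rows
    with k = number of probe types and score against the type tags."""
    type_ids = [p.type_id for p in probe_pairs]
    n_types = len(set(type_ids))
    if n_types < 2:
        raise ValueError("probe set must contain at least 2 sequence types")

    traces = [forward_collect(model, p.X, p.Td) for p in probe_pairs]
    gsm = stack_states(traces, type_ids)
    basis = pod_of(gsm.S, keep_U=False)

    modes: dict[str, dict[float, int]] = {}
    for name, block in (
        ("encoder", gsm.encoder_rows),
        ("decoder", gsm.decoder_rows),
        ("global", gsm.S),
    ):
        sigma = pod_of(block, keep_U=False).sigma
        modes[name] = {p: int(np.searchsorted(
            np.cumsum(sigma ** 2) / np.sum(sigma ** 2), p - 1e-12) + 1)
            for p in ENERGY_LEVELS} if np.any(sigma > 0) else {p: 0 for p in ENERGY_LEVELS}

    dec_rows = gsm.decoder_rows
    dec_types = gsm.type_ids[gsm.decoder_mask]
    n_eff = min(n_pcs, basis.V.shape[1])
    proj = project(dec_rows, basis, n_eff)
    ari_pc3 = ari(kmeans_pp(proj, n_types, seed=cluster_seed).labels, dec_types)
    ari_full = ari(kmeans_pp(dec_rows, n_types, seed=cluster_seed).labels, dec_types)
    ari_agglo = ari(agglomerative_cosine_single(dec_rows, n_types).labels, dec_types)

    vloss = validation_loss(model, val_pairs) if val_pairs else None
    return TrainingSnapshot(
        iteration=iteration,
        train_loss=train_loss,
        val_loss=vloss,
        ari_full=ari_full,
        ari_pc3=ari_pc3,
        ari_agglo=ari_agglo,
        n_pcs=n_eff,
        modes=modes,
        basis=basis if keep_basis else None,
    )


def snapshot_schedule(
    iterations: int, interval: int, extra: Sequence[int] = (),
) -> list[int]:
    """{1, interval, 2*interval, ...} plus the final iteration and any
    explicitly requested checkpoints."""
    if interval < 1:
        raise ValueError("interval must be >= 1")
    sched = {1, iterations}
    sched.update(range(interval, iterations + 1, interval))
    sched.update(i for i in extra if 1 <= i <= iterations)
    return sorted(sched)


def run_monitoring(
    model: Seq2Seq,
    pairs: Sequence[SequencePair],
    iterations: int,
    interval: int,
    probe_pairs: Sequence[SequencePair],
    *,
    batch_size: int | None = None,
    optimizer_config=None,
    n_pcs: int = 3,
    cluster_seed: int = 0,
    val_pairs: Sequence[SequencePair] | None = None,
    extra_iterations: Sequence[int] = (),
) -> tuple[Seq2Seq, TrainLog, list[TrainingSnapshot]]:
    """Train while recording a snapshot at each scheduled iteration."""
    snapshots: list[TrainingSnapshot] = []
    sched = snapshot_schedule(iterations, interval, extra_iterations)

    def callback(m: Seq2Seq, it: int, loss: float) -> None:
        snapshots.append(take_snapshot(
            m, probe_pairs, it, n_pcs=n_pcs, cluster_seed=cluster_seed,
            train_loss=loss, val_pairs=val_pairs,
        ))

    model, log = train(
        model, pairs, iterations, batch_size=batch_size,
        optimizer_config=optimizer_config,
        snapshot_callback=callback, snapshot_iterations=sched,
    )
    return model, log, snapshots


def detect_optimal_iteration(
    snapshots: Sequence[TrainingSnapshot],
    margin: float = 0.05,
    ari_attr: str = "ari_agglo",
) -> tuple[int, int | None, bool]:
    """Locate peak separability and minimum validation loss.

    Returns (iteration of maximum decoder ARI, iteration of minimum
    validation loss or None, overfit flag). The flag is raised when the
    final snapshot's ARI sits below the peak by more than ``margin``
    while — if validation loss is available — the final validation loss
    exceeds its minimum.
    """
    if len(snapshots) < 3:
        raise ValueError("need at least 3 snapshots")
    aris = np.array([getattr(s, ari_attr) for s in snapshots])
    iters = np.array([s.iteration for s in snapshots])
    best = int(np.argmax(aris))          # earliest on ties
    i_star_ari = int(iters[best])

    vlosses = [s.val_loss for s in snapshots]
    have_val = all(v is not None for v in vlosses)
    i_star_val = None
    ari_dropped = aris[-1] < aris[best] - margin
    if have_val:
        varr = np.array(vlosses, dtype=float)
        i_star_val = int(iters[int(np.argmin(varr))])
        overfit = bool(ari_dropped and varr[-1] > varr.min())
    else:
        overfit = bool(ari_dropped)
    return i_star_ari, i_star_val, overfit
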
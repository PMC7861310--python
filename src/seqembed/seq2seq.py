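"""Encoder-decoder recurrent model with full internal-state capture.

The encoder consumes the input sequence from an all-zero initial state; its
final internal state initializes the decoder. The decoder is
teacher-forcing-free: its first input is the last encoder input row and
every later input is its own previous output. A trailing linear map sends
hidden states to output space.

Training minimizes mean squared error with Adam and gradient-norm
clipping, fully driven by one master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .cells import make_cell
from .synthetic import SequencePair

__all__ = [
    "ModelConfig",
    "OptimizerConfig",
    "StateTrace",
    "TrainLog",
    "Seq2Seq",
    "init_model",
    "forward_collect",
    "mse_loss",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    n_units: int
    n_features: int
    share_weights: bool = False
    cell_kind: str = "GRU"
    n_layers: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1 or self.n_features < 1 or self.n_layers < 1:
            raise ValueError("n_units, n_features and n_layers must be >= 1")
        if self.cell_kind.upper() not in ("GRU", "LSTM"):
            raise ValueError(f"unsupported cell_kind {self.cell_kind!r}")
        if self.n_layers != 1:
            raise NotImplementedError("only single-layer models are supported")


@dataclass(frozen=True)
class OptimizerConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    clip_norm: float = 5.0


@dataclass
class StateTrace:
    """Per-step internal states of one forward pass."""

    E: np.ndarray      # Te x N encoder states
    D: np.ndarray      # Td x N decoder states
    Yhat: np.ndarray   # Td x M decoder outputs

    @property
    def S(self) -> np.ndarray:
        """Vertical stack of encoder states above decoder states."""
        return np.vstack([self.E, self.D])


@dataclass
class TrainLog:
    iterations: list[int] = field(default_factory=list)
    train_loss: list[float] = field(default_factory=list)


class Seq2Seq:
    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        N, M = config.n_units, config.n_features
        enc = make_cell(config.cell_kind, M, N, rng)
        dec = enc if config.share_weights else make_cell(config.cell_kind, M, N, rng)
        self.encoder = enc
        self.decoder = dec
        k = 1.0 / np.sqrt(N)
        self.out_params = {
            "Wo": rng.uniform(-k, k, (N, M)),
            "bo": rng.uniform(-k, k, M),
        }
        self.out_grads = {n: np.zeros_like(p) for n, p in self.out_params.items()}
        self.iteration = 0

    # -- parameter bookkeeping ------------------------------------------

    def param_items(self) -> list[tuple[str, np.ndarray]]:
        """Unique (key, array) pairs; shared cells appear once."""
        items = [(f"enc.{n}", p) for n, p in self.encoder.params.items()]
        if self.decoder is not self.encoder:
            items += [(f"dec.{n}", p) for n, p in self.decoder.params.items()]
        items += [(f"out.{n}", p) for n, p in self.out_params.items()]
        return items

    def grad_items(self) -> list[tuple[str, np.ndarray]]:
        items = [(f"enc.{n}", g) for n, g in self.encoder.grads.items()]
        if self.decoder is not self.encoder:
            items += [(f"dec.{n}", g) for n, g in self.decoder.grads.items()]
        items += [(f"out.{n}", g) for n, g in self.out_grads.items()]
        return items

    def zero_grads(self) -> None:
        self.encoder.zero_grads()
        if self.decoder is not self.encoder:
            self.decoder.zero_grads()
        for g in self.out_grads.values():
            g[:] = 0.0

    # -- forward / backward ---------------------------------------------

    def forward_batch(self, X: np.ndarray, Td: int, keep_caches: bool = False):
        """Run a (B, Te, M) batch; returns E, D, Yhat (+ caches)."""
        B, Te, M = X.shape
        if Te == 0 or Td == 0:
            raise ValueError("Te and Td must be positive")
        if M != self.config.n_features:
            raise ValueError(
                f"input has {M} features, model expects {self.config.n_features}"
            )
        N = self.config.n_units
        E = np.empty((B, Te, N))
        D = np.empty((B, Td, N))
        Yhat = np.empty((B, Td, M))
        enc_caches, dec_caches = [], []

        state = self.encoder.zero_state(B)
        for t in range(Te):
            h, state, cache = self.encoder.step(X[:, t], state)
            E[:, t] = h
            if keep_caches:
                enc_caches.append(cache)

        Wo, bo = self.out_params["Wo"], self.out_params["bo"]
        inp = X[:, -1]
        for t in range(Td):
            h, state, cache = self.decoder.step(inp, state)
            D[:, t] = h
            Yhat[:, t] = h @ Wo + bo
            if keep_caches:
                dec_caches.append(cache)
            inp = Yhat[:, t]

        if keep_caches:
            return E, D, Yhat, (enc_caches, dec_caches)
        return E, D, Yhat

    def backward_batch(self, dYhat: np.ndarray, D: np.ndarray, caches) -> None:
        """Accumulate parameter gradients for one batch.

        Gradients flow through the output layer, the recurrence, and the
        decoder's fed-back outputs.
        """
        enc_caches, dec_caches = caches
        B, Td, _ = dYhat.shape
        Wo = self.out_params["Wo"]
        dWo, dbo = self.out_grads["Wo"], self.out_grads["bo"]

        dstate = self._zero_dstate(B)
        dinp = None
        for t in reversed(range(Td)):
            dy = dYhat[:, t].copy()
            if dinp is not None:
                dy += dinp      # fed back as input of step t+1
            dWo += D[:, t].T @ dy
            dbo += dy.sum(axis=0)
            dh_extra = dy @ Wo.T
            dinp, dstate = self.decoder.backstep(dh_extra, dstate, dec_caches[t])
        # dinp at t=0 is w.r.t. the last encoder input row (data): dropped.
        zero = np.zeros((B, self.config.n_units))
        for t in reversed(range(len(enc_caches))):
            _, dstate = self.encoder.backstep(zero, dstate, enc_caches[t])

    def _zero_dstate(self, B: int):
        z = np.zeros((B, self.config.n_units))
        if self.config.cell_kind.upper() == "LSTM":
            return (z, z.copy())
        return z


def init_model(config: ModelConfig) -> Seq2Seq:
    """Build a model with seeded, reproducible parameter initialization."""
    return Seq2Seq(config)


def forward_collect(model: Seq2Seq, X: np.ndarray, Td: int) -> StateTrace:
    """Forward one sequence, recording every internal state."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (Te x M)")
    E, D, Yhat = model.forward_batch(X[None], Td)
    return StateTrace(E=E[0], D=D[0], Yhat=Yhat[0])


def mse_loss(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Squared error averaged over time steps and features."""
    Y = np.asarray(Y, dtype=float)
    Yhat = np.asarray(Yhat, dtype=float)
    if Y.shape != Yhat.shape:
        raise ValueError(f"shape mismatch: {Y.shape} vs {Yhat.shape}")
    return float(np.mean((Y - Yhat) ** 2))


class _Adam:
    def __init__(self, params: list[tuple[str, np.ndarray]], cfg: OptimizerConfig):
        self.cfg = cfg
        self.m = {k: np.zeros_like(p) for k, p in params}
        self.v = {k: np.zeros_like(p) for k, p in params}
        self.t = 0

    def step(self, params, grads) -> None:
        cfg = self.cfg
        total = np.sqrt(sum(float(np.sum(g * g)) for _, g in grads))
        scale = 1.0
        if cfg.clip_norm and total > cfg.clip_norm:
            scale = cfg.clip_norm / (total + 1e-12)
        self.t += 1
        b1t = 1.0 - cfg.beta1 ** self.t
        b2t = 1.0 - cfg.beta2 ** self.t
        gmap = dict(grads)
        for key, p in params:
            g = gmap[key] * scale
            m = self.m[key]
            v = self.v[key]
            m *= cfg.beta1
            m += (1.0 - cfg.beta1) * g
            v *= cfg.beta2
            v += (1.0 - cfg.beta2) * g * g
            p -= cfg.learning_rate * (m / b1t) / (np.sqrt(v / b2t) + cfg.eps)


def _batch_groups(pairs: Sequence[SequencePair], idx: np.ndarray):
    """Group batch indices by (Te, Td) so each group runs vectorized."""
    groups: dict[tuple[int, int], list[int]] = {}
    for i in idx:
        groups.setdefault((pairs[i].Te, pairs[i].Td), []).append(int(i))
    return groups


def train(
    model: Seq2Seq,
    pairs: Sequence[SequencePair],
    iterations: int,
    batch_size: int | None = None,
    optimizer_config: OptimizerConfig | None = None,
    snapshot_callback: Callable[[Seq2Seq, int, float], None] | None = None,
    snapshot_iterations: Sequence[int] | None = None,
) -> tuple[Seq2Seq, TrainLog]:
    """Minimize MSE over the dataset; returns the model and loss history.

    ``snapshot_callback(model, iteration, loss)`` is invoked after the
    optimizer step at each iteration listed in ``snapshot_iterations``.
    Callbacks must not mutate the model; they draw no randomness from the
    training stream, so a monitored run is bitwise identical to an
    unmonitored one.
    """
    if not pairs:
        raise ValueError("training dataset is empty")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    K = len(pairs)
    if batch_size is None:
        batch_size = K
    cfg = optimizer_config or OptimizerConfig()
    snap_set = frozenset(snapshot_iterations or ())

    # Batching randomness is derived from the master seed but separated
    # from the init stream.
    rng = np.random.default_rng([model.config.seed, 0x5EED])
    opt = _Adam(model.param_items(), cfg)
    log = TrainLog()

    for it in range(1, iterations + 1):
        if batch_size <= K:
            idx = rng.permutation(K)[:batch_size]
        else:
            idx = rng.integers(0, K, size=batch_size)
        model.zero_grads()
        loss_sum = 0.0
        for (Te, Td), members in _batch_groups(pairs, idx).items():
            X = np.stack([pairs[i].X for i in members])
            Y = np.stack([pairs[i].Y for i in members])
            E, D, Yhat, caches = model.forward_batch(X, Td, keep_caches=True)
            err = Yhat - Y
            loss_sum += float(np.sum(err * err)) / (Td * Y.shape[2])
            dYhat = 2.0 * err / (Td * Y.shape[2] * batch_size)
            model.backward_batch(dYhat, D, caches)
        opt.step(model.param_items(), model.grad_items())
        model.iteration += 1
        loss = loss_sum / batch_size
        log.iterations.append(model.iteration)
        log.train_loss.append(loss)
        if snapshot_callback is not None and (it in snap_set or not snap_set):
            snapshot_callback(model, model.iteration, loss)
    return model, log


def validation_loss(model: Seq2Seq, pairs: Sequence[SequencePair]) -> float:
    """Mean MSE over held-out pairs (no parameter updates)."""
    losses = []
    for p in pairs:
        trace = forward_collect(model, p.X, p.Td)
        losses.append(mse_loss(p.Y, trace.Yhat))
    return float(np.mean(losses))


def save_checkpoint(model: Seq2Seq, path) -> None:
    """Single-archive checkpoint: parameters, config, iteration count."""
    arrays = {key.replace(".", "__"): p for key, p in model.param_items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    arrays["__iteration__"] = np.array(model.iteration)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Seq2Seq:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
        model = Seq2Seq(cfg)
        for key, p in model.param_items():
            p[:] = data[key.replace(".", "__")]
        model.iteration = int(data["__iteration__"])
    return model
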
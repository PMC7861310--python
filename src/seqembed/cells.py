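"""Recurrent cells (GRU, LSTM) with explicit forward caches and
backpropagation-through-time steps.

Implemented directly in numpy: the surrounding pipeline needs per-step
hidden-state capture and exact, framework-free reproducibility, and the
models involved are small (tens of units). Gradients are verified against
central finite differences in the test suite.

Shapes: inputs ``x`` are (B, M), hidden states (B, N). A cell's recurrent
"state" is the hidden vector for GRU and an (h, c) tuple for LSTM.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GRUCell", "LSTMCell", "make_cell"]


def _sigmoid(a: np.ndarray) -> np.ndarray:
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


class _Cell:
    """Common parameter plumbing; subclasses define step/backstep."""

    gate_names: tuple[str, ...] = ()

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.input_size = input_size
        self.hidden_size = hidden_size
        k = 1.0 / np.sqrt(hidden_size)
        self.params: dict[str, np.ndarray] = {}
        for g in self.gate_names:
            self.params[f"Wx_{g}"] = rng.uniform(-k, k, (input_size, hidden_size))
            self.params[f"Wh_{g}"] = rng.uniform(-k, k, (hidden_size, hidden_size))
            self.params[f"b_{g}"] = rng.uniform(-k, k, hidden_size)
        self._extra_params(rng, k)
        self.grads: dict[str, np.ndarray] = {}
        self.zero_grads()

    def _extra_params(self, rng: np.random.Generator, k: float) -> None:
        pass

    def zero_grads(self) -> None:
        self.grads = {name: np.zeros_like(p) for name, p in self.params.items()}

    def zero_state(self, batch: int):
        raise NotImplementedError

    def step(self, x: np.ndarray, state):
        """Advance one step; returns (h, new_state, cache)."""
        raise NotImplementedError

    def backstep(self, dh_extra: np.ndarray, dstate, cache):
        """Accumulate parameter grads; returns (dx, dstate_prev).

        ``dh_extra`` is the gradient reaching h_t from outside the
        recurrence (output layer); ``dstate`` carries gradients arriving
        from step t+1.
        """
        raise NotImplementedError


class GRUCell(_Cell):
    """h_t = (1-z)*n + z*h_{t-1} with reset gate applied to the recurrent
    half of the candidate pre-activation (separate input/recurrent candidate
    biases)."""

    gate_names = ("r", "z")

    def _extra_params(self, rng: np.random.Generator, k: float) -> None:
        N, M = self.hidden_size, self.input_size
        self.params["Wx_n"] = rng.uniform(-k, k, (M, N))
        self.params["Wh_n"] = rng.uniform(-k, k, (N, N))
        self.params["bx_n"] = rng.uniform(-k, k, N)
        self.params["bh_n"] = rng.uniform(-k, k, N)

    def zero_state(self, batch: int) -> np.ndarray:
        return np.zeros((batch, self.hidden_size))

    def step(self, x, state):
        p = self.params
        h_prev = state
        r = _sigmoid(x @ p["Wx_r"] + h_prev @ p["Wh_r"] + p["b_r"])
        z = _sigmoid(x @ p["Wx_z"] + h_prev @ p["Wh_z"] + p["b_z"])
        m = h_prev @ p["Wh_n"] + p["bh_n"]
        n = np.tanh(x @ p["Wx_n"] + p["bx_n"] + r * m)
        h = (1.0 - z) * n + z * h_prev
        return h, h, (x, h_prev, r, z, m, n)

    def backstep(self, dh_extra, dstate, cache):
        x, h_prev, r, z, m, n = cache
        p, g = self.params, self.grads
        dh = dh_extra + dstate
        dn = dh * (1.0 - z)
        dz = dh * (h_prev - n)
        dh_prev = dh * z
        da_n = dn * (1.0 - n * n)
        dr = da_n * m
        dm = da_n * r
        g["Wx_n"] += x.T @ da_n
        g["bx_n"] += da_n.sum(axis=0)
        g["Wh_n"] += h_prev.T @ dm
        g["bh_n"] += dm.sum(axis=0)
        dh_prev += dm @ p["Wh_n"].T
        dx = da_n @ p["Wx_n"].T
        da_r = dr * r * (1.0 - r)
        da_z = dz * z * (1.0 - z)
        for name, da in (("r", da_r), ("z", da_z)):
            g[f"Wx_{name}"] += x.T @ da
            g[f"Wh_{name}"] += h_prev.T @ da
            g[f"b_{name}"] += da.sum(axis=0)
            dx += da @ p[f"Wx_{name}"].T
            dh_prev += da @ p[f"Wh_{name}"].T
        return dx, dh_prev


class LSTMCell(_Cell):
    gate_names = ("i", "f", "g", "o")

    def zero_state(self, batch: int):
        z = np.zeros((batch, self.hidden_size))
        return (z, z.copy())

    def step(self, x, state):
        p = self.params
        h_prev, c_prev = state
        i = _sigmoid(x @ p["Wx_i"] + h_prev @ p["Wh_i"] + p["b_i"])
        f = _sigmoid(x @ p["Wx_f"] + h_prev @ p["Wh_f"] + p["b_f"])
        gg = np.tanh(x @ p["Wx_g"] + h_prev @ p["Wh_g"] + p["b_g"])
        o = _sigmoid(x @ p["Wx_o"] + h_prev @ p["Wh_o"] + p["b_o"])
        c = f * c_prev + i * gg
        tc = np.tanh(c)
        h = o * tc
        return h, (h, c), (x, h_prev, c_prev, i, f, gg, o, tc)

    def backstep(self, dh_extra, dstate, cache):
        x, h_prev, c_prev, i, f, gg, o, tc = cache
        p, g = self.params, self.grads
        dh_next, dc_next = dstate
        dh = dh_extra + dh_next
        do = dh * tc
        dc = dh * o * (1.0 - tc * tc) + dc_next
        df = dc * c_prev
        di = dc * gg
        dg = dc * i
        dc_prev = dc * f
        da = {
            "i": di * i * (1.0 - i),
            "f": df * f * (1.0 - f),
            "g": dg * (1.0 - gg * gg),
            "o": do * o * (1.0 - o),
        }
        dx = np.zeros_like(x)
        dh_prev = np.zeros_like(h_prev)
        for name, d in da.items():
            g[f"Wx_{name}"] += x.T @ d
            g[f"Wh_{name}"] += h_prev.T @ d
            g[f"b_{name}"] += d.sum(axis=0)
            dx += d @ p[f"Wx_{name}"].T
            dh_prev += d @ p[f"Wh_{name}"].T
        return dx, (dh_prev, dc_prev)


def make_cell(kind: str, input_size: int, hidden_size: int,
              rng: np.random.Generator) -> _Cell:
    kind = kind.upper()
    if kind == "GRU":
        return GRUCell(input_size, hidden_size, rng)
    if kind == "LSTM":
        return LSTMCell(input_size, hidden_size, rng)
    raise ValueError(f"unsupported cell_kind {kind!r}")
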
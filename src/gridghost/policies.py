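"""Recurrent per-role policies: a numpy LSTM trained by backpropagation through time.

Each defensive role gets its own policy: a stacked (default two-layer) LSTM over the
full per-frame game state, with a linear head emitting the role's next-step
displacement (Δx', Δy') in yards per frame.  Displacements are integrated to
positions during rollout, which keeps the regression targets bounded by the
physical speed cap regardless of where on the field a play happens.

The implementation is self-contained numpy: forward pass, full BPTT gradients and
an Adam optimizer, with the analytic gradients verified against finite differences
in the test suite.  Inputs are divided by a fixed scale (10 yards) so coordinates
land in a well-conditioned range; hidden state is reset at window boundaries in
training and at the snap during rollout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

_INPUT_SCALE = 10.0


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class PolicyConfig:
    """Architecture and optimizer settings for one role policy."""

    input_dim: int
    hidden_size: int = 128
    n_layers: int = 2
    output_dim: int = 2
    learning_rate: float = 2e-3
    seed: int = 0


class LSTMPolicy:
    """Stacked-LSTM displacement policy with hand-derived BPTT.

    Parameters per layer l: ``W{l}`` (input→gates), ``U{l}`` (hidden→gates),
    ``b{l}`` (gate bias, forget gate initialized to 1), plus a linear output head
    ``W_out``, ``b_out``.  Gate order within the 4H axis is (input, forget, cell,
    output).
    """

    def __init__(self, config: PolicyConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        H, D = config.hidden_size, config.input_dim
        self.params: dict[str, np.ndarray] = {}
        for l in range(config.n_layers):
            d_in = D if l == 0 else H
            s_in = 1.0 / np.sqrt(d_in)
            s_h = 1.0 / np.sqrt(H)
            self.params[f"W{l}"] = rng.uniform(-s_in, s_in, (d_in, 4 * H))
            self.params[f"U{l}"] = rng.uniform(-s_h, s_h, (H, 4 * H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias keeps early memory
            self.params[f"b{l}"] = b
        self.params["W_out"] = rng.uniform(-0.01, 0.01, (H, config.output_dim))
        self.params["b_out"] = np.zeros(config.output_dim)
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # ------------------------------------------------------------------
    # forward
    # ------------------------------------------------------------------
    def init_state(self, batch: int) -> list[tuple[np.ndarray, np.ndarray]]:
        H = self.config.hidden_size
        return [(np.zeros((batch, H)), np.zeros((batch, H)))
                for _ in range(self.config.n_layers)]

    def _cell(self, l: int, x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray):
        H = self.config.hidden_size
        z = x @ self.params[f"W{l}"] + h_prev @ self.params[f"U{l}"] + self.params[f"b{l}"]
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c = f * c_prev + i * g
        tc = np.tanh(c)
        h = o * tc
        return h, c, (x, h_prev, c_prev, i, f, g, o, c, tc)

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        """X: (B, T, D) raw-unit inputs → predictions (B, T, out_dim) + cache."""
        B, T, _ = X.shape
        Xs = X / _INPUT_SCALE
        state = self.init_state(B)
        caches: list[list] = []
        Y = np.empty((B, T, self.config.output_dim))
        for t in range(T):
            inp = Xs[:, t]
            step_cache = []
            for l in range(self.config.n_layers):
                h_prev, c_prev = state[l]
                h, c, cache = self._cell(l, inp, h_prev, c_prev)
                state[l] = (h, c)
                step_cache.append(cache)
                inp = h
            Y[:, t] = inp @ self.params["W_out"] + self.params["b_out"]
            caches.append(step_cache)
        return Y, caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0]

    def step(self, x: np.ndarray, state: list) -> tuple[np.ndarray, list]:
        """One incremental frame (rollout); ``x`` is (D,) or (B, D)."""
        x = np.atleast_2d(x) / _INPUT_SCALE
        inp = x
        new_state = []
        for l in range(self.config.n_layers):
            h_prev, c_prev = state[l]
            h, c, _ = self._cell(l, inp, h_prev, c_prev)
            new_state.append((h, c))
            inp = h
        y = inp @ self.params["W_out"] + self.params["b_out"]
        return y, new_state

    # ------------------------------------------------------------------
    # backward (BPTT)
    # ------------------------------------------------------------------
    def backward(self, caches: list, dY: np.ndarray) -> dict[str, np.ndarray]:
        cfg = self.config
        H, L = cfg.hidden_size, cfg.n_layers
        B, T, _ = dY.shape
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        dh_next = [np.zeros((B, H)) for _ in range(L)]
        dc_next = [np.zeros((B, H)) for _ in range(L)]
        for t in range(T - 1, -1, -1):
            # output head: top-layer hidden is caches[t][-1][7]-derived h = o*tc
            x_top = caches[t][L - 1]
            h_top = x_top[6] * x_top[8]  # o * tanh(c)
            grads["W_out"] += h_top.T @ dY[:, t]
            grads["b_out"] += dY[:, t].sum(axis=0)
            d_from_above = dY[:, t] @ self.params["W_out"].T
            for l in range(L - 1, -1, -1):
                x, h_prev, c_prev, i, f, g, o, c, tc = caches[t][l]
                dh = d_from_above + dh_next[l]
                do = dh * tc
                dc = dh * o * (1.0 - tc ** 2) + dc_next[l]
                di = dc * g
                dg = dc * i
                df = dc * c_prev
                dc_next[l] = dc * f
                dz = np.concatenate([
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g ** 2),
                    do * o * (1.0 - o),
                ], axis=1)
                grads[f"W{l}"] += x.T @ dz
                grads[f"U{l}"] += h_prev.T @ dz
                grads[f"b{l}"] += dz.sum(axis=0)
                dh_next[l] = dz @ self.params[f"U{l}"].T
                d_from_above = dz @ self.params[f"W{l}"].T  # to layer below
        return grads

    def loss_and_grads(self, X: np.ndarray, targets: np.ndarray,
                       mask: np.ndarray | None = None):
        """Mean-squared one-step displacement loss and its parameter gradients.

        ``mask`` (B, T) optionally excludes padded frames from the loss.
        """
        Y, caches = self.forward(X)
        diff = Y - targets
        if mask is not None:
            diff = diff * mask[:, :, None]
            denom = max(float(mask.sum()) * Y.shape[2], 1.0)
        else:
            denom = float(Y.size)
        loss = float(np.sum(diff ** 2) / denom)
        dY = 2.0 * diff / denom
        return loss, self.backward(caches, dY)

    # ------------------------------------------------------------------
    # optimizer
    # ------------------------------------------------------------------
    def adam_step(self, grads: dict[str, np.ndarray],
                  beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self._adam_t += 1
        lr = self.config.learning_rate
        t = self._adam_t
        for k, g in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * g
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * g ** 2
            mhat = m / (1 - beta1 ** t)
            vhat = v / (1 - beta2 ** t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit_windows(self, inputs: list[np.ndarray], targets: list[np.ndarray],
                    epochs: int = 20, batch_size: int = 64,
                    seed: int | None = None) -> list[float]:
        """Train on variable-length windows; returns the per-epoch mean loss.

        Windows are zero-padded to a common length per batch with a loss mask, so
        short trailing windows train alongside full-length ones.
        """
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        n = len(inputs)
        if n == 0:
            raise ValueError("no training windows")
        losses = []
        for _ in range(epochs):
            order = rng.permutation(n)
            epoch_loss, n_batches = 0.0, 0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                T_max = max(inputs[i].shape[0] for i in idx)
                B = len(idx)
                X = np.zeros((B, T_max, self.config.input_dim))
                Tg = np.zeros((B, T_max, self.config.output_dim))
                mask = np.zeros((B, T_max))
                for bi, i in enumerate(idx):
                    L = inputs[i].shape[0]
                    X[bi, :L] = inputs[i]
                    Tg[bi, :L] = targets[i]
                    mask[bi, :L] = 1.0
                loss, grads = self.loss_and_grads(X, Tg, mask)
                self.adam_step(grads)
                epoch_loss += loss
                n_batches += 1
            losses.append(epoch_loss / n_batches)
        return losses

    # ------------------------------------------------------------------
    # introspection / persistence
    # ------------------------------------------------------------------
    def reset_optimizer(self) -> None:
        """Clear Adam moments (fresh optimizer for a refit on new data)."""
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for k in sorted(self.params):
            h.update(k.encode())
            h.update(np.ascontiguousarray(self.params[k]).tobytes())
        return h.hexdigest()

    def clone(self) -> "LSTMPolicy":
        other = LSTMPolicy(self.config)
        other.params = {k: v.copy() for k, v in self.params.items()}
        other._adam_m = {k: v.copy() for k, v in self._adam_m.items()}
        other._adam_v = {k: v.copy() for k, v in self._adam_v.items()}
        other._adam_t = self._adam_t
        return other
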
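"""Attention-augmented recurrent SCNN (Ra-SCNN).

The SCNN's spatial/temporal front-end produces a feature sequence
``f`` of shape (T', J).  An LSTM consumes, at each step t, not the raw
feature vector at t but a *soft-attention* summary of the entire sequence:
a scoring network ``a`` (a feed-forward stack shared across positions) maps
``[f_t' ; h_{t-1}]`` to one score per feature, the scores are softmax
normalized over positions, and the step input is the attention-weighted sum
of the whole sequence per feature.  The classifier head consumes either the
full LSTM output sequence or the last state.

The front-end is trained jointly with the recurrent stage — never frozen —
and recurrent weights carry no L2 penalty.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import softmax as _np_softmax

from .autodiff import Tensor, stack
from .scnn import SCNN, SCNNConfig, _apply_activation, plan_shapes

__all__ = [
    "RaSCNNConfig",
    "RaSCNN",
    "attention_weights",
    "attention_apply",
]


# ---------------------------------------------------------------------------
# Soft attention as plain array operations (the model uses the same math on
# the autodiff tape).


def attention_weights(scores) -> np.ndarray:
    """Softmax-normalize attention scores over the last (position) axis.

    Computed stably (max subtraction); every row sums to 1 and lies in [0,1].
    """
    scores = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("attention scores must be finite")
    return _np_softmax(scores, axis=-1)


def attention_apply(features, alpha) -> np.ndarray:
    """Attention-weighted feature summary.

    features : (T, J) sequence; alpha : weights over positions, shape
    (..., T) (per feature row or a single shared row).  Returns the weighted
    sum over the whole sequence: f_hat[..., j] = sum_i features[i, j] *
    alpha[..., i]; with a 1-D alpha of length T the result is (J,).
    """
    features = np.asarray(features, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if features.ndim != 2 or alpha.shape[-1] != features.shape[0]:
        raise ValueError(
            f"shape mismatch: features {features.shape}, alpha {alpha.shape}"
        )
    out = alpha @ features  # (..., J)
    if alpha.ndim >= 2 and alpha.shape[-2] == features.shape[1]:
        # per-feature weight rows: take the diagonal (row j weights feature j)
        out = np.einsum("...jj->...j", out)
    return np.squeeze(out) if alpha.ndim == 1 else out


@dataclass(frozen=True)
class RaSCNNConfig:
    """Ra-SCNN hyperparameterization.

    front_end: SCNN config whose dense stage is ignored (conv stages only).
    hidden_units: LSTM state size; the scoring network's layers are the same
    width.  attention_layers: depth of the scoring network.
    """

    front_end: SCNNConfig = SCNNConfig()
    hidden_units: int = 16
    attention_layers: int = 1
    use_full_sequence: bool = False
    dense_layers: tuple = ()
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if self.attention_layers < 1:
            raise ValueError("attention_layers must be >= 1")
        object.__setattr__(self, "dense_layers", tuple(self.dense_layers))
        if isinstance(self.front_end, dict):
            object.__setattr__(self, "front_end", SCNNConfig(**self.front_end))

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "RaSCNNConfig":
        return cls(**json.loads(s))


class RaSCNN:
    """A built Ra-SCNN for a fixed input geometry."""

    def __init__(self, cfg: RaSCNNConfig, T: int, C: int):
        self.cfg = cfg
        self.T, self.C = T, C
        self.front = SCNN(cfg.front_end, T, C)
        self.seq_len, self.n_feat = self.front.plan.feature_shape
        H, J = cfg.hidden_units, self.n_feat
        rng = np.random.default_rng(cfg.seed)

        def init(shape, fan_in):
            return Tensor(rng.normal(0.0, np.sqrt(1.0 / fan_in), size=shape), requires_grad=True)

        # scoring network a(): [f_t' ; h_{t-1}] -> one score per feature
        self.attn_w, self.attn_b = [], []
        width = J + H
        for _ in range(cfg.attention_layers):
            self.attn_w.append(init((width, H), width))
            self.attn_b.append(Tensor(np.zeros(H), requires_grad=True))
            width = H
        self.attn_out = init((width, J), width)

        # LSTM gates (input, forget, cell, output) stacked along columns
        self.w_x = init((J, 4 * H), J)
        self.w_h = init((H, 4 * H), H)
        b = np.zeros(4 * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        self.b_g = Tensor(b, requires_grad=True)

        head_in = self.seq_len * H if cfg.use_full_sequence else H
        self.dense_w, self.dense_b = [], []
        width = head_in
        for w_out in cfg.dense_layers:
            self.dense_w.append(init((width, w_out), width))
            self.dense_b.append(Tensor(np.zeros(w_out), requires_grad=True))
            width = w_out
        self.out_w = init((width, cfg.n_classes), width)
        self.out_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)

    # -- parameters ------------------------------------------------------------
    def parameters(self):
        return (
            self.front.parameters()
            + self.attn_w
            + self.attn_b
            + [self.attn_out, self.w_x, self.w_h, self.b_g]
            + self.dense_w
            + self.dense_b
            + [self.out_w, self.out_b]
        )

    def regularized_parameters(self):
        """L2-penalized weights; recurrent (LSTM) weights are excluded."""
        return (
            self.front.regularized_parameters()
            + self.attn_w
            + [self.attn_out]
            + self.dense_w
            + [self.out_w]
        )

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ---------------------------------------------------------------
    def _scores(self, feats: Tensor, h_prev: Tensor) -> Tensor:
        """a([f_t' ; h_{t-1}]) for every position t': (n, T', J) scores."""
        n, Tp, J = feats.shape
        H = self.cfg.hidden_units
        # broadcast h_prev across positions without a concat op:
        # first layer: [f ; h] @ W == f @ W_f + h @ W_h
        w0 = self.attn_w[0]
        z = feats.contract(w0[:J], 1) + (h_prev @ w0[J:]).reshape(n, 1, H) + self.attn_b[0]
        z = z.tanh()
        for w, b in zip(self.attn_w[1:], self.attn_b[1:]):
            z = (z.contract(w, 1) + b).tanh()
        return z.contract(self.attn_out, 1)  # (n, T', J)

    def _trunk(self, x, train: bool) -> Tensor:
        """Everything up to (not including) the output layer."""
        feats = self.front.feature_sequence(x, train)  # (n, T', J)
        n = feats.shape[0]
        H = self.cfg.hidden_units
        h = Tensor(np.zeros((n, H)))
        c = Tensor(np.zeros((n, H)))
        feats_t = feats.transpose((0, 2, 1))  # (n, J, T')
        outputs = []
        for _t in range(self.seq_len):
            e = self._scores(feats, h)  # (n, T', J)
            alpha = e.transpose((0, 2, 1)).softmax(axis=-1)  # (n, J, T')
            # x_in[b, j] = sum_i alpha[b, j, i] * feats[b, i, j]
            x_in = (alpha * feats_t).sum(axis=-1)  # (n, J)
            gates = x_in @ self.w_x + h @ self.w_h + self.b_g
            i_g = gates[:, :H].sigmoid()
            f_g = gates[:, H : 2 * H].sigmoid()
            g_g = gates[:, 2 * H : 3 * H].tanh()
            o_g = gates[:, 3 * H :].sigmoid()
            c = f_g * c + i_g * g_g
            h = o_g * c.tanh()
            outputs.append(h)
        if self.cfg.use_full_sequence:
            z = stack(outputs, axis=1).reshape(n, self.seq_len * H)
        else:
            z = h
        for w, b in zip(self.dense_w, self.dense_b):
            z = _apply_activation("selu", z @ w + b)
        return z

    def forward(self, x, train: bool = False) -> Tensor:
        return self._trunk(x, train) @ self.out_w + self.out_b

    __call__ = forward

    def predict_proba(self, x) -> np.ndarray:
        return self.forward(x).softmax(axis=-1).data

    def features(self, x) -> np.ndarray:
        """Penultimate-stage features (pre-output, evaluation mode)."""
        return self._trunk(x, False).data
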
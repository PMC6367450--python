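"""Spatial-summary convolutional network (SCNN).

The architecture factorizes channel mixing and temporal filtering: a stack of
non-linear *spatial* convolutions slides across the channel axis at each time
point (sharing weights across time) and progressively collapses the channel
axis to a set of learned spatial components; *temporal* convolutions then act
as a learned filter bank over each component sequence; optional average
pooling low-passes and shrinks the feature sequence; a fully connected stage
classifies the flattened features.

A spatial layer with kernels of ``taps`` taps maps ``P`` channel positions to
``P - taps + 1`` ("valid" convolution, no padding); the final spatial layer
must land on exactly one position.  Convolutions carry no bias terms —
batch normalization, applied after each activation, makes them redundant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Tensor

__all__ = [
    "SCNNConfig",
    "ShapePlan",
    "ConfigError",
    "activation",
    "plan_shapes",
    "SCNN",
]

ACTIVATIONS = ("relu", "elu", "selu", "identity")


class ConfigError(ValueError):
    """Invalid architecture configuration."""


def _apply_activation(name: str, x: Tensor) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "elu":
        return x.elu()
    if name == "selu":
        return x.selu()
    if name == "identity":
        return x
    raise ConfigError(f"unknown activation {name!r}; expected one of {ACTIVATIONS}")


def activation(name: str, x):
    """Elementwise activation by name (ReLU / ELU / SELU) on a numpy array."""
    name = name.lower()
    out = _apply_activation(name, Tensor(np.asarray(x, dtype=np.float64)))
    return out.data


@dataclass(frozen=True)
class SCNNConfig:
    """Complete SCNN hyperparameterization.

    spatial_layers: list of (kernel_taps, n_kernels); each layer reduces the
    channel-position axis by taps - 1, and the stack must collapse it to 1.
    pool_width 0 disables pooling; pool_mode 'avg' (default) or 'max'.
    """

    spatial_layers: tuple = ((2, 4),)
    temporal_filters: int = 8
    temporal_kernel_taps: int = 9
    pool_width: int = 0
    pool_mode: str = "avg"
    activation: str = "selu"
    dense_layers: tuple = ()
    dropout_rate: float = 0.0
    spatial_dropout_rate: float = 0.0
    l2_penalty: float = 0.0
    batch_norm: bool = True
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "spatial_layers", tuple(tuple(l) for l in self.spatial_layers))
        object.__setattr__(self, "dense_layers", tuple(self.dense_layers))
        if self.activation.lower() not in ACTIVATIONS:
            raise ConfigError(f"unknown activation {self.activation!r}")
        for r, nm in ((self.dropout_rate, "dropout_rate"), (self.spatial_dropout_rate, "spatial_dropout_rate")):
            if not (0 <= r < 1):
                raise ConfigError(f"{nm} must be in [0, 1)")
        if self.l2_penalty < 0:
            raise ConfigError("l2_penalty must be >= 0")
        if self.temporal_filters < 1 or self.temporal_kernel_taps < 1 or self.n_classes < 1:
            raise ConfigError("counts must be >= 1")
        if self.pool_width < 0:
            raise ConfigError("pool_width must be >= 0")
        if self.pool_mode not in ("avg", "max"):
            raise ConfigError("pool_mode must be 'avg' or 'max'")
        for i, (taps, k) in enumerate(self.spatial_layers):
            if taps < 1 or k < 1:
                raise ConfigError(f"spatial layer {i}: taps and n_kernels must be >= 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "SCNNConfig":
        return cls(**json.loads(s))


@dataclass
class ShapePlan:
    """Stage-by-stage (time, positions, kernels) bookkeeping for one config."""

    stages: list  # (name, time_len, positions, kernels)
    param_count: int

    @property
    def feature_shape(self):
        """(time, kernels) of the sequence entering the dense / recurrent head."""
        for name, t, p, k in reversed(self.stages):
            if name.startswith(("pool", "temporal", "spatial")):
                return (t, k)
        raise ValueError("no feature stage")  # pragma: no cover


def plan_shapes(cfg: SCNNConfig, T: int, C: int) -> ShapePlan:
    """Validate ``cfg`` against an input of T samples x C channels.

    Rejects spatial stacks that do not collapse the channel axis to exactly
    one position.  The returned parameter count equals the number of
    trainable scalars of the built model.
    """
    stages = [("input", T, C, 1)]
    positions, kernels, params = C, 1, 0
    for i, (taps, k) in enumerate(cfg.spatial_layers):
        new_pos = positions - taps + 1
        if new_pos < 1:
            raise ConfigError(f"spatial layer {i}: {taps} taps on {positions} positions")
        params += taps * kernels * k
        if cfg.batch_norm:
            params += 2 * k
        positions, kernels = new_pos, k
        stages.append((f"spatial{i}", T, positions, kernels))
    if positions != 1:
        raise ConfigError(
            f"spatial stack leaves {positions} positions (must collapse to 1); "
            f"offending layer index {len(cfg.spatial_layers) - 1}"
        )
    t_len = T - cfg.temporal_kernel_taps + 1
    if t_len < 1:
        raise ConfigError("temporal kernel longer than sequence")
    params += cfg.temporal_kernel_taps * kernels * cfg.temporal_filters
    if cfg.batch_norm:
        params += 2 * cfg.temporal_filters
    kernels = cfg.temporal_filters
    stages.append(("temporal", t_len, 1, kernels))
    if cfg.pool_width:
        t_len = t_len // cfg.pool_width
        if t_len < 1:
            raise ConfigError("pool_width larger than temporal output")
        stages.append((f"pool_{cfg.pool_mode}", t_len, 1, kernels))
    width = t_len * kernels
    for j, w in enumerate(cfg.dense_layers):
        params += width * w
        if cfg.batch_norm:
            params += 2 * w
        width = w
        stages.append((f"dense{j}", 1, 1, w))
    params += width * cfg.n_classes + cfg.n_classes
    stages.append(("output", 1, 1, cfg.n_classes))
    return ShapePlan(stages, params)


class _BatchNorm:
    """Normalize over all axes but the last; scale/shift per feature."""

    def __init__(self, n_feat: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_feat), requires_grad=True)
        self.beta = Tensor(np.zeros(n_feat), requires_grad=True)
        self.running_mean = np.zeros(n_feat)
        self.running_var = np.ones(n_feat)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=axes, keepdims=True)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mu.data.ravel()
            )
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var.data.ravel()
            )
            xn = (x - mu) / (var + self.eps) ** 0.5
        else:
            xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return xn * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class SCNN:
    """A built SCNN for a fixed input geometry (T samples x C channels)."""

    def __init__(self, cfg: SCNNConfig, T: int, C: int):
        self.cfg = cfg
        self.T, self.C = T, C
        self.plan = plan_shapes(cfg, T, C)
        rng = np.random.default_rng(cfg.seed)
        gain = 2.0 if cfg.activation == "relu" else 1.0

        self.spatial_w, self.spatial_bn = [], []
        in_k = 1
        for taps, k in cfg.spatial_layers:
            fan_in = taps * in_k
            w = rng.normal(0.0, np.sqrt(gain / fan_in), size=(taps, in_k, k))
            self.spatial_w.append(Tensor(w, requires_grad=True))
            self.spatial_bn.append(_BatchNorm(k) if cfg.batch_norm else None)
            in_k = k
        fan_in = cfg.temporal_kernel_taps * in_k
        self.temporal_w = Tensor(
            rng.normal(0.0, np.sqrt(gain / fan_in), size=(cfg.temporal_kernel_taps, in_k, cfg.temporal_filters)),
            requires_grad=True,
        )
        self.temporal_bn = _BatchNorm(cfg.temporal_filters) if cfg.batch_norm else None

        t_len, kernels = self.plan.feature_shape
        width = t_len * kernels
        self.dense_w, self.dense_bn = [], []
        for w_out in cfg.dense_layers:
            self.dense_w.append(
                Tensor(rng.normal(0.0, np.sqrt(gain / width), size=(width, w_out)), requires_grad=True)
            )
            self.dense_bn.append(_BatchNorm(w_out) if cfg.batch_norm else None)
            width = w_out
        self.out_w = Tensor(
            rng.normal(0.0, np.sqrt(1.0 / width), size=(width, cfg.n_classes)), requires_grad=True
        )
        self.out_b = Tensor(np.zeros(cfg.n_classes), requires_grad=True)
        self._rng = np.random.default_rng(cfg.seed + 1)

    # -- parameter access ------------------------------------------------------
    def parameters(self):
        ps = list(self.spatial_w) + [self.temporal_w] + list(self.dense_w) + [self.out_w, self.out_b]
        for bn in self.spatial_bn + [self.temporal_bn] + self.dense_bn:
            if bn is not None:
                ps.extend(bn.parameters())
        return ps

    def regularized_parameters(self):
        """Weights carrying the L2 penalty (conv + dense, not norm scales)."""
        return list(self.spatial_w) + [self.temporal_w] + list(self.dense_w) + [self.out_w]

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- forward ---------------------------------------------------------------
    def spatial_output(self, x, train: bool = False) -> Tensor:
        """The spatial-summary stage: (n, T, C) -> (n, T, S)."""
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
        if x.shape[1:] != (self.T, self.C):
            raise ValueError(f"batch shape {x.shape[1:]} != model geometry ({self.T}, {self.C})")
        h = x.reshape(x.shape[0], self.T, self.C, 1)
        for w, bn in zip(self.spatial_w, self.spatial_bn):
            taps = w.shape[0]
            # windows over the position axis: (n, T, P_out, in_k, taps)
            u = h.unfold(taps, axis=2)
            # contract (in_k, taps) with kernel (taps, in_k, out_k)
            u = u.transpose((0, 1, 2, 4, 3))
            h = u.contract(w, 2)
            h = _apply_activation(self.cfg.activation, h)
            if bn is not None:
                h = bn(h, train)
            if train and self.cfg.spatial_dropout_rate > 0:
                keep = 1.0 - self.cfg.spatial_dropout_rate
                mask = (self._rng.random(h.shape[-1]) < keep) / keep
                h = h * mask
        # position axis is now length 1
        return h.reshape(h.shape[0], h.shape[1], h.shape[3])

    def feature_sequence(self, x, train: bool = False, from_spatial=None) -> Tensor:
        """Temporal filtering (+ pooling): (n, T, C) -> (n, T'', F)."""
        s = from_spatial if from_spatial is not None else self.spatial_output(x, train)
        s = s if isinstance(s, Tensor) else Tensor(np.asarray(s, dtype=np.float64))
        taps = self.cfg.temporal_kernel_taps
        u = s.unfold(taps, axis=1)  # (n, T', S, taps)
        u = u.transpose((0, 1, 3, 2))  # (n, T', taps, S)
        h = u.contract(self.temporal_w, 2)  # (n, T', F)
        h = _apply_activation(self.cfg.activation, h)
        if self.temporal_bn is not None:
            h = self.temporal_bn(h, train)
        if train and self.cfg.spatial_dropout_rate > 0:
            keep = 1.0 - self.cfg.spatial_dropout_rate
            mask = (self._rng.random(h.shape[-1]) < keep) / keep
            h = h * mask
        if self.cfg.pool_width:
            p = self.cfg.pool_width
            t_len = (h.shape[1] // p) * p
            h = h[:, :t_len]
            h = h.reshape(h.shape[0], t_len // p, p, h.shape[2])
            h = h.max(axis=2) if self.cfg.pool_mode == "max" else h.mean(axis=2)
        return h

    def head(self, feats: Tensor, train: bool = False, penultimate: bool = False) -> Tensor:
        """Dense classifier on the flattened feature sequence."""
        h = feats.reshape(feats.shape[0], int(np.prod(feats.shape[1:])))
        for w, bn in zip(self.dense_w, self.dense_bn):
            h = _apply_activation(self.cfg.activation, h @ w)
            if bn is not None:
                h = bn(h, train)
            if train and self.cfg.dropout_rate > 0:
                keep = 1.0 - self.cfg.dropout_rate
                mask = (self._rng.random(h.shape) < keep) / keep
                h = h * mask
        if penultimate:
            return h
        return h @ self.out_w + self.out_b

    def forward(self, x, train: bool = False) -> Tensor:
        """Full network: (n, T, C) -> logits (n, n_classes)."""
        return self.head(self.feature_sequence(x, train), train)

    __call__ = forward

    def predict_proba(self, x) -> np.ndarray:
        return self.forward(x).softmax(axis=-1).data

    def features(self, x) -> np.ndarray:
        """Penultimate-stage features (fixed weights, evaluation mode)."""
        return self.head(self.feature_sequence(x, False), False, penultimate=True).data

    # -- checkpointing ---------------------------------------------------------
    def state_arrays(self):
        arrs = {f"p{i}": p.data for i, p in enumerate(self.parameters())}
        j = 0
        for bn in self.spatial_bn + [self.temporal_bn] + self.dense_bn:
            if bn is not None:
                arrs[f"rm{j}"] = bn.running_mean
                arrs[f"rv{j}"] = bn.running_var
                j += 1
        return arrs

    def save(self, path: str):
        np.savez(
            path,
            __config__=np.frombuffer(self.cfg.to_json().encode(), dtype=np.uint8),
            __geometry__=np.array([self.T, self.C]),
            **self.state_arrays(),
        )

    @classmethod
    def load(cls, path: str) -> "SCNN":
        with np.load(path) as z:
            cfg = SCNNConfig.from_json(bytes(z["__config__"]).decode())
            T, C = (int(v) for v in z["__geometry__"])
            model = cls(cfg, T, C)
            for i, p in enumerate(model.parameters()):
                p.data = z[f"p{i}"].copy()
            j = 0
            for bn in model.spatial_bn + [model.temporal_bn] + model.dense_bn:
                if bn is not None:
                    bn.running_mean = z[f"rm{j}"].copy()
                    bn.running_var = z[f"rv{j}"].copy()
                    j += 1
        return model
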
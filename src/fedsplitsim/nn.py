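"""A small framework-free 1D-CNN engine, splittable at a cut layer.

The engine exists to make split learning *exactly* testable: the device-side
and server-side halves execute the very same per-layer kernels in the very
same order as the unsplit network, so composing ``split_forward_device`` /
``split_forward_server`` / ``split_backward`` reproduces the full model's
outputs and gradients bit-for-bit at every cut position.  Everything runs in
float64; gradients are plain analytic backprop, verified against central
finite differences in the test suite.

Data layout: sequence tensors are ``(batch, length, channels)``; after a
flatten layer, ``(batch, features)``.  Conv kernels are ``(kernel, in_ch,
out_ch)``; dense weights ``(in_features, units)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml
from numpy.lib.stride_tricks import sliding_window_view

from ._seeding import STREAM_INIT, child_rng
from .errors import ConfigurationError, ShapeError

ParamSet = dict[str, np.ndarray]
GradientSet = dict[str, np.ndarray]

BYTES_PER_ELEMENT = 4  # single-precision wire convention for payload sizing


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class LayerSpec:
    kind: str  # conv1d | maxpool1d | flatten | dense | softmax
    filters: int = 0
    kernel: int = 0
    pool: int = 0
    units: int = 0
    padding: str = "same"
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kind not in ("conv1d", "maxpool1d", "flatten", "dense", "softmax"):
            raise ConfigurationError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv1d" and (self.filters < 1 or self.kernel < 1):
            raise ConfigurationError("conv1d needs filters >= 1 and kernel >= 1")
        if self.kind == "maxpool1d" and self.pool < 1:
            raise ConfigurationError("maxpool1d needs pool >= 1")
        if self.kind == "dense" and self.units < 1:
            raise ConfigurationError("dense needs units >= 1")
        if self.padding not in ("same", "valid"):
            raise ConfigurationError(f"unknown padding {self.padding!r}")
        if self.activation not in ("relu", "none"):
            raise ConfigurationError(f"unknown activation {self.activation!r}")


@dataclass(frozen=True)
class ModelSpec:
    layers: tuple[LayerSpec, ...]
    input_length: int = 187
    input_channels: int = 1
    cut_layer: int = 0  # layers [0, cut) run on the device, [cut, n) on the server

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if not 0 <= self.cut_layer <= len(self.layers):
            raise ConfigurationError(
                f"cut_layer {self.cut_layer} outside [0, {len(self.layers)}]"
            )

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def with_cut(self, cut: int) -> "ModelSpec":
        return ModelSpec(self.layers, self.input_length, self.input_channels, cut)

    # -- YAML/JSON interchange ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "input_length": self.input_length,
            "input_channels": self.input_channels,
            "cut_layer": self.cut_layer,
            "layers": [
                {k: v for k, v in vars(ls).items() if v not in (0, "none") or k == "kind"}
                for ls in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            layers=tuple(LayerSpec(**ld) for ld in d["layers"]),
            input_length=d.get("input_length", 187),
            input_channels=d.get("input_channels", 1),
            cut_layer=d.get("cut_layer", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_reference_model(server_hidden_units: int = 32, n_classes: int = 2) -> ModelSpec:
    """The canonical wearable/edge model.

    Device side (cut = 4): Conv1D(16 filters, kernel 5, same, relu) ->
    MaxPool(2) -> Conv1D(32 filters, kernel 3, same, relu) -> Flatten.
    Server side: Dense(32, relu) -> Dense(2) -> Softmax.
    """
    return ModelSpec(
        layers=(
            LayerSpec("conv1d", filters=16, kernel=5, padding="same", activation="relu"),
            LayerSpec("maxpool1d", pool=2),
            LayerSpec("conv1d", filters=32, kernel=3, padding="same", activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", units=server_hidden_units, activation="relu"),
            LayerSpec("dense", units=n_classes),
            LayerSpec("softmax"),
        ),
        input_length=187,
        input_channels=1,
        cut_layer=4,
    )


# ---------------------------------------------------------------------------
# shape propagation


def output_shapes(spec: ModelSpec) -> list[tuple]:
    """Shape after each layer, excluding batch: ('seq', L, C) or ('flat', F)."""
    shape: tuple = ("seq", spec.input_length, spec.input_channels)
    out = []
    for i, ls in enumerate(spec.layers):
        if ls.kind == "conv1d":
            if shape[0] != "seq":
                raise ShapeError(f"layer {i} (conv1d) needs a sequence input")
            L = shape[1] if ls.padding == "same" else shape[1] - ls.kernel + 1
            shape = ("seq", L, ls.filters)
        elif ls.kind == "maxpool1d":
            if shape[0] != "seq":
                raise ShapeError(f"layer {i} (maxpool1d) needs a sequence input")
            shape = ("seq", shape[1] // ls.pool, shape[2])
        elif ls.kind == "flatten":
            if shape[0] == "seq":
                shape = ("flat", shape[1] * shape[2])
        elif ls.kind == "dense":
            if shape[0] != "flat":
                raise ShapeError(f"layer {i} (dense) needs a flat input")
            shape = ("flat", ls.units)
        # softmax keeps shape
        out.append(shape)
    return out


def smashed_feature_count(spec: ModelSpec) -> int:
    """Features per segment crossing the cut boundary."""
    if spec.cut_layer == 0:
        return spec.input_length * spec.input_channels
    shape = output_shapes(spec)[spec.cut_layer - 1]
    return int(np.prod(shape[1:]))


# ---------------------------------------------------------------------------
# parameters


def init_params(spec: ModelSpec, seed: int) -> ParamSet:
    """He-style fan-in uniform initialisation, biases zero, deterministic."""
    rng = child_rng(seed, STREAM_INIT)
    params: ParamSet = {}
    shape: tuple = ("seq", spec.input_length, spec.input_channels)
    for i, ls in enumerate(spec.layers):
        if ls.kind == "conv1d":
            fan_in = ls.kernel * shape[2]
            limit = np.sqrt(6.0 / fan_in)
            params[f"L{i}_W"] = rng.uniform(-limit, limit, size=(ls.kernel, shape[2], ls.filters))
            params[f"L{i}_b"] = np.zeros(ls.filters)
        elif ls.kind == "dense":
            fan_in = shape[1]
            limit = np.sqrt(6.0 / fan_in)
            params[f"L{i}_W"] = rng.uniform(-limit, limit, size=(fan_in, ls.units))
            params[f"L{i}_b"] = np.zeros(ls.units)
        shape = output_shapes(ModelSpec(spec.layers[: i + 1], spec.input_length, spec.input_channels))[-1]
    return params


def param_count(params: ParamSet) -> int:
    return int(sum(v.size for v in params.values()))


def params_payload_bytes(params: ParamSet) -> int:
    return param_count(params) * BYTES_PER_ELEMENT


def save_params(params: ParamSet, path: str | Path) -> None:
    """JSON serialisation; Python float repr round-trips float64 bit-exactly."""
    payload = {k: {"shape": list(v.shape), "data": v.ravel().tolist()} for k, v in params.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_params(path: str | Path) -> ParamSet:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        k: np.array(v["data"], dtype=np.float64).reshape(v["shape"])
        for k, v in payload.items()
    }


# ---------------------------------------------------------------------------
# per-layer kernels


def _conv_pads(kernel: int, padding: str) -> tuple[int, int]:
    if padding == "same":
        return (kernel - 1) // 2, kernel // 2
    return 0, 0


def _layer_forward(
    i: int, ls: LayerSpec, params: ParamSet, x: np.ndarray
) -> tuple[np.ndarray, dict]:
    if ls.kind == "conv1d":
        if x.ndim != 3:
            raise ShapeError(f"layer {i} (conv1d) expected (batch, length, channels), got {x.shape}")
        W, b = params[f"L{i}_W"], params[f"L{i}_b"]
        if x.shape[2] != W.shape[1]:
            raise ShapeError(f"layer {i} (conv1d): {x.shape[2]} channels, kernel expects {W.shape[1]}")
        pl, pr = _conv_pads(ls.kernel, ls.padding)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        cols = sliding_window_view(xp, ls.kernel, axis=1)  # (B, L_out, C, k)
        z = np.tensordot(cols, W, axes=([3, 2], [0, 1])) + b
        a = np.maximum(z, 0.0) if ls.activation == "relu" else z
        return a, {"cols": cols, "z": z, "pads": (pl, pr), "in_len": x.shape[1]}
    if ls.kind == "maxpool1d":
        if x.ndim != 3:
            raise ShapeError(f"layer {i} (maxpool1d) expected a sequence tensor, got {x.shape}")
        B, L, C = x.shape
        Lo = L // ls.pool
        windows = x[:, : Lo * ls.pool, :].reshape(B, Lo, ls.pool, C)
        arg = windows.argmax(axis=2)
        a = np.take_along_axis(windows, arg[:, :, None, :], axis=2)[:, :, 0, :]
        return a, {"arg": arg, "in_shape": x.shape}
    if ls.kind == "flatten":
        return x.reshape(x.shape[0], -1), {"in_shape": x.shape}
    if ls.kind == "dense":
        if x.ndim != 2:
            raise ShapeError(f"layer {i} (dense) expected (batch, features), got {x.shape}")
        W, b = params[f"L{i}_W"], params[f"L{i}_b"]
        if x.shape[1] != W.shape[0]:
            raise ShapeError(f"layer {i} (dense): {x.shape[1]} features, weights expect {W.shape[0]}")
        z = x @ W + b
        a = np.maximum(z, 0.0) if ls.activation == "relu" else z
        return a, {"x": x, "z": z}
    if ls.kind == "softmax":
        shifted = x - x.max(axis=1, keepdims=True)
        e = np.exp(shifted)
        p = e / e.sum(axis=1, keepdims=True)
        return p, {"logits": x, "p": p}
    raise ConfigurationError(f"unknown layer kind {ls.kind!r}")


def _layer_backward(
    i: int, ls: LayerSpec, params: ParamSet, cache: dict, dout: np.ndarray
) -> tuple[np.ndarray, GradientSet]:
    if ls.kind == "conv1d":
        W = params[f"L{i}_W"]
        dz = dout * (cache["z"] > 0) if ls.activation == "relu" else dout
        db = dz.sum(axis=(0, 1))
        dW = np.tensordot(cache["cols"], dz, axes=([0, 1], [0, 1])).transpose(1, 0, 2)
        dcols = np.einsum("blo,kco->blck", dz, W)
        pl, pr = cache["pads"]
        B, Lo = dz.shape[0], dz.shape[1]
        dxp = np.zeros((B, cache["in_len"] + pl + pr, W.shape[1]))
        for j in range(ls.kernel):
            dxp[:, j : j + Lo, :] += dcols[:, :, :, j]
        dx = dxp[:, pl : pl + cache["in_len"], :]
        return dx, {f"L{i}_W": dW, f"L{i}_b": db}
    if ls.kind == "maxpool1d":
        B, L, C = cache["in_shape"]
        Lo = L // ls.pool
        dwin = np.zeros((B, Lo, ls.pool, C))
        np.put_along_axis(dwin, cache["arg"][:, :, None, :], dout[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, : Lo * ls.pool, :] = dwin.reshape(B, Lo * ls.pool, C)
        return dx, {}
    if ls.kind == "flatten":
        return dout.reshape(cache["in_shape"]), {}
    if ls.kind == "dense":
        W = params[f"L{i}_W"]
        dz = dout * (cache["z"] > 0) if ls.activation == "relu" else dout
        return dz @ W.T, {f"L{i}_W": cache["x"].T @ dz, f"L{i}_b": dz.sum(axis=0)}
    if ls.kind == "softmax":
        p = cache["p"]
        return p * (dout - (dout * p).sum(axis=1, keepdims=True)), {}
    raise ConfigurationError(f"unknown layer kind {ls.kind!r}")


# ---------------------------------------------------------------------------
# forward / backward over layer ranges


@dataclass
class Tape:
    """Activation record of a forward pass over layers [start, stop)."""

    spec: ModelSpec
    start: int
    stop: int
    caches: list[dict]
    output: np.ndarray


@dataclass
class SmashedData:
    """The activation tensor crossing the cut boundary (the only training-time
    payload leaving a device in split learning)."""

    activations: np.ndarray

    @property
    def byte_size(self) -> int:
        return int(self.activations.size) * BYTES_PER_ELEMENT


def _run_layers(
    params: ParamSet, spec: ModelSpec, x: np.ndarray, start: int, stop: int
) -> Tape:
    caches = []
    for i in range(start, stop):
        x, cache = _layer_forward(i, spec.layers[i], params, x)
        caches.append(cache)
    return Tape(spec=spec, start=start, stop=stop, caches=caches, output=x)


def _as_batch(spec: ModelSpec, batch: np.ndarray) -> np.ndarray:
    batch = np.asarray(batch, dtype=np.float64)
    if batch.ndim == 2:
        batch = batch[:, :, None]
    if batch.shape[1] != spec.input_length or batch.shape[2] != spec.input_channels:
        raise ShapeError(
            f"input batch {batch.shape} incompatible with "
            f"({spec.input_length}, {spec.input_channels}) input"
        )
    return batch


def forward(params: ParamSet, spec: ModelSpec, batch: np.ndarray) -> tuple[np.ndarray, Tape]:
    """Full-model forward pass: class probabilities plus the activation tape."""
    x = _as_batch(spec, batch)
    tape = _run_layers(params, spec, x, 0, spec.n_layers)
    return tape.output, tape


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim != 1 or not np.issubdtype(labels.dtype, np.integer):
        labels = labels.astype(np.int64)
    if labels.min(initial=0) < 0 or labels.max(initial=0) >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes})")
    return labels


def cross_entropy(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-likelihood of the true class."""
    labels = _check_labels(labels, probs.shape[1])
    return float(-np.log(probs[np.arange(len(labels)), labels]).mean())


def _softmax_label_grad(tape: Tape, labels: np.ndarray) -> np.ndarray:
    """d(mean cross-entropy)/d(logits) = (p - onehot)/B at the softmax layer."""
    cache = tape.caches[-1]
    p = cache["p"]
    labels = _check_labels(labels, p.shape[1])
    d = p.copy()
    d[np.arange(len(labels)), labels] -= 1.0
    return d / len(labels)


def _backprop_range(
    params: ParamSet, tape: Tape, dout: np.ndarray, stop_at: int
) -> tuple[np.ndarray, GradientSet]:
    grads: GradientSet = {}
    d = dout
    for offset in range(tape.stop - 1, stop_at - 1, -1):
        cache = tape.caches[offset - tape.start]
        d, g = _layer_backward(offset, tape.spec.layers[offset], params, cache, d)
        grads.update(g)
    return d, grads


def backward(params: ParamSet, tape: Tape, labels: np.ndarray) -> GradientSet:
    """Gradients of the mean cross-entropy loss for a full-model tape.

    The final layer must be softmax; the softmax+cross-entropy pair is
    differentiated jointly in closed form for numerical stability.
    """
    if tape.spec.layers[tape.stop - 1].kind != "softmax":
        raise ConfigurationError("backward expects a softmax-terminated tape")
    dlogits = _softmax_label_grad(tape, labels)
    # skip the softmax layer itself: start backprop just below it
    grads: GradientSet = {}
    d = dlogits
    for offset in range(tape.stop - 2, tape.start - 1, -1):
        cache = tape.caches[offset - tape.start]
        d, g = _layer_backward(offset, tape.spec.layers[offset], params, cache, d)
        grads.update(g)
    return grads


def sgd_step(params: ParamSet, grads: GradientSet, lr: float) -> ParamSet:
    """Vanilla SGD: p <- p - lr * g (parameters without a gradient pass through)."""
    return {k: (v - lr * grads[k] if k in grads else v.copy()) for k, v in params.items()}


def predict(probs: np.ndarray) -> np.ndarray:
    """Argmax class; ties resolve to the lowest class index."""
    return probs.argmax(axis=1)


# ---------------------------------------------------------------------------
# split execution


def split_params(params: ParamSet, spec: ModelSpec) -> tuple[ParamSet, ParamSet]:
    """Partition a ParamSet into (device-side, server-side) by cut layer."""
    device = {k: v for k, v in params.items() if int(k[1 : k.index("_")]) < spec.cut_layer}
    server = {k: v for k, v in params.items() if int(k[1 : k.index("_")]) >= spec.cut_layer}
    return device, server


def split_forward_device(
    params: ParamSet, spec: ModelSpec, batch: np.ndarray
) -> tuple[SmashedData, Tape]:
    """Device half: layers [0, cut); emits smashed data at the cut boundary."""
    x = _as_batch(spec, batch)
    tape = _run_layers(params, spec, x, 0, spec.cut_layer)
    return SmashedData(activations=tape.output), tape


def split_forward_server(
    params: ParamSet, spec: ModelSpec, smashed: SmashedData
) -> tuple[np.ndarray, Tape]:
    """Server half: layers [cut, n) applied to the smashed activations."""
    tape = _run_layers(params, spec, smashed.activations, spec.cut_layer, spec.n_layers)
    return tape.output, tape


def split_backward(
    params: ParamSet,
    server_tape: Tape,
    device_tape: Tape,
    labels: np.ndarray,
) -> tuple[GradientSet, np.ndarray, GradientSet]:
    """Backward through both halves.

    Returns ``(server_grads, cut_gradient, device_grads)``.  The cut gradient
    is the loss derivative w.r.t. the smashed activations — the payload the
    server returns to the device.  Operations replay the unsplit engine's
    floating-point sequence exactly, so the concatenated gradients are
    bit-identical to :func:`backward` on the full model.
    """
    spec = server_tape.spec
    if spec.layers[-1].kind != "softmax":
        raise ConfigurationError("split_backward expects a softmax-terminated model")
    if server_tape.start == server_tape.stop:
        # degenerate cut at the very end: the device holds the whole network
        device_grads = backward(params, device_tape, labels)
        return {}, np.zeros_like(server_tape.output), device_grads
    dlogits = _softmax_label_grad(server_tape, labels)
    server_grads: GradientSet = {}
    d = dlogits
    for offset in range(server_tape.stop - 2, server_tape.start - 1, -1):
        cache = server_tape.caches[offset - server_tape.start]
        d, g = _layer_backward(offset, spec.layers[offset], params, cache, d)
        server_grads.update(g)
    cut_gradient = d
    device_grads: GradientSet = {}
    d_dev = cut_gradient
    for offset in range(device_tape.stop - 1, device_tape.start - 1, -1):
        cache = device_tape.caches[offset - device_tape.start]
        d_dev, g = _layer_backward(offset, spec.layers[offset], params, cache, d_dev)
        device_grads.update(g)
    return server_grads, cut_gradient, device_grads
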
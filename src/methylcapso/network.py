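"""Forward pass of the Con-LSTM classifier and flat-vector parameter packing.

The classifier is a single rectified valid-padding convolution over the
encoding matrix, non-overlapping max pooling along the position axis, a
single-layer LSTM over the pooled feature columns, and an affine-sigmoid
head on the final hidden state.  There is no gradient training: the whole
parameter set round-trips to one flat vector that a gradient-free swarm
optimizer explores.

All nonlinearities are evaluated in numerically stable form with
pre-activation clipping at +-50, so the forward pass stays finite for the
unbounded weight vectors an optimizer may propose.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .encodings import CHANNELS

__all__ = [
    "GATE_ORDER",
    "ConvParams",
    "LstmParams",
    "HeadParams",
    "LstmState",
    "NetworkConfig",
    "conv_forward",
    "pool_forward",
    "lstm_step",
    "lstm_forward",
    "predict_proba",
    "forward_batch",
    "pack_parameters",
    "unpack_parameters",
    "parameter_count",
]

GATE_ORDER = ("forget", "input", "cell", "output")

_CLIP = 50.0


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Logistic function with pre-activation clipping for overflow safety."""
    return 1.0 / (1.0 + np.exp(-np.clip(z, -_CLIP, _CLIP)))


def tanh(z: np.ndarray | float) -> np.ndarray | float:
    return np.tanh(np.clip(z, -_CLIP, _CLIP))


@dataclass(frozen=True)
class ConvParams:
    """K convolution kernels of shape (input_channels, width) plus K biases."""

    kernels: np.ndarray  # (K, channels, width)
    biases: np.ndarray  # (K,)

    def __post_init__(self) -> None:
        kernels = np.asarray(self.kernels, dtype=float)
        biases = np.asarray(self.biases, dtype=float)
        object.__setattr__(self, "kernels", kernels)
        object.__setattr__(self, "biases", biases)
        if kernels.ndim != 3:
            raise ValueError("kernels must have shape (K, channels, width)")
        if biases.shape != (kernels.shape[0],):
            raise ValueError("need one bias per kernel")


@dataclass(frozen=True)
class LstmParams:
    """Per-gate weight triples (W, U, b) for forget/input/cell/output gates.

    W maps the feature vector (hidden x feature), U the previous hidden state
    (hidden x hidden), b is the bias (hidden,).
    """

    gates: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if tuple(self.gates) != GATE_ORDER:
            raise ValueError(f"gates must be exactly {GATE_ORDER} in order")
        shapes = {g: tuple(a.shape for a in triple) for g, triple in self.gates.items()}
        ref = shapes[GATE_ORDER[0]]
        if any(s != ref for s in shapes.values()):
            raise ValueError(f"all gates must share shapes, got {shapes}")
        w, u, b = self.gates[GATE_ORDER[0]]
        h = b.shape[0]
        if w.shape[0] != h or u.shape != (h, h):
            raise ValueError("inconsistent hidden dimension across W, U, b")

    @property
    def hidden_size(self) -> int:
        return self.gates["forget"][2].shape[0]

    @property
    def feature_size(self) -> int:
        return self.gates["forget"][0].shape[1]


@dataclass(frozen=True)
class HeadParams:
    """Affine-sigmoid classification head on the final hidden state."""

    weights: np.ndarray  # (hidden,)
    bias: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.weights.ndim != 1:
            raise ValueError("head weights must be a vector")


@dataclass(frozen=True)
class LstmState:
    """Hidden state h (componentwise in (-1, 1)) and cell state C."""

    h: np.ndarray
    C: np.ndarray


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture of the Con-LSTM classifier.

    Defaults (4 kernels of width 3, pool width 4, hidden size 8, threshold
    0.5) keep the packed parameter vector at 633 entries for the 17-channel
    fused encoding, a dimension gradient-free swarm search still handles.
    """

    scheme: str = "code9"
    n_kernels: int = 4
    kernel_width: int = 3
    pool_width: int = 4
    hidden_size: int = 8
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in CHANNELS:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in ("n_kernels", "kernel_width", "pool_width", "hidden_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def n_channels(self) -> int:
        return CHANNELS[self.scheme]


# ---------------------------------------------------------------------------
# forward pass


def conv_forward(
    encoding: np.ndarray, params: ConvParams, rectify: bool = True
) -> np.ndarray:
    """Valid cross-correlation at stride 1 with optional rectification.

    ``encoding`` is (channels, L); the result is (K, L - width + 1) with
    out[k, j] = sum_{c,u} kernel_k[c, u] * encoding[c, j + u] + bias_k,
    passed through max(0, .) unless ``rectify`` is False.
    """
    out = _conv_batch(np.asarray(encoding, dtype=float)[None], params, rectify)
    return out[0]


def _conv_batch(X: np.ndarray, params: ConvParams, rectify: bool = True) -> np.ndarray:
    K, C, width = params.kernels.shape
    n, channels, L = X.shape
    if channels != C:
        raise ValueError(f"encoding has {channels} channels, kernels expect {C}")
    if width > L:
        raise ValueError(f"kernel width {width} exceeds sequence length {L}")
    windows = np.lib.stride_tricks.sliding_window_view(X, width, axis=2)
    out = np.einsum("ncjw,kcw->nkj", windows, params.kernels) + params.biases[None, :, None]
    return np.maximum(out, 0.0) if rectify else out


def pool_forward(features: np.ndarray, pool_width: int) -> np.ndarray:
    """Non-overlapping max pooling along the position axis.

    A trailing window shorter than ``pool_width`` is pooled as-is.  Works on
    (..., T) arrays.
    """
    if pool_width < 1:
        raise ValueError("pool_width must be >= 1")
    features = np.asarray(features, dtype=float)
    T = features.shape[-1]
    starts = range(0, T, pool_width)
    blocks = [features[..., s : s + pool_width].max(axis=-1) for s in starts]
    return np.stack(blocks, axis=-1)


def lstm_step(x_t: np.ndarray, state: LstmState, params: LstmParams) -> LstmState:
    """One LSTM recurrence step.

    f = sigma(W_f x + U_f h + b_f), i = sigma(W_i x + U_i h + b_i),
    C' = tanh(W_c x + U_c h + b_c), C_t = f*C + i*C',
    o = sigma(W_o x + U_o h + b_o), h_t = o * tanh(C_t).
    """
    x_t = np.asarray(x_t, dtype=float)
    wf, uf, bf = params.gates["forget"]
    wi, ui, bi = params.gates["input"]
    wc, uc, bc = params.gates["cell"]
    wo, uo, bo = params.gates["output"]
    if x_t.shape[-1] != wf.shape[1]:
        raise ValueError(f"feature size {x_t.shape[-1]} != expected {wf.shape[1]}")
    h, C = state.h, state.C
    f = sigmoid(x_t @ wf.T + h @ uf.T + bf)
    i = sigmoid(x_t @ wi.T + h @ ui.T + bi)
    c_new = tanh(x_t @ wc.T + h @ uc.T + bc)
    C_t = f * C + i * c_new
    o = sigmoid(x_t @ wo.T + h @ uo.T + bo)
    return LstmState(h=o * tanh(C_t), C=C_t)


def lstm_forward(features: np.ndarray, params: LstmParams) -> LstmState:
    """Iterate lstm_step over feature columns (feature x T) from the zero state."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] == 0:
        raise ValueError("feature matrix must be (feature, T) with T >= 1")
    H = params.hidden_size
    state = LstmState(h=np.zeros(H), C=np.zeros(H))
    for t in range(features.shape[1]):
        state = lstm_step(features[:, t], state, params)
    return state


def predict_proba(state: LstmState, head: HeadParams) -> float:
    """Sigmoid of the affine head applied to the final hidden state."""
    if state.h.shape[-1] != head.weights.shape[0]:
        raise ValueError("head dimension does not match hidden state")
    return float(sigmoid(state.h @ head.weights + head.bias))


def forward_batch(
    X: np.ndarray,
    conv: ConvParams,
    lstm: LstmParams,
    head: HeadParams,
    pool_width: int,
) -> np.ndarray:
    """Probabilities for a batch of encoding matrices, shape (n, channels, L).

    Identical arithmetic to the per-record path (conv_forward, pool_forward,
    lstm_forward, predict_proba) vectorized over the batch axis.
    """
    feats = pool_forward(_conv_batch(X, conv), pool_width)  # (n, K, T)
    n, _, T = feats.shape
    H = lstm.hidden_size
    wf, uf, bf = lstm.gates["forget"]
    wi, ui, bi = lstm.gates["input"]
    wc, uc, bc = lstm.gates["cell"]
    wo, uo, bo = lstm.gates["output"]
    h = np.zeros((n, H))
    C = np.zeros((n, H))
    for t in range(T):
        x_t = feats[:, :, t]
        f = sigmoid(x_t @ wf.T + h @ uf.T + bf)
        i = sigmoid(x_t @ wi.T + h @ ui.T + bi)
        c_new = tanh(x_t @ wc.T + h @ uc.T + bc)
        C = f * C + i * c_new
        h = sigmoid(x_t @ wo.T + h @ uo.T + bo) * tanh(C)
    return sigmoid(h @ head.weights + head.bias)


# ---------------------------------------------------------------------------
# parameter packing


def parameter_count(config: NetworkConfig) -> int:
    """Length of the flat parameter vector implied by the architecture."""
    C, K, w, H = config.n_channels, config.n_kernels, config.kernel_width, config.hidden_size
    F = K  # LSTM feature size equals the number of conv kernels
    return K * C * w + K + 4 * (H * F + H * H + H) + H + 1


def pack_parameters(conv: ConvParams, lstm: LstmParams, head: HeadParams) -> np.ndarray:
    """Flatten parameters: conv kernels, conv biases, then per-gate W, U, b in
    forget/input/cell/output order, then head weights and bias."""
    pieces = [conv.kernels.ravel(), conv.biases.ravel()]
    for gate in GATE_ORDER:
        w, u, b = lstm.gates[gate]
        pieces += [w.ravel(), u.ravel(), b.ravel()]
    pieces += [head.weights.ravel(), np.array([head.bias])]
    return np.concatenate(pieces)


def unpack_parameters(
    vector: np.ndarray, config: NetworkConfig
) -> tuple[ConvParams, LstmParams, HeadParams]:
    """Inverse of :func:`pack_parameters` for the given architecture."""
    vector = np.asarray(vector, dtype=float)
    expected = parameter_count(config)
    if vector.shape != (expected,):
        raise ValueError(f"expected a vector of length {expected}, got {vector.shape}")
    C, K, w, H = config.n_channels, config.n_kernels, config.kernel_width, config.hidden_size
    F = K
    pos = 0

    def take(shape: tuple[int, ...]) -> np.ndarray:
        nonlocal pos
        size = int(np.prod(shape))
        block = vector[pos : pos + size].reshape(shape)
        pos += size
        return block

    conv = ConvParams(kernels=take((K, C, w)), biases=take((K,)))
    gates = {g: (take((H, F)), take((H, H)), take((H,))) for g in GATE_ORDER}
    head = HeadParams(weights=take((H,)), bias=float(take((1,))[0]))
    return conv, LstmParams(gates=gates), head
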
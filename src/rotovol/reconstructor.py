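"""Volumetric regression network: 3-D CNN from rotation stacks to z-stacks.

The network maps a temporal ROI stack (H×W×D, default 100×100×10 — ten
ROI frames sampled over one rotation period) to a confocal-like volume of
the same spatial shape.  Architecture: a ladder of 3×3×3 convolutions with
stride 1 and 'same' zero padding (default filter counts 64, 32, 16, 8, 4),
each followed by an elementwise ReLU, closed by a 1×1×1 convolution to a
single channel; training minimizes voxelwise mean squared error with Adam.

Every layer is implemented directly in NumPy: the convolution is the plain
cross-correlation sum

    Z[i,j,k,o] = sum_{l,m,n,c} W[l,m,n,c,o] * Xpad[i+l, j+m, k+n, c] + b[o]

evaluated by sliding-window tensor contraction, and the backward pass uses
the analytic gradients (transposed-kernel convolution for dX, a window/
output contraction for dW).  'same' padding is required: with valid padding
a 10-deep input would lose its depth axis before the fifth layer.

Zero padding with stride 1 keeps spatial shape constant, so the ladder can be
shortened or widened freely via ``NetworkConfig.layer_filters``; small
ladders train in minutes on a CPU while preserving the architecture family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DivergenceError
from .preprocess import ROIStack, VolumeStack

_KERNEL = (3, 3, 3)


@dataclass
class ConvLayerSpec:
    """One 3-D convolutional layer: 3×3×3 kernel, stride 1, 'same' padding.

    ``weights`` has shape (3, 3, 3, c_in, n_filters) — or (1, 1, 1, c_in,
    n_filters) for the channel-projection layer — and ``bias`` shape
    (n_filters,).
    """

    n_filters: int
    weights: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights)
        if not np.issubdtype(w.dtype, np.floating):
            w = w.astype(np.float64)
        if w.ndim != 5 or w.shape[4] != self.n_filters:
            raise ValueError("weights must be (L, M, N, c_in, n_filters)")
        if w.shape[:3] not in (_KERNEL, (1, 1, 1)):
            raise ValueError("kernel must be 3x3x3 (or 1x1x1 for projection)")
        b = np.asarray(self.bias, dtype=w.dtype)
        if b.shape != (self.n_filters,):
            raise ValueError("bias must have one entry per filter")
        self.weights = w
        self.bias = b

    @property
    def c_in(self) -> int:
        return self.weights.shape[3]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyperparameters of the regression network."""

    input_shape: tuple[int, int, int] = (100, 100, 10)
    layer_filters: tuple[int, ...] = (64, 32, 16, 8, 4)
    projection_to_one_channel: bool = True
    epochs: int = 1000
    learning_rate: float = 1e-3
    seed: int = 0
    loss: str = "mse"

    def __post_init__(self):
        if len(self.layer_filters) == 0:
            raise ValueError("layer_filters must be nonempty")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "mse":
            raise ValueError("only the mse loss is implemented")


@dataclass(frozen=True)
class TrainingHistory:
    """Per-epoch loss (MSE) and RMSE, both finite and nonnegative."""

    loss: tuple[float, ...]
    rmse: tuple[float, ...]

    def __post_init__(self):
        if len(self.loss) != len(self.rmse):
            raise ValueError("loss and rmse must have equal lengths")
        arr = np.asarray(self.loss + self.rmse, dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("history values must be finite and >= 0")


def _as_channels(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x)
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(np.float64)
    if x.ndim == 3:
        x = x[..., None]
    if x.ndim != 4:
        raise ValueError("input must be (H, W, D) or (H, W, D, C)")
    return x


def conv3d(x: np.ndarray, layer: ConvLayerSpec) -> np.ndarray:
    """'Same'-padded stride-1 3-D convolution (cross-correlation form).

    ``x`` is (H, W, D) or (H, W, D, C); the result is (H, W, D, n_filters).
    The sum over kernel taps is evaluated as 27 shifted-slice channel
    matmuls, which avoids materializing a sliding-window buffer.
    """
    x = _as_channels(x)
    kl, km, kn = layer.weights.shape[:3]
    if x.shape[3] != layer.c_in:
        raise ValueError(
            f"layer expects {layer.c_in} input channels, got {x.shape[3]}"
        )
    if kl == 1:  # 1x1x1 projection: plain channel matmul
        return x @ layer.weights[0, 0, 0] + layer.bias
    pad = ((kl // 2,) * 2, (km // 2,) * 2, (kn // 2,) * 2, (0, 0))
    xp = np.pad(x, pad)
    H, W, D, c_in = x.shape
    dtype = np.result_type(x, layer.weights)
    out = np.zeros((H * W * D, layer.n_filters), dtype=dtype)
    for l in range(kl):
        for m in range(km):
            for n in range(kn):
                sl = np.ascontiguousarray(xp[l: l + H, m: m + W, n: n + D])
                out += sl.reshape(-1, c_in) @ layer.weights[l, m, n]
    return out.reshape(H, W, D, layer.n_filters) + layer.bias


def _conv3d_grads(x: np.ndarray, layer: ConvLayerSpec, dz: np.ndarray,
                  need_dx: bool = True):
    """Analytic gradients of conv3d: returns (dx, dw, db)."""
    x = _as_channels(x)
    kl, km, kn = layer.weights.shape[:3]
    db = dz.sum(axis=(0, 1, 2))
    if kl == 1:
        w = layer.weights[0, 0, 0]  # (c_in, c_out)
        dw = np.tensordot(x, dz, axes=([0, 1, 2], [0, 1, 2]))[None, None, None]
        dx = dz @ w.T if need_dx else None
        return dx, dw, db
    pad = ((kl // 2,) * 2, (km // 2,) * 2, (kn // 2,) * 2, (0, 0))
    xp = np.pad(x, pad)
    H, W, D, c_in = x.shape
    c_out = layer.n_filters
    dw = np.empty((kl, km, kn, c_in, c_out), dtype=np.result_type(x, dz))
    for l in range(kl):
        for m in range(km):
            for n in range(kn):
                dw[l, m, n] = np.tensordot(
                    xp[l: l + H, m: m + W, n: n + D], dz,
                    axes=([0, 1, 2], [0, 1, 2]),
                )
    dx = None
    if need_dx:
        # dX: convolve dZ with the spatially flipped, channel-transposed kernel
        w_rot = np.swapaxes(layer.weights[::-1, ::-1, ::-1], 3, 4)
        back = ConvLayerSpec(n_filters=c_in,
                             weights=np.ascontiguousarray(w_rot),
                             bias=np.zeros(c_in))
        dx = conv3d(dz, back)
    return dx, dw, db


def relu(z: np.ndarray) -> np.ndarray:
    """Elementwise rectifier max(0, z)."""
    return np.maximum(0.0, z)


class Network:
    """The conv/ReLU ladder plus channel projection, with Adam training."""

    def __init__(self, config: NetworkConfig, layers: list[ConvLayerSpec]):
        self.config = config
        self.layers = layers

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """Forward pass; optionally keep per-layer activations for backprop."""
        a = _as_channels(x)
        cache = []
        n = len(self.layers)
        for li, layer in enumerate(self.layers):
            z = conv3d(a, layer)
            is_last = li == n - 1
            a_next = z if is_last else relu(z)  # linear regression head
            if keep_cache:
                cache.append((a, z))
            a = a_next
        return (a, cache) if keep_cache else a

    def backward(self, cache, d_out):
        """Gradients of the loss w.r.t. every weight/bias, given d(output)."""
        grads = [None] * len(self.layers)
        da = d_out
        n = len(self.layers)
        for li in range(n - 1, -1, -1):
            a_in, z = cache[li]
            dz = da if li == n - 1 else da * (z > 0)
            dx, dw, db = _conv3d_grads(a_in, self.layers[li], dz,
                                       need_dx=li > 0)
            grads[li] = (dw, db)
            da = dx
        return grads


def build_network(config: NetworkConfig, bias_init: float = 0.1) -> Network:
    """Construct the network with seeded He-uniform initial weights.

    The ladder applies one conv+ReLU stage per entry of ``layer_filters``
    and, when ``projection_to_one_channel`` is set, a linear 1×1×1
    convolution collapsing the final feature maps to the single-channel
    regression output.  Ladder biases start at a small positive constant so
    ReLU units stay active early in training (with zero biases and
    nonnegative image inputs, half the units start dead and whole layers
    can collapse irrecoverably).  Identical seeds give identical initial
    weights.
    """
    rng = np.random.default_rng(config.seed)
    layers: list[ConvLayerSpec] = []
    c_in = 1
    for nf in config.layer_filters:
        fan_in = 27 * c_in
        limit = np.sqrt(6.0 / fan_in)
        w = rng.uniform(-limit, limit, size=(3, 3, 3, c_in, nf))
        layers.append(ConvLayerSpec(n_filters=nf, weights=w,
                                    bias=np.full(nf, bias_init)))
        c_in = nf
    if config.projection_to_one_channel:
        limit = np.sqrt(6.0 / c_in)
        w = rng.uniform(-limit, limit, size=(1, 1, 1, c_in, 1))
        layers.append(ConvLayerSpec(n_filters=1, weights=w, bias=np.zeros(1)))
    return Network(config, layers)


def calibrate_init(network: Network, x: np.ndarray, y: np.ndarray | None = None) -> None:
    """Data-dependent rescaling of freshly initialized weights (LSUV-style).

    Random inits of a deep ReLU ladder have highly variable effective gain:
    an unlucky draw attenuates or saturates the signal and Adam then crawls
    toward a constant-output solution.  Forwarding one real sample and
    rescaling each layer so its pre-activations have unit standard
    deviation removes that variability; when a target is given, the final
    projection layer is additionally scaled and shifted to match the
    target's standard deviation and mean.  Scaling (w, b) jointly preserves
    the layer function up to the scalar, so this is pure reparameterization
    of the init, done once before the first update.
    """
    a = _as_channels(np.asarray(x, dtype=np.float64))
    n = len(network.layers)
    for li, layer in enumerate(network.layers):
        z = conv3d(a, layer)
        is_last = li == n - 1
        sd = float(z.std())
        if sd > 1e-12:
            layer.weights = layer.weights / sd
            layer.bias = layer.bias / sd
            z = z / sd
        if is_last and y is not None:
            target = np.asarray(y, dtype=np.float64)
            t_sd = float(target.std())
            if t_sd > 1e-12:
                layer.weights = layer.weights * t_sd
                layer.bias = layer.bias * t_sd
                z = z * t_sd
            layer.bias = layer.bias + (float(target.mean()) - float(z.mean()))
        a = z if is_last else relu(z)


def train(
    network: Network,
    pairs: list[tuple[ROIStack | np.ndarray, VolumeStack | np.ndarray]],
    epochs: int | None = None,
    learning_rate: float | None = None,
    seed: int | None = None,
    dtype=np.float32,
    calibrate: bool = True,
    max_restarts: int = 3,
    restart_patience: int = 25,
) -> tuple[Network, TrainingHistory]:
    """Fit the network to (input stack, target stack) pairs by full-batch Adam.

    Minimizes the mean squared error over all voxels of all pairs; the
    history records the per-epoch loss and RMSE = sqrt(loss).  Training is
    deterministic for a fixed seed and thread count.  A non-finite loss
    aborts with the offending epoch.  Arithmetic runs in float32 by default
    (pass ``dtype=np.float64`` for full precision).  Unless ``calibrate``
    is disabled, the initial weights are first rescaled on the first
    training pair (see :func:`calibrate_init`).

    Some init draws of a deep ReLU ladder collapse to the constant-output
    solution, whose RMSE equals the pooled target standard deviation, and
    never escape it.  If after ``restart_patience`` epochs the best RMSE has
    not dropped below that constant-prediction baseline, training restarts
    from a fresh seeded init (up to ``max_restarts`` times; the returned
    history covers only the final attempt, keeping its length equal to
    ``epochs``).
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    cfg = network.config
    epochs = cfg.epochs if epochs is None else int(epochs)
    lr = cfg.learning_rate if learning_rate is None else float(learning_rate)
    xs = [np.asarray(p[0].tensor if isinstance(p[0], ROIStack) else p[0], dtype)
          for p in pairs]
    ys = [np.asarray(p[1].tensor if isinstance(p[1], VolumeStack) else p[1], dtype)
          for p in pairs]
    for x, y in zip(xs, ys):
        if x.shape != cfg.input_shape or y.shape != cfg.input_shape:
            raise ValueError("pair shape inconsistent with the network config")
    # RMSE of the best constant prediction: the stalled-run signature
    baseline_rmse = float(np.std(np.stack(ys)))

    attempt = 0
    while True:
        if attempt > 0:
            reseeded = NetworkConfig(
                input_shape=cfg.input_shape,
                layer_filters=cfg.layer_filters,
                projection_to_one_channel=cfg.projection_to_one_channel,
                epochs=cfg.epochs,
                learning_rate=cfg.learning_rate,
                seed=(cfg.seed + 9973 * attempt) % (2**31),
                loss=cfg.loss,
            )
            network = build_network(reseeded)
        if calibrate:
            calibrate_init(network, xs[0], ys[0])
        for layer in network.layers:
            layer.weights = layer.weights.astype(dtype)
            layer.bias = layer.bias.astype(dtype)
        result = _fit(network, xs, ys, epochs, lr, dtype,
                      baseline_rmse if attempt < max_restarts else None,
                      restart_patience)
        if result is not None:
            losses, rmses = result
            return network, TrainingHistory(loss=tuple(losses), rmse=tuple(rmses))
        attempt += 1


def _fit(network, xs, ys, epochs, lr, dtype, stall_baseline, patience):
    """One Adam run; returns (losses, rmses) or None on an early stall."""
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = [(np.zeros_like(l.weights), np.zeros_like(l.bias)) for l in network.layers]
    v = [(np.zeros_like(l.weights), np.zeros_like(l.bias)) for l in network.layers]
    n_vox = sum(y.size for y in ys)
    losses, rmses = [], []
    t = 0
    for epoch in range(epochs):
        total_sq = 0.0
        grad_acc = [(np.zeros_like(l.weights), np.zeros_like(l.bias))
                    for l in network.layers]
        for x, y in zip(xs, ys):
            out, cache = network.forward(x, keep_cache=True)
            resid = out[..., 0] - y
            total_sq += float(np.sum(resid**2))
            d_out = (2.0 / n_vox) * resid[..., None]
            grads = network.backward(cache, d_out)
            for gi, (dw, db) in enumerate(grads):
                grad_acc[gi] = (grad_acc[gi][0] + dw, grad_acc[gi][1] + db)
        loss = total_sq / n_vox
        if not np.isfinite(loss):
            raise DivergenceError(epoch)
        losses.append(loss)
        rmses.append(float(np.sqrt(loss)))
        if (stall_baseline is not None and epoch + 1 == patience
                and epochs > patience
                and min(rmses) > 0.95 * stall_baseline):
            return None
        t += 1
        for li, layer in enumerate(network.layers):
            for slot, (param, g) in enumerate(
                ((layer.weights, grad_acc[li][0]), (layer.bias, grad_acc[li][1]))
            ):
                m_s = beta1 * m[li][slot] + (1 - beta1) * g
                v_s = beta2 * v[li][slot] + (1 - beta2) * g**2
                m[li] = (m_s, m[li][1]) if slot == 0 else (m[li][0], m_s)
                v[li] = (v_s, v[li][1]) if slot == 0 else (v[li][0], v_s)
                mhat = m_s / (1 - beta1**t)
                vhat = v_s / (1 - beta2**t)
                param -= lr * mhat / (np.sqrt(vhat) + eps)
    return losses, rmses


def predict(model: Network, stack: ROIStack | np.ndarray) -> VolumeStack:
    """Regress a volume from one input stack; output clipped to [0, 1]."""
    x = np.asarray(stack.tensor if isinstance(stack, ROIStack) else stack, float)
    if x.shape != model.config.input_shape:
        raise ValueError(
            f"input shape {x.shape} != model input {model.config.input_shape}"
        )
    out = model.forward(x)[..., 0]
    return VolumeStack(tensor=np.clip(out, 0.0, 1.0))


# ---- checkpoint serialization ----------------------------------------------

def save_model(model: Network, path) -> None:
    """Write a portable .npz checkpoint (config + per-layer weights)."""
    cfg = model.config
    arrays = {}
    for i, layer in enumerate(model.layers):
        arrays[f"w{i}"] = layer.weights
        arrays[f"b{i}"] = layer.bias
    np.savez(
        path,
        input_shape=np.array(cfg.input_shape),
        layer_filters=np.array(cfg.layer_filters),
        projection=np.array(int(cfg.projection_to_one_channel)),
        learning_rate=np.array(cfg.learning_rate),
        epochs=np.array(cfg.epochs),
        seed=np.array(cfg.seed),
        n_layers=np.array(len(model.layers)),
        **arrays,
    )


def load_model(path) -> Network:
    """Load a checkpoint written by :func:`save_model`."""
    data = np.load(path)
    cfg = NetworkConfig(
        input_shape=tuple(int(s) for s in data["input_shape"]),
        layer_filters=tuple(int(f) for f in data["layer_filters"]),
        projection_to_one_channel=bool(int(data["projection"])),
        epochs=int(data["epochs"]),
        learning_rate=float(data["learning_rate"]),
        seed=int(data["seed"]),
    )
    layers = [
        ConvLayerSpec(
            n_filters=data[f"w{i}"].shape[4],
            weights=data[f"w{i}"],
            bias=data[f"b{i}"],
        )
        for i in range(int(data["n_layers"]))
    ]
    return Network(cfg, layers)
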
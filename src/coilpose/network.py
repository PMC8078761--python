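"""Residual convolutional regressor from worm images to centerline angles.

The network maps a standardized square grayscale image to the 100 tangent
angles of the centerline, trained with a head-tail-symmetric loss: the
training error is the minimum of the root-mean-square wrapped angle
distance between the prediction and the two equivalent labels (theta and
flip(theta) + pi), so the learned mapping is to an *unoriented* pose.

Architecture (pre-activation residual style): a 7x7/stride-2 stem
convolution, 2x2 max-pooling, three residual stages of basic blocks with
leaky-rectifier activations, global average pooling and a dense output.

Everything here — convolutions (im2col), batch normalization, the residual
blocks, Adam and the loss gradients — is implemented directly on NumPy
arrays, which keeps the regressor dependency-free and fully deterministic
given a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import flip_centerline, wrap_angle, wrap_angle_diff

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "PredictionPair",
    "symmetric_loss",
    "symmetric_loss_batch",
    "build_model",
    "train",
    "predict",
    "prepare_inputs",
    "save_model",
    "load_model",
    "PoseRegressor",
]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


# ---------------------------------------------------------------------------
# loss


def symmetric_loss(theta_hat: np.ndarray, theta_a: np.ndarray) -> float:
    """Head-tail-symmetric training loss for a single pose:
    ``min(d(theta_hat, theta_a), d(theta_hat, flip(theta_a)))`` with d the
    RMS wrapped angle distance. Exactly invariant to flipping either
    argument."""
    theta_hat = np.asarray(theta_hat, float)
    theta_a = np.asarray(theta_a, float)
    if theta_hat.shape != theta_a.shape:
        raise ValueError("centerline length mismatch")
    loss, _ = _symmetric_loss_and_grad(theta_hat[None, :], theta_a[None, :])
    return float(loss)


def symmetric_loss_batch(pred: np.ndarray, labels: np.ndarray) -> float:
    """Mean symmetric loss over a batch of (B, N) predictions/labels."""
    loss, _ = _symmetric_loss_and_grad(np.asarray(pred, float), np.asarray(labels, float))
    return float(loss)


def _symmetric_loss_and_grad(pred: np.ndarray, labels: np.ndarray):
    """Loss value and gradient w.r.t. the raw predicted angles.

    The wrapped difference is the identity almost everywhere, so the
    gradient of d through each branch is ``eps_i / (N * d)``; only the
    winning branch receives gradient.
    """
    n = pred.shape[1]
    labels_flipped = wrap_angle(labels[:, ::-1] + np.pi)
    eps_a = wrap_angle_diff(pred, labels)
    eps_b = wrap_angle_diff(pred, labels_flipped)
    d_a = np.sqrt(np.mean(eps_a**2, axis=1))
    d_b = np.sqrt(np.mean(eps_b**2, axis=1))
    take_a = d_a <= d_b
    d = np.where(take_a, d_a, d_b)
    eps = np.where(take_a[:, None], eps_a, eps_b)
    safe_d = np.maximum(d, 1e-12)
    grad = eps / (n * safe_d[:, None]) / pred.shape[0]
    grad[d < 1e-12] = 0.0
    return float(d.mean()), grad.astype(pred.dtype)


# ---------------------------------------------------------------------------
# layers


class _Conv2D:
    def __init__(self, k, c_in, c_out, stride, pad, rng):
        scale = np.sqrt(2.0 / (k * k * c_in))
        self.w = (rng.standard_normal((k, k, c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.stride, self.pad = k, stride, pad
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"w": self.w, "b": self.b}

    def set_param(self, name, value):
        setattr(self, name, value)

    def forward(self, x, train):
        k, s, p = self.k, self.stride, self.pad
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        view = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
        view = view[:, ::s, ::s]  # (B, OH, OW, C, k, k)
        b_, oh, ow = view.shape[:3]
        cols = np.ascontiguousarray(view.transpose(0, 1, 2, 4, 5, 3)).reshape(
            b_ * oh * ow, k * k * self.w.shape[2]
        )
        out = cols @ self.w.reshape(-1, self.w.shape[3]) + self.b
        out = out.reshape(b_, oh, ow, -1)
        if train:
            self._cache = (cols, x.shape, (b_, oh, ow))
        return out

    def backward(self, dout):
        cols, xp_shape, (b_, oh, ow) = self._cache
        k, s, p = self.k, self.stride, self.pad
        c_in, c_out = self.w.shape[2], self.w.shape[3]
        dout_m = dout.reshape(b_ * oh * ow, c_out)
        self.grads["w"] = (cols.T @ dout_m).reshape(self.w.shape)
        self.grads["b"] = dout_m.sum(axis=0)
        dcols = (dout_m @ self.w.reshape(-1, c_out).T).reshape(b_, oh, ow, k, k, c_in)
        dxp = np.zeros(xp_shape, dtype=dout.dtype)
        for ki in range(k):
            for kj in range(k):
                dxp[:, ki : ki + s * oh : s, kj : kj + s * ow : s, :] += dcols[:, :, :, ki, kj, :]
        if p:
            dxp = dxp[:, p:-p, p:-p, :]
        self._cache = None
        return dxp


class _BatchNorm:
    def __init__(self, c):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.grads: dict[str, np.ndarray] = {}
        self._cache = None

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def set_param(self, name, value):
        setattr(self, name, value)

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, train):
        if train:
            axes = tuple(range(x.ndim - 1))
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (_BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean).astype(np.float32)
            self.running_var = (_BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        x_hat = (x - mean) * inv_std
        if train:
            self._cache = (x_hat, inv_std)
        return self.gamma * x_hat + self.beta

    def backward(self, dout):
        x_hat, inv_std = self._cache
        axes = tuple(range(dout.ndim - 1))
        m = float(np.prod([dout.shape[a] for a in axes]))
        self.grads["gamma"] = (dout * x_hat).sum(axis=axes)
        self.grads["beta"] = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (
            inv_std
            / m
            * (m * dxhat - dxhat.sum(axis=axes) - x_hat * (dxhat * x_hat).sum(axis=axes))
        )
        self._cache = None
        return dx.astype(dout.dtype)


class _LeakyReLU:
    def __init__(self, slope=0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x, train):
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout):
        dx = np.where(self._mask, dout, self.slope * dout)
        self._mask = None
        return dx


class _MaxPool2:
    def forward(self, x, train):
        b, h, w, c = x.shape
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c)
        out = xr.max(axis=(2, 4))
        if train:
            self._cache = (xr, out)
        return out

    def backward(self, dout):
        xr, out = self._cache
        mask = xr == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dx = mask * (dout[:, :, None, :, None, :] / counts)
        self._cache = None
        return dx.reshape(xr.shape[0], xr.shape[1] * 2, xr.shape[3] * 2, xr.shape[5])


class _GlobalAvgPool:
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        b, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :], self._shape) / (h * w)


class _Dense:
    def __init__(self, c_in, c_out, rng):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_in, c_out)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.grads: dict[str, np.ndarray] = {}

    def params(self):
        return {"w": self.w, "b": self.b}

    def set_param(self, name, value):
        setattr(self, name, value)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.grads["w"] = self._x.T @ dout
        self.grads["b"] = dout.sum(axis=0)
        dx = dout @ self.w.T
        self._x = None
        return dx


class _ResidualBlock:
    """Pre-activation basic block: BN -> act -> conv3x3 -> BN -> act ->
    conv3x3, added to the shortcut (1x1 projection when the shape changes,
    applied to the pre-activated input)."""

    def __init__(self, c_in, c_out, stride, slope, rng):
        self.bn1 = _BatchNorm(c_in)
        self.act1 = _LeakyReLU(slope)
        self.conv1 = _Conv2D(3, c_in, c_out, stride, 1, rng)
        self.bn2 = _BatchNorm(c_out)
        self.act2 = _LeakyReLU(slope)
        self.conv2 = _Conv2D(3, c_out, c_out, 1, 1, rng)
        self.proj = _Conv2D(1, c_in, c_out, stride, 0, rng) if (stride != 1 or c_in != c_out) else None

    def sublayers(self):
        layers = [self.bn1, self.conv1, self.bn2, self.conv2]
        if self.proj is not None:
            layers.append(self.proj)
        return layers

    def forward(self, x, train):
        pre = self.act1.forward(self.bn1.forward(x, train), train)
        shortcut = self.proj.forward(pre, train) if self.proj is not None else x
        h = self.conv1.forward(pre, train)
        h = self.act2.forward(self.bn2.forward(h, train), train)
        h = self.conv2.forward(h, train)
        return h + shortcut

    def backward(self, dout):
        dh = self.conv2.backward(dout)
        dh = self.bn2.backward(self.act2.backward(dh))
        dpre = self.conv1.backward(dh)
        if self.proj is not None:
            dpre = dpre + self.proj.backward(dout)
            dx_extra = 0.0
        else:
            dx_extra = dout
        dx = self.bn1.backward(self.act1.backward(dpre))
        return dx + dx_extra


# ---------------------------------------------------------------------------
# model


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    The defaults mirror the full-scale configuration (128 px input, stages
    of 3 blocks with 32/64/128 filters); a reduced configuration — smaller
    input, one block per stage, fewer filters — trains in minutes on a CPU
    and is used throughout the test fixtures.
    """

    input_side: int = 128
    n_outputs: int = 100
    stem_filters: int = 32
    stem_kernel: int = 7
    blocks_per_stage: int = 3
    stage_filters: tuple[int, ...] = (32, 64, 128)
    leaky_slope: float = 0.1

    def __post_init__(self) -> None:
        if self.input_side < 32:
            raise ValueError("minimum image size is 32 x 32 pixels")
        # the stem halves the image, the pool halves it again, and every
        # stage after the first halves it once more
        div = 4 * 2 ** (len(self.stage_filters) - 1)
        if self.input_side % div != 0:
            raise ValueError(
                f"input side {self.input_side} is incompatible with the "
                f"downsampling chain (must be a multiple of {div})"
            )


def reduced_spec(input_side: int = 48) -> NetworkSpec:
    """The scaled-down configuration used by fixtures and desk-scale runs."""
    return NetworkSpec(
        input_side=input_side,
        stem_filters=16,
        blocks_per_stage=2,
        stage_filters=(16, 32, 64),
    )


class PoseRegressor:
    """The assembled network; see the module docstring for the topology."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.stem = _Conv2D(spec.stem_kernel, 1, spec.stem_filters, 2, spec.stem_kernel // 2, rng)
        self.pool = _MaxPool2()
        self.blocks: list[_ResidualBlock] = []
        c_in = spec.stem_filters
        for stage, c_out in enumerate(spec.stage_filters):
            for b in range(spec.blocks_per_stage):
                stride = 2 if (stage > 0 and b == 0) else 1
                self.blocks.append(_ResidualBlock(c_in, c_out, stride, spec.leaky_slope, rng))
                c_in = c_out
        self.final_bn = _BatchNorm(c_in)
        self.final_act = _LeakyReLU(spec.leaky_slope)
        self.gap = _GlobalAvgPool()
        self.dense = _Dense(c_in, spec.n_outputs, rng)

    # -- parameter traversal -------------------------------------------------
    def _param_layers(self):
        layers = [self.stem]
        for block in self.blocks:
            layers.extend(block.sublayers())
        layers.extend([self.final_bn, self.dense])
        return layers

    def parameter_count(self) -> int:
        return int(sum(p.size for layer in self._param_layers() for p in layer.params().values()))

    def get_weights(self) -> list[np.ndarray]:
        arrays = []
        for layer in self._param_layers():
            arrays.extend(v.copy() for v in layer.params().values())
            if isinstance(layer, _BatchNorm):
                arrays.extend(v.copy() for v in layer.state().values())
        return arrays

    def set_weights(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for layer in self._param_layers():
            for name in layer.params():
                layer.set_param(name, next(it).copy())
            if isinstance(layer, _BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.stem.forward(x, train)
        h = self.pool.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train)
        h = self.final_act.forward(self.final_bn.forward(h, train), train)
        h = self.gap.forward(h, train)
        return self.dense.forward(h, train)

    def backward(self, dout: np.ndarray) -> None:
        dh = self.dense.backward(dout)
        dh = self.gap.backward(dh)
        dh = self.final_bn.backward(self.final_act.backward(dh))
        for block in reversed(self.blocks):
            dh = block.backward(dh)
        dh = self.pool.backward(dh)
        self.stem.backward(dh)


class _Adam:
    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.params().items()} for layer in layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.params().items()} for layer in layers
        ]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for i, layer in enumerate(self.layers):
            for k, p in layer.params().items():
                g = layer.grads[k].astype(np.float32)
                self.m[i][k] = b1 * self.m[i][k] + (1 - b1) * g
                self.v[i][k] = b2 * self.v[i][k] + (1 - b2) * g * g
                m_hat = self.m[i][k] / corr1
                v_hat = self.v[i][k] / corr2
                layer.set_param(k, p - self.lr * m_hat / (np.sqrt(v_hat) + self.eps))


# ---------------------------------------------------------------------------
# training and prediction


@dataclass
class TrainConfig:
    """Training hyperparameters (defaults follow the full-scale recipe:
    Adam at 1e-3, batch 128, 100 epochs, best-eval checkpointing).

    ``learning_rates`` optionally sets a per-epoch schedule (its length
    overrides ``epochs``); short desk-scale runs benefit from decaying the
    rate over the final epochs, which the long full-scale run does not
    need.
    """

    batch_size: int = 128
    epochs: int = 100
    learning_rate: float = 1e-3
    learning_rates: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) <= 0 or self.learning_rate <= 0:
            raise ValueError("training configuration values must be positive")
        if self.learning_rates is not None:
            if len(self.learning_rates) == 0 or min(self.learning_rates) <= 0:
                raise ValueError("learning_rates must be positive")
            self.epochs = len(self.learning_rates)

    def epoch_lr(self, epoch: int) -> float:
        if self.learning_rates is not None:
            return self.learning_rates[epoch]
        return self.learning_rate


@dataclass
class PredictionPair:
    """The two head-tail-equivalent centerline candidates for one frame."""

    theta_hat: np.ndarray
    theta_hat_flipped: np.ndarray
    frame_index: int = -1


def prepare_inputs(images: np.ndarray, background_values: np.ndarray | float) -> np.ndarray:
    """Network input normalization: pixels scaled to [0, 1] with the
    per-image background mean subtracted."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    bg = np.asarray(background_values, dtype=np.float32) / 255.0
    if bg.ndim == 0:
        bg = np.full(x.shape[0], float(bg), dtype=np.float32)
    x = x - bg[:, None, None]
    return x[..., None]


def build_model(spec: NetworkSpec, seed: int = 0) -> PoseRegressor:
    """Construct the regressor with deterministic, seed-controlled
    initialization."""
    return PoseRegressor(spec, seed=seed)


def train(
    model: PoseRegressor,
    train_images: np.ndarray,
    train_targets: np.ndarray,
    train_backgrounds: np.ndarray | float,
    eval_images: np.ndarray,
    eval_targets: np.ndarray,
    eval_backgrounds: np.ndarray | float,
    config: TrainConfig,
    verbose: bool = False,
) -> dict:
    """Train with the symmetric loss and return the history.

    The model is left holding the checkpoint with the smallest evaluation
    loss (computed once per epoch). A NaN loss aborts with diagnostics.
    """
    rng = np.random.default_rng(config.seed)
    x_eval = prepare_inputs(eval_images, eval_backgrounds)
    y_eval = np.asarray(eval_targets, dtype=np.float32)
    n = train_images.shape[0]
    optimizer = _Adam(model._param_layers(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "eval_loss": []}
    best_loss = np.inf
    best_weights = None
    x_all = prepare_inputs(train_images, train_backgrounds)
    y_all = np.asarray(train_targets, dtype=np.float32)
    for epoch in range(config.epochs):
        optimizer.lr = config.epoch_lr(epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pred = model.forward(x_all[idx], train=True)
            loss, grad = _symmetric_loss_and_grad(pred.astype(np.float64), y_all[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (loss={loss}) at epoch {epoch}, "
                    f"batch {n_batches}; try a lower learning rate"
                )
            model.backward(grad.astype(np.float32))
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        eval_loss = evaluate(model, x_eval, y_eval, config.batch_size, prepared=True)
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        history["eval_loss"].append(eval_loss)
        if eval_loss < best_loss:
            best_loss = eval_loss
            best_weights = model.get_weights()
        if verbose:
            print(
                f"epoch {epoch + 1}/{config.epochs}: "
                f"train {history['train_loss'][-1]:.4f} rad, eval {eval_loss:.4f} rad"
            )
    if best_weights is not None:
        model.set_weights(best_weights)
    history["best_eval_loss"] = float(best_loss)
    return history


def evaluate(
    model: PoseRegressor,
    images: np.ndarray,
    targets: np.ndarray,
    batch_size: int = 128,
    backgrounds: np.ndarray | float = 0.0,
    prepared: bool = False,
) -> float:
    x = images if prepared else prepare_inputs(images, backgrounds)
    y = np.asarray(targets, dtype=np.float64)
    total, count = 0.0, 0
    for start in range(0, x.shape[0], batch_size):
        pred = model.forward(x[start : start + batch_size], train=False)
        loss, _ = _symmetric_loss_and_grad(pred.astype(np.float64), y[start : start + batch_size])
        b = pred.shape[0]
        total += loss * b
        count += b
    return total / max(count, 1)


def predict(
    model: PoseRegressor,
    images: np.ndarray,
    background_values: np.ndarray | float,
    frame_indices: np.ndarray | None = None,
    batch_size: int = 128,
) -> list[PredictionPair]:
    """Predict centerlines for a stack of standardized frames.

    One :class:`PredictionPair` per frame; the flipped member is derived
    from the prediction, not re-inferred. Frames whose size differs from
    the model input side are resized (with a warning).
    """
    images = np.asarray(images)
    side = model.spec.input_side
    if images.shape[1] != side or images.shape[2] != side:
        import warnings

        from skimage.transform import resize

        warnings.warn(
            f"resizing frames from {images.shape[1:3]} to the model input side {side}",
            stacklevel=2,
        )
        images = np.stack(
            [resize(im, (side, side), preserve_range=True, anti_aliasing=True) for im in images]
        )
    x = prepare_inputs(images, background_values)
    outputs = []
    for start in range(0, x.shape[0], batch_size):
        outputs.append(model.forward(x[start : start + batch_size], train=False))
    theta = wrap_angle(np.concatenate(outputs, axis=0).astype(np.float64))
    if frame_indices is None:
        frame_indices = np.arange(theta.shape[0])
    return [
        PredictionPair(
            theta_hat=theta[i],
            theta_hat_flipped=flip_centerline(theta[i]),
            frame_index=int(frame_indices[i]),
        )
        for i in range(theta.shape[0])
    ]


# ---------------------------------------------------------------------------
# serialization


def save_model(model: PoseRegressor, directory) -> None:
    """Checkpoint: architecture JSON + weight arrays in one npz."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    spec = model.spec
    arch = {
        "input_side": spec.input_side,
        "n_outputs": spec.n_outputs,
        "stem_filters": spec.stem_filters,
        "stem_kernel": spec.stem_kernel,
        "blocks_per_stage": spec.blocks_per_stage,
        "stage_filters": list(spec.stage_filters),
        "leaky_slope": spec.leaky_slope,
    }
    (directory / "architecture.json").write_text(json.dumps(arch, indent=2))
    weights = model.get_weights()
    np.savez_compressed(
        directory / "weights.npz", **{f"arr_{i}": w for i, w in enumerate(weights)}
    )


def load_model(directory) -> PoseRegressor:
    directory = Path(directory)
    arch = json.loads((directory / "architecture.json").read_text())
    arch["stage_filters"] = tuple(arch["stage_filters"])
    model = PoseRegressor(NetworkSpec(**arch), seed=0)
    with np.load(directory / "weights.npz") as archive:
        weights = [archive[f"arr_{i}"] for i in range(len(archive.files))]
    model.set_weights(weights)
    return model
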
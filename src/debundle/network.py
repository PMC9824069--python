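"""Three-layer convolutional network for honeycomb artifact removal.

The restoration mapping is a small SRCNN-style stack — patch extraction
(9x9, 64 maps), nonlinear mapping (1x1, 32 maps), reconstruction (5x5,
1 map) — trained with a mean-squared-error loss and plain stochastic
gradient descent on 33x33 sub-image pairs.  The first filter is sized to
enclose a full honeycomb cell (core pitch 5-6 px), so one forward pass maps
a raw bundle image of any size directly to an artifact-free image.

Convolutions use replicate ("same") padding in both training and
inference, keeping the loss defined on full patches and making restoration
shape-preserving.  Forward and backward passes are written against BLAS
matmuls: layers with a small patch volume go through an explicit im2col
matrix, wide layers through shift-and-accumulate matmuls, and the adjoint
of replicate padding folds boundary gradients back onto edge pixels.  With
a fixed seed, initialization and batch order are deterministic.

Per-image inference cost is (f1^2*n1 + n1*f2^2*n2 + n2*f3^2) * H * W
multiply-accumulates, i.e. linear in pixel count.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np

from .patches import PatchDataset

logger = logging.getLogger(__name__)

try:  # numba accelerates the wide conv layer; numpy path remains correct
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is an optional speed-up
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(fastmath=True, cache=False)
    def _tap_conv_fwd(xp, W, b, y):  # pragma: no cover - compiled
        B, H, Wd, O = y.shape
        k = W.shape[0]
        C = xp.shape[3]
        for bi in range(B):
            for i in range(H):
                for j in range(Wd):
                    for o in range(O):
                        acc = b[o]
                        for u in range(k):
                            for v in range(k):
                                for c in range(C):
                                    acc += xp[bi, i + u, j + v, c] * W[u, v, c, o]
                        y[bi, i, j, o] = acc

    @_njit(fastmath=True, cache=False)
    def _tap_conv_bwd(xp, W, dout, dW, dxp, need_dx):  # pragma: no cover
        B, H, Wd, O = dout.shape
        k = W.shape[0]
        C = xp.shape[3]
        for bi in range(B):
            for i in range(H):
                for j in range(Wd):
                    for o in range(O):
                        d = dout[bi, i, j, o]
                        if need_dx:
                            for u in range(k):
                                for v in range(k):
                                    for c in range(C):
                                        dW[u, v, c, o] += xp[bi, i + u, j + v, c] * d
                                        dxp[bi, i + u, j + v, c] += d * W[u, v, c, o]
                        else:
                            for u in range(k):
                                for v in range(k):
                                    for c in range(C):
                                        dW[u, v, c, o] += xp[bi, i + u, j + v, c] * d

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "forward",
    "train",
    "restore",
    "mac_count",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimization hyperparameters.

    Defaults follow the published recipe: filter sizes 9/1/5, feature maps
    64/32, MSE loss, SGD with learning rate 1e-4, batch 128.  ``momentum``
    and ``init`` extend plain SGD for desk-scale runs: ``init="gaussian"``
    draws weights from N(0, init_sigma^2) (the SRCNN convention), while
    ``init="he"`` scales by fan-in, which lets short training budgets make
    progress.
    """

    f1: int = 9
    f2: int = 1
    f3: int = 5
    n1: int = 64
    n2: int = 32
    lr: float = 1e-4
    momentum: float = 0.0
    batch_size: int = 128
    iterations: int = 10_000
    seed: int = 0
    init: str = "gaussian"
    init_sigma: float = 1e-3
    log_interval: int = 100
    val_interval: int | None = None

    def __post_init__(self) -> None:
        for f in (self.f1, self.f2, self.f3):
            if f < 1 or f % 2 == 0:
                raise ValueError("filter sizes must be odd and >= 1")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("feature-map counts must be >= 1")
        if self.init not in ("gaussian", "he"):
            raise ValueError(f"unknown init {self.init!r}")


@dataclass
class ModelParams:
    """Weights and biases of the three layers.

    Kernels are stored channels-last as (k, k, in, out); biases as (out,).
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray
    config: ModelConfig = field(default_factory=ModelConfig)
    trained_steps: int = 0

    def tensors(self) -> list[np.ndarray]:
        return [self.W1, self.b1, self.W2, self.b2, self.W3, self.b3]

    def validate(self) -> None:
        c = self.config
        expect = [
            (c.f1, c.f1, 1, c.n1), (c.n1,),
            (c.f2, c.f2, c.n1, c.n2), (c.n2,),
            (c.f3, c.f3, c.n2, 1), (1,),
        ]
        for t, shape in zip(self.tensors(), expect):
            if t.shape != shape:
                raise ValueError(f"parameter shape {t.shape} != {shape}")
            if not np.all(np.isfinite(t)):
                raise ValueError("non-finite parameter values")


def init_params(config: ModelConfig) -> ModelParams:
    """Draw initial weights (seeded); biases start at zero."""
    rng = np.random.default_rng(config.seed)

    def draw(shape: tuple[int, ...]) -> np.ndarray:
        if config.init == "he":
            fan_in = shape[0] * shape[1] * shape[2]
            sigma = np.sqrt(2.0 / fan_in)
        else:
            sigma = config.init_sigma
        return rng.normal(0.0, sigma, shape).astype(np.float32)

    c = config
    return ModelParams(
        W1=draw((c.f1, c.f1, 1, c.n1)), b1=np.zeros(c.n1, dtype=np.float32),
        W2=draw((c.f2, c.f2, c.n1, c.n2)), b2=np.zeros(c.n2, dtype=np.float32),
        W3=draw((c.f3, c.f3, c.n2, 1)), b3=np.zeros(1, dtype=np.float32),
        config=config,
    )


# ---------------------------------------------------------------------------
# convolution primitives (channels-last, replicate same-padding)

_IM2COL_MAX_PATCH = 128  # use im2col when k*k*C is at most this


def _pad_edge(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)), mode="edge")


def _unpad_edge_adjoint(gp: np.ndarray, p: int) -> np.ndarray:
    """Adjoint of replicate padding: fold pad-band gradients onto edges."""
    if p == 0:
        return gp
    g = gp[:, p:-p, :, :].copy()
    g[:, 0, :, :] += gp[:, :p, :, :].sum(axis=1)
    g[:, -1, :, :] += gp[:, -p:, :, :].sum(axis=1)
    g2 = g[:, :, p:-p, :].copy()
    g2[:, :, 0, :] += g[:, :, :p, :].sum(axis=2)
    g2[:, :, -1, :] += g[:, :, -p:, :].sum(axis=2)
    return g2


def _im2col(xp: np.ndarray, k: int, out_shape: tuple[int, int]) -> np.ndarray:
    """Column matrix of a padded batch, laid out (k*k*C, B*H*W).

    One contiguous row per (tap row, tap col, channel); rows are cheap
    strided-slice copies and the layout lets BLAS consume the transpose
    without materializing it.
    """
    B = xp.shape[0]
    cin = xp.shape[3]
    H, Wd = out_shape
    cols = np.empty((k * k * cin, B * H * Wd), dtype=xp.dtype)
    idx = 0
    for u in range(k):
        for v in range(k):
            for c in range(cin):
                cols[idx] = xp[:, u : u + H, v : v + Wd, c].ravel()
                idx += 1
    return cols


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray,
                  want_cache: bool = False):
    """Same-size convolution of (B, H, W, C) with kernel (k, k, C, O).

    Returns (y, cache); the cache carries whatever the backward pass
    needs.  Small patch volumes (k*k*C) go through an explicit im2col
    GEMM; larger ones through shift-and-accumulate matmuls over the taps.
    """
    k = W.shape[0]
    cin, cout = W.shape[2], W.shape[3]
    p = (k - 1) // 2
    B, H, Wd, _ = x.shape
    if k == 1:
        y = x @ W[0, 0] + b
        return y, (x if want_cache else None)
    xp = _pad_edge(x, p)
    if k * k * cin <= _IM2COL_MAX_PATCH:
        cols = _im2col(xp, k, (H, Wd))
        y = cols.T @ W.reshape(k * k * cin, cout) + b
        return y.reshape(B, H, Wd, cout), (cols if want_cache else None)
    if _HAVE_NUMBA:
        y = np.empty((B, H, Wd, cout), dtype=x.dtype)
        _tap_conv_fwd(xp, W.astype(x.dtype), b.astype(x.dtype), y)
        return y, (xp if want_cache else None)
    y = np.broadcast_to(b, (B, H, Wd, cout)).astype(x.dtype).copy()
    for u in range(k):
        for v in range(k):
            y += xp[:, u : u + H, v : v + Wd, :] @ W[u, v]
    return y, (xp if want_cache else None)


def _conv_backward(dout: np.ndarray, x: np.ndarray, W: np.ndarray,
                   cache, need_dx: bool = True):
    """Gradients (dW, db, dx) for :func:`_conv_forward`."""
    k = W.shape[0]
    cin, cout = W.shape[2], W.shape[3]
    p = (k - 1) // 2
    B, H, Wd, _ = x.shape
    db = dout.sum(axis=(0, 1, 2))
    if k == 1:
        xin = cache if cache is not None else x
        n = B * H * Wd
        dW = (xin.reshape(n, cin).T @ dout.reshape(n, cout))[None, None]
        dx = dout @ W[0, 0].T if need_dx else None
        return dW, db, dx
    dout_mat = np.ascontiguousarray(dout.reshape(B * H * Wd, cout))
    if k * k * cin <= _IM2COL_MAX_PATCH:
        cols = cache
        if cols is None:
            xp = _pad_edge(x, p)
            cols = _im2col(xp, k, (H, Wd))
        dW = (cols @ dout_mat).reshape(k, k, cin, cout)
        dx = None
        if need_dx:
            dcols = W.reshape(k * k * cin, cout) @ dout_mat.T
            dxp = np.zeros((B, H + 2 * p, Wd + 2 * p, cin), dtype=x.dtype)
            idx = 0
            for u in range(k):
                for v in range(k):
                    for c in range(cin):
                        dxp[:, u : u + H, v : v + Wd, c] += dcols[idx].reshape(
                            B, H, Wd)
                        idx += 1
            dx = _unpad_edge_adjoint(dxp, p)
        return dW, db, dx
    xp = cache if cache is not None else _pad_edge(x, p)
    if _HAVE_NUMBA:
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp) if need_dx else np.zeros((1, 1, 1, cin),
                                                         dtype=xp.dtype)
        _tap_conv_bwd(xp, W, np.ascontiguousarray(dout), dW, dxp, need_dx)
        dx = _unpad_edge_adjoint(dxp, p) if need_dx else None
        return dW, db, dx
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp) if need_dx else None
    buf = np.empty((B, H, Wd, cin), dtype=xp.dtype)
    buf_mat = buf.reshape(B * H * Wd, cin)
    for u in range(k):
        for v in range(k):
            buf[...] = xp[:, u : u + H, v : v + Wd, :]
            dW[u, v] = buf_mat.T @ dout_mat
            if need_dx:
                dxp[:, u : u + H, v : v + Wd, :] += (
                    dout_mat @ W[u, v].T).reshape(B, H, Wd, cin)
    dx = _unpad_edge_adjoint(dxp, p) if need_dx else None
    return dW, db, dx


def _forward_batch(params: ModelParams, x: np.ndarray, want_cache: bool = False):
    """conv(f1) -> ReLU -> conv(f2) -> ReLU -> conv(f3) on (B, H, W, 1)."""
    z1, c1 = _conv_forward(x, params.W1, params.b1, want_cache)
    a1 = np.maximum(z1, 0.0)
    z2, c2 = _conv_forward(a1, params.W2, params.b2, want_cache)
    a2 = np.maximum(z2, 0.0)
    z3, c3 = _conv_forward(a2, params.W3, params.b3, want_cache)
    if want_cache:
        return z3, (x, z1, a1, c1, z2, a2, c2, c3)
    return z3, None


def _backward_batch(params: ModelParams, dz3: np.ndarray, cache):
    x, z1, a1, c1, z2, a2, c2, c3 = cache
    dW3, db3, da2 = _conv_backward(dz3, a2, params.W3, c3, need_dx=True)
    dz2 = da2 * (z2 > 0)
    dW2, db2, da1 = _conv_backward(dz2, a1, params.W2, c2, need_dx=True)
    dz1 = da1 * (z1 > 0)
    dW1, db1, _ = _conv_backward(dz1, x, params.W1, c1, need_dx=False)
    return [dW1, db1, dW2, db2, dW3, db3]


def forward(params: ModelParams, image: np.ndarray) -> np.ndarray:
    """Raw network output for a 2-D image (same shape, unclipped)."""
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("forward expects a 2-D raster")
    if min(img.shape) < params.config.f1:
        raise ValueError("image smaller than the first filter")
    params.validate()
    x = img.astype(np.float32)[None, :, :, None]
    z3, _ = _forward_batch(params, x)
    return z3[0, :, :, 0].astype(np.float64)


def restore(params: ModelParams, bundle_image: np.ndarray) -> np.ndarray:
    """Full-image restoration: forward pass clipped to [0, 1]."""
    if params.trained_steps == 0:
        logger.warning("restoring with untrained parameters")
    return np.clip(forward(params, bundle_image), 0.0, 1.0)


def mac_count(config: ModelConfig, shape: tuple[int, int]) -> int:
    """Analytic multiply-accumulate count for one forward pass."""
    c = config
    per_pixel = c.f1**2 * c.n1 + c.n1 * c.f2**2 * c.n2 + c.n2 * c.f3**2
    return per_pixel * shape[0] * shape[1]


def train(
    config: ModelConfig,
    dataset: PatchDataset,
    val: list | None = None,
    params: ModelParams | None = None,
) -> tuple[ModelParams, dict]:
    """Minimize MSE between network output and target patches with SGD.

    Batches are drawn by cycling a seeded shuffle of the dataset (each pass
    reshuffled), so a fixed seed reproduces the run.  ``history`` records
    the batch loss every ``log_interval`` steps and, if validation pairs
    are given, mean restored-image PSNR every ``val_interval`` steps.
    Raises on a non-finite loss.
    """
    from .metrics import psnr as _psnr

    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if params is None:
        params = init_params(config)
    params.validate()
    rng = np.random.default_rng(config.seed + 1)
    inputs = dataset.inputs[..., None]
    targets = dataset.targets[..., None]
    n = len(dataset)
    weights = params.tensors()
    velocity = [np.zeros_like(w) for w in weights]
    history: dict = {"step": [], "loss": [], "val_step": [], "val_psnr": []}
    val_interval = config.val_interval or max(1, config.iterations // 10)

    order = rng.permutation(n)
    ptr = 0
    for step in range(1, config.iterations + 1):
        take = min(config.batch_size, n)
        if ptr + take > n:
            order = rng.permutation(n)
            ptr = 0
        idx = order[ptr : ptr + take]
        ptr += take
        xb, tb = inputs[idx], targets[idx]

        z3, cache = _forward_batch(params, xb, want_cache=True)
        diff = z3 - tb
        loss = float(np.mean(diff**2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at step {step} (lr={config.lr}); "
                "reduce the learning rate")
        grads = _backward_batch(params, (2.0 / diff.size) * diff, cache)

        for w, v, g in zip(weights, velocity, grads):
            if config.momentum > 0.0:
                v *= config.momentum
                v -= config.lr * g
                w += v
            else:
                w -= config.lr * g

        if step == 1 or step % config.log_interval == 0 or step == config.iterations:
            history["step"].append(step)
            history["loss"].append(loss)
            logger.info("step %d  loss %.6f", step, loss)
        if val and (step % val_interval == 0 or step == config.iterations):
            scores = [
                _psnr(p.ground_truth,
                      np.clip(forward(params, p.bundle_image), 0.0, 1.0))
                for p in val[:3]
            ]
            history["val_step"].append(step)
            history["val_psnr"].append(float(np.mean(scores)))
        params.trained_steps += 1
    return params, history


# ---------------------------------------------------------------------------
# serialization: JSON header + raw float32 payload in one file

_MAGIC = b"DEBUNDLE1\n"


def save_model(params: ModelParams, path) -> None:
    params.validate()
    header = {
        "config": asdict(params.config),
        "trained_steps": params.trained_steps,
        "tensors": [list(t.shape) for t in params.tensors()],
        "dtype": "float32",
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        for t in params.tensors():
            fh.write(np.ascontiguousarray(t, dtype=np.float32).tobytes())


def load_model(path) -> ModelParams:
    with open(path, "rb") as fh:
        if fh.read(len(_MAGIC)) != _MAGIC:
            raise ValueError("not a debundle model file")
        hlen = int.from_bytes(fh.read(8), "little")
        header = json.loads(fh.read(hlen).decode())
        tensors = []
        for shape in header["tensors"]:
            count = int(np.prod(shape))
            buf = fh.read(count * 4)
            tensors.append(np.frombuffer(buf, dtype=np.float32).reshape(shape).copy())
    config = ModelConfig(**header["config"])
    params = ModelParams(*tensors, config=config,
                         trained_steps=header["trained_steps"])
    params.validate()
    return params
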
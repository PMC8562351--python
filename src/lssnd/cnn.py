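"""A small 1D convolutional network for three-class spectrum classification.

The fixed topology is

    conv(3 filters, kernel 5, stride 2, ReLU)
    conv(3, 5, 2, ReLU)
    maxpool(pool 2, stride 2, no padding)
    conv(3, 5, 2, ReLU)
    maxpool(2, 2, no padding)
    flatten
    dense(3) + softmax

with at most a few hundred trainable parameters, so the whole thing --
forward pass, backpropagation, and an Adam optimizer -- is implemented
directly in NumPy.  Training minimizes categorical cross-entropy computed
from the logits and monitors the per-epoch training loss for checkpointing
(weights of the minimum-loss epoch are restored) and early stopping (stop
once the loss has failed to improve by more than ``min_delta`` for
``patience_epochs`` epochs).

Because hyperparameter searches train many such networks on identical data,
the training engine operates on a *population*: parameters carry a leading
model axis and every step trains all still-active models in lockstep with
batched matrix products.  Training a single network is the population of
one.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

CLASS_LABELS = ("low", "medium", "high")


class InputTooShortError(ValueError):
    """Raised when a layer's output length would fall below 1."""


@dataclass(frozen=True)
class NetworkSpec:
    conv_filters: int = 3
    conv_kernel: int = 5
    conv_stride: int = 2
    pool_size: int = 2
    pool_stride: int = 2
    conv_padding: str = "valid"   # "valid" or "same"
    n_classes: int = 3

    def __post_init__(self) -> None:
        if self.conv_padding not in ("valid", "same"):
            raise ValueError("conv_padding must be 'valid' or 'same'")
        if self.n_classes != 3:
            raise ValueError("the ND classifier has exactly 3 classes")


@dataclass(frozen=True)
class TrainingConfig:
    learning_rate: float = 0.005
    min_delta: float = 0.001
    patience_epochs: int = 100
    max_epochs: int = 1000
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.min_delta <= 0:
            raise ValueError("learning_rate and min_delta must be positive")
        if self.patience_epochs > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


def _conv_out_len(n: int, kernel: int, stride: int, padding: str) -> int:
    if padding == "same":
        return -(-n // stride)          # ceil(n / stride)
    return (n - kernel) // stride + 1


def _pool_out_len(n: int, pool: int, stride: int) -> int:
    return (n - pool) // stride + 1


def layer_plan(input_length: int, spec: NetworkSpec) -> list[tuple]:
    """(name, out_length, in_channels, out_channels) per layer; validates."""
    plan = []
    n, c = input_length, 1
    for name in ("conv1", "conv2", "pool1", "conv3", "pool2"):
        if name.startswith("conv"):
            out = _conv_out_len(n, spec.conv_kernel, spec.conv_stride,
                                spec.conv_padding)
            c_out = spec.conv_filters
        else:
            out = _pool_out_len(n, spec.pool_size, spec.pool_stride)
            c_out = c
        if out < 1:
            raise InputTooShortError(
                f"layer {name}: output length {out} < 1 for input length "
                f"{input_length}")
        plan.append((name, out, c, c_out))
        n, c = out, c_out
    plan.append(("flatten", n * c, c, n * c))
    plan.append(("dense", spec.n_classes, n * c, spec.n_classes))
    return plan


def _param_shapes(input_length: int, spec: NetworkSpec) -> dict[str, tuple]:
    shapes = {}
    for name, out, c_in, c_out in layer_plan(input_length, spec):
        if name.startswith("conv"):
            shapes[name + "_W"] = (spec.conv_kernel, c_in, c_out)
            shapes[name + "_b"] = (c_out,)
        elif name == "dense":
            shapes["dense_W"] = (c_in, c_out)
            shapes["dense_b"] = (c_out,)
    return shapes


def _glorot_init(shapes: dict[str, tuple], rng: np.random.Generator,
                 dtype) -> dict[str, np.ndarray]:
    params = {}
    for key, shape in shapes.items():
        if key.endswith("_b"):
            params[key] = np.zeros(shape, dtype=dtype)
        elif key.startswith("conv"):
            k, c_in, c_out = shape
            lim = np.sqrt(6.0 / (k * c_in + k * c_out))
            params[key] = rng.uniform(-lim, lim, size=shape).astype(dtype)
        else:
            f_in, f_out = shape
            lim = np.sqrt(6.0 / (f_in + f_out))
            params[key] = rng.uniform(-lim, lim, size=shape).astype(dtype)
    return params


class Network:
    """Instantiated network of the fixed topology for one input length.

    Holds a parameter dict and provides the forward pass used for
    prediction; training happens in :func:`train_with_early_stopping` /
    :func:`train_population`.
    """

    def __init__(self, input_length: int, spec: NetworkSpec = NetworkSpec(),
                 dtype=np.float32):
        self.spec = spec
        self.dtype = np.dtype(dtype)
        self.input_length = int(input_length)
        self.plan = layer_plan(self.input_length, spec)
        self.shapes = _param_shapes(self.input_length, spec)
        self.init_params(np.random.default_rng(0))

    def init_params(self, rng: np.random.Generator) -> None:
        """Glorot-uniform weights, zero biases."""
        self.params = _glorot_init(self.shapes, rng, self.dtype)

    def get_weights(self) -> dict[str, np.ndarray]:
        return copy.deepcopy(self.params)

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        self.params = {k: np.asarray(v, dtype=self.dtype).copy()
                       for k, v in weights.items()}

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Logits for a (B, input_length) batch."""
        X = np.atleast_2d(np.asarray(X, dtype=self.dtype))
        if X.shape[1] != self.input_length:
            raise ValueError(f"spectrum length {X.shape[1]} does not match "
                             f"model input length {self.input_length}")
        pop = _Population(self.input_length, self.spec, 1, dtype=self.dtype)
        pop.load(0, self.params)
        return pop.forward(X)[0]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.forward(X)
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        """Mean categorical cross-entropy from logits (numerically stable)."""
        logits = self.forward(X).astype(float)
        z = logits - logits.max(axis=1, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=1))
        return float(np.mean(lse - z[np.arange(len(y)), np.asarray(y)]))


def build_network(input_length: int,
                  spec: NetworkSpec = NetworkSpec()) -> Network:
    """Untrained network for spectra of the given length."""
    return Network(input_length, spec)


def count_trainable_parameters(model: Network) -> int:
    """Exact number of trainable weights and biases."""
    return int(sum(np.prod(s) for s in model.shapes.values()))


# ---------------------------------------------------------------------------
# population engine: M models with identical topology trained in lockstep
# ---------------------------------------------------------------------------

class _Population:
    """Flat parameter storage (M, P) with per-layer views and batched math."""

    def __init__(self, input_length: int, spec: NetworkSpec, M: int,
                 dtype=np.float32):
        self.spec = spec
        self.input_length = int(input_length)
        self.dtype = np.dtype(dtype)
        self.plan = layer_plan(self.input_length, spec)
        self.shapes = _param_shapes(self.input_length, spec)
        self.offsets = {}
        off = 0
        for key, shape in self.shapes.items():
            size = int(np.prod(shape))
            self.offsets[key] = (off, off + size)
            off += size
        self.P = off
        self.M = int(M)
        self.flat = np.zeros((M, self.P), dtype=self.dtype)
        self._conv_geom = {}
        n = self.input_length
        for name, out, c_in, _ in self.plan:
            if name.startswith("conv"):
                k, s = spec.conv_kernel, spec.conv_stride
                if spec.conv_padding == "same":
                    pad_total = max((out - 1) * s + k - n, 0)
                    left = pad_total // 2
                    right = pad_total - left
                else:
                    left = right = 0
                idx = (np.arange(out) * s)[:, None] + np.arange(k)[None, :]
                self._conv_geom[name] = (idx, left, right, n, c_in, out)
            n = out

    # -- parameter access --------------------------------------------------

    def view(self, key: str, flat: np.ndarray | None = None) -> np.ndarray:
        lo, hi = self.offsets[key]
        buf = self.flat if flat is None else flat
        return buf[:, lo:hi].reshape((buf.shape[0],) + self.shapes[key])

    def load(self, m: int, params: dict[str, np.ndarray]) -> None:
        for key in self.shapes:
            self.view(key)[m] = params[key]

    def export(self, m: int) -> dict[str, np.ndarray]:
        return {key: self.view(key)[m].copy() for key in self.shapes}

    # -- batched forward/backward -----------------------------------------

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        """Logits (M, B, n_classes) for a shared input batch (B, L)."""
        X = np.asarray(X, dtype=self.dtype)
        B = X.shape[0]
        M = self.M
        a = None   # per-model activations (M, B, n, c); None while shared
        n_in = self.input_length
        for name, out, c_in, c_out in self.plan:
            if name.startswith("conv"):
                idx, left, right, n_raw, _, _ = self._conv_geom[name]
                k = self.spec.conv_kernel
                W = self.view(name + "_W").reshape(M, k * c_in, c_out)
                b = self.view(name + "_b")
                if a is None:
                    xp = np.pad(X, ((0, 0), (left, right))) \
                        if (left or right) else X
                    win = xp[:, idx].reshape(B * out, k)   # shared windows
                    z = np.matmul(win, W) + b[:, None, :]
                else:
                    xp = np.pad(a, ((0, 0), (0, 0), (left, right), (0, 0))) \
                        if (left or right) else a
                    win = xp[:, :, idx, :].reshape(M, B * out, k * c_in)
                    z = np.matmul(win, W) + b[:, None, :]
                relu_mask = z > 0
                a = np.where(relu_mask, z, 0).reshape(M, B, out, c_out)
                if cache is not None:
                    cache[name] = (win, relu_mask, xp.shape)
            elif name.startswith("pool"):
                p, s = self.spec.pool_size, self.spec.pool_stride
                idx = (np.arange(out) * s)[:, None] + np.arange(p)[None, :]
                win = a[:, :, idx, :]                  # (M, B, out, p, c)
                arg = win.argmax(axis=3)
                a = np.take_along_axis(win, arg[:, :, :, None, :],
                                       axis=3)[:, :, :, 0, :]
                if cache is not None:
                    cache[name] = (a.shape, idx, arg, win.shape[2:])
            elif name == "flatten":
                if cache is not None:
                    cache["flatten_shape"] = a.shape
                a = a.reshape(M, B, -1)
            elif name == "dense":
                W = self.view("dense_W")
                b = self.view("dense_b")
                if cache is not None:
                    cache["dense_in"] = a
                a = np.matmul(a, W) + b[:, None, :]
        return a

    def backward(self, dlogits: np.ndarray, cache: dict,
                 gflat: np.ndarray) -> None:
        """Accumulate parameter gradients into ``gflat`` (M, P)."""
        M = self.M
        a_in = cache["dense_in"]
        self.view("dense_b", gflat)[...] = dlogits.sum(axis=1)
        self.view("dense_W", gflat)[...] = np.matmul(
            a_in.transpose(0, 2, 1), dlogits)
        da = np.matmul(dlogits, self.view("dense_W").transpose(0, 2, 1))
        da = da.reshape(cache["flatten_shape"])
        for name, out, c_in, c_out in reversed(self.plan[:-2]):
            if name.startswith("pool"):
                out_shape, idx, arg, _ = cache[name]
                in_len = self._pool_in_len(name)
                B = da.shape[1]
                dx = np.zeros((M, B, in_len, c_out), dtype=da.dtype)
                pos = idx[np.arange(out)[None, None, :, None], arg]
                m_ix = np.arange(M)[:, None, None, None]
                b_ix = np.arange(B)[None, :, None, None]
                c_ix = np.arange(c_out)[None, None, None, :]
                if self.spec.pool_stride >= self.spec.pool_size:
                    dx[m_ix, b_ix, pos, c_ix] = da
                else:
                    np.add.at(dx, (m_ix, b_ix, pos, c_ix), da)
                da = dx
            else:
                idx, left, right, n_raw, _, _ = self._conv_geom[name]
                k = self.spec.conv_kernel
                win, relu_mask, xp_shape = cache[name]
                B = da.shape[1]
                dz = (da.reshape(M, B * out, c_out)
                      * relu_mask).astype(da.dtype)
                self.view(name + "_b", gflat)[...] = dz.sum(axis=1)
                gW = self.view(name + "_W", gflat).reshape(
                    M, k * c_in, c_out)
                if name == "conv1":
                    gW[...] = np.matmul(win.T[None], dz)
                    return  # no gradient needed below the input layer
                gW[...] = np.matmul(win.transpose(0, 2, 1), dz)
                W = self.view(name + "_W").reshape(M, k * c_in, c_out)
                dwin = np.matmul(dz, W.transpose(0, 2, 1)).reshape(
                    M, B, out, k, c_in)
                dxp = np.zeros(xp_shape, dtype=da.dtype)
                starts = idx[:, 0]
                for j in range(k):
                    dxp[:, :, starts + j, :] += dwin[:, :, :, j, :]
                da = dxp[:, :, left:left + n_raw, :]

    def _pool_in_len(self, name: str) -> int:
        seq = [p[0] for p in self.plan]
        prev = self.plan[seq.index(name) - 1]
        return prev[1]

    def select(self, keep: np.ndarray) -> None:
        """Drop models not in ``keep`` (boolean mask over the model axis)."""
        self.flat = self.flat[keep]
        self.M = self.flat.shape[0]


@dataclass
class TrainedModel:
    network: Network
    history: list = field(default_factory=list)   # per-epoch training loss
    best_epoch: int = 0
    best_loss: float = np.inf
    config: TrainingConfig | None = None

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(X)


class _NumpyEngine:
    """Reference population engine built on :class:`_Population`."""

    def __init__(self, input_length, spec, init_params_per_model,
                 learning_rates, dtype=np.float32):
        M = len(init_params_per_model)
        self.pop = _Population(input_length, spec, M, dtype=dtype)
        for m, params in enumerate(init_params_per_model):
            self.pop.load(m, params)
        self.lr = np.asarray(learning_rates, dtype=float)[:, None]
        self.mstate = np.zeros_like(self.pop.flat, dtype=np.float64)
        self.vstate = np.zeros_like(self.pop.flat, dtype=np.float64)
        self.gflat = np.zeros_like(self.pop.flat)
        self.t = 0

    @property
    def M(self):
        return self.pop.M

    def step(self, xb, yb):
        cache: dict = {}
        logits = self.pop.forward(xb, cache)
        z = logits - logits.max(axis=2, keepdims=True)
        e = np.exp(z)
        se = e.sum(axis=2, keepdims=True)
        rows = np.arange(len(yb))
        loss_sum = np.log(se[:, :, 0]).sum(axis=1) \
            - z[:, rows, yb].sum(axis=1)
        dlogits = e / se
        dlogits[:, rows, yb] -= 1.0
        dlogits /= len(yb)
        self.pop.backward(dlogits, cache, self.gflat)
        self.t += 1
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        g = self.gflat.astype(np.float64)
        self.mstate = beta1 * self.mstate + (1 - beta1) * g
        self.vstate = beta2 * self.vstate + (1 - beta2) * g * g
        mhat = self.mstate / (1 - beta1 ** self.t)
        vhat = self.vstate / (1 - beta2 ** self.t)
        self.pop.flat -= (self.lr * mhat / (np.sqrt(vhat) + eps)
                          ).astype(self.pop.flat.dtype)
        return loss_sum

    def snapshot(self):
        return self.pop.flat.copy()

    def select(self, keep):
        self.pop.select(keep)
        self.mstate = self.mstate[keep]
        self.vstate = self.vstate[keep]
        self.gflat = self.gflat[keep]
        self.lr = self.lr[keep]

    def export_row(self, row):
        params = {}
        for key, shape in self.pop.shapes.items():
            lo, hi = self.pop.offsets[key]
            params[key] = row[lo:hi].reshape(shape).copy()
        return params


def _make_engine(engine: str, input_length, spec, inits, lrs, dtype):
    if engine == "auto":
        try:
            from ._fast import HAVE_NUMBA, NumbaEngine
            if HAVE_NUMBA:
                return NumbaEngine(input_length, spec, inits, lrs,
                                   dtype=dtype)
        except (ImportError, ValueError):
            pass
        return _NumpyEngine(input_length, spec, inits, lrs, dtype=dtype)
    if engine == "numba":
        from ._fast import NumbaEngine
        return NumbaEngine(input_length, spec, inits, lrs, dtype=dtype)
    if engine == "numpy":
        return _NumpyEngine(input_length, spec, inits, lrs, dtype=dtype)
    raise ValueError(f"unknown engine {engine!r}")


def train_population(input_length: int, spec: NetworkSpec,
                     configs: list[TrainingConfig],
                     X: np.ndarray, y: np.ndarray,
                     perm_seed: int | None = None,
                     shared_rng: np.random.Generator | None = None,
                     dtype=np.float32,
                     engine: str = "auto") -> list[TrainedModel]:
    """Train one network per config on shared data, in lockstep.

    All configs must share the batch size; learning rates, minimum deltas,
    patience and epoch budgets may differ per model.  Weight initialization
    is seeded per config; the mini-batch shuffling stream is shared across
    the population (``perm_seed``), which keeps every model's training
    deterministic while letting each step update all models with batched
    array arithmetic.  Models that hit their early-stopping criterion drop
    out of the population as training proceeds.

    ``engine`` selects the numerical backend: the vectorized NumPy
    reference implementation or the Numba kernels (``"auto"`` prefers Numba
    when it supports the topology).
    """
    X = np.ascontiguousarray(X, dtype=dtype)
    y = np.asarray(y, dtype=int)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    if np.unique(y).size == 1:
        warnings.warn("single-class training set: degenerate classifier",
                      stacklevel=2)
    M = len(configs)
    if M == 0:
        raise ValueError("no training configs")
    batch = configs[0].batch_size
    if any(c.batch_size != batch for c in configs):
        raise ValueError("population training requires one batch size")

    shapes = _param_shapes(input_length, spec)
    if shared_rng is not None:
        if M != 1:
            raise ValueError("shared_rng only applies to a single model")
        perm_rng = shared_rng
        inits = [_glorot_init(shapes, shared_rng, dtype)]
    else:
        perm_rng = np.random.default_rng(
            perm_seed if perm_seed is not None else 0)
        inits = [_glorot_init(shapes, np.random.default_rng(cfg.seed), dtype)
                 for cfg in configs]
    lrs = [c.learning_rate for c in configs]
    eng = _make_engine(engine, input_length, spec, inits, lrs, dtype)

    min_delta = np.array([c.min_delta for c in configs])
    patience = np.array([c.patience_epochs for c in configs])
    max_epochs = np.array([c.max_epochs for c in configs])
    alive = np.arange(M)

    best_loss = np.full(M, np.inf)
    best_flat = eng.snapshot()
    best_epoch = np.full(M, -1)
    monitor_best = np.full(M, np.inf)
    wait = np.zeros(M, dtype=int)
    histories: list[list[float]] = [[] for _ in range(M)]

    epoch = 0
    while alive.size:
        perm = perm_rng.permutation(n)
        loss_sum = np.zeros(eng.M)
        for start in range(0, n, batch):
            sel = perm[start:start + batch]
            loss_sum += eng.step(X[sel], y[sel])
        epoch_loss = loss_sum / n
        for local, m in enumerate(alive):
            histories[m].append(float(epoch_loss[local]))
        improved = epoch_loss < best_loss[alive]
        if improved.any():
            snap = eng.snapshot()
            idx_imp = alive[improved]
            best_flat[idx_imp] = snap[improved]
            best_loss[idx_imp] = epoch_loss[improved]
            best_epoch[idx_imp] = epoch
        progressed = epoch_loss < monitor_best[alive] - min_delta[alive]
        monitor_best[alive[progressed]] = epoch_loss[progressed]
        wait[alive[progressed]] = 0
        wait[alive[~progressed]] += 1
        stop = (wait[alive] >= patience[alive]) \
            | (epoch + 1 >= max_epochs[alive])
        if stop.any():
            keep = ~stop
            eng.select(keep)
            alive = alive[keep]
        epoch += 1

    results = []
    for m, cfg in enumerate(configs):
        net = Network(input_length, spec, dtype=dtype)
        net.set_weights(eng.export_row(best_flat[m]))
        results.append(TrainedModel(network=net, history=histories[m],
                                    best_epoch=int(best_epoch[m]),
                                    best_loss=float(best_loss[m]),
                                    config=cfg))
    return results


def train_with_early_stopping(model: Network, X: np.ndarray, y: np.ndarray,
                              config: TrainingConfig = TrainingConfig()
                              ) -> TrainedModel:
    """Seeded mini-batch Adam training with checkpointing and early stopping.

    ``y`` holds integer class indices (0=low, 1=medium, 2=high).  The
    monitored quantity is the epoch-average training cross-entropy: weights
    are checkpointed whenever it reaches a new minimum, and training stops
    early once it has not improved by more than ``min_delta`` for
    ``patience_epochs`` consecutive epochs (or at ``max_epochs``).  The
    returned model carries the minimum-loss weights; ``model`` itself is
    updated in place with the same weights.
    """
    rng = np.random.default_rng(config.seed)
    trained = train_population(model.input_length, model.spec, [config],
                               X, y, shared_rng=rng, dtype=model.dtype)[0]
    model.set_weights(trained.network.params)
    trained.network = model
    return trained


def predict_classes(model: Network | TrainedModel, X: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Predicted class indices and probability vectors for spectra.

    The label is the argmax probability; exact ties break toward the lower
    class index.
    """
    net = model.network if isinstance(model, TrainedModel) else model
    probs = net.predict_proba(np.asarray(X, dtype=net.dtype))
    return probs.argmax(axis=1), probs
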
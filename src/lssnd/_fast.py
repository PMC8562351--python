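"""Numba-accelerated population training engine.

Activations and parameters are laid out with the model axis last and
contiguous; every kernel's innermost loop runs over that axis, so the
per-model multiply-accumulates vectorize.  The arithmetic mirrors the NumPy
engine in :mod:`lssnd.cnn` (same layer semantics, same Adam update); the
two are cross-checked in the test suite.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
    HAVE_NUMBA = True
except ImportError:          # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(fastmath=True, cache=True)
def _conv1_fwd(x, W, b, stride, out):
    # x (B, n); W (k, f, M); b (f, M)
    B = x.shape[0]
    k, f, M = W.shape
    a = np.empty((B, out, f, M), dtype=W.dtype)
    mask = np.empty((B, out, f, M), dtype=np.uint8)
    acc = np.empty(M, dtype=W.dtype)
    for bb in range(B):
        for o in range(out):
            base = o * stride
            for ff in range(f):
                for m in range(M):
                    acc[m] = b[ff, m]
                for j in range(k):
                    xv = x[bb, base + j]
                    for m in range(M):
                        acc[m] += xv * W[j, ff, m]
                for m in range(M):
                    if acc[m] > 0:
                        a[bb, o, ff, m] = acc[m]
                        mask[bb, o, ff, m] = 1
                    else:
                        a[bb, o, ff, m] = 0.0
                        mask[bb, o, ff, m] = 0
    return a, mask


@njit(fastmath=True, cache=True)
def _conv1_bwd(da, mask, x, stride, k):
    # da (B, out, f, M); x (B, n); returns dW (k, f, M), db (f, M)
    B, out, f, M = da.shape
    dW = np.zeros((k, f, M), dtype=da.dtype)
    db = np.zeros((f, M), dtype=da.dtype)
    g = np.empty(M, dtype=da.dtype)
    for bb in range(B):
        for o in range(out):
            base = o * stride
            for ff in range(f):
                for m in range(M):
                    g[m] = da[bb, o, ff, m] if mask[bb, o, ff, m] else 0.0
                    db[ff, m] += g[m]
                for j in range(k):
                    xv = x[bb, base + j]
                    for m in range(M):
                        dW[j, ff, m] += xv * g[m]
    return dW, db


@njit(fastmath=True, cache=True)
def _conv_fwd(a_in, W, b, stride, out):
    # a_in (B, n, c, M); W (k, c, f, M); b (f, M)
    B, n, c, M = a_in.shape
    k = W.shape[0]
    f = W.shape[2]
    a = np.empty((B, out, f, M), dtype=a_in.dtype)
    mask = np.empty((B, out, f, M), dtype=np.uint8)
    acc = np.empty(M, dtype=a_in.dtype)
    for bb in range(B):
        for o in range(out):
            base = o * stride
            for ff in range(f):
                for m in range(M):
                    acc[m] = b[ff, m]
                for j in range(k):
                    for cc in range(c):
                        for m in range(M):
                            acc[m] += a_in[bb, base + j, cc, m] \
                                * W[j, cc, ff, m]
                for m in range(M):
                    if acc[m] > 0:
                        a[bb, o, ff, m] = acc[m]
                        mask[bb, o, ff, m] = 1
                    else:
                        a[bb, o, ff, m] = 0.0
                        mask[bb, o, ff, m] = 0
    return a, mask


@njit(fastmath=True, cache=True)
def _conv_bwd(da, mask, a_in, W, stride):
    # returns dW (k,c,f,M), db (f,M), dx (B,n,c,M)
    B, out, f, M = da.shape
    k, c = W.shape[0], W.shape[1]
    dW = np.zeros((k, c, f, M), dtype=da.dtype)
    db = np.zeros((f, M), dtype=da.dtype)
    dx = np.zeros(a_in.shape, dtype=da.dtype)
    g = np.empty(M, dtype=da.dtype)
    for bb in range(B):
        for o in range(out):
            base = o * stride
            for ff in range(f):
                for m in range(M):
                    g[m] = da[bb, o, ff, m] if mask[bb, o, ff, m] else 0.0
                    db[ff, m] += g[m]
                for j in range(k):
                    for cc in range(c):
                        for m in range(M):
                            dW[j, cc, ff, m] += a_in[bb, base + j, cc, m] \
                                * g[m]
                            dx[bb, base + j, cc, m] += W[j, cc, ff, m] * g[m]
    return dW, db, dx


@njit(fastmath=True, cache=True)
def _pool_fwd(a_in, size, stride, out):
    B, n, c, M = a_in.shape
    val = np.empty((B, out, c, M), dtype=a_in.dtype)
    arg = np.empty((B, out, c, M), dtype=np.uint8)
    for bb in range(B):
        for o in range(out):
            base = o * stride
            for cc in range(c):
                for m in range(M):
                    best = a_in[bb, base, cc, m]
                    bidx = 0
                    for j in range(1, size):
                        v = a_in[bb, base + j, cc, m]
                        if v > best:
                            best = v
                            bidx = j
                    val[bb, o, cc, m] = best
                    arg[bb, o, cc, m] = bidx
    return val, arg


@njit(fastmath=True, cache=True)
def _pool_bwd(dval, arg, n, stride):
    B, out, c, M = dval.shape
    dx = np.zeros((B, n, c, M), dtype=dval.dtype)
    for bb in range(B):
        for o in range(out):
            base = o * stride
            for cc in range(c):
                for m in range(M):
                    dx[bb, base + arg[bb, o, cc, m], cc, m] += \
                        dval[bb, o, cc, m]
    return dx


@njit(fastmath=True, cache=True)
def _dense_fwd(a_in, W, b):
    # a_in (B, F, M); W (F, K, M); b (K, M) -> logits (B, K, M)
    B, F, M = a_in.shape
    K = W.shape[1]
    z = np.empty((B, K, M), dtype=a_in.dtype)
    for bb in range(B):
        for kk in range(K):
            for m in range(M):
                z[bb, kk, m] = b[kk, m]
            for f in range(F):
                for m in range(M):
                    z[bb, kk, m] += a_in[bb, f, m] * W[f, kk, m]
    return z


@njit(fastmath=True, cache=True)
def _dense_bwd(a_in, dz, W):
    B, F, M = a_in.shape
    K = W.shape[1]
    dW = np.zeros((F, K, M), dtype=dz.dtype)
    db = np.zeros((K, M), dtype=dz.dtype)
    dx = np.zeros((B, F, M), dtype=dz.dtype)
    for bb in range(B):
        for kk in range(K):
            for m in range(M):
                db[kk, m] += dz[bb, kk, m]
            for f in range(F):
                for m in range(M):
                    dW[f, kk, m] += a_in[bb, f, m] * dz[bb, kk, m]
                    dx[bb, f, m] += W[f, kk, m] * dz[bb, kk, m]
    return dW, db, dx


@njit(fastmath=True, cache=True)
def _adam_step(flat, grad, mstate, vstate, lr, t, beta1, beta2, eps):
    # flat (P, M); lr (M,)
    P, M = flat.shape
    b1t = 1.0 - beta1 ** t
    b2t = 1.0 - beta2 ** t
    for p in range(P):
        for m in range(M):
            g = grad[p, m]
            mstate[p, m] = beta1 * mstate[p, m] + (1.0 - beta1) * g
            vstate[p, m] = beta2 * vstate[p, m] + (1.0 - beta2) * g * g
            flat[p, m] -= lr[m] * (mstate[p, m] / b1t) / (
                np.sqrt(vstate[p, m] / b2t) + eps)


class NumbaEngine:
    """Population trainer state with model-last layout (P, M)."""

    def __init__(self, input_length, spec, init_params_per_model,
                 learning_rates, dtype=np.float32):
        from .cnn import _param_shapes, layer_plan
        if spec.conv_padding != "valid":
            raise ValueError("fast engine supports valid padding only")
        self.spec = spec
        self.input_length = int(input_length)
        self.plan = layer_plan(self.input_length, spec)
        self.shapes = _param_shapes(self.input_length, spec)
        self.dtype = np.dtype(dtype)
        M = len(init_params_per_model)
        self.offsets = {}
        off = 0
        for key, shape in self.shapes.items():
            size = int(np.prod(shape))
            self.offsets[key] = (off, off + size)
            off += size
        self.P = off
        self.flat = np.zeros((self.P, M), dtype=self.dtype)
        for m, params in enumerate(init_params_per_model):
            for key in self.shapes:
                lo, hi = self.offsets[key]
                self.flat[lo:hi, m] = params[key].ravel()
        self.mstate = np.zeros((self.P, M), dtype=np.float64)
        self.vstate = np.zeros((self.P, M), dtype=np.float64)
        self.lr = np.ascontiguousarray(learning_rates, dtype=np.float64)
        self.t = 0

    @property
    def M(self) -> int:
        return self.flat.shape[1]

    def _w(self, key):
        lo, hi = self.offsets[key]
        shape = self.shapes[key] + (self.M,)
        if key == "conv1_W":
            # stored (k, 1, f); drop the singleton channel for the kernel
            k, _, f = self.shapes[key]
            shape = (k, f, self.M)
        return self.flat[lo:hi].reshape(shape)

    def forward(self, X, cache=None):
        """Logits (M, B, K) for a shared (B, L) batch."""
        s = self.spec
        a = None
        for name, out, c_in, c_out in self.plan:
            if name == "conv1":
                a, mask = _conv1_fwd(X, self._w("conv1_W"),
                                     self._w("conv1_b"), s.conv_stride, out)
            elif name.startswith("conv"):
                prev = a
                a, mask = _conv_fwd(a, self._w(name + "_W"),
                                    self._w(name + "_b"), s.conv_stride, out)
                if cache is not None:
                    cache[name + "_in"] = prev
            elif name.startswith("pool"):
                prev_len = a.shape[1]
                a, arg = _pool_fwd(a, s.pool_size, s.pool_stride, out)
                if cache is not None:
                    cache[name] = (arg, prev_len)
            elif name == "flatten":
                if cache is not None:
                    cache["flatten_shape"] = a.shape
                a = a.reshape(a.shape[0], -1, a.shape[3])
            elif name == "dense":
                if cache is not None:
                    cache["dense_in"] = a
                a = _dense_fwd(a, self._w("dense_W"), self._w("dense_b"))
            if cache is not None and name.startswith("conv"):
                cache[name + "_mask"] = mask
        return np.ascontiguousarray(a.transpose(2, 0, 1))

    def step(self, xb, yb):
        """One mini-batch update for all models; returns summed losses (M,)."""
        cache: dict = {}
        logits = self.forward(xb, cache)          # (M, B, K)
        z = logits - logits.max(axis=2, keepdims=True)
        e = np.exp(z)
        se = e.sum(axis=2, keepdims=True)
        rows = np.arange(len(yb))
        loss_sum = np.log(se[:, :, 0]).sum(axis=1) \
            - z[:, rows, yb].sum(axis=1)
        dlog = e / se
        dlog[:, rows, yb] -= 1.0
        dlog /= len(yb)
        dlog = np.ascontiguousarray(dlog.transpose(1, 2, 0),
                                    dtype=self.dtype)  # (B, K, M)

        grad = np.empty((self.P, self.M), dtype=self.dtype)

        def put(key, arr):
            lo, hi = self.offsets[key]
            grad[lo:hi] = arr.reshape(hi - lo, self.M)

        dW, db, da = _dense_bwd(cache["dense_in"], dlog, self._w("dense_W"))
        put("dense_W", dW)
        put("dense_b", db)
        da = da.reshape(cache["flatten_shape"])
        for name, out, c_in, c_out in reversed(self.plan[:-2]):
            if name.startswith("pool"):
                arg, prev_len = cache[name]
                da = _pool_bwd(da, arg, prev_len, self.spec.pool_stride)
            elif name == "conv1":
                dW, db = _conv1_bwd(da, cache["conv1_mask"], xb,
                                    self.spec.conv_stride,
                                    self.spec.conv_kernel)
                put("conv1_W", dW)
                put("conv1_b", db)
            else:
                dW, db, da = _conv_bwd(da, cache[name + "_mask"],
                                       cache[name + "_in"],
                                       self._w(name + "_W"),
                                       self.spec.conv_stride)
                put(name + "_W", dW)
                put(name + "_b", db)

        self.t += 1
        _adam_step(self.flat, grad, self.mstate, self.vstate, self.lr,
                   self.t, 0.9, 0.999, 1e-8)
        return loss_sum

    def snapshot(self) -> np.ndarray:
        """Current parameters as (M, P)."""
        return self.flat.T.copy()

    def select(self, keep) -> None:
        self.flat = np.ascontiguousarray(self.flat[:, keep])
        self.mstate = np.ascontiguousarray(self.mstate[:, keep])
        self.vstate = np.ascontiguousarray(self.vstate[:, keep])
        self.lr = np.ascontiguousarray(self.lr[keep])

    def export_row(self, row: np.ndarray) -> dict:
        """Parameter dict from one (P,) snapshot row."""
        params = {}
        for key, shape in self.shapes.items():
            lo, hi = self.offsets[key]
            params[key] = row[lo:hi].reshape(shape).copy()
        return params
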
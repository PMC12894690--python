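"""JIT-compiled memory-movement kernels for the conv layers.

The 3x3x3 convolution is a large GEMM after an im2col gather; the gather
itself is memory-bound and dominated by strided small-chunk copies when done
with numpy slicing.  These numba kernels do the gather/scatter with tight
loops.  If numba is unavailable the numpy fallbacks keep everything working,
just slower.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=True)
def _im2col3_numba(xp, cols, d, h, w):  # pragma: no cover - exercised via wrapper
    # blocked over (b, i, j): the w-row of output and the 3x3 source slab
    # both fit in cache, so reads stay sequential and writes local
    n = xp.shape[0]
    c = xp.shape[4]
    for b in range(n):
        for i in range(d):
            for j in range(h):
                row0 = (b * d * h + i * h + j) * w
                col = 0
                for oi in range(3):
                    for oj in range(3):
                        for ok in range(3):
                            for cc in range(c):
                                for k in range(w):
                                    cols[row0 + k, col] = xp[
                                        b, i + oi, j + oj, k + ok, cc
                                    ]
                                col += 1


@njit(cache=True, fastmath=True)
def _col2im3_numba(dcols, dxp, d, h, w):  # pragma: no cover
    n = dxp.shape[0]
    c = dxp.shape[4]
    for b in range(n):
        for i in range(d):
            for j in range(h):
                row0 = (b * d * h + i * h + j) * w
                col = 0
                for oi in range(3):
                    for oj in range(3):
                        for ok in range(3):
                            for cc in range(c):
                                for k in range(w):
                                    dxp[b, i + oi, j + oj, k + ok, cc] += dcols[
                                        row0 + k, col
                                    ]
                                col += 1


_OFFSETS3 = [(i, j, k) for i in range(3) for j in range(3) for k in range(3)]


def _buffer(store: dict, key: str, shape: tuple, dtype) -> np.ndarray:
    """Persistent scratch array; fresh large allocations are page-fault bound,
    so layers reuse their workspaces across iterations."""
    buf = store.get(key)
    if buf is None or buf.shape != shape or buf.dtype != dtype:
        buf = np.empty(shape, dtype=dtype)
        store[key] = buf
    return buf


def im2col3(
    xp: np.ndarray, d: int, h: int, w: int, store: dict | None = None
) -> np.ndarray:
    """Gather 3x3x3 neighbourhoods of a padded (n, d+2, h+2, w+2, c) volume
    into a contiguous (n*d*h*w, 27*c) matrix."""
    n, _, _, _, c = xp.shape
    shape = (n * d * h * w, 27 * c)
    cols = (
        _buffer(store, "cols", shape, xp.dtype)
        if store is not None
        else np.empty(shape, dtype=xp.dtype)
    )
    if HAVE_NUMBA:
        _im2col3_numba(xp, cols, d, h, w)
    else:
        for o, (i, j, k) in enumerate(_OFFSETS3):
            cols[:, o * c : (o + 1) * c] = xp[
                :, i : i + d, j : j + h, k : k + w, :
            ].reshape(-1, c)
    return cols


def col2im3(
    dcols: np.ndarray,
    n: int,
    d: int,
    h: int,
    w: int,
    c: int,
    store: dict | None = None,
) -> np.ndarray:
    """Scatter-add column gradients back to a padded volume gradient."""
    shape = (n, d + 2, h + 2, w + 2, c)
    dxp = (
        _buffer(store, "dxp", shape, dcols.dtype)
        if store is not None
        else np.empty(shape, dtype=dcols.dtype)
    )
    dxp[...] = 0.0
    if HAVE_NUMBA:
        _col2im3_numba(dcols, dxp, d, h, w)
    else:
        for o, (i, j, k) in enumerate(_OFFSETS3):
            dxp[:, i : i + d, j : j + h, k : k + w, :] += dcols[
                :, o * c : (o + 1) * c
            ].reshape(n, d, h, w, c)
    return dxp


@njit(cache=True, fastmath=True)
def _to_blocks_numba(x, out):  # pragma: no cover
    n, d, h, w, c = x.shape
    for b in range(n):
        for i in range(d // 2):
            for j in range(h // 2):
                for k in range(w // 2):
                    col = 0
                    for oi in range(2):
                        for oj in range(2):
                            for ok in range(2):
                                for cc in range(c):
                                    out[b, i, j, k, col] = x[
                                        b, 2 * i + oi, 2 * j + oj, 2 * k + ok, cc
                                    ]
                                    col += 1


@njit(cache=True, fastmath=True)
def _from_blocks_numba(y, out):  # pragma: no cover
    n, d2, h2, w2, _ = y.shape
    c = out.shape[4]
    for b in range(n):
        for i in range(d2):
            for j in range(h2):
                for k in range(w2):
                    col = 0
                    for oi in range(2):
                        for oj in range(2):
                            for ok in range(2):
                                for cc in range(c):
                                    out[b, 2 * i + oi, 2 * j + oj, 2 * k + ok, cc] = y[
                                        b, i, j, k, col
                                    ]
                                    col += 1


def to_blocks(x: np.ndarray, store: dict | None = None, key: str = "blk") -> np.ndarray:
    """(N, D, H, W, C) -> (N, D/2, H/2, W/2, 8C) by 2-cube flattening."""
    n, d, h, w, c = x.shape
    shape = (n, d // 2, h // 2, w // 2, 8 * c)
    out = (
        _buffer(store, key, shape, x.dtype)
        if store is not None
        else np.empty(shape, dtype=x.dtype)
    )
    if HAVE_NUMBA:
        _to_blocks_numba(np.ascontiguousarray(x), out)
    else:
        xr = x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
        out[...] = xr.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(out.shape)
    return out


def from_blocks(
    y: np.ndarray, c: int, store: dict | None = None, key: str = "unblk"
) -> np.ndarray:
    """Inverse of :func:`to_blocks`."""
    n, d2, h2, w2, _ = y.shape
    shape = (n, d2 * 2, h2 * 2, w2 * 2, c)
    out = (
        _buffer(store, key, shape, y.dtype)
        if store is not None
        else np.empty(shape, dtype=y.dtype)
    )
    if HAVE_NUMBA:
        _from_blocks_numba(np.ascontiguousarray(y), out)
    else:
        yr = y.reshape(n, d2, h2, w2, 2, 2, 2, c)
        out[...] = yr.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(out.shape)
    return out
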
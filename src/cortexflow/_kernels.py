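"""Numba kernels for the hot loops (batched sparse lateral interactions).

The settling dynamics apply a fixed sparse lateral operator to a dense
activity matrix whose columns are (tile, sequence) pairs; scipy's CSR
matmul is column-at-a-time and becomes the bottleneck, so a row-accumulator
kernel is used for wide right-hand sides.
"""

from __future__ import annotations

import numba
import numpy as np
import scipy.sparse as sp

_COL_CHUNK = 4096  # keep the per-row accumulator inside L1/L2


@numba.njit(cache=True)
def _csr_matmul_kernel(indptr, indices, data, X, out):  # pragma: no cover
    nrow = indptr.shape[0] - 1
    B = X.shape[1]
    for i in range(nrow):
        acc = np.zeros(B, dtype=X.dtype)
        for p in range(indptr[i], indptr[i + 1]):
            w = data[p]
            j = indices[p]
            for b in range(B):
                acc[b] += w * X[j, b]
        out[i, :] = acc


def csr_matmul(m: sp.csr_matrix, X: np.ndarray) -> np.ndarray:
    """``m @ X`` for a CSR matrix and a C-contiguous dense matrix."""
    X = np.ascontiguousarray(X)
    data = m.data.astype(X.dtype, copy=False)
    out = np.empty((m.shape[0], X.shape[1]), dtype=X.dtype)
    for c0 in range(0, X.shape[1], _COL_CHUNK):
        c1 = min(c0 + _COL_CHUNK, X.shape[1])
        _csr_matmul_kernel(
            m.indptr, m.indices, data,
            np.ascontiguousarray(X[:, c0:c1]), out[:, c0:c1],
        )
    return out
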
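"""MT-analogue mid-stages over mosaic tile responses.

Two alternatives read the front-end mosaic:

* the cell-plane network (CPNW): 8 independent planes of grid x grid
  neurons; plane n trains only on direction-n translational sequences with a
  normalized Hebbian rule, so each plane becomes a template for one motion
  direction.  Classification takes the plane with maximal summed activity,
  using plane labels recorded on the training set.

* the winner-take-all Hebbian network (HBNW): grid x grid columns of 8
  competing neurons; per presentation only the maximally active neuron of
  each column updates (and only its weights are renormalized), carving the
  continuum of local motion directions into per-column clusters.

Both read the same geometry: neuron (p, q) receives the full response of
tile (p, q).  Activations are logistic sigmoids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np


def logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _as_tiles(Z) -> np.ndarray:
    """Accept a MosaicResponse or a (T, n) array."""
    return Z.tiles if hasattr(Z, "tiles") else np.asarray(Z)


@dataclass
class CellPlaneNet:
    """Independent direction-tuned planes over the tile grid."""

    W: np.ndarray  # (n_planes, T, n_in); rows (plane, tile) sum to 1
    plane_labels: np.ndarray | None = None  # class label of each plane
    grid: int = 16

    @property
    def n_planes(self) -> int:
        return self.W.shape[0]


def cpnw_response(net: CellPlaneNet, Z) -> np.ndarray:
    """C[n, p, q] = logistic(sum_rs W[n, pq, rs] * Z[pq, rs])."""
    tiles = _as_tiles(Z)
    if tiles.shape[0] != net.W.shape[1]:
        raise ValueError(
            f"tile count {tiles.shape[0]} != net geometry {net.W.shape[1]}"
        )
    C = logistic(np.einsum("ntr,tr->nt", net.W, tiles))
    return C.reshape(net.n_planes, net.grid, net.grid)


def cpnw_feature_vector(net: CellPlaneNet, Z) -> np.ndarray:
    """The 8 plane activities flattened and concatenated (length 8*T)."""
    return cpnw_response(net, Z).ravel()


def cpnw_train(
    train_responses,
    train_labels,
    n_classes: int = 8,
    epochs: int = 1000,
    lr: float = 0.05,
    seed=None,
    grid: int = 16,
) -> CellPlaneNet:
    """Train one plane per class on that class's responses only.

    Per sequence presentation: C = logistic(W . Z), then
    W <- normalize(W + lr * Z * C) row-wise (the rule's built-in
    normalization).  Plane labels are recorded afterwards as the winning
    plane per class on the training set.
    """
    Zs = np.stack([_as_tiles(z) for z in train_responses])  # (S, T, n_in)
    y = np.asarray(train_labels)
    present = np.unique(y)
    if len(present) < n_classes:
        missing = sorted(set(range(n_classes)) - set(present.tolist()))
        raise ValueError(f"missing training subsets for classes {missing}")
    rng = np.random.default_rng(seed)
    S, T, R = Zs.shape
    W = rng.random((n_classes, T, R))
    W /= W.sum(axis=2, keepdims=True)
    net = CellPlaneNet(W=W, grid=grid)
    for n in range(n_classes):
        Zn = Zs[y == n]
        for _ in range(epochs):
            for z in Zn:
                C = logistic(np.einsum("tr,tr->t", W[n], z))
                W[n] += lr * z * C[:, None]
                W[n] /= W[n].sum(axis=1, keepdims=True)
    # record the winning plane per class on the training set
    win = np.zeros((n_classes, n_classes), dtype=int)
    for z, l in zip(Zs, y):
        scores = cpnw_response(net, z).reshape(n_classes, -1).sum(axis=1)
        win[l, scores.argmax()] += 1
    net.plane_labels = win.argmax(axis=0)
    return net


def cpnw_classify(net: CellPlaneNet, Z) -> int:
    """Label of the plane with maximal summed activity."""
    if net.plane_labels is None:
        raise ValueError("plane labels not recorded; train the net first")
    scores = cpnw_response(net, Z).reshape(net.n_planes, -1).sum(axis=1)
    return int(net.plane_labels[scores.argmax()])


def cpnw_accuracy(net: CellPlaneNet, responses, labels) -> float:
    preds = np.array([cpnw_classify(net, z) for z in responses])
    return float((preds == np.asarray(labels)).mean())


@dataclass
class HebbNet:
    """Winner-take-all columns of competing neurons over the tile grid."""

    W: np.ndarray  # (T, K, n_in)
    grid: int = 16

    @property
    def n_per_column(self) -> int:
        return self.W.shape[1]


def hbnw_response_and_winners(net: HebbNet, Z):
    """Post-sigmoid activities (T, K) and per-column winner indices (T,).

    Ties break toward the lowest neuron index.
    """
    tiles = _as_tiles(Z)
    C = logistic(np.einsum("tkr,tr->tk", net.W, tiles))
    return C, C.argmax(axis=1)


def hbnw_feature_vector(net: HebbNet, Z) -> np.ndarray:
    """All column activities flattened (length T*K; 2048 for the DSMN grid)."""
    C, _ = hbnw_response_and_winners(net, Z)
    return C.ravel()


@numba.njit(cache=True)
def _hbnw_train_kernel(W, Zs, order, lr):  # pragma: no cover
    T, K, R = W.shape
    for s in order:
        for t in range(T):
            z = Zs[s, t]
            best = 0
            bestv = -1e300
            for k in range(K):
                acc = 0.0
                for r in range(R):
                    acc += W[t, k, r] * z[r]
                if acc > bestv:
                    bestv = acc
                    best = k
            c = 1.0 / (1.0 + np.exp(-bestv))
            ssum = 0.0
            for r in range(R):
                W[t, best, r] += lr * z[r] * c
                ssum += W[t, best, r]
            for r in range(R):
                w = W[t, best, r] / ssum
                # flush vanishing weights to exact zero (avoids denormals)
                W[t, best, r] = w if w > 1e-30 else 0.0


@numba.njit(cache=True)
def _hbnw_train_kernel_sparse(W, indptr, indices, data, order, T, lr):  # pragma: no cover
    # identical update rule; the per-presentation tile responses are CSR
    # rows (row = s*T + t), exploiting the sparsity of the settled code
    K, R = W.shape[1], W.shape[2]
    for s in order:
        for t in range(T):
            row = s * T + t
            p0, p1 = indptr[row], indptr[row + 1]
            best = 0
            bestv = -1e300
            for k in range(K):
                acc = 0.0
                for p in range(p0, p1):
                    acc += W[t, k, indices[p]] * data[p]
                if acc > bestv:
                    bestv = acc
                    best = k
            c = 1.0 / (1.0 + np.exp(-bestv))
            ssum = 0.0
            for r in range(R):
                ssum += W[t, best, r]
            for p in range(p0, p1):
                ssum += lr * data[p] * c
                W[t, best, indices[p]] += lr * data[p] * c
            for r in range(R):
                w = W[t, best, r] / ssum
                W[t, best, r] = w if w > 1e-30 else 0.0


def hbnw_train(
    train_responses,
    n_per_column: int = 8,
    epochs: int = 10000,
    lr: float = 0.05,
    seed=None,
    grid: int = 16,
) -> HebbNet:
    """Competitive learning over the whole (mixed-direction) training set.

    Per presentation only the winner of each column updates, and only the
    winner's weight vector is renormalized to unit sum.  Presentation order
    is reshuffled every epoch.
    """
    Zs = np.stack([_as_tiles(z) for z in train_responses]).astype(np.float64)
    rng = np.random.default_rng(seed)
    S, T, R = Zs.shape
    W = rng.random((T, n_per_column, R))
    W /= W.sum(axis=2, keepdims=True)
    order = np.concatenate([rng.permutation(S) for _ in range(epochs)])
    density = np.count_nonzero(Zs) / Zs.size
    if density < 0.25:
        import scipy.sparse as sp

        Zc = sp.csr_matrix(Zs.reshape(S * T, R))
        _hbnw_train_kernel_sparse(
            W, Zc.indptr, Zc.indices, Zc.data, order, T, lr
        )
    else:
        _hbnw_train_kernel(W, Zs, order, lr)
    return HebbNet(W=W, grid=grid)
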
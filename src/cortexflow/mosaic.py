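"""Mosaics of neural-field tiles covering the 80x80 image.

The direction-selective mosaic (DSMN) tiles the image with a 16x16 grid of
20x20-neuron fields, each reading one 5x5 window; the velocity-selective
mosaic (VSMN) uses a 10x10 grid of 48x48-neuron fields over 8x8 windows.
Tiles are trained on locally generated single-dot sequences; with
``share_weights`` one tile is trained and copied to all grid positions
(always used for the VSMN, and the desk-scale option for the DSMN).

Downstream stages consume the settled activity after the final frame of a
sequence, per tile and concatenated into a single 2D image
(16*20 = 320 px for the DSMN, 10*48 = 480 px for the VSMN).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from . import neural_field as nf
from ._kernels import csr_matmul
from .neural_field import FieldParams, FieldState

_BATCH_COLS = 8192  # column budget for the batched settle (memory bound)


class GeometryError(ValueError):
    """Tile grid and receptive field do not tile the image."""


@dataclass(frozen=True)
class MosaicConfig:
    grid: int
    tile_params: FieldParams
    share_weights: bool = True
    side: int = 80

    def __post_init__(self):
        if self.grid * self.tile_params.rf != self.side:
            raise GeometryError(
                f"grid {self.grid} x rf {self.tile_params.rf} != side {self.side}"
            )


#: Paper geometries.
def dsmn_config(tile_params: FieldParams | None = None, share_weights: bool = True):
    return MosaicConfig(16, tile_params or nf.DSMN_TILE, share_weights)


def vsmn_config(tile_params: FieldParams | None = None, share_weights: bool = True):
    return MosaicConfig(10, tile_params or nf.VSMN_TILE, share_weights)


@dataclass
class MosaicResponse:
    """Per-tile settled activity and its concatenated 2D image."""

    tiles: np.ndarray  # (grid*grid, dims*dims)
    grid: int
    dims: int

    @property
    def concat(self) -> np.ndarray:
        """Tiled 2D image of all activities, shape (grid*dims, grid*dims)."""
        g, d = self.grid, self.dims
        return (
            self.tiles.reshape(g, g, d, d)
            .transpose(0, 2, 1, 3)
            .reshape(g * d, g * d)
        )

    @property
    def flat(self) -> np.ndarray:
        return self.tiles.ravel()


@dataclass
class Mosaic:
    config: MosaicConfig
    tiles: list  # list of FieldState; length 1 when share_weights

    @property
    def n_tiles(self) -> int:
        return self.config.grid ** 2

    def tile(self, index: int) -> FieldState:
        if self.config.share_weights:
            return self.tiles[0]
        return self.tiles[index]


def train_mosaic(
    config: MosaicConfig, training_set: Sequence, seed=None
) -> Mosaic:
    """Train the mosaic's tiles on the local stimulus set.

    With ``share_weights`` a single tile is trained and replicated; otherwise
    every tile trains independently from its own spawned seed, so tile
    preferences vary across the mosaic.
    """
    if config.share_weights:
        return Mosaic(config, [nf.train_field(config.tile_params, training_set, seed)])
    seeds = np.random.SeedSequence(seed).spawn(config.grid ** 2)
    states = [
        nf.train_field(config.tile_params, training_set, s) for s in seeds
    ]
    return Mosaic(config, states)


def _patches(frame: np.ndarray, grid: int, rf: int) -> np.ndarray:
    """Split a (side, side) frame into (grid*grid, rf*rf) tile windows."""
    return (
        frame.reshape(grid, rf, grid, rf)
        .transpose(0, 2, 1, 3)
        .reshape(grid * grid, rf * rf)
    )


def _lateral_operator(state: FieldState) -> sp.csr_matrix:
    """gamma_exc * E - gamma_inhb * I as one CSR matrix (inference only)."""
    p = state.params
    L = (p.gamma_exc * state.E - p.gamma_inhb * state.I).tocsr()
    L.sort_indices()
    return L


def mosaic_responses(mosaic: Mosaic, sequences: Sequence, dtype=np.float32):
    """End-of-sequence settled responses for a batch of sequences.

    Weights are never modified (inference mode).  For shared-weight mosaics
    all (tile, sequence) columns settle in one batched sparse matmul; for
    independent tiles each tile's operator is applied to its own columns.
    Returns a list of :class:`MosaicResponse`.
    """
    cfg = mosaic.config
    p = cfg.tile_params
    grid, rf, n = cfg.grid, p.rf, p.dims ** 2
    T = grid * grid
    seqs = list(sequences)
    out = [None] * len(seqs)

    n_per_batch = max(1, _BATCH_COLS // T)
    for b0 in range(0, len(seqs), n_per_batch):
        batch = seqs[b0 : b0 + n_per_batch]
        S = len(batch)
        n_frames = batch[0].frames.shape[0]
        if any(s.frames.shape[0] != n_frames for s in batch):
            n_frames = None  # ragged: fall back to per-sequence
        if any(s.frames.shape[1] != cfg.side for s in batch):
            raise GeometryError("sequence frame side does not match mosaic")

        if cfg.share_weights and n_frames is not None:
            st = mosaic.tiles[0]
            L = _lateral_operator(st)
            W = st.W_aff.astype(dtype)
            eta = np.zeros((n, T * S), dtype=dtype)
            for f in range(n_frames):
                P = np.concatenate(
                    [_patches(s.frames[f].astype(dtype), grid, rf) for s in batch]
                )  # (T*S, rf*rf)
                A = nf.pwl_sigmoid(p.gamma_aff * (W @ P.T), p.aff_window)
                for _ in range(p.settle_steps):
                    drive = A + csr_matmul(L, eta)
                    if p.decay:
                        drive -= p.decay * eta
                    eta = nf.pwl_sigmoid(drive, p.settle_window)
            for si in range(S):
                out[b0 + si] = MosaicResponse(
                    eta[:, si * T : (si + 1) * T].T.astype(np.float64),
                    grid, p.dims,
                )
        else:
            for si, s in enumerate(batch):
                out[b0 + si] = _response_one(mosaic, s)
    return out


def _response_one(mosaic: Mosaic, sequence) -> MosaicResponse:
    cfg = mosaic.config
    p = cfg.tile_params
    grid, rf, n = cfg.grid, p.rf, p.dims ** 2
    T = grid * grid
    ops = [_lateral_operator(mosaic.tile(t)) for t in range(T)] \
        if not cfg.share_weights else [_lateral_operator(mosaic.tiles[0])] * T
    Ws = [mosaic.tile(t).W_aff for t in range(T)] \
        if not cfg.share_weights else [mosaic.tiles[0].W_aff] * T
    etas = np.zeros((T, n))
    for fr in sequence.frames:
        P = _patches(fr.astype(float), grid, rf)
        for t in range(T):
            A = nf.pwl_sigmoid(p.gamma_aff * (Ws[t] @ P[t]), p.aff_window)
            e = etas[t]
            for _ in range(p.settle_steps):
                drive = A + ops[t] @ e
                if p.decay:
                    drive = drive - p.decay * e
                e = nf.pwl_sigmoid(drive, p.settle_window)
            etas[t] = e
    return MosaicResponse(etas, grid, p.dims)


def mosaic_response(mosaic: Mosaic, sequence) -> MosaicResponse:
    """End-of-sequence response to a single sequence (inference mode)."""
    return mosaic_responses(mosaic, [sequence])[0]
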
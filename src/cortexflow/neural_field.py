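"""Neural-field engine: afferent drive, lateral settling, Hebbian learning.

One field ("tile") is a ``dims x dims`` sheet of rate neurons that all read
the same ``rf x rf`` image window.  Each neuron carries three weight sets:

* afferent weights ``W`` onto the window pixels (symmetric Hebbian rule),
* excitatory lateral weights ``E`` from neurons in the punctured Euclidean
  disc ``0 < d <= r_exc``,
* inhibitory lateral weights ``I`` from the annulus ``r_exc < d <= r_inhb``,

the lateral weights adapted with the asymmetric Hebbian rule
``dW = alpha * max(0, eta(t) - eta(t-1)) * eta_pre(t-1)``, which is the sole
source of direction selectivity: it potentiates connections from neurons
active on the previous frame onto neurons whose activity rises on the
current frame, carving motion-order-specific chains into the sheet.

For each frame the field settles for a fixed number of lateral-interaction
steps; settling starts from the previous frame's settled activity (zeros at
sequence start), so the response at inference time depends on stimulus
history through both the carried activity and the learned asymmetric
laterals.

Activation functions are piecewise-linear sigmoids
``clip((x - lo) / (hi - lo), 0, 1)`` with separate windows for the afferent
stage and the settling stage.  After every update each weight vector is
renormalized to a fixed total mass (1 for afferent and excitatory weights;
a larger configurable mass for inhibitory weights so that total inhibition
exceeds total excitation and the sheet operates in a sparse competitive
regime rather than saturating).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp


class LateralConfigError(ValueError):
    """Invalid lateral-radius configuration (requires r_exc < r_inhb)."""


@dataclass(frozen=True)
class FieldParams:
    """All tunable parameters of one neural-field tile.

    ``dims``/``rf`` set the geometry; the gamma values scale afferent,
    excitatory and inhibitory drive; the alpha values are Hebbian learning
    rates; ``settle_steps`` is the fixed settling iteration count; ``decay``
    is the activity self-decay used by velocity-selective fields.
    ``aff_window`` and ``settle_window`` are the (lo, hi) thresholds of the
    two piecewise-linear sigmoids, and ``inhb_mass`` the total inhibitory
    weight mass per neuron.
    """

    dims: int = 20
    rf: int = 5
    r_exc: float = 2.0
    r_inhb: float = 5.0
    gamma_aff: float = 1.0
    gamma_exc: float = 21.6
    gamma_inhb: float = 1.0
    alpha_aff: float = 0.05
    alpha_exc: float = 0.05
    alpha_inhb: float = 0.05
    settle_steps: int = 10
    decay: float = 0.0
    epochs: int = 500
    aff_window: tuple = (0.0, 0.08)
    settle_window: tuple = (0.5, 12.0)
    exc_mass: float = 1.0
    inhb_mass: float = 40.0

    def __post_init__(self):
        if self.r_inhb <= self.r_exc:
            raise LateralConfigError(
                f"r_inhb ({self.r_inhb}) must exceed r_exc ({self.r_exc})"
            )
        if min(self.gamma_aff, self.gamma_exc, self.gamma_inhb) <= 0:
            raise ValueError("gamma factors must be positive")
        if self.settle_steps <= 0:
            raise ValueError("settle_steps must be positive")
        if self.decay < 0:
            raise ValueError("decay must be nonnegative")


#: Table of defaults for the direction-selective (DSMN) tiles.
DSMN_TILE = FieldParams()

#: Table of defaults for the velocity-selective (VSMN) tiles.
VSMN_TILE = FieldParams(
    dims=48,
    rf=8,
    r_exc=2.0,
    r_inhb=4.0,
    gamma_exc=50.0,
    gamma_inhb=1.5,
    settle_steps=10,
    decay=0.01,
    epochs=250,
    aff_window=(0.0, 0.08),
    settle_window=(0.5, 35.0),
    inhb_mass=75.0,
)


def pwl_sigmoid(x, window):
    """Piecewise-linear sigmoid: clip((x - lo)/(hi - lo), 0, 1)."""
    lo, hi = window
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def lateral_masks(dims: int, r_exc: float, r_inhb: float):
    """Boolean CSR adjacency for excitatory disc and inhibitory annulus.

    Excitation connects neuron (i,j) to neurons at Euclidean distance
    0 < d <= r_exc (self excluded); inhibition covers r_exc < d <= r_inhb.
    Neighborhoods truncate at the grid edge (tiles are independent patches,
    no toroidal wrap).
    """
    if r_inhb <= r_exc:
        raise LateralConfigError("r_inhb must exceed r_exc")

    def offsets(r2lo, r2hi):
        R = int(np.floor(np.sqrt(r2hi)))
        out = []
        for dx in range(-R, R + 1):
            for dy in range(-R, R + 1):
                d2 = dx * dx + dy * dy
                if r2lo < d2 <= r2hi:
                    out.append((dx, dy))
        return out

    n = dims * dims
    ii, jj = np.meshgrid(np.arange(dims), np.arange(dims), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()

    def build(offs):
        rows, cols = [], []
        for dx, dy in offs:
            k, l = ii + dx, jj + dy
            ok = (k >= 0) & (k < dims) & (l >= 0) & (l < dims)
            rows.append(np.flatnonzero(ok))
            cols.append(k[ok] * dims + l[ok])
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        m = sp.csr_matrix(
            (np.ones(len(rows), bool), (rows, cols)), shape=(n, n)
        )
        m.sort_indices()
        return m

    return build(offsets(0.0, r_exc**2)), build(offsets(r_exc**2, r_inhb**2))


def _row_counts(m: sp.csr_matrix) -> np.ndarray:
    return np.diff(m.indptr)


def _renormalize_rows(m: sp.csr_matrix, mass: float) -> None:
    """Scale each row of ``m`` in place so it sums to ``mass`` (empty rows kept)."""
    if m.nnz == 0:
        return
    counts = _row_counts(m)
    sums = np.asarray(m.sum(axis=1)).ravel()
    sums[counts == 0] = 1.0
    np.maximum(sums, 1e-300, out=sums)
    m.data *= np.repeat(mass / sums, counts)


@dataclass
class FieldState:
    """Weights and activity of one neural field."""

    params: FieldParams
    W_aff: np.ndarray  # (n, rf*rf), rows sum to 1
    E: sp.csr_matrix  # (n, n) on the excitatory disc, rows sum to exc_mass
    I: sp.csr_matrix  # (n, n) on the annulus, rows sum to inhb_mass
    eta: np.ndarray  # settled activity of the most recent frame
    eta_prev: np.ndarray  # settled activity of the frame before

    _e_rows: np.ndarray = dc_field(default=None, repr=False)
    _i_rows: np.ndarray = dc_field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.params.dims ** 2

    def __post_init__(self):
        if self._e_rows is None:
            self._e_rows = np.repeat(np.arange(self.n), _row_counts(self.E))
        if self._i_rows is None:
            self._i_rows = np.repeat(np.arange(self.n), _row_counts(self.I))

    def reset_sequence(self) -> None:
        """Zero the carried activity at a sequence boundary."""
        self.eta = np.zeros(self.n)
        self.eta_prev = np.zeros(self.n)


def init_field(params: FieldParams, seed=None) -> FieldState:
    """Uniform-random weights on [0,1], renormalized to their target masses."""
    rng = np.random.default_rng(seed)
    n = params.dims ** 2
    e_mask, i_mask = lateral_masks(params.dims, params.r_exc, params.r_inhb)
    E = sp.csr_matrix(
        (rng.random(e_mask.nnz), e_mask.indices.copy(), e_mask.indptr.copy()),
        shape=e_mask.shape,
    )
    I = sp.csr_matrix(
        (rng.random(i_mask.nnz), i_mask.indices.copy(), i_mask.indptr.copy()),
        shape=i_mask.shape,
    )
    _renormalize_rows(E, params.exc_mass)
    _renormalize_rows(I, params.inhb_mass)
    W = rng.random((n, params.rf * params.rf))
    W /= W.sum(axis=1, keepdims=True)
    return FieldState(
        params=params, W_aff=W, E=E, I=I,
        eta=np.zeros(n), eta_prev=np.zeros(n),
    )


def afferent_response(state: FieldState, patch: np.ndarray) -> np.ndarray:
    """A = sigma(gamma_aff * W @ x) for one rf x rf window."""
    p = state.params
    x = np.asarray(patch, dtype=float).ravel()
    if x.size != p.rf * p.rf:
        raise ValueError(f"patch size {x.size} != rf^2 = {p.rf * p.rf}")
    return pwl_sigmoid(p.gamma_aff * (state.W_aff @ x), p.aff_window)


def settle(state: FieldState, A: np.ndarray, carry: bool = True) -> np.ndarray:
    """Iterate the lateral dynamics for ``settle_steps`` and return eta.

    eta(s) = sigma(A + g_exc E eta(s-1) - g_inhb I eta(s-1) - decay eta(s-1));
    eta(0) is the carried settled activity of the previous frame (zeros when
    ``carry`` is False or at sequence start).  Updates the state's eta /
    eta_prev bookkeeping.
    """
    p = state.params
    e = state.eta if carry else np.zeros(state.n)
    for _ in range(p.settle_steps):
        drive = (
            A
            + p.gamma_exc * (state.E @ e)
            - p.gamma_inhb * (state.I @ e)
            - p.decay * e
        )
        e = pwl_sigmoid(drive, p.settle_window)
    state.eta_prev = state.eta
    state.eta = e
    return e


def hebbian_updates(
    state: FieldState,
    patch: np.ndarray,
    eta_t: np.ndarray,
    eta_tm1: np.ndarray,
) -> FieldState:
    """Apply the symmetric (afferent) and asymmetric (lateral) Hebbian rules.

    dW_aff = alpha_aff * x * eta(t);
    dE, dI = alpha * max(0, eta(t) - eta(t-1)) * eta_pre(t-1);
    every weight vector is then renormalized to its fixed total mass.
    """
    p = state.params
    x = np.asarray(patch, dtype=float).ravel()
    state.W_aff += p.alpha_aff * np.outer(eta_t, x)
    sums = state.W_aff.sum(axis=1, keepdims=True)
    np.maximum(sums, 1e-300, out=sums)
    state.W_aff /= sums

    gain = np.maximum(0.0, eta_t - eta_tm1)
    state.E.data += p.alpha_exc * gain[state._e_rows] * eta_tm1[state.E.indices]
    state.I.data += p.alpha_inhb * gain[state._i_rows] * eta_tm1[state.I.indices]
    _renormalize_rows(state.E, p.exc_mass)
    _renormalize_rows(state.I, p.inhb_mass)
    return state


def present_frame(state: FieldState, frame: np.ndarray, learn: bool) -> np.ndarray:
    """Afferent -> settle -> (optionally) Hebbian updates for one frame."""
    A = afferent_response(state, frame)
    eta_t = settle(state, A)
    if learn:
        hebbian_updates(state, frame, eta_t, state.eta_prev)
    return eta_t


def respond(state: FieldState, sequence, learn: bool = False) -> np.ndarray:
    """End-of-sequence settled activity for a local rf x rf sequence."""
    frames = sequence.frames if hasattr(sequence, "frames") else sequence
    state.reset_sequence()
    eta = state.eta
    for fr in frames:
        eta = present_frame(state, fr, learn)
    return eta


def train_field(params: FieldParams, training_set: Sequence, seed=None) -> FieldState:
    """Train one field on local motion sequences.

    Weights start uniform-random (normalized); for every epoch each sequence
    is presented frame by frame, with settling and weight updates after each
    frame.  Returns the trained state.
    """
    if len(training_set) == 0:
        raise ValueError("training set is empty")
    state = init_field(params, seed)
    for _ in range(params.epochs):
        for seq in training_set:
            respond(state, seq, learn=True)
    state.reset_sequence()
    return state


def preference_map(state: FieldState, probes: Sequence) -> np.ndarray:
    """Per-neuron index of the probe class with maximal end-of-sequence response.

    Ties break toward the lowest class index.  Returns a dims x dims integer
    grid.
    """
    R = np.stack([respond(state, pr) for pr in probes])
    state.reset_sequence()
    return R.argmax(axis=0).reshape(state.params.dims, state.params.dims)
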
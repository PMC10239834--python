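"""Naive reference implementations used as independent oracles.

Everything here is deliberately written with per-neuron Python loops and
hand polar arithmetic, independent of the engine's vectorized code paths.
"""

from __future__ import annotations

import math

import numpy as np


def sigmoid_window(x, lo, hi):
    y = (x - lo) / (hi - lo)
    return min(1.0, max(0.0, y))


def neighbors(dims, i, j, r2lo, r2hi):
    """Integer grid offsets with r2lo < dx^2+dy^2 <= r2hi, truncated in-grid."""
    out = []
    for k in range(dims):
        for l in range(dims):
            d2 = (k - i) ** 2 + (l - j) ** 2
            if r2lo < d2 <= r2hi:
                out.append((k, l))
    return out


def settle_loop(W_aff, E_dense, I_dense, params, frames, carry=True):
    """Per-neuron loop settling over a sequence; returns per-frame etas.

    E_dense / I_dense are (n, n) dense weight matrices (zero off support).
    """
    n = W_aff.shape[0]
    lo_a, hi_a = params.aff_window
    lo_s, hi_s = params.settle_window
    eta = [0.0] * n
    per_frame = []
    for frame in frames:
        x = np.asarray(frame, dtype=float).ravel()
        A = [
            sigmoid_window(params.gamma_aff * sum(W_aff[i, r] * x[r] for r in range(len(x))), lo_a, hi_a)
            for i in range(n)
        ]
        e = list(eta) if carry else [0.0] * n
        for _ in range(params.settle_steps):
            new = []
            for i in range(n):
                exc = sum(E_dense[i, k] * e[k] for k in range(n))
                inh = sum(I_dense[i, k] * e[k] for k in range(n))
                drive = (
                    A[i]
                    + params.gamma_exc * exc
                    - params.gamma_inhb * inh
                    - params.decay * e[i]
                )
                new.append(sigmoid_window(drive, lo_s, hi_s))
            e = new
        eta = e
        per_frame.append(np.array(e))
    return per_frame


def hebbian_loop(W_aff, E_dense, I_dense, params, x, eta_t, eta_tm1,
                 exc_mass=1.0, inhb_mass=None):
    """Per-neuron Hebbian updates + mass renormalization (dense laterals)."""
    inhb_mass = params.inhb_mass if inhb_mass is None else inhb_mass
    n = len(eta_t)
    W = W_aff.copy()
    E = E_dense.copy()
    I = I_dense.copy()
    x = np.asarray(x, dtype=float).ravel()
    for i in range(n):
        for r in range(len(x)):
            W[i, r] += params.alpha_aff * x[r] * eta_t[i]
        s = W[i].sum()
        W[i] /= s
        gain = max(0.0, eta_t[i] - eta_tm1[i])
        for k in range(n):
            if E[i, k] != 0:
                E[i, k] += params.alpha_exc * gain * eta_tm1[k]
            if I[i, k] != 0:
                I[i, k] += params.alpha_inhb * gain * eta_tm1[k]
        se = E[i].sum()
        if se > 0:
            E[i] *= params.exc_mass / se
        si = I[i].sum()
        if si > 0:
            I[i] *= inhb_mass / si
    return W, E, I


def polar_step(x, y, cx, cy, kind, v):
    """Hand polar update for one dot (no re-seeding)."""
    theta = {
        "expansion": 0.0,
        "contraction": math.pi,
        "clockwise": -math.pi / 2,
        "anticlockwise": math.pi / 2,
    }[kind]
    m = math.hypot(x - cx, y - cy)
    phi = math.atan2(y - cy, x - cx)
    m2 = m + v * math.cos(theta)
    phi2 = phi + v * math.sin(theta)
    return cx + m2 * math.cos(phi2), cy + m2 * math.sin(phi2)
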
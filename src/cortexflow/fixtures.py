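"""Deterministic micro-fixtures: tiny fields and single-dot sequences.

Small enough that the settling dynamics and Hebbian updates can be
cross-checked against naive per-neuron loop oracles, and regenerable from
(name, seed) alone.
"""

from __future__ import annotations

import numpy as np

from . import neural_field as nf
from .stimuli import DotField, MotionSequence, MotionSpec, make_sequence


def tiny_field(
    dims: int = 3,
    rf: int = 3,
    r_exc: float = 1.0,
    r_inhb: float = 2.0,
    seed=0,
    **overrides,
) -> nf.FieldState:
    """A field small enough to enumerate every lateral neighborhood by hand."""
    params = nf.FieldParams(
        dims=dims,
        rf=rf,
        r_exc=r_exc,
        r_inhb=r_inhb,
        **{**dict(epochs=1), **overrides},
    )
    return nf.init_field(params, seed)


def single_dot_sequence(
    direction_deg: float,
    speed: float = 1.0,
    patch_side: int = 5,
    n_frames: int = 15,
    start=(2, 2),
    dot_extent: int = 1,
) -> MotionSequence:
    """One dot moving through a patch-sized frame with wrap-around."""
    if not (0 <= start[0] < patch_side and 0 <= start[1] < patch_side):
        raise ValueError(f"start {start} outside patch of side {patch_side}")
    field = DotField(
        positions=np.array([[float(start[0]), float(start[1])]]),
        dot_extent=dot_extent,
        window=patch_side,
        side=patch_side,
    )
    spec = MotionSpec(
        kind="translation",
        direction_deg=direction_deg,
        speed=speed,
        n_frames=n_frames,
    )
    return make_sequence(spec, field)
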
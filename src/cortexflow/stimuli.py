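"""Random-dot motion stimuli: translational, radial, and rotational sequences.

All frames are binary ``side x side`` images (white dots on black). Dot
anchors live in continuous coordinates ``(x, y)`` with the origin at the
top-left pixel, x growing rightward and y growing downward; rendering rounds
to the nearest pixel and wraps toroidally so that the number of dots is
conserved in every frame.

Translation advances each dot by ``(v cos(a), v sin(a))`` per frame.  Radial
and rotational flows update the polar coordinates ``(m, phi)`` of each dot
about the flow center: ``m <- m + v cos(theta)`` and
``phi <- phi + v sin(theta)``, where the flow-type angle ``theta`` is 0 for
expansion, pi for contraction, -pi/2 for clockwise and +pi/2 for
anti-clockwise rotation.  Dots contracted through the center (``m < 0``) are
re-seeded at the largest in-frame radius on the same ray, which keeps dot
density constant, mirroring the wrap-around rule used for translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

FlowKind = Literal["translation", "expansion", "contraction", "clockwise", "anticlockwise"]

#: flow-type angle theta: expansion 0, contraction pi, clockwise -pi/2,
#: anti-clockwise +pi/2
FLOW_THETA = {
    "expansion": 0.0,
    "contraction": np.pi,
    "clockwise": -np.pi / 2,
    "anticlockwise": np.pi / 2,
}
FLOW_KINDS = ("expansion", "contraction", "clockwise", "anticlockwise")
DIRECTIONS_DEG = (0, 45, 90, 135, 180, 225, 270, 315)


class InfeasibleDensityError(ValueError):
    """More dots requested than exclusion-grid cells available."""


@dataclass
class DotField:
    """A set of dot anchors under a one-anchor-per-window density constraint.

    positions : (n, 2) float array of (x, y) anchors in [0, side)
    dot_extent : side length of the rendered square per dot (1 or 2 px)
    window : exclusion-grid cell side; at most one anchor per cell at placement
    side : frame side length in pixels
    """

    positions: np.ndarray
    dot_extent: int
    window: int
    side: int

    @property
    def n_dots(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class MotionSpec:
    """Parameters of one motion sequence."""

    kind: FlowKind
    direction_deg: float = 0.0  # translational direction alpha; unused for flows
    speed: float = 1.0  # v, pixels per frame (translation) / per-step polar increment
    n_frames: int = 15
    center: tuple[float, float] | None = None  # flow center; None -> image center

    def resolved_center(self, side: int) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return (side / 2.0, side / 2.0)


@dataclass
class MotionSequence:
    """A rendered stack of binary frames with its generating spec."""

    frames: np.ndarray  # (n_frames, side, side) uint8 in {0, 1}
    spec: MotionSpec
    seed: int | None = None

    @property
    def side(self) -> int:
        return self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


def place_dots(
    n_dots: int, dot_extent: int, window: int, side: int, seed=None
) -> DotField:
    """Place ``n_dots`` anchors, at most one per ``window x window`` cell.

    Cells are chosen uniformly without replacement; within a chosen cell the
    anchor is uniform.  Raises :class:`InfeasibleDensityError` when more dots
    are requested than there are cells.
    """
    if side % window != 0:
        raise ValueError(f"window {window} does not divide side {side}")
    gw = side // window
    n_cells = gw * gw
    if n_dots > n_cells:
        raise InfeasibleDensityError(
            f"{n_dots} dots do not fit {n_cells} cells of side {window}"
        )
    rng = np.random.default_rng(seed)
    cells = rng.choice(n_cells, size=n_dots, replace=False)
    cx = (cells % gw) * window
    cy = (cells // gw) * window
    offs = rng.random((n_dots, 2)) * window
    pos = np.column_stack([cx + offs[:, 0], cy + offs[:, 1]])
    return DotField(positions=pos, dot_extent=dot_extent, window=window, side=side)


def translate_step(field: DotField, direction_deg: float, speed: float) -> DotField:
    """Advance every anchor by (v cos a, v sin a), wrapping modulo the side."""
    if speed <= 0:
        raise ValueError("speed must be positive")
    a = np.deg2rad(direction_deg)
    pos = field.positions + np.array([speed * np.cos(a), speed * np.sin(a)])
    pos %= field.side
    return replace(field, positions=pos)


def _max_ray_radius(phi: np.ndarray, center: tuple[float, float], side: int) -> np.ndarray:
    """Largest radius r >= 0 with center + r*(cos phi, sin phi) inside the frame."""
    cx, cy = center
    hi = side - 1.0
    r = np.full(phi.shape, np.inf)
    for c, u in ((cx, np.cos(phi)), (cy, np.sin(phi))):
        with np.errstate(divide="ignore"):
            t_lo = (0.0 - c) / u
            t_hi = (hi - c) / u
        t = np.where(u > 0, t_hi, np.where(u < 0, t_lo, np.inf))
        r = np.minimum(r, t)
    return np.maximum(r, 0.0)


def flow_step(
    field: DotField, kind: str, speed: float, center: tuple[float, float]
) -> DotField:
    """One radial/rotational step: m += v cos(theta), phi += v sin(theta).

    Dots whose radius would go negative (contraction through the center) are
    re-seeded at the maximum in-frame radius on the same ray, conserving dot
    count.  phi increments are radians.
    """
    theta = FLOW_THETA[kind]
    cx, cy = center
    dx = field.positions[:, 0] - cx
    dy = field.positions[:, 1] - cy
    m = np.hypot(dx, dy)
    phi = np.arctan2(dy, dx)
    m = m + speed * np.cos(theta)
    phi = phi + speed * np.sin(theta)
    under = m < 0
    if np.any(under):
        m = np.where(under, _max_ray_radius(phi, center, field.side), m)
    pos = np.column_stack([cx + m * np.cos(phi), cy + m * np.sin(phi)])
    return replace(field, positions=pos)


def render(field: DotField) -> np.ndarray:
    """Render anchors to a binary frame; squares wrap at borders (binary OR)."""
    f = np.zeros((field.side, field.side), dtype=np.uint8)
    if field.n_dots == 0:
        return f
    xi = np.rint(field.positions[:, 0]).astype(int) % field.side
    yi = np.rint(field.positions[:, 1]).astype(int) % field.side
    e = field.dot_extent
    for ddy in range(e):
        for ddx in range(e):
            f[(yi + ddy) % field.side, (xi + ddx) % field.side] = 1
    return f


def make_sequence(spec: MotionSpec, field: DotField, seed: int | None = None) -> MotionSequence:
    """Render ``spec.n_frames`` frames; frame k is the field after k-1 steps."""
    frames = [render(field)]
    cur = field
    center = spec.resolved_center(field.side)
    for _ in range(spec.n_frames - 1):
        if spec.kind == "translation":
            cur = translate_step(cur, spec.direction_deg, spec.speed)
        else:
            cur = flow_step(cur, spec.kind, spec.speed, center)
        frames.append(render(cur))
    return MotionSequence(frames=np.stack(frames), spec=spec, seed=seed)


@dataclass
class StimulusSet:
    """A labelled train/test partition of motion sequences."""

    train: list
    test: list
    train_labels: np.ndarray
    test_labels: np.ndarray
    classes: list
    train_configs: np.ndarray = field(default=None)
    test_configs: np.ndarray = field(default=None)


def _spawn_seeds(seed, n) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _single_dot_local(direction_deg, speed, patch_side, n_frames, start, extent) -> MotionSequence:
    f = DotField(
        positions=np.array([[float(start[0]), float(start[1])]]),
        dot_extent=extent,
        window=patch_side,
        side=patch_side,
    )
    spec = MotionSpec(kind="translation", direction_deg=direction_deg,
                      speed=speed, n_frames=n_frames)
    return make_sequence(spec, f)


def local_training_set(model_id: int) -> list[MotionSequence]:
    """The per-tile training sequences for the front-end neural fields.

    Models 1-2 (direction-selective tiles): a 1x1 dot moving in 8 directions
    from 3 start positions inside the 5x5 receptive field -> 24 sequences of
    15 frames.  Model 3 (velocity-selective tiles): a 2x2 dot moving in 8
    directions at speeds 1 and 2 inside the 8x8 receptive field -> 16
    sequences of 10 frames.
    """
    if model_id in (1, 2):
        starts = [(2, 2), (0, 0), (4, 4)]
        return [
            _single_dot_local(d, 1.0, 5, 15, st, 1)
            for d in DIRECTIONS_DEG
            for st in starts
        ]
    if model_id == 3:
        return [
            _single_dot_local(d, v, 8, 10, (3, 3), 2)
            for v in (1.0, 2.0)
            for d in DIRECTIONS_DEG
        ]
    raise ValueError(f"unknown model_id {model_id}")


def local_class_labels(model_id: int):
    """Class names matching :func:`local_training_set` probe order."""
    if model_id in (1, 2):
        return [f"{d}deg" for d in DIRECTIONS_DEG for _ in range(3)]
    return [f"{d}deg_v{int(v)}" for v in (1, 2) for d in DIRECTIONS_DEG]


def build_dataset(model_id: int, stage: str, n_configs: int = 15, seed=0) -> StimulusSet:
    """Build the labelled stimulus sets used to train and test each stage.

    stage ``translational``: ``n_configs`` dot configurations translated in 8
    directions; the first 2/3 of configs are the training split (paper counts:
    15 configs -> 120 sequences, 80 train / 40 test).  stage ``flow``: 4 flow
    types per configuration, one speed for models 1-2 (40/20) and two speeds
    for model 3 (80/40).  For model 3 the translational set also spans two
    speeds (240 sequences, 160/80).
    """
    if stage == "v1_local":
        seqs = local_training_set(model_id)
        labels = np.arange(len(seqs))
        return StimulusSet(seqs, [], labels, np.array([], dtype=int),
                           classes=local_class_labels(model_id))
    if stage not in ("translational", "flow"):
        raise ValueError(f"unknown stage {stage!r}")

    if model_id in (1, 2):
        n_dots, window, extent, n_frames, speeds = 64, 10, 1, 15, (1.0,)
    elif model_id == 3:
        n_dots, window, extent, n_frames, speeds = 100, 8, 2, 10, (1.0, 2.0)
    else:
        raise ValueError(f"unknown model_id {model_id}")

    n_train_cfg = (2 * n_configs) // 3
    cfg_seeds = _spawn_seeds(seed, n_configs)

    if stage == "translational":
        motions = [("translation", d, v) for v in speeds for d in DIRECTIONS_DEG]
        if len(speeds) == 1:
            classes = [f"{d}deg" for d in DIRECTIONS_DEG]
        else:
            classes = [f"{d}deg_v{int(v)}" for v in speeds for d in DIRECTIONS_DEG]
    else:
        motions = [(k, 0.0, v) for v in speeds for k in FLOW_KINDS]
        if len(speeds) == 1:
            classes = list(FLOW_KINDS)
        else:
            classes = [f"{k}_v{int(v)}" for v in speeds for k in FLOW_KINDS]

    train, test, ytr, yte, ctr, cte = [], [], [], [], [], []
    for c, cseed in enumerate(cfg_seeds):
        field0 = place_dots(n_dots, extent, window, 80, seed=cseed)
        for li, (kind, d, v) in enumerate(motions):
            spec = MotionSpec(kind=kind, direction_deg=d, speed=v, n_frames=n_frames)
            seq = make_sequence(spec, field0, seed=cseed)
            if c < n_train_cfg:
                train.append(seq); ytr.append(li); ctr.append(c)
            else:
                test.append(seq); yte.append(li); cte.append(c)
    return StimulusSet(train, test, np.array(ytr), np.array(yte), classes,
                       np.array(ctr), np.array(cte))
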
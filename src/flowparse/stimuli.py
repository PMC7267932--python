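"""Synthetic movie stimuli with exact ground-truth optic flow.

The experiment distinguishes five viewing conditions of a moving object
(a train) in a landscape:

* ``Offboard`` — stationary observer watches the moving object: the
  background is static, only the object translates on screen
  (pure object-motion).
* ``Onboard`` — observer rides the object looking ahead: the whole
  scene translates coherently, no separate object is visible
  (pure self-motion).
* ``Joint`` — observer moves alongside the object at matched velocity:
  the background flows but the object's screen position is fixed.
* ``Disjoint`` — observer and object both move, with different
  trajectories: background flow plus an independently moving object.
* ``Static`` — four held frames, no physical motion.

Because the original virtual-reality movies are not distributable, this
module renders 2D parametric stand-ins: band-limited random textures
translated by programmed integer displacements, with a distinct textured
rectangle composited as the object.  Every rendered movie comes with the
dense displacement field it was built from, which downstream code uses
as an oracle for block-matching motion estimates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

CONDITIONS = ("Offboard", "Onboard", "Joint", "Disjoint", "Static")
MOTION_CONDITIONS = ("Offboard", "Onboard", "Joint", "Disjoint")

#: seconds each held frame of a Static pseudo-movie is displayed
STATIC_FRAME_HOLD_S = 0.75

#: number of held frames in a Static pseudo-movie
STATIC_N_HELD = 4


class SceneSpecError(ValueError):
    """A scene specification violates a condition invariant."""


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames plus timing metadata.

    frames: array of shape (n_frames, height, width), values in [0, 255].
    """

    frames: np.ndarray
    frame_rate: float
    condition_label: str

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, height, width) array")
        if self.condition_label not in CONDITIONS:
            raise ValueError(f"unknown condition label {self.condition_label!r}")
        if self.condition_label != "Static" and self.n_frames < 2:
            raise ValueError("motion conditions need at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


@dataclass
class SceneSpec:
    """Parametric description of one movie trial.

    ``background_flow`` lists the global (dx, dy) displacement in pixels
    for each consecutive frame pair; ``object_trajectory`` lists the
    object's centre (x, y) for each frame, or is None when the condition
    has no visible object (Onboard).  Displacements must be integers so
    the rendered flow is exact.
    """

    condition_label: str
    background_flow: list[tuple[int, int]]
    object_trajectory: list[tuple[int, int]] | None
    object_size: int = 16
    texture_seed: int = 0
    frame_rate: float = 25.0
    frame_shape: tuple[int, int] = (64, 64)

    @property
    def n_frames(self) -> int:
        return len(self.background_flow) + 1

    def validate(self) -> None:
        if self.condition_label not in MOTION_CONDITIONS:
            raise SceneSpecError(
                f"renderable condition must be one of {MOTION_CONDITIONS}, "
                f"got {self.condition_label!r}"
            )
        if len(self.background_flow) < 1:
            raise SceneSpecError("need at least one frame pair")
        flow = np.asarray(self.background_flow)
        if not np.all(flow == np.round(flow)):
            raise SceneSpecError("background_flow displacements must be integers")
        bg_moves = bool(np.any(flow != 0))
        traj = None
        if self.object_trajectory is not None:
            traj = np.asarray(self.object_trajectory)
            if traj.shape != (self.n_frames, 2):
                raise SceneSpecError(
                    "object_trajectory must give one (x, y) centre per frame"
                )
            if not np.all(traj == np.round(traj)):
                raise SceneSpecError("object positions must be integers")
        obj_moves = traj is not None and bool(np.any(np.diff(traj, axis=0) != 0))

        label = self.condition_label
        if label == "Onboard":
            if traj is not None:
                raise SceneSpecError("Onboard scenes contain no object")
            if not bg_moves:
                raise SceneSpecError("Onboard requires nonzero background flow")
        elif label == "Offboard":
            if bg_moves:
                raise SceneSpecError("Offboard requires a static background")
            if traj is None or not obj_moves:
                raise SceneSpecError("Offboard requires a moving object")
        elif label == "Joint":
            if traj is None:
                raise SceneSpecError("Joint requires an object")
            if obj_moves:
                raise SceneSpecError(
                    "Joint requires a screen-stationary object centre"
                )
            if not bg_moves:
                raise SceneSpecError("Joint requires nonzero background flow")
        elif label == "Disjoint":
            if traj is None or not obj_moves:
                raise SceneSpecError("Disjoint requires a moving object")
            if not bg_moves:
                raise SceneSpecError("Disjoint requires nonzero background flow")


@dataclass
class GroundTruthFlow:
    """Dense per-pixel displacement field for each frame pair.

    ``flow`` has shape (n_pairs, height, width, 2) storing (dx, dy);
    object pixels (mask taken at the earlier frame of each pair,
    occluded background included) carry the object displacement,
    all other pixels carry the global background displacement.
    """

    flow: np.ndarray

    def __post_init__(self) -> None:
        self.flow = np.asarray(self.flow, dtype=float)
        if self.flow.ndim != 4 or self.flow.shape[-1] != 2:
            raise ValueError("flow must have shape (n_pairs, H, W, 2)")

    @property
    def n_pairs(self) -> int:
        return self.flow.shape[0]


def _band_limited_texture(
    shape: tuple[int, int], rng: np.random.Generator, smooth: float = 2.0
) -> np.ndarray:
    """Smooth random texture scaled to [0, 255].

    Filtering uses wrap-around boundaries so that integer np.roll shifts
    reproduce the texture exactly — rendered flow is then bit-true.
    Smoothness keeps the block-matching cost surface well behaved.
    """
    noise = rng.standard_normal(shape)
    tex = gaussian_filter(noise, smooth, mode="wrap")
    tex -= tex.min()
    peak = tex.max()
    if peak > 0:
        tex *= 255.0 / peak
    return tex


def _object_mask(
    shape: tuple[int, int], center: tuple[int, int], size: int
) -> np.ndarray:
    h, w = shape
    cx, cy = int(center[0]), int(center[1])
    half = size // 2
    x0, x1 = max(cx - half, 0), min(cx - half + size, w)
    y0, y1 = max(cy - half, 0), min(cy - half + size, h)
    mask = np.zeros(shape, dtype=bool)
    if x1 > x0 and y1 > y0:
        mask[y0:y1, x0:x1] = True
    return mask


def render_condition_movie(spec: SceneSpec) -> tuple[FrameSequence, GroundTruthFlow]:
    """Render one movie trial and its exact displacement field.

    The background is a band-limited texture translated globally by the
    programmed per-pair displacements (wrap-around shifts, so the flow
    is exact everywhere).  The object, when present, is a brighter,
    coarser-textured square composited on top at each trajectory point.
    """
    spec.validate()
    h, w = spec.frame_shape
    rng = np.random.default_rng(spec.texture_seed)
    background = _band_limited_texture((h, w), rng, smooth=2.0)
    # object texture: an independent draw with the same amplitude and
    # correlation statistics as the background, so matching costs on
    # object and background blocks are on a common scale and a block is
    # claimed by whichever surface dominates it
    obj_tex = _band_limited_texture(
        (spec.object_size, spec.object_size), rng, smooth=2.0
    )

    n = spec.n_frames
    frames = np.empty((n, h, w), dtype=float)
    flow = np.zeros((n - 1, h, w, 2), dtype=float)

    # cumulative integer background offset per frame
    offsets = np.zeros((n, 2), dtype=int)
    for t, (dx, dy) in enumerate(spec.background_flow):
        offsets[t + 1] = offsets[t] + (int(dx), int(dy))

    traj = (
        np.asarray(spec.object_trajectory, dtype=int)
        if spec.object_trajectory is not None
        else None
    )

    for t in range(n):
        frame = np.roll(background, shift=tuple(offsets[t][::-1]), axis=(0, 1))
        if traj is not None:
            half = spec.object_size // 2
            cx, cy = traj[t]
            x0, x1 = max(cx - half, 0), min(cx - half + spec.object_size, w)
            y0, y1 = max(cy - half, 0), min(cy - half + spec.object_size, h)
            if x1 > x0 and y1 > y0:
                frame[y0:y1, x0:x1] = obj_tex[
                    y0 - (cy - half) : y1 - (cy - half),
                    x0 - (cx - half) : x1 - (cx - half),
                ]
        frames[t] = np.clip(frame, 0.0, 255.0)

    for t in range(n - 1):
        flow[t, :, :, 0] = spec.background_flow[t][0]
        flow[t, :, :, 1] = spec.background_flow[t][1]
        if traj is not None:
            mask = _object_mask((h, w), traj[t], spec.object_size)
            dxy = traj[t + 1] - traj[t]
            flow[t][mask] = dxy

    seq = FrameSequence(frames, spec.frame_rate, spec.condition_label)
    return seq, GroundTruthFlow(flow)


def render_static_sequence(
    source_movies: list[FrameSequence],
    seed: int,
    frame_rate: float | None = None,
) -> FrameSequence:
    """Build a Static pseudo-movie of four held frames.

    One frame is drawn from each of four distinct source movies and held
    for 0.75 s at the output frame rate, yielding a sequence with no
    physical motion but the same luminance statistics as the movies.
    """
    if len(source_movies) < STATIC_N_HELD:
        raise ValueError(
            f"need at least {STATIC_N_HELD} source movies, got {len(source_movies)}"
        )
    rng = np.random.default_rng(seed)
    fps = frame_rate if frame_rate is not None else source_movies[0].frame_rate
    reps = int(round(STATIC_FRAME_HOLD_S * fps))
    if reps < 1:
        raise ValueError("frame rate too low to hold a frame for 0.75 s")
    picked = rng.choice(len(source_movies), size=STATIC_N_HELD, replace=False)
    held = []
    for idx in picked:
        movie = source_movies[int(idx)]
        f = int(rng.integers(movie.n_frames))
        held.append(np.repeat(movie.frames[f][None], reps, axis=0))
    return FrameSequence(np.concatenate(held, axis=0), fps, "Static")


def ground_truth_summary(flow: GroundTruthFlow) -> tuple[float, float]:
    """QoM and SoM computed directly on a dense ground-truth field.

    Applies the same definitions as the block-matching summary: QoM is
    the mean displacement amplitude across pixels and frame pairs; SoM
    is the standard deviation (degrees) of displacement orientations
    over nonzero pixels within each frame pair, averaged over pairs that
    contain any nonzero displacement.  Serves as the oracle against
    which estimated motion fields are scored.
    """
    f = flow.flow
    if f.size == 0:
        raise ValueError("empty flow")
    amp = np.hypot(f[..., 0], f[..., 1])
    qom = float(amp.mean())
    sds = []
    for t in range(f.shape[0]):
        nz = amp[t] > 0
        if not nz.any():
            continue
        ang = np.degrees(np.arctan2(f[t, ..., 1][nz], f[t, ..., 0][nz]))
        sds.append(float(np.std(ang)))
    som = float(np.mean(sds)) if sds else 0.0
    return qom, som


# ---------------------------------------------------------------------------
# Default trial-set generator
# ---------------------------------------------------------------------------

#: programmed per-frame background speeds (pixels/frame pair) per condition.
#: Chosen to mirror the ordering of motion energy across conditions measured
#: on the original movies: the Disjoint viewpoint carries the most screen
#: motion, running alongside the object (Joint) more than riding it
#: (Onboard), and a stationary observer (Offboard) sees only the object
#: move.  All speeds stay within the matcher's default +/-7 search range.
DEFAULT_SPEEDS = {"Onboard": 3, "Joint": 4, "Disjoint": 5}
DEFAULT_OFFBOARD_OBJECT_SPEED = 2

_DIRS = [(1, 0), (0, 1), (-1, 0), (0, -1), (1, 1), (-1, 1), (1, -1), (-1, -1)]

#: headings for conditions containing an object: restricted to the
#: right half-plane plus the vertical axes so that estimated
#: orientations stay clear of the +/-180 degree discontinuity of the
#: linear (non-circular) orientation-SD convention, where a one-pixel
#: vector error would otherwise flip the sign of the angle
_OBJ_SCENE_DIRS = [(1, 0), (0, 1), (0, -1), (1, 1), (1, -1)]


def make_trial_specs(
    seed: int,
    n_per_condition: int = 15,
    frame_shape: tuple[int, int] = (128, 128),
    n_frames: int = 8,
    object_size: int = 16,
) -> list[tuple[str, str, SceneSpec]]:
    """Build the motion-condition trial set for one scan.

    Returns (movie_id, condition, spec) triples, ``n_per_condition``
    trials for each of Offboard / Onboard / Joint / Disjoint.  Per-trial
    jitter (+/-1 px on speed, random headings) gives across-trial
    variance while preserving the programmed condition ordering of
    motion quantity.

    Object trajectories are confined to a macroblock-aligned horizontal
    band (and the Joint object sits on exactly one macroblock) so that
    the default 16 px matcher tessellation resolves the object cleanly:
    block-level motion summaries then agree closely with the dense
    ground-truth flow instead of being dominated by straddling-block
    quantisation.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    block = 16
    rows = h // block
    specs: list[tuple[str, str, SceneSpec]] = []
    for cond in MOTION_CONDITIONS:
        for i in range(n_per_condition):
            movie_id = f"{cond}_{i:02d}"
            tex_seed = int(rng.integers(2**31 - 1))
            jitter = int(rng.integers(-1, 2))
            # block-aligned band centre for the object (not at the border)
            band_row = int(rng.integers(1, max(rows - 1, 2)))
            cy = band_row * block + block // 2
            vsign = 1 if rng.integers(2) else -1
            if cond == "Offboard":
                speed = max(DEFAULT_OFFBOARD_OBJECT_SPEED + jitter, 1)
                traj = _bounded_walk(
                    (w // 2, cy), (speed, 0),
                    n_frames, frame_shape, object_size,
                )
                spec = SceneSpec(
                    "Offboard",
                    background_flow=[(0, 0)] * (n_frames - 1),
                    object_trajectory=traj,
                    object_size=object_size,
                    texture_seed=tex_seed,
                    frame_shape=frame_shape,
                )
            elif cond == "Onboard":
                speed = max(DEFAULT_SPEEDS["Onboard"] + jitter, 1)
                direction = _DIRS[int(rng.integers(len(_DIRS)))]
                bg = [(direction[0] * speed, direction[1] * speed)] * (n_frames - 1)
                spec = SceneSpec(
                    "Onboard", bg, None,
                    texture_seed=tex_seed, frame_shape=frame_shape,
                )
            elif cond == "Joint":
                speed = max(DEFAULT_SPEEDS["Joint"] + jitter, 1)
                # axis-aligned headings keep the flow magnitude equal to
                # the programmed speed (a diagonal step would inflate it
                # by sqrt(2) and blur the programmed condition ordering)
                direction = _OBJ_SCENE_DIRS[int(rng.integers(3))]
                bg = [(direction[0] * speed, direction[1] * speed)] * (n_frames - 1)
                # object covers exactly one macroblock
                cx = int(rng.integers(1, max(w // block - 1, 2))) * block + block // 2
                spec = SceneSpec(
                    "Joint", bg, [(cx, cy)] * n_frames,
                    object_size=object_size,
                    texture_seed=tex_seed, frame_shape=frame_shape,
                )
            else:  # Disjoint: vertical flow, object crossing horizontally
                speed = max(DEFAULT_SPEEDS["Disjoint"] + jitter, 1)
                bg = [(0, vsign * speed)] * (n_frames - 1)
                obj_speed = max(2 + jitter, 1)
                traj = _bounded_walk(
                    (w // 2, cy), (obj_speed, 0),
                    n_frames, frame_shape, object_size,
                )
                spec = SceneSpec(
                    "Disjoint", bg, traj,
                    object_size=object_size,
                    texture_seed=tex_seed, frame_shape=frame_shape,
                )
            specs.append((movie_id, cond, spec))
    return specs


def _bounded_walk(
    start: tuple[int, int],
    step: tuple[int, int],
    n_frames: int,
    frame_shape: tuple[int, int],
    object_size: int,
) -> list[tuple[int, int]]:
    """Constant-velocity trajectory that bounces off frame borders."""
    h, w = frame_shape
    half = object_size // 2
    lo_x, hi_x = half, w - (object_size - half)
    lo_y, hi_y = half, h - (object_size - half)
    x, y = start
    dx, dy = step
    traj = [(x, y)]
    for _ in range(n_frames - 1):
        if not (lo_x <= x + dx <= hi_x):
            dx = -dx
        if not (lo_y <= y + dy <= hi_y):
            dy = -dy
        x, y = x + dx, y + dy
        traj.append((x, y))
    return traj


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def save_frames(seq: FrameSequence, out_dir: str | Path) -> None:
    """Write a frame stack as numbered PNGs plus a JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:04d}.png", frame.astype(np.uint8))
    meta = {"frame_rate": seq.frame_rate, "condition_label": seq.condition_label}
    (out / "sequence.json").write_text(json.dumps(meta, indent=2))


def load_frames(in_dir: str | Path) -> FrameSequence:
    """Read a frame stack written by :func:`save_frames`."""
    src = Path(in_dir)
    meta = json.loads((src / "sequence.json").read_text())
    paths = sorted(src.glob("frame_*.png"))
    if not paths:
        raise FileNotFoundError(f"no frame_*.png files in {src}")
    frames = np.stack([iio.imread(p).astype(float) for p in paths])
    return FrameSequence(frames, meta["frame_rate"], meta["condition_label"])
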
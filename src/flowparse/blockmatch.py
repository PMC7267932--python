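"""Block-matching motion estimation and the QoM/SoM movie statistics.

A block-matching algorithm (BMA) tessellates each video frame into
square macroblocks and, for every consecutive frame pair, finds for each
macroblock the integer displacement (within a +/-p search range) that
minimises the mean absolute difference (MAD) against the previous
frame.  Two search strategies are provided:

* ``full_search`` — exhaustive scan of the (2p+1)^2 window; slow but
  provably optimal, used as the oracle.
* ``arps_ds`` — adaptive rood pattern search seeded by the left
  neighbour's motion vector, refined by iterative large-diamond steps
  and one small-diamond step; the production strategy.

Per-movie motion is summarised by two scalars: the quantity of motion
(QoM), the mean motion-vector amplitude across blocks and frame pairs,
and the spread of motion (SoM), the standard deviation of motion-vector
orientations within each frame pair averaged across pairs.  Low SoM
indicates coherent (self-motion-like) flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from flowparse.stimuli import FrameSequence

_LDSP = ((0, 2), (0, -2), (2, 0), (-2, 0), (1, 1), (1, -1), (-1, 1), (-1, -1))
_SDSP = ((0, 1), (0, -1), (1, 0), (-1, 0))

#: ITU-R 601 luma weights, applied if colour frames are supplied
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class SearchConfig:
    """Parameters of the block-matching search.

    ``border`` controls candidate handling at frame edges: ``"wrap"``
    indexes the reference frame toroidally (exact for the periodic
    synthetic textures this package renders), ``"clip"`` discards
    candidates whose reference block would leave the frame (appropriate
    for real footage).
    """

    block_size: int = 16
    search_range: int = 7
    zero_motion_threshold: float = 0.0
    strategy: str = "arps_ds"
    border: str = "wrap"

    def __post_init__(self) -> None:
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.search_range < 1:
            raise ValueError("search_range must be >= 1")
        if self.zero_motion_threshold < 0:
            raise ValueError("zero_motion_threshold must be >= 0")
        if self.strategy not in ("arps_ds", "full_search"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.border not in ("wrap", "clip"):
            raise ValueError(f"unknown border mode {self.border!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SearchConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


@dataclass
class MotionVectorField:
    """Per-macroblock (dx, dy) displacements for one frame pair."""

    vectors: np.ndarray  # (rows, cols, 2) int
    block_size: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors)
        if self.vectors.ndim != 3 or self.vectors.shape[-1] != 2:
            raise ValueError("vectors must have shape (rows, cols, 2)")

    @property
    def amplitudes(self) -> np.ndarray:
        return np.hypot(self.vectors[..., 0], self.vectors[..., 1])


@dataclass
class MotionSummary:
    """QoM/SoM summary of one movie's estimated motion fields."""

    qom: float
    som: float
    per_frame_qom: np.ndarray
    all_zero: bool = False


def tessellate(height: int, width: int, block_size: int) -> tuple[int, int]:
    """Macroblock grid geometry: (rows, cols); partial border blocks drop."""
    if height < block_size or width < block_size:
        raise ValueError(
            f"frame ({height}x{width}) smaller than one {block_size}px block"
        )
    return height // block_size, width // block_size


def mad_cost(
    current_block: np.ndarray,
    reference_block: np.ndarray,
    zero_motion_threshold: float = 0.0,
) -> float:
    """Mean absolute difference between two blocks.

    Pixel pairs whose absolute difference does not exceed the zero
    motion threshold contribute nothing to the sum — suppressing noise
    between genuinely still regions — while the divisor stays N^2.
    """
    c = np.asarray(current_block, dtype=float)
    r = np.asarray(reference_block, dtype=float)
    if c.shape != r.shape:
        raise ValueError(f"block shapes differ: {c.shape} vs {r.shape}")
    diff = np.abs(c - r)
    diff[diff <= zero_motion_threshold] = 0.0
    return float(diff.sum() / diff.size)


def estimate_zero_motion_threshold(
    movie: FrameSequence,
    still_region: tuple[int, int, int, int],
    quantile: float = 0.95,
) -> float:
    """Estimate the zero motion threshold from a known-still region.

    ``still_region`` is (y0, y1, x0, x1) in pixel coordinates.  Returns
    the chosen quantile of absolute frame-to-frame luminance differences
    over that region — an upper bound on noise-driven differences, used
    to suppress spurious motion between still blocks.
    """
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to estimate the threshold")
    h, w = movie.shape
    y0, y1, x0, x1 = still_region
    if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
        raise ValueError(f"still region {still_region} outside {h}x{w} frame")
    patch = movie.frames[:, y0:y1, x0:x1]
    diffs = np.abs(np.diff(patch, axis=0))
    return float(np.quantile(diffs, quantile))


def _to_grayscale(frames: np.ndarray) -> np.ndarray:
    if frames.ndim == 4 and frames.shape[-1] == 3:
        return frames @ _LUMA
    return frames


class _BlockMatcher:
    """Candidate bookkeeping for one macroblock's search."""

    def __init__(
        self,
        current: np.ndarray,
        reference: np.ndarray,
        y0: int,
        x0: int,
        config: SearchConfig,
    ):
        n = config.block_size
        h, w = reference.shape
        if y0 < 0 or x0 < 0 or y0 + n > current.shape[0] or x0 + n > current.shape[1]:
            raise ValueError(f"block at ({y0},{x0}) out of bounds")
        self.block = current[y0 : y0 + n, x0 : x0 + n]
        self.reference = reference
        self.y0, self.x0, self.n = y0, x0, n
        self.h, self.w = h, w
        self.cfg = config
        self.costs: dict[tuple[int, int], float] = {}

    def _valid(self, dx: int, dy: int) -> bool:
        p = self.cfg.search_range
        if abs(dx) > p or abs(dy) > p:
            return False
        if self.cfg.border == "wrap":
            return True
        ry, rx = self.y0 - dy, self.x0 - dx
        return 0 <= ry and ry + self.n <= self.h and 0 <= rx and rx + self.n <= self.w

    def evaluate(self, dx: int, dy: int) -> None:
        key = (dx, dy)
        if key in self.costs or not self._valid(dx, dy):
            return
        ry, rx = self.y0 - dy, self.x0 - dx
        if self.cfg.border == "wrap":
            rows = np.arange(ry, ry + self.n) % self.h
            cols = np.arange(rx, rx + self.n) % self.w
            ref = self.reference[np.ix_(rows, cols)]
        else:
            ref = self.reference[ry : ry + self.n, rx : rx + self.n]
        self.costs[key] = mad_cost(self.block, ref, self.cfg.zero_motion_threshold)

    def best(self) -> tuple[int, int, float]:
        # deterministic tie-break: cost, then smaller displacement,
        # then row-major (dy, dx) order
        (dx, dy), cost = min(
            self.costs.items(),
            key=lambda kv: (kv[1], kv[0][0] ** 2 + kv[0][1] ** 2, kv[0][1], kv[0][0]),
        )
        return dx, dy, cost


def match_block(
    current_frame: np.ndarray,
    reference_frame: np.ndarray,
    block_origin: tuple[int, int],
    predicted_mv: tuple[int, int],
    config: SearchConfig,
    extra_candidates: tuple[tuple[int, int], ...] = (),
) -> tuple[int, int, float]:
    """Find the displacement of one macroblock between two frames.

    Returns (dx, dy, cost): the current block at ``block_origin``
    (y0, x0) is matched against reference blocks displaced by (-dy,
    -dx), i.e. (dx, dy) is the motion from the reference frame to the
    current one.  Strategy ``full_search`` scans the whole window;
    ``arps_ds`` runs the adaptive rood pattern (centre, four rood arms
    of length max(|predicted|, 1), the predicted vector itself) followed
    by iterated large-diamond refinement and a final small-diamond step;
    ``extra_candidates`` (e.g. a second neighbour's vector) join the
    initial rood pool.
    """
    y0, x0 = block_origin
    pdx, pdy = int(predicted_mv[0]), int(predicted_mv[1])
    p = config.search_range
    if abs(pdx) > p or abs(pdy) > p:
        raise ValueError("predicted vector outside the search range")
    m = _BlockMatcher(current_frame, reference_frame, y0, x0, config)

    if config.strategy == "full_search":
        for dy in range(-p, p + 1):
            for dx in range(-p, p + 1):
                m.evaluate(dx, dy)
        if not m.costs:
            raise ValueError("no valid candidate in search window")
        return m.best()

    # --- ARPS: rood pattern around the origin plus the prediction ---
    arm = max(abs(pdx), abs(pdy), 1)
    for dx, dy in ((0, 0), (arm, 0), (-arm, 0), (0, arm), (0, -arm), (pdx, pdy)):
        m.evaluate(dx, dy)
    for dx, dy in extra_candidates:
        m.evaluate(int(dx), int(dy))
    if not m.costs:
        raise ValueError("no valid candidate in search window")

    # --- iterated large diamond, re-centred on the running best ---
    for _ in range(4 * p):  # generous cap; each step moves <= 2 px
        cx, cy, _ = m.best()
        for ox, oy in _LDSP:
            m.evaluate(cx + ox, cy + oy)
        nx, ny, _ = m.best()
        if (nx, ny) == (cx, cy):
            break

    # --- one small-diamond refinement ---
    cx, cy, _ = m.best()
    for ox, oy in _SDSP:
        m.evaluate(cx + ox, cy + oy)
    return m.best()


def estimate_motion_field(
    movie: FrameSequence, config: SearchConfig | None = None
) -> list[MotionVectorField]:
    """Estimate one motion vector field per consecutive frame pair.

    Macroblocks are processed left-to-right, top-to-bottom so that each
    block's left neighbour supplies its motion prediction, exploiting
    the spatial coherence of natural motion.  The first block of each
    row, having no left neighbour, predicts from the block above it;
    the top-left block of each frame pair — the root of the prediction
    chain — is matched exhaustively so that a poor initial guess cannot
    propagate through the field.  Each block also evaluates the block
    above it and its own vector from the previous frame pair as extra
    candidates: motion coherent across space is usually coherent across
    time too, which keeps small independently moving surfaces locked
    once they have been found.
    """
    if config is None:
        config = SearchConfig()
    frames = _to_grayscale(movie.frames)
    if frames.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    h, w = frames.shape[1:3]
    rows, cols = tessellate(h, w, config.block_size)
    n = config.block_size
    seed_cfg = SearchConfig(
        block_size=config.block_size,
        search_range=config.search_range,
        zero_motion_threshold=config.zero_motion_threshold,
        strategy="full_search",
        border=config.border,
    )
    fields = []
    prev_vectors: np.ndarray | None = None
    for t in range(frames.shape[0] - 1):
        ref, cur = frames[t], frames[t + 1]
        vectors = np.zeros((rows, cols, 2), dtype=int)
        for r in range(rows):
            for c in range(cols):
                if c > 0:
                    pred = tuple(vectors[r, c - 1])
                elif r > 0:
                    pred = tuple(vectors[r - 1, 0])
                else:
                    pred = (0, 0)
                extra = []
                if r > 0:  # second first-order neighbour: the row above
                    extra.append(tuple(vectors[r - 1, c]))
                if prev_vectors is not None:  # temporal predictor
                    extra.append(tuple(prev_vectors[r, c]))
                cfg = seed_cfg if (r, c) == (0, 0) else config
                dx, dy, _ = match_block(
                    cur, ref, (r * n, c * n), pred, cfg,
                    extra_candidates=tuple(extra),
                )
                vectors[r, c] = (dx, dy)
        fields.append(MotionVectorField(vectors, n))
        prev_vectors = vectors
    return fields


def motion_summary(fields: list[MotionVectorField]) -> MotionSummary:
    """Summarise motion fields as QoM and SoM.

    QoM: mean vector amplitude across blocks and frame pairs (each
    block's vector stands for all its pixels, so with equal-size blocks
    the block mean equals the pixel mean).  SoM: per frame pair, the
    standard deviation of vector orientations (degrees, atan2) over
    blocks with nonzero amplitude, averaged across pairs; pairs with no
    moving block carry no orientation information and are excluded.  If
    no pair has motion, SoM is reported as 0 with ``all_zero`` set.
    """
    if not fields:
        raise ValueError("empty field list")
    per_frame_qom = np.array([f.amplitudes.mean() for f in fields])
    sds = []
    for f in fields:
        amp = f.amplitudes
        nz = amp > 0
        if not nz.any():
            continue
        ang = np.degrees(
            np.arctan2(f.vectors[..., 1][nz], f.vectors[..., 0][nz])
        )
        sds.append(float(np.std(ang)))
    all_zero = not sds
    som = float(np.mean(sds)) if sds else 0.0
    return MotionSummary(
        qom=float(per_frame_qom.mean()),
        som=som,
        per_frame_qom=per_frame_qom,
        all_zero=all_zero,
    )


def summarize_trial_set(
    trials: list[tuple[str, str, FrameSequence]],
    config: SearchConfig | None = None,
) -> pd.DataFrame:
    """Estimate QoM/SoM for a set of movie trials.

    ``trials`` holds (movie_id, condition, FrameSequence) triples.
    Returns a DataFrame with one row per trial (movie_id, condition,
    QoM, SoM, per_frame_QoM); condition-level means are obtained with
    :func:`condition_means`.  The per-trial values feed the GLM as
    parametric modulators.
    """
    if not trials:
        raise ValueError("empty trial set")
    records = []
    for movie_id, condition, seq in trials:
        summary = motion_summary(estimate_motion_field(seq, config))
        records.append(
            {
                "movie_id": movie_id,
                "condition": condition,
                "QoM": summary.qom,
                "SoM": summary.som,
                "per_frame_QoM": list(summary.per_frame_qom),
            }
        )
    return pd.DataFrame.from_records(records)


def condition_means(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean QoM and SoM from a trial summary table."""
    return trial_table.groupby("condition")[["QoM", "SoM"]].mean()


def write_motion_report(trial_table: pd.DataFrame, path: str | Path) -> None:
    """Write the trial summary as a TSV (per_frame_QoM JSON-encoded)."""
    out = trial_table.copy()
    out["per_frame_QoM"] = out["per_frame_QoM"].map(
        lambda v: "[" + ",".join(f"{x:.6g}" for x in v) + "]"
    )
    out.to_csv(path, sep="\t", index=False)
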
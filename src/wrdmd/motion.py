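"""Block-matching motion estimation and scalar motion summaries.

Motion between two frames is estimated with the classic block-matching
scheme: the reference frame is tiled into fixed-size blocks (with a
configurable overlap), and for each block an exhaustive full search evaluates
every candidate displacement within ``±max_disp`` and keeps the one
minimising the matching cost on the target frame. The mean Euclidean norm of
the block displacements summarises the motion of a frame pair, and averaging
over pairs (consecutive, or every frame against the first) yields the global
mean motion magnitude — the stability metric of the pipeline: smaller means
more stable. The per-frame series against the first frame also exposes the
periodicity of breathing-like motion, which drives window-length selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError
from .frames import FrameStack

__all__ = [
    "BlockMatchConfig",
    "MotionField",
    "MotionProfile",
    "block_match",
    "mean_motion_magnitude",
    "estimate_period",
]

logger = logging.getLogger(__name__)

#: Autocorrelation value a candidate lag must exceed to count as periodic.
PERIODICITY_THRESHOLD = 0.3


@dataclass(frozen=True)
class BlockMatchConfig:
    """Block geometry, search range and matching cost.

    Defaults follow the standard renography evaluation setting: 15x15 blocks
    with 5-pixel overlap and a ±5-pixel exhaustive search. ``cost`` is
    ``"mse"`` (mean squared error) or ``"mad"`` (mean absolute difference).
    """

    block_height: int = 15
    block_width: int = 15
    overlap_r: int = 5
    overlap_c: int = 5
    max_disp_r: int = 5
    max_disp_c: int = 5
    cost: str = "mse"

    def __post_init__(self) -> None:
        if self.block_height <= 0 or self.block_width <= 0:
            raise InvalidConfigError("block dimensions must be positive")
        if not (0 <= self.overlap_r < self.block_height):
            raise InvalidConfigError("overlap_r must be in [0, block_height)")
        if not (0 <= self.overlap_c < self.block_width):
            raise InvalidConfigError("overlap_c must be in [0, block_width)")
        if self.max_disp_r < 0 or self.max_disp_c < 0:
            raise InvalidConfigError("max displacements must be >= 0")
        if self.cost not in ("mse", "mad"):
            raise InvalidConfigError(f"unknown cost {self.cost!r}")

    @property
    def step_r(self) -> int:
        return self.block_height - self.overlap_r

    @property
    def step_c(self) -> int:
        return self.block_width - self.overlap_c


@dataclass(frozen=True)
class MotionField:
    """Per-block displacement vectors between one frame pair."""

    displacements: np.ndarray  # (n_blocks, 2) int, (dr, dc) in pixels
    block_centres: np.ndarray  # (n_blocks, 2) float, (row, col)
    config: BlockMatchConfig

    @property
    def magnitudes(self) -> np.ndarray:
        d = self.displacements.astype(np.float64)
        return np.hypot(d[:, 0], d[:, 1])

    @property
    def mean_magnitude(self) -> float:
        return float(self.magnitudes.mean())


@dataclass(frozen=True)
class MotionProfile:
    """Scalar motion summary of a sequence: one mean magnitude per frame pair."""

    magnitudes: np.ndarray  # pixels, one per frame pair
    scheme: str  # "consecutive" | "vs_first"
    pair_indices: np.ndarray = field(repr=False, default=None)  # (n_pairs, 2)

    @property
    def global_mean(self) -> float:
        """Arithmetic mean of the per-pair magnitudes."""
        return float(np.mean(self.magnitudes))

    def to_dataframe(self) -> pd.DataFrame:
        pairs = (
            self.pair_indices
            if self.pair_indices is not None
            else np.zeros((len(self.magnitudes), 2), dtype=int)
        )
        return pd.DataFrame(
            {
                "frame_pair": [f"{a}-{b}" for a, b in pairs],
                "mean_magnitude_px": self.magnitudes,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _cost_fn(name: str):
    if name == "mse":
        return lambda a, b: float(np.mean((a - b) ** 2))
    return lambda a, b: float(np.mean(np.abs(a - b)))


def block_match(
    ref: np.ndarray, target: np.ndarray, config: BlockMatchConfig | None = None
) -> MotionField:
    """Exhaustive-search block matching between two frames.

    Every block of ``ref`` (full blocks only; partial border blocks are
    skipped) is compared against the target at every displacement
    ``(dr, dc)`` with ``|dr| <= max_disp_r``, ``|dc| <= max_disp_c`` that
    keeps the block inside the frame. The displacement minimising the
    matching cost wins; exact ties resolve to the smallest Euclidean norm and
    then to row-major candidate order, so the search is fully deterministic.
    """
    if config is None:
        config = BlockMatchConfig()
    ref = np.asarray(ref, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if ref.ndim != 2 or ref.shape != target.shape:
        raise InvalidInputError(
            f"frames must be 2-D and same size, got {ref.shape} vs {target.shape}"
        )
    m, n = ref.shape
    bh, bw = config.block_height, config.block_width
    if m < bh or n < bw:
        raise InvalidInputError(
            f"frame {ref.shape} smaller than block ({bh}, {bw})"
        )
    cost = _cost_fn(config.cost)

    displacements = []
    centres = []
    for r0 in range(0, m - bh + 1, config.step_r):
        for c0 in range(0, n - bw + 1, config.step_c):
            block = ref[r0 : r0 + bh, c0 : c0 + bw]
            best_key = None
            best = (0, 0)
            for dr in range(-config.max_disp_r, config.max_disp_r + 1):
                r1 = r0 + dr
                if r1 < 0 or r1 + bh > m:
                    continue
                for dc in range(-config.max_disp_c, config.max_disp_c + 1):
                    c1 = c0 + dc
                    if c1 < 0 or c1 + bw > n:
                        continue
                    key = (
                        cost(block, target[r1 : r1 + bh, c1 : c1 + bw]),
                        dr * dr + dc * dc,
                    )
                    if best_key is None or key < best_key:
                        best_key = key
                        best = (dr, dc)
            displacements.append(best)
            centres.append((r0 + (bh - 1) / 2.0, c0 + (bw - 1) / 2.0))

    return MotionField(
        displacements=np.asarray(displacements, dtype=np.intp).reshape(-1, 2),
        block_centres=np.asarray(centres, dtype=np.float64).reshape(-1, 2),
        config=config,
    )


def mean_motion_magnitude(
    stack: FrameStack,
    config: BlockMatchConfig | None = None,
    scheme: str = "consecutive",
) -> MotionProfile:
    """Per-pair mean block displacement magnitudes across a sequence.

    ``scheme="consecutive"`` pairs frame i with frame i+1 (sequence
    stability); ``scheme="vs_first"`` pairs every later frame with frame 0
    (periodicity analysis). The profile's ``global_mean`` averages the
    per-pair means; the grand mean over all blocks of all pairs is logged for
    reference.
    """
    if config is None:
        config = BlockMatchConfig()
    if stack.n_frames < 2:
        raise InvalidInputError("need at least 2 frames")
    if scheme == "consecutive":
        pairs = [(i, i + 1) for i in range(stack.n_frames - 1)]
    elif scheme == "vs_first":
        pairs = [(0, i) for i in range(1, stack.n_frames)]
    else:
        raise InvalidInputError(f"unknown scheme {scheme!r}")

    per_pair = []
    all_mags = []
    for a, b in pairs:
        field_ab = block_match(stack.frame(a), stack.frame(b), config)
        per_pair.append(field_ab.mean_magnitude)
        all_mags.append(field_ab.magnitudes)
    profile = MotionProfile(
        magnitudes=np.asarray(per_pair),
        scheme=scheme,
        pair_indices=np.asarray(pairs, dtype=np.intp),
    )
    logger.debug(
        "motion profile (%s): mean over pairs %.4f px, mean over all blocks %.4f px",
        scheme,
        profile.global_mean,
        float(np.concatenate(all_mags).mean()),
    )
    return profile


def estimate_period(
    series,
    max_period: int | None = None,
    threshold: float = PERIODICITY_THRESHOLD,
    min_period: int = 2,
) -> int:
    """Dominant period (in samples) of a nonnegative series, or 0 if none.

    Only lags of at least ``min_period`` are considered: a one-sample
    "period" carries no cycle information for a sampled motion trace.

    The series is detrended with a centred moving average (motion-magnitude
    series ride on the slow contrast-enhancement envelope, which would
    otherwise dominate the autocorrelation), then autocorrelated with biased
    normalisation by the zero-lag energy; the first local maximum exceeding
    ``threshold`` gives the period. A constant or aperiodic series returns 0.
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or x.size < 4:
        raise InvalidInputError("series must be 1-D with at least 4 samples")
    x = x - x.mean()
    win = min(x.size if x.size % 2 == 1 else x.size - 1, 2 * (x.size // 4) + 1)
    if win >= 3:
        kernel = np.ones(win) / win
        trend = np.convolve(np.pad(x, win // 2, mode="reflect"), kernel, "valid")
        x = x - trend
    energy = float(np.dot(x, x))
    if energy == 0.0:
        return 0
    max_lag = x.size // 2 if max_period is None else min(max_period, x.size - 1)
    acf = np.array(
        [float(np.dot(x[:-lag], x[lag:])) / energy for lag in range(1, max_lag + 1)]
    )
    for i in range(max(0, min_period - 1), acf.size):
        if acf[i] <= threshold:
            continue
        left_ok = i == 0 or acf[i] >= acf[i - 1]
        right_ok = i == acf.size - 1 or acf[i] >= acf[i + 1]
        if left_ok and right_ok:
            return i + 1
    return 0
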
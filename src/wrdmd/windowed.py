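"""Windowed DMD (W-DMD): sliding-window low-rank / sparse separation.

Pseudo-periodic breathing motion repeats every few frames, so a DMD run on a
short window of ``W`` consecutive frames cleanly splits each window into a
slowly varying background mode and fast-varying remainder modes. Sliding the
window with stride 1 over the sequence and concatenating the per-window
background images yields the low-rank component C1 — the sequence with the
periodic motion suppressed — while the concatenated remainders form the
sparse component C2 carrying the motion. With the default ``W = 3`` each
window yields exactly two modes, one per channel.

Dynamic modes are defined only up to a complex scale, so the raw background
mode is not a photometrically meaningful image. Each window's mode
amplitudes are therefore fixed by least-squares projection of the window's
first frame onto the modes (``x1 ≈ Ψ b``); the emitted images
``c1 = Re(Ψ_bg b_bg)`` and ``c2 = Re(Σ_{j≠bg} Ψ_j b_j)`` then live on the
input intensity scale, which downstream time–intensity analysis requires.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .core import build_snapshot_matrix, compute_dmd
from .exceptions import InvalidInputError
from .frames import FrameStack
from .motion import BlockMatchConfig, estimate_period, mean_motion_magnitude

__all__ = [
    "WDMDResult",
    "window_components",
    "run_wdmd",
    "select_window_length",
    "DEFAULT_WINDOW_LENGTH",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_LENGTH = 3
DEFAULT_WINDOW_CANDIDATES = (2, 3, 4, 5, 6)


@dataclass(frozen=True)
class WDMDResult:
    """Concatenated low-rank (C1) and sparse (C2) sequences from one pass.

    Both stacks have the input frame geometry and length ``N - W + 1``; C2 is
    kept for inspection even though only C1 feeds the next pipeline stage.
    """

    c1: FrameStack
    c2: FrameStack
    window_length: int


def window_components(window: FrameStack) -> tuple[np.ndarray, np.ndarray]:
    """Low-rank and sparse component images of one window.

    The background mode is the one with frequency magnitude ``|mu|`` nearest
    zero (neither growing, decaying nor oscillating), ties broken by the
    largest eigenvalue magnitude; ``|mu|`` rather than ``|Re(mu)|`` is used
    because a period-two alternation has eigenvalue near -1, hence
    ``Re(mu) = 0`` like the background, and must not be mistaken for it.
    ``c1`` is the background's amplitude-scaled real image, ``c2``
    aggregates all remaining modes. A window of identical frames has a
    single (background) mode, so ``c2`` is the zero frame.
    """
    if window.n_frames < 2:
        raise InvalidInputError("window must contain at least 2 frames")
    X = build_snapshot_matrix(window)
    decomp = compute_dmd(X)

    abs_mu = np.abs(decomp.frequencies)
    mags = np.abs(decomp.eigenvalues)
    bg = min(range(decomp.n_modes), key=lambda j: (abs_mu[j], -mags[j]))

    b, *_ = np.linalg.lstsq(decomp.modes, X.data[:, 0], rcond=None)
    scaled = decomp.modes * b[np.newaxis, :]
    c1 = scaled[:, bg].real.reshape(window.frame_shape)
    c2 = (scaled.sum(axis=1) - scaled[:, bg]).real.reshape(window.frame_shape)
    return c1, c2


def run_wdmd(stack: FrameStack, W: int = DEFAULT_WINDOW_LENGTH) -> WDMDResult:
    """Slide a length-``W`` window with stride 1 and concatenate components.

    Windows are maximally overlapping: frames ``{1..W}, {2..W+1}, ...``; the
    output stacks have ``N - W + 1`` frames each, labelled from the original
    index of their window's first frame.
    """
    if W < 2:
        raise InvalidInputError(f"window length must be >= 2, got {W}")
    if stack.n_frames < W:
        raise InvalidInputError(
            f"sequence of {stack.n_frames} frames is shorter than window {W}"
        )
    c1_frames = []
    c2_frames = []
    for start in range(stack.n_frames - W + 1):
        c1, c2 = window_components(stack.window(start, W))
        c1_frames.append(c1)
        c2_frames.append(c2)
    c1_stack = FrameStack(
        np.stack(c1_frames), dt=stack.dt, start_index=stack.start_index
    )
    c2_stack = FrameStack(
        np.stack(c2_frames), dt=stack.dt, start_index=stack.start_index
    )
    logger.info(
        "W-DMD: %d frames, W=%d -> %d component frames",
        stack.n_frames,
        W,
        c1_stack.n_frames,
    )
    return WDMDResult(c1=c1_stack, c2=c2_stack, window_length=W)


def select_window_length(
    stack: FrameStack,
    bm_config: BlockMatchConfig | None = None,
    candidates=DEFAULT_WINDOW_CANDIDATES,
) -> int:
    """Pick the window length from the periodicity of the breathing motion.

    The motion magnitude of every frame against the first is computed by
    block matching and its dominant period estimated by autocorrelation. If
    that period is among ``candidates`` it becomes the window length;
    otherwise (no detectable periodicity, or a period outside the candidate
    range) the default of 3 is returned with a warning.
    """
    candidates = tuple(candidates)
    if not candidates or any(c < 2 for c in candidates):
        raise InvalidInputError("candidates must be non-empty and all >= 2")
    profile = mean_motion_magnitude(stack, bm_config, scheme="vs_first")
    period = estimate_period(profile.magnitudes, max_period=max(candidates) * 2)
    if period in candidates:
        logger.info("detected motion period %d; using W=%d", period, period)
        return period
    warnings.warn(
        f"no usable motion periodicity detected (estimate: {period}); "
        f"falling back to W={DEFAULT_WINDOW_LENGTH}",
        stacklevel=2,
    )
    return DEFAULT_WINDOW_LENGTH
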
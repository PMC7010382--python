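"""The FrameStack container: an ordered, equally sized grayscale frame sequence.

Every stage of the pipeline consumes and produces :class:`FrameStack`, so the
conventions fixed here (float64 intensities, a raster/C-order flattening when a
stack is turned into a snapshot matrix, and an explicit inter-frame interval
``dt``) hold everywhere downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["FrameStack"]


@dataclass(frozen=True)
class FrameStack:
    """An ordered sequence of equally sized 2-D grayscale frames.

    Parameters
    ----------
    data
        Array of shape ``(N, m, n)``: ``N`` frames of ``m`` rows by ``n``
        columns. Any real dtype is accepted and promoted to float64.
    dt
        Inter-frame interval in seconds (must be positive).
    start_index
        Index of the first frame within the original acquisition. Stages that
        drop leading frames (windowing, reconstruction) advance this so time
        axes stay honest.
    """

    data: np.ndarray
    dt: float = 1.5
    start_index: int = 0

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 3:
            raise InvalidInputError(
                f"frame stack must be a (N, m, n) array, got shape {arr.shape}"
            )
        if arr.shape[0] < 1:
            raise InvalidInputError("frame stack needs at least one frame")
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("frame intensities must be finite")
        if not self.dt > 0:
            raise InvalidInputError(f"dt must be positive, got {self.dt}")
        object.__setattr__(self, "data", arr)

    @classmethod
    def from_frames(
        cls, frames, dt: float = 1.5, start_index: int = 0
    ) -> "FrameStack":
        """Build a stack from an iterable of 2-D arrays, checking geometry."""
        frames = [np.asarray(f, dtype=np.float64) for f in frames]
        if not frames:
            raise InvalidInputError("no frames given")
        shape = frames[0].shape
        for i, f in enumerate(frames):
            if f.ndim != 2 or f.shape != shape:
                raise InvalidInputError(
                    f"frame {i} has shape {f.shape}, expected {shape}"
                )
        return cls(np.stack(frames), dt=dt, start_index=start_index)

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Acquisition times in seconds, offset by ``start_index``."""
        return (self.start_index + np.arange(self.n_frames)) * self.dt

    def __len__(self) -> int:
        return self.n_frames

    def frame(self, i: int) -> np.ndarray:
        return self.data[i]

    def window(self, start: int, length: int) -> "FrameStack":
        """A contiguous sub-sequence of ``length`` frames starting at ``start``."""
        if start < 0 or start + length > self.n_frames:
            raise InvalidInputError(
                f"window [{start}, {start + length}) outside stack of {self.n_frames}"
            )
        return FrameStack(
            self.data[start : start + length],
            dt=self.dt,
            start_index=self.start_index + start,
        )
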
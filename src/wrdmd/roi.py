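"""ROI time–intensity curves and the degree-of-smoothness score.

The clinical readout of a dynamic contrast-enhanced sequence is the mean
intensity of a fixed region of interest (the kidney) over time. Respiratory
motion moves tissue in and out of the fixed ROI and shows up as frame-to-
frame fluctuations on that curve. The degree-of-smoothness score

    D = std(t~) / |mean(t~)|,   t~[i] = t^[i+1] - t^[i]

measures those fluctuations on the first-differenced curve (differencing
avoids assuming stationarity; the ratio makes the score invariant to
intensity scale and offset). Smaller D means a smoother curve, i.e. better
motion compensation. ``std`` is the sample standard deviation (ddof=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .frames import FrameStack

__all__ = [
    "ROIMask",
    "TimeIntensityCurve",
    "time_intensity_curve",
    "degree_of_smoothness",
]


@dataclass(frozen=True)
class ROIMask:
    """Binary region-of-interest mask matching the frame geometry."""

    mask: np.ndarray  # 2-D bool

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim != 2:
            raise InvalidInputError("mask must be 2-D")
        arr = arr != 0
        if not arr.any():
            raise InvalidInputError("mask has no pixels")
        object.__setattr__(self, "mask", arr)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class TimeIntensityCurve:
    """Mean ROI intensity per frame, with acquisition times in seconds."""

    values: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        t = np.asarray(self.times, dtype=np.float64)
        if v.ndim != 1 or v.shape != t.shape:
            raise InvalidInputError("values and times must be matching 1-D arrays")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "times", t)

    def __len__(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self)),
                "time_s": self.times,
                "mean_intensity": self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def time_intensity_curve(stack: FrameStack, mask: ROIMask) -> TimeIntensityCurve:
    """Mean intensity over the mask pixels of every frame."""
    if mask.shape != stack.frame_shape:
        raise InvalidInputError(
            f"mask shape {mask.shape} does not match frames {stack.frame_shape}"
        )
    values = stack.data[:, mask.mask].mean(axis=1)
    return TimeIntensityCurve(values=values, times=stack.times)


def degree_of_smoothness(curve: TimeIntensityCurve) -> float:
    """D = std(diff(curve)) / |mean(diff(curve))|; smaller is smoother.

    Returns ``+inf`` (with a warning) when the mean difference is exactly
    zero — e.g. a constant curve — where the score is undefined.
    """
    if len(curve) < 3:
        raise InvalidInputError("curve must have at least 3 points")
    diffs = np.diff(curve.values)
    mean = float(diffs.mean())
    if mean == 0.0:
        warnings.warn(
            "mean of first differences is zero; degree of smoothness is undefined "
            "(returning +inf)",
            stacklevel=2,
        )
        return float("inf")
    return float(diffs.std(ddof=1) / abs(mean))
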
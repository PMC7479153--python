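"""In-memory containers shared across the acquisition/analysis chain."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass(frozen=True)
class ScanProtocol:
    """Raster-scan timing and geometry.

    Defaults mirror the confocal protocol used throughout: 12.5 us pixel
    dwell, 256 x 256 pixels of 0.05 um, 100 frames.  The line time includes
    the retrace overhead; when not given it defaults to 1.1 x (dwell x
    columns).  The frame interval defaults to line_time x rows (no
    inter-frame dead time).
    """

    pixel_dwell: float = 12.5e-6  # s
    pixel_size: float = 0.05  # um
    shape: tuple[int, int] = (256, 256)  # rows, columns
    n_frames: int = 100
    line_time: Optional[float] = None  # s
    frame_interval: Optional[float] = None  # s

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if self.pixel_dwell <= 0 or self.pixel_size <= 0:
            raise ValueError("pixel dwell and pixel size must be positive")
        if rows < 1 or cols < 1 or self.n_frames < 1:
            raise ValueError("frame shape and frame count must be positive")
        if self.line_time is None:
            object.__setattr__(self, "line_time", 1.1 * self.pixel_dwell * cols)
        if self.line_time < self.pixel_dwell * cols:
            raise ValueError("line time shorter than dwell x columns")
        if self.frame_interval is None:
            object.__setattr__(self, "frame_interval", self.line_time * rows)
        if self.frame_interval < self.line_time * rows:
            raise ValueError("frame interval shorter than line time x rows")

    @property
    def frame_extent(self) -> tuple[float, float]:
        """Physical frame size (height, width) in um."""
        rows, cols = self.shape
        return rows * self.pixel_size, cols * self.pixel_size

    @property
    def total_duration(self) -> float:
        """Wall-clock span of the full stack acquisition, s."""
        return self.n_frames * self.frame_interval

    def to_dict(self) -> dict:
        return {
            "pixel_dwell": self.pixel_dwell,
            "pixel_size": self.pixel_size,
            "shape": list(self.shape),
            "n_frames": self.n_frames,
            "line_time": self.line_time,
            "frame_interval": self.frame_interval,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanProtocol":
        d = dict(d)
        if "shape" in d:
            d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass
class IntensityTrace:
    """Uniformly sampled intensity series (one value per dwell)."""

    values: np.ndarray
    dwell_time: float  # s
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace must be one-dimensional")
        if self.dwell_time <= 0:
            raise ValueError("dwell time must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Sample times (start of each dwell), s."""
        return np.arange(self.values.size) * self.dwell_time


@dataclass
class ImageStack:
    """frame x row x column intensity array with scan timing metadata."""

    data: np.ndarray
    scan: ScanProtocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("stack must be frame x row x column")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1], self.data.shape[2]

    def crop(self, x: int, y: int, width: int, height: int) -> "ImageStack":
        """Return the (x, y, width, height) pixel rectangle as a new stack."""
        rows, cols = self.frame_shape
        if x < 0 or y < 0 or x + width > cols or y + height > rows:
            raise ValueError("ROI outside the frame")
        return ImageStack(
            self.data[:, y : y + height, x : x + width].copy(),
            scan=self.scan,
            meta=dict(self.meta),
        )
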
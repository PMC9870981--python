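"""Multi-channel image frames.

Pixel coordinates are 0-based ``(row, col)`` with the origin at the top-left
corner; intensities are kept as floating point throughout the analysis and are
only quantized on TIFF export.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .exceptions import UnknownChannelError


@dataclass
class ImageFrame:
    """One multi-channel fluorescence frame.

    Parameters
    ----------
    channels
        Mapping from channel name to a 2-D float array. All channels must
        share the same shape.
    pixel_scale
        Microns per pixel (> 0).
    time_min
        Acquisition time in minutes after tracer injection, if known.
    """

    channels: Mapping[str, np.ndarray]
    pixel_scale: float = 1.0
    time_min: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("frame needs at least one channel")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        (shape,) = shapes
        if len(shape) != 2:
            raise ValueError("channel arrays must be 2-D")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def height_px(self) -> int:
        return next(iter(self.channels.values())).shape[0]

    @property
    def width_px(self) -> int:
        return next(iter(self.channels.values())).shape[1]

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise UnknownChannelError(
                f"channel {name!r} not in frame (have {list(self.channels)})"
            ) from None
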
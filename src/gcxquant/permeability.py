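"""Tracer extravasation: interstitial ROI intensities over time.

Vascular permeability is scored as the mean fluorescence of an intravascular
tracer inside three randomly placed, vessel-free 80x80-px square regions of
interest, tracked at 15/30/60/90 min after injection. The three ROI means
are averaged into one value per channel per time point; ROIs are fixed once
per animal and reused across time points.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import RoiPlacementError
from .frame import ImageFrame

__all__ = ["Roi", "RoiSet", "PermeabilityTimeSeries", "select_rois",
           "roi_mean", "measure_timecourse"]

DEFAULT_TIMES_MIN = (15.0, 30.0, 60.0, 90.0)


@dataclass(frozen=True)
class Roi:
    """Square region of interest, addressed by its top-left pixel."""

    row: int
    col: int
    size_px: int = 80

    def __post_init__(self) -> None:
        if self.size_px <= 0:
            raise ValueError("size_px must be positive")
        if self.row < 0 or self.col < 0:
            raise ValueError("ROI top-left must be non-negative")

    @property
    def slices(self) -> tuple[slice, slice]:
        return (slice(self.row, self.row + self.size_px),
                slice(self.col, self.col + self.size_px))

    def overlaps(self, other: "Roi") -> bool:
        return not (
            self.row + self.size_px <= other.row
            or other.row + other.size_px <= self.row
            or self.col + self.size_px <= other.col
            or other.col + other.size_px <= self.col
        )


@dataclass(frozen=True)
class RoiSet:
    """The vessel-free ROIs of one animal/frame geometry."""

    rois: tuple[Roi, ...]
    seed: int = 0
    frame_id: str = ""


@dataclass(frozen=True)
class PermeabilityTimeSeries:
    """Per-channel interstitial intensity at each time point.

    ``values[channel]`` is ordered by ``times_min`` and equals the arithmetic
    mean of the three per-ROI means; ``roi_values`` keeps the per-ROI data.
    """

    times_min: tuple[float, ...]
    values: Mapping[str, tuple[float, ...]]
    roi_values: Mapping[str, np.ndarray]  # (n_times, n_rois)
    rois: RoiSet

    def to_frame(self, normalize_to_first: bool = False) -> pd.DataFrame:
        """Tidy frame (time_min, channel, intensity); optionally relative to
        the first time point (the published curves are relative plots)."""
        rows = []
        for ch, vals in self.values.items():
            ref = vals[0] if normalize_to_first else None
            for t, v in zip(self.times_min, vals):
                rows.append((t, ch, v / ref if ref else v))
        col = "relative_intensity" if normalize_to_first else "intensity"
        return pd.DataFrame(rows, columns=["time_min", "channel", col])


def select_rois(
    vessel_mask: np.ndarray,
    size_px: int = 80,
    n: int = 3,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> RoiSet:
    """Draw ``n`` disjoint vessel-free ROIs by seeded rejection sampling.

    Candidate top-left corners are drawn uniformly over all in-bounds
    positions and rejected if the ROI touches the vessel mask or overlaps an
    already accepted ROI. Deterministic under ``seed``; raises
    :class:`RoiPlacementError` after ``max_attempts`` draws.
    """
    mask = np.asarray(vessel_mask, dtype=bool)
    h, w = mask.shape
    if h < size_px or w < size_px:
        raise RoiPlacementError(f"frame {h}x{w} smaller than ROI size {size_px}")
    rng = np.random.default_rng(seed)
    accepted: list[Roi] = []
    for _ in range(max_attempts):
        roi = Roi(
            row=int(rng.integers(0, h - size_px + 1)),
            col=int(rng.integers(0, w - size_px + 1)),
            size_px=size_px,
        )
        if mask[roi.slices].any():
            continue
        if any(roi.overlaps(other) for other in accepted):
            continue
        accepted.append(roi)
        if len(accepted) == n:
            return RoiSet(rois=tuple(accepted), seed=seed)
    raise RoiPlacementError(
        f"placed {len(accepted)}/{n} vessel-free disjoint {size_px}x{size_px} ROIs "
        f"within {max_attempts} attempts"
    )


def roi_mean(frame: ImageFrame, channel: str, roi: Roi) -> float:
    """Arithmetic mean of the ROI's size^2 pixel intensities."""
    data = frame.channel(channel)
    h, w = data.shape
    if roi.row + roi.size_px > h or roi.col + roi.size_px > w:
        raise ValueError(f"ROI {roi} exceeds the {h}x{w} frame")
    return float(data[roi.slices].mean())


def measure_timecourse(
    frames: Mapping[float, ImageFrame],
    rois: RoiSet,
    channels: Sequence[str],
    times_min: Sequence[float] = DEFAULT_TIMES_MIN,
) -> PermeabilityTimeSeries:
    """Mean interstitial intensity per channel at each requested time.

    ``frames`` maps acquisition time (min) to the frame; all frames must
    share the geometry the RoiSet was drawn for.
    """
    times = tuple(float(t) for t in times_min)
    missing = [t for t in times if t not in frames]
    if missing:
        raise ValueError(f"missing frames for time points {missing}")
    shapes = {frames[t].channel(channels[0]).shape for t in times}
    if len(shapes) != 1:
        raise ValueError(f"frames differ in geometry: {shapes}")

    values: dict[str, tuple[float, ...]] = {}
    roi_values: dict[str, np.ndarray] = {}
    for ch in channels:
        per_roi = np.array(
            [[roi_mean(frames[t], ch, roi) for roi in rois.rois] for t in times]
        )
        roi_values[ch] = per_roi
        values[ch] = tuple(float(v) for v in per_roi.mean(axis=1))
    return PermeabilityTimeSeries(
        times_min=times, values=values, roi_values=roi_values, rois=rois
    )
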
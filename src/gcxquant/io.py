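"""File formats: multi-channel TIFF + JSON sidecar, annotations, CSV export.

Frames travel as one 16-bit TIFF page per channel together with a JSON
sidecar carrying channel names, pixel scale, the quantization scale factor,
and (for synthetic frames) the ground truth: wall trace, run-length-encoded
vessel mask and leakage truth. Intensities are floating point everywhere in
memory; quantization happens only at export, as ``round(value * scale)``
clipped to the uint16 range, so integer-valued data at scale 1 round-trips
exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

from .exceptions import GcxquantError
from .frame import ImageFrame
from .profiles import WallTrace
from .scene import GroundTruth

__all__ = [
    "write_frame",
    "read_frame",
    "read_wall_trace",
    "write_wall_trace",
    "rle_encode",
    "rle_decode",
    "FLOAT_FORMAT",
]

#: fixed float serialization for reproducible CSV output
FLOAT_FORMAT = "%.9g"


def rle_encode(mask: np.ndarray) -> dict:
    """Run-length encode a boolean grid (row-major runs of True)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    edges = np.flatnonzero(np.diff(flat.astype(np.int8)))
    starts = np.concatenate([[0], edges + 1])
    lengths = np.diff(np.concatenate([starts, [flat.size]]))
    true_runs = [
        (int(s), int(l)) for s, l in zip(starts, lengths) if flat[s]
    ]
    return {"shape": list(mask.shape), "runs": true_runs}


def rle_decode(encoded: Mapping) -> np.ndarray:
    flat = np.zeros(int(np.prod(encoded["shape"])), dtype=bool)
    for start, length in encoded["runs"]:
        flat[start : start + length] = True
    return flat.reshape(encoded["shape"])


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_frame(
    frame: ImageFrame,
    path: str | Path,
    scale: float = 1.0,
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write a multi-page 16-bit TIFF plus its JSON sidecar.

    ``scale`` converts intensity units to counts before quantization and is
    recorded in the sidecar so readers can invert it.
    """
    path = Path(path)
    pages = np.stack(
        [
            np.clip(np.round(frame.channels[ch] * scale), 0, 65535).astype(np.uint16)
            for ch in frame.channel_names
        ]
    )
    tifffile.imwrite(path, pages, photometric="minisblack")
    sidecar: dict = {
        "channels": list(frame.channel_names),
        "pixel_scale_um": frame.pixel_scale,
        "intensity_scale": scale,
        "time_min": frame.time_min,
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = {
            "wall_trace": np.asarray(ground_truth.wall_trace).tolist(),
            "interstitial_side": ground_truth.interstitial_side,
            "vessel_mask_rle": rle_encode(ground_truth.vessel_mask),
            "true_width_px": ground_truth.true_width_px,
            "true_width_um": ground_truth.true_width_um,
            "interstitial_truth": {
                ch: {str(t): v for t, v in curve.items()}
                for ch, curve in ground_truth.interstitial_truth.items()
            },
        }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_frame(
    path: str | Path,
    channel_names: list[str] | None = None,
    pixel_scale: float | None = None,
) -> ImageFrame:
    """Read a multi-page TIFF back into a float frame.

    Channel names and pixel scale come from the sidecar when present;
    otherwise they must be supplied. Page count must match the channel list.
    """
    path = Path(path)
    try:
        pages = tifffile.imread(path)
    except (OSError, ValueError) as exc:
        raise GcxquantError(f"unreadable TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    scale = 1.0
    time_min = None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        channel_names = channel_names or meta.get("channels")
        pixel_scale = pixel_scale or meta.get("pixel_scale_um")
        scale = meta.get("intensity_scale", 1.0)
        time_min = meta.get("time_min")
    if channel_names is None:
        raise GcxquantError(
            f"{path}: no channel metadata (sidecar missing) and no channel map given"
        )
    if len(channel_names) != pages.shape[0]:
        raise GcxquantError(
            f"{path}: {pages.shape[0]} pages but {len(channel_names)} channel names"
        )
    channels = {
        ch: pages[i].astype(float) / scale for i, ch in enumerate(channel_names)
    }
    return ImageFrame(channels=channels, pixel_scale=pixel_scale or 1.0, time_min=time_min)


def write_wall_trace(trace: WallTrace, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "artery_id": trace.artery_id,
                "diameter_class": trace.diameter_class,
                "points": trace.points.tolist(),
                "interstitial_side": trace.interstitial_side,
            },
            indent=1,
        )
    )
    return path


def read_wall_trace(path: str | Path) -> WallTrace:
    """Read one wall-trace annotation JSON."""
    obj = json.loads(Path(path).read_text())
    return WallTrace(
        points=np.asarray(obj["points"], dtype=float),
        interstitial_side=int(obj.get("interstitial_side", 1)),
        artery_id=str(obj.get("artery_id", "")),
        diameter_class=obj.get("diameter_class"),
    )
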
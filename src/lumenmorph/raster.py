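"""In-memory raster containers and TIFF I/O.

The pipeline's carriers are deliberately thin: a :class:`RasterImage` is a
channel-first intensity array with named channels and physical pixel spacing
in micrometres, and a :class:`LabelMap` is an integer segmentation on the
same grid.  Everything user-facing is expressed in µm; pixel indices appear
only inside rasters.

TIFF files are written one channel per page, with channel names and spacing
stored as a JSON document in the image description tag so that a write/read
round trip is lossless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import tifffile

__all__ = [
    "RasterImage",
    "LabelMap",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "GridMismatchError",
    "ChannelError",
    "FormatError",
]


class GridMismatchError(ValueError):
    """Two rasters that must share a grid do not."""


class ChannelError(KeyError):
    """A named channel is missing or the channel map is inconsistent."""


class FormatError(ValueError):
    """A file on disk cannot be interpreted as expected."""


def _check_spacing(spacing: Sequence[float], ndim: int) -> Tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise GridMismatchError(
            f"spacing has {len(spacing)} entries for a {ndim}-dimensional grid"
        )
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass
class RasterImage:
    """A 2D or 3D multi-channel intensity image with physical spacing.

    Parameters
    ----------
    data:
        Array of shape ``(n_channels, *spatial)``.
    channels:
        Mapping from channel name (e.g. ``"actin"``, ``"gfp"``) to the index
        along the first axis of ``data``.
    spacing:
        Physical size of one pixel along each *spatial* axis, in µm.
    provenance:
        Free-form processing log; operations append one line each.
    """

    data: np.ndarray
    channels: Dict[str, int]
    spacing: Tuple[float, ...]
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim < 2:
            raise ValueError("data must be (channels, *spatial)")
        self.spacing = _check_spacing(self.spacing, self.data.ndim - 1)
        n = self.data.shape[0]
        indices = sorted(self.channels.values())
        if len(set(self.channels)) != len(self.channels):
            raise ChannelError("duplicate channel names")
        if any(i < 0 or i >= n for i in indices):
            raise ChannelError(
                f"channel indices {indices} out of range for {n} channels"
            )

    @property
    def spatial_shape(self) -> Tuple[int, ...]:
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the 2D/3D array of the named channel."""
        if name not in self.channels:
            raise ChannelError(
                f"channel {name!r} not present (have {sorted(self.channels)})"
            )
        return self.data[self.channels[name]]

    def has_channel(self, name: str) -> bool:
        return name in self.channels

    def with_channel_data(self, name: str, new: np.ndarray, note: str) -> "RasterImage":
        """Copy of the image with one channel replaced and a log line appended."""
        if new.shape != self.spatial_shape:
            raise GridMismatchError(
                f"replacement channel shape {new.shape} != {self.spatial_shape}"
            )
        data = self.data.copy()
        data[self.channels[name]] = new
        return replace(
            self, data=data, channels=dict(self.channels),
            provenance=[*self.provenance, note],
        )


@dataclass
class LabelMap:
    """Integer-labelled segmentation; 0 is background."""

    labels: np.ndarray
    spacing: Tuple[float, ...]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer raster")
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing, self.labels.ndim)

    @property
    def ids(self) -> np.ndarray:
        """Sorted array of object labels present (background excluded)."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_objects(self) -> int:
        return int(self.ids.size)

    def pixel_volume(self) -> float:
        """Physical area (2D) or volume (3D) of one pixel, in µm^ndim."""
        return float(np.prod(self.spacing))


def _description(channels: Dict[str, int], spacing: Sequence[float]) -> str:
    return json.dumps({"lumenmorph": {"channels": channels, "spacing_um": list(spacing)}})


def write_stack(path: str | Path, image: RasterImage) -> None:
    """Write a RasterImage as a multi-page TIFF (one channel per page)."""
    tifffile.imwrite(
        str(path),
        np.asarray(image.data, dtype=np.float32),
        description=_description(image.channels, image.spacing),
    )


def read_stack(
    path: str | Path,
    channel_map: Dict[str, int] | None = None,
    spacing: Sequence[float] | None = None,
) -> RasterImage:
    """Read a multi-page TIFF into a RasterImage.

    ``channel_map`` and ``spacing`` override what is found in the file
    metadata; either must be supplied if the file carries no metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta: Dict = {}
    try:
        meta = json.loads(desc).get("lumenmorph", {})
    except (json.JSONDecodeError, AttributeError):
        meta = {}
    if data.ndim == 2:  # single-channel 2D file
        data = data[None]
    channels = channel_map if channel_map is not None else meta.get("channels")
    if channels is None:
        channels = {f"ch{i}": i for i in range(data.shape[0])}
    if max(channels.values()) >= data.shape[0]:
        raise FormatError(
            f"{path}: channel map {channels} needs more channels than the "
            f"{data.shape[0]} pages present"
        )
    sp = spacing if spacing is not None else meta.get("spacing_um")
    if sp is None:
        raise FormatError(f"{path}: no spacing metadata; pass spacing explicitly")
    return RasterImage(
        data=data,
        channels=dict(channels),
        spacing=tuple(float(s) for s in sp),
        provenance=[f"read {path}"],
    )


def write_labels(path: str | Path, labels: LabelMap) -> None:
    """Write a LabelMap as a 16-bit TIFF."""
    if labels.labels.max(initial=0) >= 2**16:
        raise ValueError("more than 65535 objects; cannot write 16-bit labels")
    tifffile.imwrite(
        str(path),
        labels.labels.astype(np.uint16),
        description=_description({}, labels.spacing),
    )


def read_labels(path: str | Path, spacing: Sequence[float] | None = None) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    try:
        meta = json.loads(desc).get("lumenmorph", {})
    except (json.JSONDecodeError, AttributeError):
        meta = {}
    sp = spacing if spacing is not None else meta.get("spacing_um")
    if sp is None:
        raise FormatError(f"{path}: no spacing metadata; pass spacing explicitly")
    return LabelMap(labels=data.astype(np.int32), spacing=tuple(float(s) for s in sp))
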
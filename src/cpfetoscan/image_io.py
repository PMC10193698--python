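"""Tile-scan, z-stack and mask containers with explicit acquisition geometry.

All pixel coordinates are 0-based ``(row, col)`` with the origin at the
top-left; geometry is carried in micrometres and reported in mm^2 / mm^3.
TIFF is the single raster dialect; channel roles are resolved through a
sidecar JSON (never by page order when metadata is present).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: sidecar JSON channel labels, in storage order
CHANNEL_LABELS = ("SHG405", "TPAF550")


@dataclass
class TileScan:
    """One two-channel tile scan.

    ``narrow_channel`` holds the 405/10 nm band (second harmonic
    generation from collagen plus particle white light); ``broad_channel``
    holds the 550/200 nm band (tissue autofluorescence plus particle
    white light).
    """

    narrow_channel: np.ndarray
    broad_channel: np.ndarray
    pixel_size_um: float
    section_thickness_um: float = 7.0
    sample_id: str = ""
    region_id: str = ""

    def __post_init__(self) -> None:
        self.narrow_channel = np.asarray(self.narrow_channel)
        self.broad_channel = np.asarray(self.broad_channel)
        if self.narrow_channel.shape != self.broad_channel.shape:
            raise ValueError(
                f"channel shape mismatch: {self.narrow_channel.shape} vs {self.broad_channel.shape}"
            )
        if self.narrow_channel.ndim != 2 or self.narrow_channel.size == 0:
            raise ValueError("channels must be non-empty 2-D arrays")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.narrow_channel.shape

    @property
    def tile_area_mm2(self) -> float:
        r, c = self.shape
        return r * c * (self.pixel_size_um * 1e-3) ** 2


@dataclass
class ZStack:
    """Ordered optical sections through a tissue section."""

    slices: np.ndarray  # (n_slices, rows, cols)
    slice_spacing_um: float
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise ValueError("ZStack needs >=1 uniformly shaped slice")
        if not (self.slice_spacing_um > 0 and self.pixel_size_um > 0):
            raise ValueError("spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]


@dataclass
class TissueMask:
    """Boolean tissue mask co-registered to a tile scan."""

    mask: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")

    @property
    def area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.pixel_size_um * 1e-3) ** 2


def write_tile(path: str | Path, tile: TileScan) -> Path:
    """Write a tile as a 2-page TIFF plus sidecar JSON geometry metadata."""
    path = Path(path)
    stack = np.stack([tile.narrow_channel, tile.broad_channel])
    tifffile.imwrite(path, stack)
    meta = {
        "channels": list(CHANNEL_LABELS),
        "pixel_size_um": tile.pixel_size_um,
        "section_thickness_um": tile.section_thickness_um,
        "sample_id": tile.sample_id,
        "region_id": tile.region_id,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def read_tile(path: str | Path, metadata: dict | None = None) -> TileScan:
    """Read a two-channel TIFF tile, mapping channels to roles via metadata.

    Parameters
    ----------
    path:
        TIFF file with >=2 pages/channels.
    metadata:
        Geometry and channel-role dict.  When ``None``, the sidecar JSON
        written by :func:`write_tile` is read from ``path`` with a
        ``.json`` suffix.  ``pixel_size_um`` is mandatory: loads are
        volumetric, so a tile without physical pixel size is unusable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if metadata is None:
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise ValueError(f"no metadata given and no sidecar JSON at {sidecar}")
        metadata = json.loads(sidecar.read_text())
    if "pixel_size_um" not in metadata:
        raise ValueError("missing pixel size — volumetric loads require physical geometry")

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        raise ValueError("missing channel: single-channel file, need narrow and broad bands")
    if arr.ndim != 3 or arr.shape[0] < 2:
        raise ValueError(f"cannot resolve >=2 channels from array of shape {arr.shape}")

    channels = metadata.get("channels", list(CHANNEL_LABELS))
    try:
        i_narrow = channels.index("SHG405")
        i_broad = channels.index("TPAF550")
    except ValueError as exc:
        raise ValueError(f"channel roles not resolvable from metadata {channels!r}") from exc

    return TileScan(
        narrow_channel=arr[i_narrow],
        broad_channel=arr[i_broad],
        pixel_size_um=float(metadata["pixel_size_um"]),
        section_thickness_um=float(metadata.get("section_thickness_um", 7.0)),
        sample_id=str(metadata.get("sample_id", "")),
        region_id=str(metadata.get("region_id", "")),
    )


def write_mask(path: str | Path, mask: TissueMask) -> Path:
    path = Path(path)
    tifffile.imwrite(path, mask.mask.astype(np.uint8) * 255)
    return path


def read_mask(path: str | Path, pixel_size_um: float) -> TissueMask:
    return TissueMask(tifffile.imread(Path(path)) > 0, pixel_size_um)


def orthogonal_projections(z: ZStack) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-intensity xz- and yz-projections of a z-stack.

    Returns ``(xz, yz)`` where ``xz`` has shape (n_slices, cols) — the
    projection along the row (y) axis — and ``yz`` has shape
    (n_slices, rows).  Axis scaling differs between the two array axes
    (slice spacing vs pixel size); both are recorded on the stack.
    """
    if z.n_slices < 2:
        raise ValueError("orthogonal projections need >=2 slices")
    xz = z.slices.max(axis=1)
    yz = z.slices.max(axis=2)
    return xz, yz
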
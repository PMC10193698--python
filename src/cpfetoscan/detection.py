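"""Dual-channel saturation particle caller.

A carbon particle emits broadband light that saturates both detection
channels, while collagen second harmonic generation and tissue
autofluorescence each dominate only one band.  The caller therefore
thresholds each channel at a fraction of its own per-tile maximum
(99.5% of the narrow-channel maximum, 55% of the broad-channel
maximum), intersects the two masks, and reports connected components of
the intersection as particles.  A z-stack check classifies calls as
tissue-embedded vs surface contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import TileScan, ZStack

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass
class DetectionParams:
    """Caller thresholds and component rules.

    ``narrow_fraction`` / ``broad_fraction`` are fractions of each
    channel's per-tile maximum intensity (the tile is the acquisition
    unit).  "Connected pixels" default to 8-connectivity — the safer
    reading for few-pixel saturated blobs — and every component of at
    least ``min_component_px`` pixels is one particle; no sub-peak
    splitting is attempted because the method counts thresholded
    overlapping pixels, not resolved peaks.
    """

    narrow_fraction: float = 0.995
    broad_fraction: float = 0.55
    connectivity: int = 8
    min_component_px: int = 1

    def __post_init__(self) -> None:
        for f in (self.narrow_fraction, self.broad_fraction):
            if not (0.0 < f <= 1.0):
                raise ValueError("threshold fractions must be in (0, 1]")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >=1")


@dataclass
class ParticleCallSet:
    """Particle calls for one tile, with thresholds used."""

    centroids: np.ndarray  # (n, 2) pixel-count-weighted (row, col)
    pixel_counts: np.ndarray  # (n,)
    labels: np.ndarray  # labelled intersection mask, 0 = background
    n_particles: int
    narrow_max: float
    broad_max: float
    narrow_threshold: float
    broad_threshold: float
    sample_id: str = ""
    region_id: str = ""


def channel_threshold(channel: np.ndarray, fraction: float) -> np.ndarray:
    """Mask of pixels at or above ``fraction`` of the channel maximum.

    The comparison is ``>=`` so that all pixels tied at the maximum
    (saturated pixels) pass by construction.  A constant-zero channel
    yields an empty mask with a warning: no particles are callable.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("empty channel")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    peak = float(channel.max())
    if peak <= 0:
        warnings.warn("constant-zero channel: no particles callable", stacklevel=2)
        return np.zeros(channel.shape, dtype=bool)
    return channel >= fraction * peak


def call_particles(tile: TileScan, params: DetectionParams | None = None) -> ParticleCallSet:
    """Call particles on a tile: threshold both channels, intersect, label.

    Only pixels thresholded in BOTH channels simultaneously count — a
    bright collagen structure confined to the narrow channel never
    yields a call.  Each connected component of the intersection mask
    with at least ``min_component_px`` pixels is one particle; its
    centroid is the unweighted mean of its pixel coordinates.
    """
    params = params or DetectionParams()
    if tile.narrow_channel.shape != tile.broad_channel.shape:
        raise ValueError("channel shape mismatch")

    narrow_max = float(tile.narrow_channel.max())
    broad_max = float(tile.broad_channel.max())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        narrow_mask = channel_threshold(tile.narrow_channel, params.narrow_fraction)
        broad_mask = channel_threshold(tile.broad_channel, params.broad_fraction)
    overlap = narrow_mask & broad_mask

    labels, n = ndimage.label(overlap, structure=_STRUCTURES[params.connectivity])
    if n and params.min_component_px > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = np.flatnonzero(sizes >= params.min_component_px) + 1
        relabel = np.zeros(n + 1, dtype=labels.dtype)
        relabel[keep] = np.arange(1, len(keep) + 1)
        labels = relabel[labels]
        n = len(keep)

    if n:
        rows, cols = np.nonzero(labels)
        lab = labels[rows, cols]
        counts = np.bincount(lab, minlength=n + 1)[1:]
        centroids = np.stack(
            [
                np.bincount(lab, weights=rows, minlength=n + 1)[1:] / counts,
                np.bincount(lab, weights=cols, minlength=n + 1)[1:] / counts,
            ],
            axis=1,
        )
    else:
        centroids = np.empty((0, 2))
        counts = np.empty(0, dtype=int)

    return ParticleCallSet(
        centroids=centroids,
        pixel_counts=counts,
        labels=labels,
        n_particles=int(n),
        narrow_max=narrow_max,
        broad_max=broad_max,
        narrow_threshold=params.narrow_fraction * narrow_max,
        broad_threshold=params.broad_fraction * broad_max,
        sample_id=tile.sample_id,
        region_id=tile.region_id,
    )


def verify_embedment(z: ZStack, centroid: tuple[float, float], window_px: int = 4) -> str:
    """Classify a call as ``embedded``, ``surface`` or ``indeterminate``.

    The axial intensity profile is taken as the per-slice maximum in a
    small window around the centroid.  ``embedded`` requires the
    profile maximum in an interior slice with signal spanning >=2
    slices; signal confined to a boundary slice is ``surface``; an
    empty or ambiguous profile is ``indeterminate``.
    """
    row, col = centroid
    n_slices, n_rows, n_cols = z.slices.shape
    if not (0 <= row < n_rows and 0 <= col < n_cols):
        raise ValueError("centroid outside stack")
    if n_slices < 3:
        raise ValueError("stack too shallow for embedment verification")
    r0, r1 = max(0, int(row) - window_px), min(n_rows, int(row) + window_px + 1)
    c0, c1 = max(0, int(col) - window_px), min(n_cols, int(col) + window_px + 1)
    profile = z.slices[:, r0:r1, c0:c1].reshape(n_slices, -1).max(axis=1)

    floor = np.median(profile)
    signal = profile - floor
    peak = signal.max()
    if peak <= 5 * max(1.0, float(np.std(signal[signal <= np.quantile(signal, 0.5)]))):
        return "indeterminate"
    above = np.flatnonzero(signal > 0.3 * peak)
    peak_slice = int(np.argmax(signal))
    if peak_slice in (0, n_slices - 1):
        return "surface"
    if len(above) >= 2:
        return "embedded"
    return "indeterminate"
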
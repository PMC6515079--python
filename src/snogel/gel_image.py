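"""Synthetic gel rendering and spot quantification.

This optional stage closes the loop between spot-volume tables and images:
spots are rendered as isotropic 2-D Gaussians on a pI x molecular-weight
grid, and quantified back by background-subtracted disc integration around
*supplied* coordinates.  Spot correspondence is an input, not an inference —
the pipeline's contract is that the same spot id addresses the same protein
on every gel, so no detection or cross-gel registration is attempted.

Axes follow 2DE convention: pI (pH) increases left to right; molecular
weight runs top (high) to bottom (low) on a log10 scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from scipy.special import ndtr

__all__ = [
    "ImageParams",
    "GelImage",
    "render_gel",
    "quantify_spots",
    "write_tiff",
    "read_tiff",
    "CoordinateError",
]


class CoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class ImageParams:
    """Grid geometry: image shape and axis ranges."""

    shape: tuple[int, int] = (512, 512)  # rows (MW axis), cols (pI axis)
    pi_range: tuple[float, float] = (3.0, 11.0)
    mw_range_kda: tuple[float, float] = (5.0, 300.0)

    def __post_init__(self) -> None:
        if self.shape[0] < 16 or self.shape[1] < 16:
            raise CoordinateError("image must be at least 16x16")
        if not (self.pi_range[0] < self.pi_range[1] and 0 < self.mw_range_kda[0] < self.mw_range_kda[1]):
            raise CoordinateError("axis ranges must be strictly ordered and positive")


@dataclass
class GelImage:
    """A rendered or loaded gel image with its axis mapping."""

    pixels: np.ndarray
    params: ImageParams
    gel_id: str = ""
    channel: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise CoordinateError("pixels must be a 2-D array")
        if self.pixels.shape != self.params.shape:
            raise CoordinateError("pixel grid does not match image params")
        if (self.pixels < 0).any():
            raise CoordinateError("intensities must be non-negative")

    # axis helpers: x in pI units, y in log10(kDa); row 0 = highest MW
    def x_edges(self) -> np.ndarray:
        lo, hi = self.params.pi_range
        return np.linspace(lo, hi, self.params.shape[1] + 1)

    def y_edges(self) -> np.ndarray:
        lo, hi = np.log10(self.params.mw_range_kda)
        return np.linspace(hi, lo, self.params.shape[0] + 1)  # descending

    def x_centers(self) -> np.ndarray:
        e = self.x_edges()
        return 0.5 * (e[:-1] + e[1:])

    def y_centers(self) -> np.ndarray:
        e = self.y_edges()
        return 0.5 * (e[:-1] + e[1:])

    def integral(self) -> float:
        return float(self.pixels.sum())


def _check_coords(
    coords: Mapping[str, tuple[float, float]], params: ImageParams
) -> None:
    lo_pi, hi_pi = params.pi_range
    lo_mw, hi_mw = params.mw_range_kda
    for sid, (pi, mw) in coords.items():
        if not (lo_pi <= pi <= hi_pi and lo_mw <= mw <= hi_mw):
            raise CoordinateError(
                f"spot {sid!r} at (pI={pi}, MW={mw} kDa) lies outside the axes"
            )


def render_gel(
    volumes: Mapping[str, float],
    coords: Mapping[str, tuple[float, float]],
    psf_sigma: float,
    params: ImageParams = ImageParams(),
    *,
    gel_id: str = "",
    channel: str = "",
) -> GelImage:
    """Render spots as isotropic Gaussians whose integrals equal the volumes.

    Each spot deposits per-pixel the exact Gaussian mass falling in the
    pixel (product of CDF differences along each axis), so the image
    integral matches the summed volumes up to the mass lying outside the
    frame.  ``psf_sigma`` is the spot width in axis units (pH horizontally,
    log10 kDa vertically).
    """
    if psf_sigma <= 0:
        raise CoordinateError("psf_sigma must be > 0")
    missing = set(volumes) - set(coords)
    if missing:
        raise CoordinateError(f"spots without coordinates: {sorted(missing)[:5]}")
    _check_coords({s: coords[s] for s in volumes}, params)

    pixels = np.zeros(params.shape)
    img = GelImage(pixels, params, gel_id=gel_id, channel=channel)
    xe, ye = img.x_edges(), img.y_edges()
    for sid, v in volumes.items():
        if v < 0:
            raise CoordinateError(f"spot {sid!r}: negative volume")
        if v == 0:
            continue
        pi, mw = coords[sid]
        y0 = np.log10(mw)
        cx = ndtr((xe - pi) / psf_sigma)
        # y edges descend; flip the difference to keep masses positive
        cy = ndtr((ye - y0) / psf_sigma)
        mass_x = np.diff(cx)
        mass_y = -np.diff(cy)
        pixels += v * np.outer(mass_y, mass_x)
    img.pixels = pixels
    return img


def quantify_spots(
    image: GelImage,
    coords: Mapping[str, tuple[float, float]],
    radius: float,
) -> tuple[dict[str, float], set[str]]:
    """Background-subtracted integrated intensity in a disc per coordinate.

    The background is the median pixel intensity outside all discs,
    subtracted per pixel and clamped at zero.  Returns the per-spot volumes
    and the set of spot ids whose discs overlap another disc (values are
    still returned for those).  Distances are measured in axis units
    (pH, log10 kDa), matching the isotropic rendering PSF.
    """
    if radius <= 0:
        raise CoordinateError("radius must be > 0")
    _check_coords(coords, image.params)

    xc = image.x_centers()
    yc = image.y_centers()
    xx, yy = np.meshgrid(xc, yc)

    masks: dict[str, np.ndarray] = {}
    centers: dict[str, tuple[float, float]] = {}
    for sid, (pi, mw) in coords.items():
        y0 = np.log10(mw)
        masks[sid] = (xx - pi) ** 2 + (yy - y0) ** 2 <= radius**2
        centers[sid] = (pi, y0)

    any_disc = np.zeros(image.params.shape, dtype=bool)
    for m in masks.values():
        any_disc |= m
    outside = image.pixels[~any_disc]
    background = float(np.median(outside)) if outside.size else 0.0
    corrected = np.clip(image.pixels - background, 0.0, None)

    overlapping: set[str] = set()
    ids = list(coords)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            dx = centers[a][0] - centers[b][0]
            dy = centers[a][1] - centers[b][1]
            if dx * dx + dy * dy < (2 * radius) ** 2:
                overlapping.add(a)
                overlapping.add(b)

    volumes = {sid: float(corrected[m].sum()) for sid, m in masks.items()}
    return volumes, overlapping


# -- 16-bit TIFF I/O ----------------------------------------------------- #

def write_tiff(image: GelImage, path: str | Path, *, max_count: int = 60000) -> float:
    """Write as 16-bit grayscale TIFF; returns the counts-per-unit gain used.

    Intensities are scaled so the brightest pixel reads ``max_count``
    (emulating fixed-target scanner gain); the gain and axis metadata are
    stored in the TIFF description for lossless-enough round-tripping.
    """
    import tifffile

    peak = float(image.pixels.max())
    gain = max_count / peak if peak > 0 else 1.0
    data = np.round(image.pixels * gain).astype(np.uint16)
    meta = {
        "gain": gain,
        "gel_id": image.gel_id,
        "channel": image.channel,
        "shape": list(image.params.shape),
        "pi_range": list(image.params.pi_range),
        "mw_range_kda": list(image.params.mw_range_kda),
    }
    tifffile.imwrite(str(path), data, description=json.dumps(meta))
    return gain


def read_tiff(path: str | Path) -> GelImage:
    """Read a gel TIFF written by :func:`write_tiff`, undoing the gain."""
    import tifffile

    with tifffile.TiffFile(str(path)) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(float)
        meta = json.loads(page.tags["ImageDescription"].value)
    params = ImageParams(
        shape=tuple(meta["shape"]),
        pi_range=tuple(meta["pi_range"]),
        mw_range_kda=tuple(meta["mw_range_kda"]),
    )
    return GelImage(
        data / meta["gain"], params, gel_id=meta["gel_id"], channel=meta["channel"]
    )
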
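"""Raster images of enriched 2-D maps, rigid registration, texturing.

A map is rasterized by splatting each vertex as a small disc, with up
to three feature channels normalized into 8-bit intensities. Two maps
are compared by exhaustive rigid search (rotation grid x best integer
translation) maximizing normalized cross-correlation, and an arbitrary
image can be textured back onto the 3-D surface through the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from skimage.feature import match_template
from skimage.transform import rotate as _sk_rotate

from .types import (
    ArgumentError,
    Embedding2D,
    FeatureField,
    SurfcartError,
    TriMesh3D,
)


@dataclass
class MapTransform:
    """Affine map-coordinate <-> pixel-index transform.

    Pixel column = (x - x0) / scale, pixel row = (y1 - y) / scale
    (row 0 is the top of the raster); ``scale`` is map units per pixel.
    """

    scale: float
    x0: float
    y1: float

    def to_pixel(self, coords: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        c = np.atleast_2d(np.asarray(coords, dtype=float))
        cols = (c[:, 0] - self.x0) / self.scale
        rows = (self.y1 - c[:, 1]) / self.scale
        return rows, cols

    def to_map(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        x = self.x0 + np.asarray(cols, dtype=float) * self.scale
        y = self.y1 - np.asarray(rows, dtype=float) * self.scale
        return np.column_stack([x, y])


@dataclass
class SurfaceImage:
    """8-bit multi-channel raster of a surface map.

    ``mask`` marks pixels covered by at least one splat; uncovered
    pixels are zero.
    """

    pixels: np.ndarray  # (H, W, C) uint8
    channel_semantics: Tuple[str, ...]
    transform: MapTransform
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = self.pixels[:, :, None]
        if self.pixels.dtype != np.uint8:
            raise ArgumentError("pixels must be 8-bit")
        self.channel_semantics = tuple(self.channel_semantics)
        if len(self.channel_semantics) != self.pixels.shape[2]:
            raise ArgumentError(
                f"{len(self.channel_semantics)} channel tags for "
                f"{self.pixels.shape[2]} channels"
            )
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape[:2]:
                raise ArgumentError("mask shape must match the raster")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.pixels.shape

    def grayscale(self) -> np.ndarray:
        """Channel-averaged float image in [0, 1]."""
        return self.pixels.astype(float).mean(axis=2) / 255.0


@dataclass
class RigidTransform2D:
    """Rotation (about the image center) + integer pixel translation,
    optionally preceded by a left-right reflection; ``score`` is the
    NCC value achieved at this pose."""

    rotation: float  # radians
    translation: Tuple[float, float] = (0.0, 0.0)  # (row, col) pixels
    reflected: bool = False
    score: float = 0.0

    params: dict = field(default_factory=dict)


def _normalize_field(f: FeatureField) -> np.ndarray:
    lo, hi = f.clip_range
    if hi <= lo:
        hi = lo + 1.0
    x = np.clip(f.values, lo, hi)
    return np.round((x - lo) / (hi - lo) * 255.0).astype(np.uint8)


def rasterize(
    emb: Embedding2D,
    fields: Sequence[FeatureField],
    resolution: int = 256,
    splat_radius: int = 2,
) -> SurfaceImage:
    """Splat an enriched map into a multi-channel 8-bit raster.

    The map bounding box is fitted to the raster with a 5% margin and
    preserved aspect ratio (the longest side spans ``resolution``
    pixels). Each vertex paints a disc of ``splat_radius`` pixels;
    where discs overlap the nearest vertex wins. Each field is
    normalized to 0..255 over its own clip range, so assigned colors
    do not depend on the raster size.
    """
    if resolution < 16:
        raise ArgumentError("resolution must be >= 16 pixels")
    if not (1 <= len(fields) <= 3):
        raise ArgumentError("need 1 to 3 feature channels")
    for f in fields:
        if len(f) != emb.n_points:
            raise ArgumentError("field not aligned with the embedding")

    xy = emb.coords
    span = xy.max(axis=0) - xy.min(axis=0)
    if np.all(span == 0.0):
        if emb.n_points > 1:
            raise ArgumentError("embedding has zero extent")
        span = np.array([1.0, 1.0])  # lone vertex: unit frame around it
    margin = 0.05 * max(span.max(), 1e-12)
    lo = xy.min(axis=0) - margin
    hi = xy.max(axis=0) + margin
    extent = hi - lo
    scale = extent.max() / (resolution - 1)
    width = max(int(np.ceil(extent[0] / scale)) + 1, 1)
    height = max(int(np.ceil(extent[1] / scale)) + 1, 1)
    transform = MapTransform(scale=scale, x0=lo[0], y1=hi[1])

    channels = np.stack([_normalize_field(f) for f in fields], axis=1)  # (n, C)
    rows, cols = transform.to_pixel(xy)

    best = np.full((height, width), np.inf)
    owner = np.full((height, width), -1, dtype=np.int64)
    r = int(splat_radius)
    for i in range(emb.n_points):
        r0 = int(np.floor(rows[i])) - r
        c0 = int(np.floor(cols[i])) - r
        for rr in range(max(r0, 0), min(r0 + 2 * r + 2, height)):
            for cc in range(max(c0, 0), min(c0 + 2 * r + 2, width)):
                d = np.hypot(rr - rows[i], cc - cols[i])
                if d <= r + 0.5 and d < best[rr, cc]:
                    best[rr, cc] = d
                    owner[rr, cc] = i
    mask = owner >= 0
    pixels = np.zeros((height, width, len(fields)), dtype=np.uint8)
    pixels[mask] = channels[owner[mask]]
    return SurfaceImage(
        pixels=pixels,
        channel_semantics=tuple(f.kind for f in fields),
        transform=transform,
        mask=mask,
    )


def _pad_to(img: np.ndarray, shape: Tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=img.dtype)
    out[: img.shape[0], : img.shape[1]] = img
    return out


def _shift_int(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(img)
    h, w = img.shape[:2]
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = img[src_r, src_c]
    return out


def _masked_ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two images over the masked pixels."""
    av = a[mask]
    bv = b[mask]
    if av.size < 16:
        return -np.inf
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    if denom == 0.0:
        return -np.inf
    return float((av * bv).sum() / denom)


def register_rigid(
    a: SurfaceImage,
    b: SurfaceImage,
    angle_step: float = 2.0,
    allow_reflection: bool = False,
) -> RigidTransform2D:
    """Best rigid pose of B onto A by exhaustive NCC search.

    Rotations are scanned from 0 to 360 degrees in ``angle_step``
    increments (optionally with a reflected copy of B). For each
    rotation a fast cross-correlation proposes the best integer
    translation, and the pose is scored by normalized cross-correlation
    over the pixels where both images are covered; the pose with the
    highest overlap NCC is returned. Raises on constant
    (zero-variance) inputs, for which NCC is undefined, and when no
    pose yields an overlap.
    """
    ag = a.grayscale()
    bg = b.grayscale()
    if np.ptp(ag) == 0.0 or np.ptp(bg) == 0.0:
        raise SurfcartError("NCC undefined for a constant image")

    shape = (max(ag.shape[0], bg.shape[0]), max(ag.shape[1], bg.shape[1]))
    ag = _pad_to(ag, shape)
    bg = _pad_to(bg, shape)
    a_mask = _pad_to(np.asarray(a.mask, dtype=float), shape) > 0.5
    b_mask = _pad_to(np.asarray(b.mask, dtype=float), shape)
    center = (shape[0] // 2, shape[1] // 2)

    best = RigidTransform2D(rotation=0.0, score=-np.inf)
    angles = np.arange(0.0, 360.0, angle_step)
    for reflected in ([False, True] if allow_reflection else [False]):
        base = bg[:, ::-1] if reflected else bg
        base_mask = b_mask[:, ::-1] if reflected else b_mask
        for ang in angles:
            rot = _sk_rotate(base, ang, resize=False, preserve_range=True)
            if np.ptp(rot) == 0.0:
                continue
            rot_mask = (
                _sk_rotate(base_mask, ang, resize=False, preserve_range=True)
                > 0.5
            )
            ncc = match_template(ag, rot, pad_input=True)
            peak = np.unravel_index(np.argmax(ncc), ncc.shape)
            dr, dc = peak[0] - center[0], peak[1] - center[1]
            overlap = a_mask & _shift_int(rot_mask, dr, dc)
            score = _masked_ncc(ag, _shift_int(rot, dr, dc), overlap)
            if score > best.score:
                best = RigidTransform2D(
                    rotation=np.deg2rad(ang),
                    translation=(float(dr), float(dc)),
                    reflected=reflected,
                    score=score,
                )
    if not np.isfinite(best.score):
        raise SurfcartError("no overlapping pose found")
    return best


def _apply_rigid(img: np.ndarray, transform: RigidTransform2D) -> np.ndarray:
    out = img[:, ::-1] if transform.reflected else img
    out = _sk_rotate(
        out.astype(float),
        np.rad2deg(transform.rotation),
        resize=False,
        preserve_range=True,
        order=0,
    )
    dr = int(round(transform.translation[0]))
    dc = int(round(transform.translation[1]))
    return _shift_int(out, dr, dc)


def superpose(
    a: SurfaceImage, b: SurfaceImage, transform: RigidTransform2D
) -> Tuple[SurfaceImage, float]:
    """Resample B into A's frame under ``transform`` (nearest neighbor)
    and blend 50/50 where both cover a pixel.

    Returns (blended image, overlap fraction over the union of the two
    coverage masks); a zero overlap raises a warning.
    """
    shape = (
        max(a.pixels.shape[0], b.pixels.shape[0]),
        max(a.pixels.shape[1], b.pixels.shape[1]),
    )
    n_chan = a.pixels.shape[2]
    if b.pixels.shape[2] != n_chan:
        raise ArgumentError("channel counts differ")

    a_px = np.zeros(shape + (n_chan,), dtype=float)
    a_px[: a.pixels.shape[0], : a.pixels.shape[1]] = a.pixels
    a_mask = _pad_to(a.mask, shape)

    b_px = np.zeros(shape + (n_chan,), dtype=float)
    b_px[: b.pixels.shape[0], : b.pixels.shape[1]] = b.pixels
    b_mask = _pad_to(b.mask, shape)
    b_warp = np.stack(
        [_apply_rigid(b_px[:, :, c], transform) for c in range(n_chan)], axis=2
    )
    b_mask_warp = _apply_rigid(b_mask.astype(float), transform) > 0.5

    both = a_mask & b_mask_warp
    either = a_mask | b_mask_warp
    out = np.zeros_like(a_px)
    out[a_mask] = a_px[a_mask]
    out[b_mask_warp & ~a_mask] = b_warp[b_mask_warp & ~a_mask]
    out[both] = 0.5 * a_px[both] + 0.5 * b_warp[both]
    overlap = float(both.sum() / either.sum()) if either.any() else 0.0
    if overlap == 0.0:
        warnings.warn("superposition has zero overlap", stacklevel=2)
    return (
        SurfaceImage(
            pixels=np.clip(np.round(out), 0, 255).astype(np.uint8),
            channel_semantics=a.channel_semantics,
            transform=a.transform,
            mask=either,
        ),
        overlap,
    )


def texture_assign(emb: Embedding2D, image: SurfaceImage) -> np.ndarray:
    """Sample the containing pixel of each map point.

    Returns vertex-aligned (n, C) uint8 colors; a point falling
    outside the raster is an error.
    """
    rows, cols = image.transform.to_pixel(emb.coords)
    r = np.round(rows).astype(int)
    c = np.round(cols).astype(int)
    h, w = image.pixels.shape[:2]
    bad = (r < 0) | (r >= h) | (c < 0) | (c >= w)
    if bad.any():
        raise ArgumentError(
            f"{int(bad.sum())} map points fall outside the image"
        )
    return image.pixels[r, c]


def colorize_mesh(
    mesh: TriMesh3D, vertex_colors: np.ndarray, path: str
) -> None:
    """Write the mesh as an ASCII PLY with per-vertex RGB colors.

    Viewers interpolate the vertex colors across each triangle, which
    reproduces the smooth textured appearance on the 3-D surface.
    """
    from .surface_io import write_ply

    vertex_colors = np.asarray(vertex_colors)
    if vertex_colors.shape[0] != mesh.n_vertices:
        raise ArgumentError("vertex_colors length must match vertex count")
    if vertex_colors.ndim != 2 or vertex_colors.shape[1] not in (1, 3):
        raise ArgumentError("vertex_colors must be (n, 1) or (n, 3)")
    if vertex_colors.shape[1] == 1:
        vertex_colors = np.repeat(vertex_colors, 3, axis=1)
    write_ply(mesh, path, vertex_colors=vertex_colors)
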
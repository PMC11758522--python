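"""Virtual thin sections and cementum straightening.

Tomographic cementum data arrive as stacks of transverse slices.  Two
preprocessing steps precede any increment measurement:

* **virtual thin section (VTS)** — averaging a short run of aligned
  slices (10 by default) to boost the contrast of annual increments
  relative to uncorrelated noise;
* **straightening** — resampling an annotated annular cementum region
  (between the cementum-dentine junction and the outer root surface)
  into a rectangular array whose rows are radial distance from the
  inner boundary and whose columns are circumferential position.

Region-of-interest boundaries are supplied as polylines (the choice of
region is an expert call, not automated here).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.measure import label, regionprops

__all__ = [
    "VirtualThinSection",
    "RoiAnnotation",
    "StraightenedCementum",
    "make_vts",
    "straighten",
    "trim_boundary_artifacts",
    "screen_voids",
    "read_stack",
]


@dataclass
class VirtualThinSection:
    """One z-projected slice window of an image stack."""

    pixels: np.ndarray  # 2D uint8
    voxel_size_um: float
    source_slices: tuple[int, int]  # (start, count)
    specimen_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("VTS pixels must be 2D")


@dataclass
class RoiAnnotation:
    """Inner/outer cementum boundary polylines in pixel coordinates.

    Polylines are ``(N, 2)`` arrays of ``(row, col)`` vertices.  The
    inner polyline traces the cementum-dentine junction (hyaline layer),
    the outer one the root surface.  ``exclusion_mask`` marks pixels
    (voids, damage) that must not contribute to any straightened column.
    """

    inner_boundary: np.ndarray
    outer_boundary: np.ndarray
    exclusion_mask: np.ndarray | None = None
    roi_id: str = ""

    def __post_init__(self):
        self.inner_boundary = np.asarray(self.inner_boundary, dtype=float)
        self.outer_boundary = np.asarray(self.outer_boundary, dtype=float)
        for name, poly in (
            ("inner_boundary", self.inner_boundary),
            ("outer_boundary", self.outer_boundary),
        ):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 2:
                raise ValueError(f"{name} must be an (N>=2, 2) polyline")


@dataclass
class StraightenedCementum:
    """Cementum resampled to radial (rows) x circumferential (cols).

    Row 0 is the inner boundary.  ``row_step_um`` gives the per-column
    radial sampling step in μm, so position of row ``r`` in column ``c``
    is ``r * row_step_um[c]``; for already-straight synthetic input the
    step equals the voxel size everywhere.
    """

    pixels: np.ndarray
    voxel_size_um: float
    row_step_um: np.ndarray | None = None
    provenance: tuple = ()

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.row_step_um is None:
            self.row_step_um = np.full(self.pixels.shape[1], self.voxel_size_um)
        else:
            self.row_step_um = np.asarray(self.row_step_um, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def read_stack(path: str | Path) -> np.ndarray:
    """Read a multi-page TIFF (or a directory of single-page TIFFs)."""
    import tifffile

    p = Path(path)
    if p.is_dir():
        pages = sorted(p.glob("*.tif")) + sorted(p.glob("*.tiff"))
        if not pages:
            raise FileNotFoundError(f"no TIFF slices in {p}")
        return np.stack([tifffile.imread(f) for f in pages])
    arr = tifffile.imread(p)
    return arr if arr.ndim == 3 else arr[None]


def make_vts(
    stack: np.ndarray,
    center_slice: int,
    n_slices: int = 10,
    voxel_size_um: float = 1.0,
    specimen_id: str = "",
) -> VirtualThinSection:
    """Z-project a window of ``n_slices`` slices into one thin section.

    Each output pixel is the arithmetic mean of the aligned input
    pixels, rounded half-up to 8 bits (half-up so results are identical
    across platforms).

    The window is centered on ``center_slice``: it spans
    ``[center_slice - n_slices//2, ...)`` and must fit in the stack.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D (slices, rows, cols)")
    nz = stack.shape[0]
    start = center_slice - n_slices // 2
    if n_slices < 1 or start < 0 or start + n_slices > nz:
        lo, hi = n_slices // 2, nz - (n_slices - n_slices // 2)
        raise ValueError(
            f"VTS window of {n_slices} slices at center {center_slice} exceeds "
            f"stack bounds; valid centers are [{lo}, {hi}]"
        )
    mean = stack[start : start + n_slices].astype(np.float64).mean(axis=0)
    pixels = np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)
    return VirtualThinSection(
        pixels=pixels,
        voxel_size_um=voxel_size_um,
        source_slices=(start, n_slices),
        specimen_id=specimen_id,
    )


def vts_centers(usable_range: tuple[int, int], n_vts: int = 9) -> list[int]:
    """Centers of ``n_vts`` evenly spaced VTS through a usable slice range.

    spacing = floor(range / n_vts); the first center sits at
    ``start + spacing // 2``.
    """
    start, stop = usable_range
    span = stop - start
    if span < n_vts:
        raise ValueError(f"slice range {usable_range} too short for {n_vts} VTS")
    spacing = span // n_vts
    return [start + spacing // 2 + k * spacing for k in range(n_vts)]


# ---------------------------------------------------------------------------
# straightening


def _resample_polyline(poly: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to n points equally spaced by arc length."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] == 0:
        raise ValueError("degenerate polyline with zero length")
    target = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, poly[:, 0])
    out[:, 1] = np.interp(target, s, poly[:, 1])
    return out


def _normals(points: np.ndarray, toward: np.ndarray) -> np.ndarray:
    """Unit normals of a resampled polyline, oriented toward `toward` points."""
    tang = np.gradient(points, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    nrm = np.stack([-tang[:, 1], tang[:, 0]], axis=1)
    flip = np.einsum("ij,ij->i", nrm, toward - points) < 0
    nrm[flip] *= -1.0
    return nrm


def _ray_polyline_intersection(
    origin: np.ndarray, direction: np.ndarray, poly: np.ndarray
) -> float | None:
    """Distance along a ray to its first crossing of a polyline, or None."""
    from shapely.geometry import LineString

    far = np.linalg.norm(poly.max(axis=0) - poly.min(axis=0)) + np.linalg.norm(
        origin - poly.mean(axis=0)
    )
    ray = LineString([tuple(origin), tuple(origin + direction * (far + 1.0))])
    hit = ray.intersection(LineString([tuple(p) for p in poly]))
    if hit.is_empty:
        return None
    pts = []
    if hit.geom_type == "Point":
        pts = [hit]
    elif hasattr(hit, "geoms"):
        pts = [g for g in hit.geoms if g.geom_type == "Point"]
        for g in hit.geoms:
            if g.geom_type == "LineString":
                pts.extend(
                    type(hit.geoms[0])(c) for c in []
                )  # pragma: no cover - line overlaps not expected
    elif hit.geom_type == "LineString":
        from shapely.geometry import Point

        pts = [Point(hit.coords[0])]
    if not pts:
        return None
    dists = [np.dot(np.asarray(p.coords[0]) - origin, direction) for p in pts]
    dists = [d for d in dists if d > 0]
    return min(dists) if dists else None


def straighten(
    vts: VirtualThinSection,
    roi: RoiAnnotation,
    radial_samples: int,
    circumferential_samples: int,
    max_dropped_fraction: float = 0.2,
) -> StraightenedCementum:
    """Resample an annular ROI into a radial x circumferential array.

    For each of ``circumferential_samples`` arc positions along the
    inner boundary, grayscale is sampled (bilinear) at
    ``radial_samples`` points along the local inner-boundary normal, up
    to its intersection with the outer boundary.  The per-column radial
    step (inner-to-outer distance / (radial_samples - 1), in μm) is kept
    in ``row_step_um`` so widths stay exact even where the cementum is
    locally thicker.

    Columns whose normal misses the outer boundary, or that touch the
    exclusion mask, are dropped with a warning; if more than
    ``max_dropped_fraction`` of columns drop, an error is raised.
    """
    if radial_samples < 2 or circumferential_samples < 2:
        raise ValueError("sampling counts must be >= 2")
    inner = _resample_polyline(roi.inner_boundary, circumferential_samples)
    outer_poly = roi.outer_boundary
    normals = _normals(inner, toward=np.full_like(inner, outer_poly.mean(axis=0)))

    img = vts.pixels.astype(float)
    cols: list[np.ndarray] = []
    steps: list[float] = []
    dropped = 0
    for c in range(circumferential_samples):
        dist = _ray_polyline_intersection(inner[c], normals[c], outer_poly)
        if dist is None or dist <= 0:
            dropped += 1
            continue
        ts = np.linspace(0.0, dist, radial_samples)
        pts = inner[c][None, :] + ts[:, None] * normals[c][None, :]
        if roi.exclusion_mask is not None:
            ri = np.clip(np.round(pts[:, 0]).astype(int), 0, img.shape[0] - 1)
            ci = np.clip(np.round(pts[:, 1]).astype(int), 0, img.shape[1] - 1)
            if roi.exclusion_mask[ri, ci].any():
                dropped += 1
                continue
        vals = map_coordinates(img, [pts[:, 0], pts[:, 1]], order=1, mode="nearest")
        cols.append(vals)
        steps.append(dist / (radial_samples - 1) * vts.voxel_size_um)
    if dropped:
        warnings.warn(
            f"straighten: dropped {dropped}/{circumferential_samples} columns",
            stacklevel=2,
        )
    if dropped > max_dropped_fraction * circumferential_samples:
        raise ValueError(
            f"straighten: {dropped}/{circumferential_samples} columns dropped "
            f"(> {max_dropped_fraction:.0%}); check the ROI annotation"
        )
    pixels = np.stack(cols, axis=1)
    return StraightenedCementum(
        pixels=pixels,
        voxel_size_um=vts.voxel_size_um,
        row_step_um=np.asarray(steps),
        provenance=(vts.specimen_id, vts.source_slices, roi.roi_id),
    )


# ---------------------------------------------------------------------------
# boundary artifacts


def trim_boundary_artifacts(
    region: StraightenedCementum,
    bright_threshold: float = 225.0,
) -> tuple[StraightenedCementum, float]:
    """Crop the hyaline layer and outer phase fringe off a region.

    Increment transects are measured *between* the hyaline layer (a
    bright band at the cementum-dentine junction) and the outer root
    surface, whose cementum-air interface produces a bright phase
    fringe in propagation-based tomography.  Both saturate toward white
    and would defeat the segmented peak threshold, so they are removed:
    the leading run of rows whose mean exceeds ``bright_threshold`` is
    cropped, and everything from the first later bright row (the
    fringe) outward is cropped.

    Returns ``(trimmed_region, offset_um)`` where ``offset_um`` is the
    radial position of the new row 0 in the original region.
    """
    means = region.pixels.astype(float).mean(axis=1)
    n = means.size
    start = 0
    while start < n and means[start] >= bright_threshold:
        start += 1
    stop = n
    for r in range(start, n):
        if means[r] >= bright_threshold:
            stop = r
            break
    if stop - start < 8:
        raise ValueError("trimming boundary artifacts leaves too little cementum")
    step = float(np.mean(region.row_step_um))
    return (
        StraightenedCementum(
            pixels=region.pixels[start:stop],
            voxel_size_um=region.voxel_size_um,
            row_step_um=region.row_step_um,
            provenance=region.provenance,
        ),
        start * step,
    )


# ---------------------------------------------------------------------------
# void screening


def screen_voids(
    region: StraightenedCementum | np.ndarray,
    gray_threshold: int = 40,
    min_area_px: int = 6,
    max_dark_fraction: float = 0.5,
) -> tuple[int, bool]:
    """Count cellular voids (dark blobs) and accept void-free regions.

    Voids — lacunae of cellular cementum (CIFC) — appear as connected
    dark blobs well below the dark-increment gray level.  A region is
    accepted for increment analysis only when no void is found, since
    CIFC incrementation is distorted and would corrupt width series.

    Returns ``(void_count, accept)``.  A degenerate, mostly-dark image
    (fraction of dark pixels above ``max_dark_fraction``) is rejected
    outright with ``void_count = -1``.
    """
    pixels = region.pixels if isinstance(region, StraightenedCementum) else np.asarray(region)
    dark = pixels < gray_threshold
    if dark.mean() > max_dark_fraction:
        warnings.warn(
            "screen_voids: image is predominantly dark; not interpretable "
            "as AEFC cementum",
            stacklevel=2,
        )
        return -1, False
    lab = label(dark, connectivity=2)
    count = sum(1 for p in regionprops(lab) if p.area >= min_area_px)
    return count, count == 0
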
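"""RGB-D reconstruction and integral-imaging display rendering.

A metric depth map and the matching 2D color image are combined into an
RGB-D point cloud, optionally rotated/zoomed by the user, sliced into
depth layers, and rendered into a display elemental image array by
direction-reversal calculation (DRC): one backward ray per EIA pixel,
cast through the pixel's elemental lens center, keeping the color of the
first (nearest) occupied depth-layer cell it meets.  Ray count therefore
equals the EIA raster pixel count, and occlusion falls out of the
nearest-first traversal.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.transform import resize

from .calibration import CalibrationFit, MetricDepthMap
from .lightfield import LensArraySpec

__all__ = [
    "PointCloud",
    "LayeredScene",
    "DisplaySpec",
    "RenderedEIA",
    "upsample_depth",
    "fill_holes",
    "build_point_cloud",
    "layer_scene",
    "default_layer_count",
    "apply_interaction",
    "place_scene",
    "render_eia_drc",
    "preview_views",
    "save_point_cloud",
    "load_point_cloud",
]


@dataclass
class PointCloud:
    """Colored 3D points in millimetres: ``points[i] = (x, y, z)``."""

    points: np.ndarray  # (N, 3) mm
    colors: np.ndarray  # (N, 3) in [0, 1]
    lateral_scale: float  # mm between laterally adjacent source pixels

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.colors = np.asarray(self.colors, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.colors.shape != self.points.shape:
            raise ValueError("colors must match points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.colors.size and (self.colors.min() < 0 or self.colors.max() > 1):
            raise ValueError("colors must lie in [0, 1]")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class LayeredScene:
    """Depth-sliced scene on a lateral grid.

    ``z_planes`` are the slice depths in mm, strictly increasing (nearest
    to the lens array first); each occupied cell belongs to exactly one
    layer.  ``origin_xy`` is the (x, y) of cell (row 0, col 0)'s center.
    """

    z_planes: np.ndarray  # (n,)
    masks: np.ndarray  # (n, H, W) bool
    colors: np.ndarray  # (n, H, W, 3)
    cell_size_mm: float
    origin_xy: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.z_planes) <= 0) and len(self.z_planes) > 1:
            raise ValueError("layer z-planes must be strictly increasing")
        if self.masks.sum(axis=0).max(initial=0) > 1:
            raise ValueError("a cell may be occupied in at most one layer")

    @property
    def n_layers(self) -> int:
        return len(self.z_planes)


@dataclass(frozen=True)
class DisplaySpec:
    """Integral-imaging display: a lens sheet over a flat panel."""

    pixel_pitch_mm: float
    panel_resolution: tuple[int, int]
    lens_array: LensArraySpec  # pitch/focal length/gap in mm

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")
        if min(self.panel_resolution) < 1:
            raise ValueError("panel resolution must be positive")

    @property
    def pixels_per_lens(self) -> int:
        """EIA pixels per lens from the pitch ratio (e.g. 1 mm / 0.089 mm -> 11)."""
        return int(self.lens_array.lens_pitch / self.pixel_pitch_mm)

    @property
    def conjugate_plane_mm(self) -> float:
        """Image-side conjugate of the panel through a lens (thin-lens)."""
        f, g = self.lens_array.focal_length, self.lens_array.gap
        if g <= f:
            raise ValueError("panel gap must exceed the lens focal length")
        return f * g / (g - f)


@dataclass
class RenderedEIA:
    """Display elemental image array plus its tiling and ray instrumentation."""

    raster: np.ndarray  # (Lu*ps, Lv*pt, 3) in [0, 1]
    lens_counts: tuple[int, int]
    pixels_per_lens: tuple[int, int]
    rays_cast: int = 0

    def __post_init__(self) -> None:
        lu, lv = self.lens_counts
        ps, pt = self.pixels_per_lens
        if self.raster.shape != (lu * ps, lv * pt, 3):
            raise ValueError(
                f"raster {self.raster.shape} does not tile {lu}x{lv} lenses "
                f"at {ps}x{pt} px"
            )


def upsample_depth(depth: MetricDepthMap, target_resolution: tuple[int, int]) -> MetricDepthMap:
    """Bicubic upsampling of a metric depth map to the 2D-image resolution.

    Output values are clipped to the input's min-max range (bicubic
    overshoot would otherwise create depths no input pixel has).
    """
    h, w = depth.depth_mm.shape
    th, tw = target_resolution
    if th < h or tw < w:
        raise ValueError(f"target {target_resolution} smaller than source {(h, w)}")
    if (th, tw) == (h, w):
        return MetricDepthMap(depth_mm=depth.depth_mm.copy(), provenance=depth.provenance)
    out = resize(depth.depth_mm, (th, tw), order=3, mode="edge",
                 anti_aliasing=False, preserve_range=True)
    out = np.clip(out, depth.depth_mm.min(), depth.depth_mm.max())
    return MetricDepthMap(depth_mm=out, provenance=depth.provenance)


def _coons_patch(top: np.ndarray, bottom: np.ndarray, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Coons surface through four boundary curves sampled on a grid.

    ``top``/``bottom`` have length n, ``left``/``right`` length m, and the
    corners must agree (top[0] == left[0], etc.).  Returns an (m, n) grid
    whose border equals the curves; bilinear/affine data is reproduced
    exactly.
    """
    m, n = left.size, top.size
    u = np.linspace(0.0, 1.0, m)[:, None]
    v = np.linspace(0.0, 1.0, n)[None, :]
    ruled_ud = (1 - u) * top[None, :] + u * bottom[None, :]
    ruled_lr = (1 - v) * left[:, None] + v * right[:, None]
    corners = (
        (1 - u) * (1 - v) * top[0]
        + (1 - u) * v * top[-1]
        + u * (1 - v) * bottom[0]
        + u * v * bottom[-1]
    )
    return ruled_ud + ruled_lr - corners


def fill_holes(depth: MetricDepthMap, hole_mask: np.ndarray) -> MetricDepthMap:
    """Fill hole regions with Coons patches spanned by their boundary curves.

    Each connected hole is boxed by its bounding rectangle; the depth
    values on the rectangle's one-pixel frame provide the four boundary
    curves of a Coons patch, which interpolates them smoothly (planes are
    reproduced exactly).  Holes touching the image border have no complete
    frame and fall back to nearest-valid extension with a warning.
    """
    d = depth.depth_mm.copy()
    mask = np.asarray(hole_mask, dtype=bool)
    if mask.shape != d.shape:
        raise ValueError("hole mask must match the depth map")
    if not mask.any():
        return MetricDepthMap(depth_mm=d, provenance=depth.provenance)
    h, w = d.shape
    labels, n_holes = ndimage.label(mask)
    border_fallback = False
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        comp = labels[sl] == lab
        r0, r1 = sl[0].start, sl[0].stop
        c0, c1 = sl[1].start, sl[1].stop
        if r0 == 0 or c0 == 0 or r1 == h or c1 == w:
            border_fallback = True
            continue
        top = d[r0 - 1, c0 - 1 : c1 + 1]
        bottom = d[r1, c0 - 1 : c1 + 1]
        left = d[r0 - 1 : r1 + 1, c0 - 1]
        right = d[r0 - 1 : r1 + 1, c1]
        patch = _coons_patch(top, bottom, left, right)
        interior = patch[1:-1, 1:-1]
        block = d[r0:r1, c0:c1]
        block[comp] = interior[comp]
    if border_fallback:
        warnings.warn("hole touches the image border; filled by nearest-valid extension")
        remaining = mask & (labels > 0)
        # recompute which pixels are still unfilled: border-touching components
        filled = np.zeros_like(mask)
        for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
            r0, r1 = sl[0].start, sl[0].stop
            c0, c1 = sl[1].start, sl[1].stop
            if not (r0 == 0 or c0 == 0 or r1 == h or c1 == w):
                filled[sl][labels[sl] == lab] = True
        remaining = mask & ~filled
        if remaining.any():
            idx = ndimage.distance_transform_edt(
                remaining, return_distances=False, return_indices=True
            )
            d[remaining] = d[tuple(i[remaining] for i in idx)]
    return MetricDepthMap(depth_mm=d, provenance=depth.provenance)


def build_point_cloud(
    depth_mm: MetricDepthMap,
    rgb: np.ndarray,
    lateral_scale: float,
    stride: int = 1,
    keep_mask: np.ndarray | None = None,
) -> PointCloud:
    """One point per retained pixel: ``(col*scale, row*scale, depth)`` plus color."""
    d = depth_mm.depth_mm
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.shape[:2] != d.shape:
        raise ValueError(f"depth {d.shape} and image {rgb.shape[:2]} resolutions differ")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    keep = np.ones(d.shape, dtype=bool) if keep_mask is None else np.asarray(keep_mask, bool)
    sub = np.zeros_like(keep)
    sub[::stride, ::stride] = True
    keep = keep & sub
    rows, cols = np.nonzero(keep)
    pts = np.column_stack([cols * lateral_scale, rows * lateral_scale, d[rows, cols]])
    return PointCloud(points=pts, colors=rgb[rows, cols], lateral_scale=lateral_scale * stride)


def default_layer_count(
    z_range_mm: float, alpha_step: float, slope_mm_per_alpha: float, cap: int = 128
) -> int:
    """Layers so each slab spans about one alpha-grid step of metric depth."""
    dz = abs(alpha_step * slope_mm_per_alpha)
    if dz <= 0 or z_range_mm <= 0:
        return 1
    return int(np.clip(np.ceil(z_range_mm / dz), 1, cap))


def layer_scene(pc: PointCloud, n_layers: int, cell_size_mm: float | None = None) -> LayeredScene:
    """Uniform z-binning of a point cloud into depth layers on a lateral grid.

    Every point is assigned to exactly one z-bin; within a (layer, cell)
    collision the nearest point wins.  A degenerate z-range collapses to a
    single layer.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if len(pc) == 0:
        raise ValueError("cannot layer an empty point cloud")
    cell = pc.lateral_scale if cell_size_mm is None else cell_size_mm
    x, y, z = pc.points.T
    zmin, zmax = z.min(), z.max()
    if zmax <= zmin:
        n_layers = 1
    edges = np.linspace(zmin, zmax, n_layers + 1)
    li = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, n_layers - 1)
    z_planes = 0.5 * (edges[:-1] + edges[1:])
    if n_layers == 1:
        z_planes = np.array([0.5 * (zmin + zmax)])

    x0, y0 = x.min(), y.min()
    cols = np.round((x - x0) / cell).astype(int)
    rows = np.round((y - y0) / cell).astype(int)
    H, W = rows.max() + 1, cols.max() + 1
    masks = np.zeros((n_layers, H, W), dtype=bool)
    colors = np.zeros((n_layers, H, W, 3))
    # nearest point wins a cell across all layers (single occupancy per cell):
    # write far-to-near so nearer points overwrite (stable sort -> deterministic)
    order = np.argsort(-z, kind="stable")
    cell_layer = np.full((H, W), -1, dtype=int)
    cell_layer[rows[order], cols[order]] = li[order]
    cell_color = np.zeros((H, W, 3))
    cell_color[rows[order], cols[order]] = pc.colors[order]
    for k in range(n_layers):
        masks[k] = cell_layer == k
        colors[k][masks[k]] = cell_color[masks[k]]
    return LayeredScene(
        z_planes=z_planes, masks=masks, colors=colors,
        cell_size_mm=cell, origin_xy=(float(x0), float(y0)),
    )


def apply_interaction(
    pc: PointCloud,
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0),
    zoom: float = 1.0,
) -> PointCloud:
    """Rigid rotation about the cloud centroid followed by uniform zoom.

    Angles are extrinsic x-y-z Euler angles in degrees; point count is
    preserved and pairwise distances scale by exactly ``zoom``.
    """
    if zoom <= 0:
        raise ValueError("zoom must be positive")
    centroid = pc.points.mean(axis=0)
    R = Rotation.from_euler("xyz", rotation_deg, degrees=True).as_matrix()
    pts = (pc.points - centroid) @ R.T * zoom + centroid
    return PointCloud(points=pts, colors=pc.colors.copy(), lateral_scale=pc.lateral_scale * zoom)


def place_scene(pc: PointCloud, display: DisplaySpec, fit_fraction: float = 0.9) -> PointCloud:
    """Map a specimen-scale cloud into display space for rendering.

    Uniform similarity: the lateral footprint is scaled to ``fit_fraction``
    of the lens-array aperture and centered on the optical axis, and the
    depth extent (scaled by the same factor, preserving shape) is centered
    on the panel's conjugate plane beyond the lens sheet.
    """
    la = display.lens_array
    aperture = min(la.lens_count_u, la.lens_count_v) * la.lens_pitch
    lo = pc.points.min(axis=0)
    hi = pc.points.max(axis=0)
    extent = max(hi[0] - lo[0], hi[1] - lo[1])
    s = fit_fraction * aperture / extent if extent > 0 else 1.0
    mid = 0.5 * (lo + hi)
    pts = (pc.points - mid) * s
    pts[:, 2] += display.conjugate_plane_mm
    return PointCloud(points=pts, colors=pc.colors.copy(), lateral_scale=pc.lateral_scale * s)


def _lens_centers(display: DisplaySpec) -> tuple[np.ndarray, np.ndarray]:
    la = display.lens_array
    cy = (np.arange(la.lens_count_u) + 0.5 - la.lens_count_u / 2) * la.lens_pitch
    cx = (np.arange(la.lens_count_v) + 0.5 - la.lens_count_v / 2) * la.lens_pitch
    return cy, cx


def render_eia_drc(
    scene: LayeredScene,
    display: DisplaySpec,
    eia_pixels_per_lens: tuple[int, int] | None = None,
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> RenderedEIA:
    """Backward (direction-reversal) rendering of the display EIA.

    For every EIA pixel, one ray is cast from the pixel through its
    elemental lens center into the scene; depth layers are visited
    nearest-first and the first occupied cell hit supplies the color, so
    nearer layers occlude farther ones by construction.  Rays that hit
    nothing get the background color.  Elemental images are mutually
    independent; they are rendered serially lens by lens.
    """
    if len(scene.z_planes) and scene.z_planes.min() <= 0:
        raise ValueError("scene layers must lie beyond the lens plane (z > 0)")
    la = display.lens_array
    if eia_pixels_per_lens is None:
        eia_pixels_per_lens = (display.pixels_per_lens, display.pixels_per_lens)
    ps, pt = eia_pixels_per_lens
    lu, lv = la.lens_count_u, la.lens_count_v
    g = la.gap
    pp = display.pixel_pitch_mm
    cell = scene.cell_size_mm
    x0, y0 = scene.origin_xy
    nH, nW = scene.masks.shape[1:] if scene.n_layers else (0, 0)

    off_y = ((np.arange(ps) + 0.5) - ps / 2) * pp  # pixel offset from lens center
    off_x = ((np.arange(pt) + 0.5) - pt / 2) * pp
    oy = off_y[:, None]
    ox = off_x[None, :]
    cy, cx = _lens_centers(display)
    raster = np.empty((lu * ps, lv * pt, 3))
    raster[:] = np.asarray(background, dtype=np.float64)
    rays_cast = 0
    for i in range(lu):
        for j in range(lv):
            rays_cast += ps * pt
            if scene.n_layers == 0:
                continue
            done = np.zeros((ps, pt), dtype=bool)
            tile = raster[i * ps : (i + 1) * ps, j * pt : (j + 1) * pt]
            for k in range(scene.n_layers):  # nearest-first
                z = scene.z_planes[k]
                # ray q -> lens center continues to lateral c + (z/g)(c - q)
                ly = cy[i] - (z / g) * oy
                lx = cx[j] - (z / g) * ox
                rr, cc = np.broadcast_arrays(
                    np.round((ly - y0) / cell).astype(int),
                    np.round((lx - x0) / cell).astype(int),
                )
                inside = (rr >= 0) & (rr < nH) & (cc >= 0) & (cc < nW)
                rr_c = np.clip(rr, 0, max(nH - 1, 0))
                cc_c = np.clip(cc, 0, max(nW - 1, 0))
                hit = inside & scene.masks[k][rr_c, cc_c] & ~done
                if hit.any():
                    tile[hit] = scene.colors[k][rr_c[hit], cc_c[hit]]
                    done |= hit
                if done.all():
                    break
    return RenderedEIA(
        raster=raster,
        lens_counts=(lu, lv),
        pixels_per_lens=(ps, pt),
        rays_cast=rays_cast,
    )


def preview_views(
    eia: RenderedEIA,
    display: DisplaySpec,
    view_angles: list[float | tuple[float, float]],
) -> list[np.ndarray]:
    """Software preview of the 3D display: one image per viewing angle.

    Reverse pinhole mapping: at angle theta the eye's ray through each
    lens center comes from the panel pixel offset by ``-gap * tan(theta)``
    from the center, giving one pixel per lens.  Angles may be scalars
    (horizontal tilt, degrees) or (theta_x, theta_y) pairs.  Angles beyond
    the lens acceptance produce a warning and background pixels.
    """
    la = display.lens_array
    ps, pt = eia.pixels_per_lens
    lu, lv = eia.lens_counts
    pp = display.pixel_pitch_mm
    g = la.gap
    out = []
    for ang in view_angles:
        tx, ty = (ang, 0.0) if np.isscalar(ang) else ang
        dx = np.tan(np.radians(tx))
        dy = np.tan(np.radians(ty))
        a = int(np.floor((-g * dy) / pp + ps / 2))
        b = int(np.floor((-g * dx) / pp + pt / 2))
        img = np.zeros((lu, lv, 3))
        if not (0 <= a < ps and 0 <= b < pt):
            warnings.warn(f"view angle {ang} deg outside the lens acceptance; cropped")
        else:
            img = eia.raster[a::ps, b::pt][:lu, :lv].copy()
        out.append(img)
    return out


def save_point_cloud(pc: PointCloud, path: str | os.PathLike, binary: bool = True) -> None:
    """Write the cloud as PLY (binary little-endian by default, else ASCII)."""
    cloud = trimesh.PointCloud(
        vertices=pc.points, colors=(np.clip(pc.colors, 0, 1) * 255).astype(np.uint8)
    )
    data = cloud.export(file_type="ply", encoding="binary" if binary else "ascii")
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


def load_point_cloud(path: str | os.PathLike, lateral_scale: float = 1.0) -> PointCloud:
    """Read a PLY point cloud written by :func:`save_point_cloud`."""
    cloud = trimesh.load(os.fspath(path), process=False)
    colors = np.asarray(cloud.colors, dtype=np.float64)[:, :3] / 255.0
    return PointCloud(points=np.asarray(cloud.vertices, dtype=np.float64),
                      colors=colors, lateral_scale=lateral_scale)
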
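"""Elemental image arrays, lens-array layouts and orthographic view extraction.

A focused light-field microscope records the 4D radiance ``L(s, t, u, v)``
as a tiled raster: one tile per microlens.  Here ``(u, v)`` indexes the
lens (the spatial sample) and ``(s, t)`` the pixel inside the lens (the
angular sample), so an orthographic view is formed by picking the same
intra-lens pixel across every lens and has one pixel per lens.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

__all__ = [
    "LensArraySpec",
    "ElementalImageArray",
    "ViewStack",
    "load_eia",
    "save_eia",
    "load_layout",
    "save_layout",
    "eia_from_raster",
    "eia_to_raster",
    "crop_active_area",
    "extract_views",
    "views_to_eia",
    "central_view",
    "luminance",
]


@dataclass(frozen=True)
class LensArraySpec:
    """Geometry of a lens array (capture MLA or display lens sheet).

    Lengths are carried in the unit natural to the device: micrometres for
    a capture microlens array, millimetres for a display lens sheet; the
    ``unit`` field records which.
    """

    lens_count_u: int
    lens_count_v: int
    lens_pitch: float
    focal_length: float
    gap: float
    unit: str = "mm"

    def __post_init__(self) -> None:
        if self.lens_count_u < 1 or self.lens_count_v < 1:
            raise ValueError("lens counts must be >= 1")
        for name in ("lens_pitch", "focal_length", "gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ElementalImageArray:
    """The 4D light field stored as ``pixels[u, v, s, t, channel]``.

    ``(u, v)`` is the lens index (row, col), ``(s, t)`` the pixel inside a
    lens.  Intensities are floats in [0, 1].
    """

    pixels: np.ndarray
    layout: LensArraySpec

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim != 5 or p.shape[4] != 3:
            raise ValueError(f"expected (Nu, Nv, Ns, Nt, 3) tensor, got {p.shape}")
        if p.shape[0] != self.layout.lens_count_u or p.shape[1] != self.layout.lens_count_v:
            raise ValueError(
                f"tensor lens grid {p.shape[:2]} does not match layout "
                f"({self.layout.lens_count_u}, {self.layout.lens_count_v})"
            )
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = np.clip(p, 0.0, 1.0)

    @property
    def lens_counts(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    @property
    def pixels_per_lens(self) -> tuple[int, int]:
        return self.pixels.shape[2], self.pixels.shape[3]


@dataclass
class ViewStack:
    """All orthographic (sub-aperture) views: ``views[s, t, u, v, channel]``.

    Each view has one pixel per lens; there are ``Ns * Nt`` of them.  The
    central view index follows the floor-half convention ``(Ns//2, Nt//2)``
    (0-based; even counts pick the upper-left of the central 2x2).
    """

    views: np.ndarray
    central_index: tuple[int, int] = field(init=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.views, dtype=np.float64)
        if v.ndim != 5 or v.shape[4] != 3:
            raise ValueError(f"expected (Ns, Nt, Nu, Nv, 3) tensor, got {v.shape}")
        self.views = v
        self.central_index = (v.shape[0] // 2, v.shape[1] // 2)

    @property
    def n_views(self) -> int:
        return self.views.shape[0] * self.views.shape[1]

    @property
    def view_shape(self) -> tuple[int, int]:
        return self.views.shape[2], self.views.shape[3]


def _normalize_raster(raster: np.ndarray) -> np.ndarray:
    raster = np.asarray(raster)
    if raster.ndim == 2:
        raster = raster[:, :, None]
    if raster.shape[2] == 1:
        raster = np.repeat(raster, 3, axis=2)
    elif raster.shape[2] == 4:  # drop alpha
        raster = raster[:, :, :3]
    if raster.dtype == np.uint8:
        return raster.astype(np.float64) / 255.0
    if raster.dtype == np.uint16:
        return raster.astype(np.float64) / 65535.0
    out = raster.astype(np.float64)
    if out.size and (out.min() < 0 or out.max() > 1):
        raise ValueError("float rasters must already be scaled to [0, 1]")
    return out


def eia_from_raster(
    raster: np.ndarray, layout: LensArraySpec, pixels_per_lens: tuple[int, int]
) -> ElementalImageArray:
    """Tile a raster image into a 4D elemental image array.

    The raster must cover ``lens_count * pixels_per_lens`` pixels in each
    dimension; any remainder (e.g. a 4000 px sensor over 76 lenses leaves
    4000 - 76*52 = 48 px) is removed by a centered crop, never resampled.
    """
    raster = _normalize_raster(raster)
    nu, nv = layout.lens_count_u, layout.lens_count_v
    ns, nt = pixels_per_lens
    need_h, need_w = nu * ns, nv * nt
    h, w = raster.shape[:2]
    if h < need_h or w < need_w:
        raise ValueError(
            f"raster {h}x{w} too small for {nu}x{nv} lenses at {ns}x{nt} px/lens "
            f"(needs {need_h}x{need_w})"
        )
    r0 = (h - need_h) // 2
    c0 = (w - need_w) // 2
    raster = raster[r0 : r0 + need_h, c0 : c0 + need_w]
    pixels = (
        raster.reshape(nu, ns, nv, nt, 3).transpose(0, 2, 1, 3, 4).copy()
    )
    return ElementalImageArray(pixels=pixels, layout=layout)


def eia_to_raster(eia: ElementalImageArray) -> np.ndarray:
    """Inverse of :func:`eia_from_raster` for exact tilings."""
    nu, nv = eia.lens_counts
    ns, nt = eia.pixels_per_lens
    return eia.pixels.transpose(0, 2, 1, 3, 4).reshape(nu * ns, nv * nt, 3)


def load_eia(
    raster_path: str | os.PathLike,
    layout: LensArraySpec,
    pixels_per_lens: tuple[int, int] | None = None,
) -> ElementalImageArray:
    """Read a PNG/TIFF raster and tile it into an elemental image array.

    If ``pixels_per_lens`` is omitted it defaults to
    ``floor(raster_dim / lens_count)`` per axis.
    """
    path = os.fspath(raster_path)
    if path.lower().endswith((".tif", ".tiff")):
        raster = tifffile.imread(path)
    else:
        raster = iio.imread(path)
    if pixels_per_lens is None:
        pixels_per_lens = (
            raster.shape[0] // layout.lens_count_u,
            raster.shape[1] // layout.lens_count_v,
        )
    return eia_from_raster(raster, layout, pixels_per_lens)


def save_eia(eia: ElementalImageArray, raster_path: str | os.PathLike) -> None:
    """Write the tiled raster as 8-bit PNG or 32-bit float TIFF by extension."""
    path = os.fspath(raster_path)
    raster = eia_to_raster(eia)
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, raster.astype(np.float32))
    else:
        iio.imwrite(path, np.round(raster * 255.0).astype(np.uint8))


def save_layout(layout: LensArraySpec, path: str | os.PathLike) -> None:
    data = {
        "lens_count_u": layout.lens_count_u,
        "lens_count_v": layout.lens_count_v,
        "lens_pitch": layout.lens_pitch,
        "focal_length": layout.focal_length,
        "gap": layout.gap,
        "unit": layout.unit,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh)


def load_layout(path: str | os.PathLike) -> LensArraySpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return LensArraySpec(**data)


def crop_active_area(
    raw: ElementalImageArray, active_lenses: tuple[int, int]
) -> ElementalImageArray:
    """Keep the centered ``active_lenses`` sub-grid of whole elemental images.

    Mirrors the usual capture workflow where the camera only covers the
    middle of the MLA and the dark outer lens rings are discarded (e.g.
    100x100 physical lenses, 76x76 active).
    """
    au, av = active_lenses
    nu, nv = raw.lens_counts
    if au > nu or av > nv:
        raise ValueError(f"active area {au}x{av} exceeds available {nu}x{nv} lenses")
    if au < 1 or av < 1:
        raise ValueError("active area must contain at least one lens")
    u0 = (nu - au) // 2
    v0 = (nv - av) // 2
    sub = raw.pixels[u0 : u0 + au, v0 : v0 + av]
    layout = replace(raw.layout, lens_count_u=au, lens_count_v=av)
    return ElementalImageArray(pixels=sub.copy(), layout=layout)


def extract_views(eia: ElementalImageArray) -> ViewStack:
    """Re-index the EIA into orthographic views: view (s,t) pixel (u,v) = eia[u,v,s,t].

    This is a bijective re-indexing — every EIA pixel lands in exactly one
    view — so :func:`views_to_eia` inverts it bit-exactly.
    """
    return ViewStack(views=eia.pixels.transpose(2, 3, 0, 1, 4).copy())


def views_to_eia(views: ViewStack, layout: LensArraySpec) -> ElementalImageArray:
    """Inverse of :func:`extract_views`."""
    return ElementalImageArray(
        pixels=views.views.transpose(2, 3, 0, 1, 4).copy(), layout=layout
    )


def central_view(views: ViewStack) -> np.ndarray:
    """The view at the central angular index (same viewpoint as refocused images)."""
    s, t = views.central_index
    return views.views[s, t]


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an RGB image with a trailing channel axis."""
    rgb = np.asarray(rgb, dtype=np.float64)
    return rgb @ np.array([0.299, 0.587, 0.114])
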
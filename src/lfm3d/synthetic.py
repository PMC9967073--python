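"""Ground-truth phantoms and a forward pinhole-array capture simulator.

The simulator emulates a focused light-field microscope viewing a
textured height field (a Lambertian, occlusion-free relief such as a 3D
printed calibration staircase): orthographic view ``(s, t)`` sees the
surface texture shifted by a parallax proportional to local height,

    view[s, t](p) = texture(p - gamma * (h(p) - z0) * ((s, t) - center))

where ``gamma`` is the disparity gain in view-pixels per angular index
per millimetre of height and ``z0`` the native (in-focus) plane.  The
depth-to-disparity map is exactly linear, so shift-and-sum refocusing
brings a plane at height ``z`` into focus at ``beta = gamma * (z - z0)``
(alpha = 1 + beta under the linear shear convention), and the implied
alpha-to-mm calibration line is ``mm = alpha/gamma + (z0 - 1/gamma)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .calibration import CalibrationFit, MetricDepthMap
from .lightfield import ElementalImageArray, LensArraySpec, ViewStack, views_to_eia
from .refocus import AlphaGrid

__all__ = [
    "Phantom",
    "CaptureConfig",
    "make_step_phantom",
    "make_shape_phantom",
    "make_texture",
    "simulate_capture",
    "end_to_end_fixture",
    "fixture_alpha_grid",
]


@dataclass
class Phantom:
    """Textured height field: heights in mm, RGB texture in [0, 1]."""

    height_map: np.ndarray
    texture: np.ndarray
    lateral_scale: float = 1.0  # mm per grid cell

    def __post_init__(self) -> None:
        self.height_map = np.asarray(self.height_map, dtype=np.float64)
        self.texture = np.asarray(self.texture, dtype=np.float64)
        if not np.all(np.isfinite(self.height_map)):
            raise ValueError("heights must be finite")
        if self.texture.shape[:2] != self.height_map.shape:
            raise ValueError("texture and height map grids differ")
        if self.texture.min() < 0 or self.texture.max() > 1:
            raise ValueError("texture must lie in [0, 1]")


@dataclass(frozen=True)
class CaptureConfig:
    """Simulated capture geometry and noise.

    Defaults mirror the real instrument where that is tractable: a 76x76
    active lens grid (hence 76x76 px views).  The angular resolution is
    kept at 7x7 intra-lens pixels so the whole pipeline runs at desk
    scale; gamma = 1 gives one view-pixel of disparity per angular index
    per millimetre, i.e. a 1 mm-per-alpha calibration line.
    """

    lens_count_u: int = 76
    lens_count_v: int = 76
    pixels_per_lens: tuple[int, int] = (7, 7)
    gamma: float = 1.0  # view-px per angular index per mm
    native_plane_mm: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    layout: LensArraySpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.isfinite(self.gamma):
            raise ValueError("gamma must be finite")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        if self.layout is None:
            object.__setattr__(
                self,
                "layout",
                LensArraySpec(
                    lens_count_u=self.lens_count_u,
                    lens_count_v=self.lens_count_v,
                    lens_pitch=125.0,
                    focal_length=2400.0,
                    gap=2400.0,
                    unit="um",
                ),
            )

    @property
    def truth_fit(self) -> CalibrationFit:
        """The exact alpha-to-mm line implied by gamma (linear shear)."""
        slope = 1.0 / self.gamma
        return CalibrationFit(
            slope=slope,
            intercept=self.native_plane_mm - slope,
            r_squared=1.0,
            n_points=2,
        )


def make_texture(shape: tuple[int, int], seed: int, smooth_sigma: float = 1.0) -> np.ndarray:
    """High-contrast band-limited random RGB texture (smoothed white noise).

    Smoothing keeps the texture within the sub-pixel interpolation band so
    the focus measure has signal everywhere; each channel is stretched to
    the full [0, 1] range.
    """
    rng = np.random.default_rng(seed)
    tex = rng.normal(size=shape + (3,))
    tex = ndimage.gaussian_filter(tex, sigma=(smooth_sigma, smooth_sigma, 0))
    lo = tex.min(axis=(0, 1))
    hi = tex.max(axis=(0, 1))
    return (tex - lo) / (hi - lo)


def make_step_phantom(
    n_steps: int,
    step_height_mm: float = 1.0,
    step_width_px: int = 19,
    texture_seed: int = 0,
    margin_px: int = 0,
) -> Phantom:
    """Staircase relief with floors at 0, h, 2h, ... running along columns.

    ``margin_px`` extends the board on all sides (lowest floor on the
    left, highest on the right) so an off-plane capture can sample
    texture beyond the active field of view.
    """
    if n_steps < 2:
        raise ValueError("a staircase needs at least 2 steps")
    w = n_steps * step_width_px + 2 * margin_px
    cols = np.arange(w)
    floor = np.clip((cols - margin_px) // step_width_px, 0, n_steps - 1)
    height = np.tile(floor * step_height_mm, (w, 1)).astype(np.float64)
    return Phantom(height_map=height, texture=make_texture((w, w), texture_seed))


def make_shape_phantom(
    shape: str,
    height_mm: float,
    texture_seed: int = 0,
    size_px: int = 76,
    margin_px: int = 0,
) -> Phantom:
    """A raised column of the named footprint on a flat zero base.

    Shapes (mirroring the printed measurement test boards): a
    ``triangular_column``, a ``cylinder`` and a ``square_column``.  The
    footprint is sized relative to ``size_px``; ``margin_px`` adds flat
    base around it.
    """
    if height_mm < 0:
        raise ValueError("height must be nonnegative")
    n = size_px
    full = n + 2 * margin_px
    yy, xx = np.mgrid[0:full, 0:full] - margin_px
    cy = cx = (n - 1) / 2
    if shape == "cylinder":
        footprint = (yy - cy) ** 2 + (xx - cx) ** 2 <= (0.3 * n) ** 2
    elif shape == "square_column":
        side = n // 2
        r0 = (n - side) // 2
        footprint = (yy >= r0) & (yy < r0 + side) & (xx >= r0) & (xx < r0 + side)
    elif shape == "triangular_column":
        # upright isosceles triangle inscribed in the central half
        h_tri = 0.6 * n
        base_y = cy + h_tri / 2
        apex_y = cy - h_tri / 2
        half_w = 0.35 * n * (yy - apex_y) / h_tri
        footprint = (yy >= apex_y) & (yy <= base_y) & (np.abs(xx - cx) <= half_w)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    height = np.where(footprint, float(height_mm), 0.0)
    texture = make_texture((full, full), texture_seed)
    # the printed column is a different material from the ground: recolor the
    # foreground (channel rotation plus a warm cast) without losing texture
    # contrast, so depth edges coincide with color edges as the
    # matting-Laplacian guide assumes of real specimens
    fg = np.clip(texture[:, :, [1, 2, 0]] + np.array([0.12, -0.08, -0.08]), 0.0, 1.0)
    texture = np.where(footprint[:, :, None], fg, texture)
    return Phantom(height_map=height, texture=texture)


def simulate_capture(phantom: Phantom, cfg: CaptureConfig) -> ElementalImageArray:
    """Forward pinhole-array capture of a phantom into an elemental image array.

    The phantom grid must match the lens grid (one surface sample per
    lens).  Sampling is bilinear with edge clamping; shifts that leave the
    grid are clamped with a warning.  Additive Gaussian noise (clipped to
    [0, 1]) is drawn from the config seed; the capture is deterministic
    given the seed.
    """
    nu, nv = cfg.lens_count_u, cfg.lens_count_v
    ns, nt = cfg.pixels_per_lens
    hp, wp = phantom.height_map.shape
    if hp < nu or wp < nv:
        raise ValueError(
            f"phantom grid {phantom.height_map.shape} smaller than the lens grid {(nu, nv)}"
        )
    # the lens grid sees the centered window of a (possibly larger) specimen
    oy, ox = (hp - nu) // 2, (wp - nv) // 2
    sc, tc = ns // 2, nt // 2
    dz = phantom.height_map[oy : oy + nu, ox : ox + nv] - cfg.native_plane_mm
    yy, xx = np.mgrid[oy : oy + nu, ox : ox + nv].astype(np.float64)
    views = np.empty((ns, nt, nu, nv, 3))
    clamped = False
    for s in range(ns):
        for t in range(nt):
            ys = yy - cfg.gamma * dz * (s - sc)
            xs = xx - cfg.gamma * dz * (t - tc)
            if ys.min() < 0 or ys.max() > hp - 1 or xs.min() < 0 or xs.max() > wp - 1:
                clamped = True
            coords = np.stack([ys, xs])
            for c in range(3):
                views[s, t, :, :, c] = ndimage.map_coordinates(
                    phantom.texture[:, :, c], coords, order=1, mode="nearest"
                )
    if clamped:
        warnings.warn("parallax shifts exceed the grid and were clamped at the edges")
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        views = views + rng.normal(scale=cfg.noise_sigma, size=views.shape)
    views = np.clip(views, 0.0, 1.0)
    return views_to_eia(ViewStack(views=views), cfg.layout)


def fixture_alpha_grid(
    heights_mm: np.ndarray, cfg: CaptureConfig, n: int = 64, margin_beta: float = 0.5
) -> AlphaGrid:
    """Refocus grid covering a phantom's disparity range with margin.

    Uses the linear shear convention: beta = gamma * (h - z0).
    """
    betas = cfg.gamma * (np.asarray(heights_mm, dtype=np.float64) - cfg.native_plane_mm)
    lo = min(betas.min() - margin_beta, -margin_beta)
    hi = max(betas.max() + margin_beta, margin_beta)
    return AlphaGrid(np.linspace(lo, hi, n) + 1.0)


_FIXTURES = ("steps4", "flat", "cylinder2mm", "square3mm", "triangle1mm")


def end_to_end_fixture(
    name: str, seed: int = 0, noise_sigma: float = 0.0
) -> tuple[ElementalImageArray, MetricDepthMap, CalibrationFit]:
    """Packaged phantom + capture + its exact calibration line.

    Fixtures: ``steps4`` (4-floor staircase, 1 mm floors), ``flat`` (plane
    at the native plane), and the measurement boards ``cylinder2mm``,
    ``square3mm``, ``triangle1mm``.  The returned metric depth map is the
    phantom's true height field at view resolution; the fit is the
    simulator's own alpha-to-mm line.
    """
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURES}")
    cfg = CaptureConfig(seed=seed, noise_sigma=noise_sigma)
    n = cfg.lens_count_u
    margin = 12  # exceeds the largest parallax shift of any fixture
    if name == "steps4":
        phantom = make_step_phantom(4, 1.0, n // 4, texture_seed=seed, margin_px=margin)
    elif name == "flat":
        full = n + 2 * margin
        phantom = Phantom(
            height_map=np.zeros((full, full)),
            texture=make_texture((full, full), seed),
        )
    elif name == "cylinder2mm":
        phantom = make_shape_phantom("cylinder", 2.0, seed, n, margin_px=margin)
    elif name == "square3mm":
        phantom = make_shape_phantom("square_column", 3.0, seed, n, margin_px=margin)
    else:  # triangle1mm
        phantom = make_shape_phantom("triangular_column", 1.0, seed, n, margin_px=margin)
    eia = simulate_capture(phantom, cfg)
    hm = phantom.height_map[margin : margin + n, margin : margin + n]
    truth = MetricDepthMap(depth_mm=hm.copy(), provenance=cfg.truth_fit)
    return eia, truth, cfg.truth_fit
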
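"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

import lfm3d as L


def bandlimited_views(
    nu: int = 16, nv: int = 16, ns: int = 5, nt: int = 5, kmax: int = 2, seed: int = 0
) -> L.ViewStack:
    """Periodic band-limited random view stack (spectrum support |k| <= kmax).

    Periodicity makes frequency-domain shifting exact, so the spatial and
    Fourier refocusing routes can be compared without boundary effects.
    """
    rng = np.random.default_rng(seed)
    out = np.empty((ns, nt, nu, nv, 3))
    ks = range(-kmax, kmax + 1)
    for s in range(ns):
        for t in range(nt):
            for c in range(3):
                F = np.zeros((nu, nv), dtype=complex)
                for ky in ks:
                    for kx in ks:
                        F[ky % nu, kx % nv] = rng.normal() + 1j * rng.normal()
                v = np.fft.ifft2(F).real
                out[s, t, :, :, c] = (v - v.min()) / (v.max() - v.min())
    return L.ViewStack(views=out)


def zbuffer_render_oracle(
    scene: L.LayeredScene,
    display: L.DisplaySpec,
    pixels_per_lens: tuple[int, int],
    background: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Brute-force DRC oracle: per-pixel z-buffer over all layers, plain loops.

    Uses the same sampling rules as the production renderer (ray through
    the lens center, nearest-cell lookup) but no vectorization and no
    early termination: every layer is tested and the nearest occupied hit
    wins by z comparison.
    """
    la = display.lens_array
    ps, pt = pixels_per_lens
    lu, lv = la.lens_count_u, la.lens_count_v
    g, pp = la.gap, display.pixel_pitch_mm
    cell = scene.cell_size_mm
    x0, y0 = scene.origin_xy
    nH, nW = scene.masks.shape[1:]
    out = np.empty((lu * ps, lv * pt, 3))
    out[:] = background
    for i in range(lu):
        cy = (i + 0.5 - lu / 2) * la.lens_pitch
        for j in range(lv):
            cx = (j + 0.5 - lv / 2) * la.lens_pitch
            for a in range(ps):
                oy = ((a + 0.5) - ps / 2) * pp
                for b in range(pt):
                    ox = ((b + 0.5) - pt / 2) * pp
                    best_z, best_color = np.inf, None
                    for k in range(scene.n_layers):
                        z = scene.z_planes[k]
                        rr = int(np.round(((cy - (z / g) * oy) - y0) / cell))
                        cc = int(np.round(((cx - (z / g) * ox) - x0) / cell))
                        if 0 <= rr < nH and 0 <= cc < nW and scene.masks[k][rr, cc]:
                            if z < best_z:
                                best_z, best_color = z, scene.colors[k][rr, cc]
                    if best_color is not None:
                        out[i * ps + a, j * pt + b] = best_color
    return out


def random_layered_scene(
    seed: int, n_layers: int = 3, hw: int = 20, occupancy: float = 0.25
) -> L.LayeredScene:
    """Random single-occupancy layered scene straddling the display conjugate plane."""
    rng = np.random.default_rng(seed)
    zs = np.sort(rng.uniform(5.5, 9.5, size=n_layers))
    raw = rng.random((n_layers, hw, hw)) < occupancy
    occ = raw.argmax(axis=0)
    any_ = raw.any(axis=0)
    masks = np.zeros_like(raw)
    for k in range(n_layers):
        masks[k] = any_ & (occ == k)
    colors = rng.random((n_layers, hw, hw, 3)) * masks[..., None]
    return L.LayeredScene(
        z_planes=zs, masks=masks, colors=colors, cell_size_mm=0.3,
        origin_xy=(-0.15 * hw, -0.15 * hw),
    )


@pytest.fixture(scope="session")
def small_display() -> L.DisplaySpec:
    la = L.LensArraySpec(
        lens_count_u=6, lens_count_v=6, lens_pitch=1.0, focal_length=3.3, gap=6.0
    )
    return L.DisplaySpec(pixel_pitch_mm=0.089, panel_resolution=(66, 66), lens_array=la)


@pytest.fixture(scope="session")
def tiny_capture() -> L.CaptureConfig:
    """Desk-scale capture: 32x32 lenses, 5x5 views."""
    return L.CaptureConfig(lens_count_u=32, lens_count_v=32, pixels_per_lens=(5, 5))


def capture_plane(
    height_mm: float, cfg: L.CaptureConfig, seed: int = 0, margin: int = 10
) -> L.ElementalImageArray:
    """Capture a flat textured plane at the given height."""
    n = cfg.lens_count_u + 2 * margin
    phantom = L.Phantom(
        height_map=np.full((n, n), float(height_mm)),
        texture=L.synthetic.make_texture((n, n), seed),
    )
    return L.simulate_capture(phantom, cfg)
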
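"""Shape-from-focus depth estimation with matting-Laplacian densification.

The pipeline: measure per-pixel focus (squared-Laplacian energy) across
the focal stack, take the per-pixel argmax alpha as an initial depth map,
keep only high-confidence pixels (sparse depth ``d_tilde`` with diagonal
precision ``Lambda``), build the closed-form-matting Laplacian ``L`` from
the central view, and recover the dense map as the MAP estimate

    (L + Lambda) d = Lambda d_tilde

whose smoothness prior propagates the reliable depths along the color
structure of the guide image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, spsolve

from .lightfield import ElementalImageArray, central_view, extract_views
from .refocus import AlphaGrid, Convention, FocalStack, build_focal_stack

__all__ = [
    "FocusVolume",
    "RelativeDepthMap",
    "SparseDepth",
    "PrecisionDiag",
    "MattingLaplacianMatrix",
    "DepthConfig",
    "focus_measure",
    "initial_depth",
    "reliability_filter",
    "matting_laplacian",
    "solve_map",
    "estimate_depth",
    "depth_pipeline",
]

LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class FocusVolume:
    """Nonnegative focus score per (pixel, alpha): shape (H, W, n_alpha)."""

    values: np.ndarray
    alpha_grid: AlphaGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3 or v.shape[2] != len(self.alpha_grid):
            raise ValueError(
                f"volume shape {v.shape} inconsistent with grid of {len(self.alpha_grid)}"
            )
        if v.min() < 0:
            raise ValueError("focus measures must be nonnegative")
        self.values = v


@dataclass
class RelativeDepthMap:
    """Per-pixel depth in alpha units with a validity mask."""

    depth: np.ndarray
    validity: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=np.float64)
        if self.validity is None:
            self.validity = np.ones(self.depth.shape, dtype=bool)
        self.validity = np.asarray(self.validity, dtype=bool)
        if self.validity.shape != self.depth.shape:
            raise ValueError("validity mask must match depth shape")


@dataclass
class SparseDepth:
    """High-confidence depth observations d_tilde on a pixel mask."""

    d_tilde: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.d_tilde = np.asarray(self.d_tilde, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.d_tilde.shape:
            raise ValueError("mask must match d_tilde shape")
        if not self.mask.any():
            raise ValueError("sparse depth must observe at least one pixel")


@dataclass
class PrecisionDiag:
    """Diagonal data precision: positive on observed pixels, zero elsewhere."""

    lambda_diag: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.lambda_diag, dtype=np.float64)
        if lam.min() < 0:
            raise ValueError("precision must be nonnegative")
        self.lambda_diag = lam


@dataclass
class MattingLaplacianMatrix:
    """Closed-form-matting Laplacian: sparse symmetric PSD with zero row sums."""

    matrix: sparse.csr_matrix
    shape_hw: tuple[int, int]
    window_radius: int
    epsilon: float


@dataclass
class DepthConfig:
    """Tunable parameters of the depth pipeline.

    ``alphas`` overrides the automatic grid; otherwise ``n_alpha`` planes
    uniform in beta over ``[-beta_max, beta_max]`` are used (``beta_max``
    defaulting to a quarter-view-width maximal shift).
    """

    alphas: np.ndarray | None = None
    n_alpha: int = 64
    beta_max: float | None = None
    convention: Convention = "linear"
    refocus_method: Literal["shift_sum", "fourier"] = "shift_sum"
    interp_order: int = 3
    focus_window: int = 9
    tau: float = 1.0
    prominence_ratio: float = 1.5
    lambda_val: float = 1e3
    matting_radius: int = 1
    matting_epsilon: float = 1e-5
    solver_tol: float = 1e-8

    @classmethod
    def from_yaml(cls, path: str) -> "DepthConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "alphas" in data and data["alphas"] is not None:
            data["alphas"] = np.asarray(data["alphas"], dtype=np.float64)
        return cls(**data)


def focus_measure(stack: FocalStack, window: int = 9) -> FocusVolume:
    """Squared 3x3-Laplacian energy summed over a ``window`` x ``window`` patch.

    Borders are reflect-padded for both the Laplacian and the window sum.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"focus window must be odd and >= 3, got {window}")
    images = stack.images
    if images.ndim == 4:  # RGB stack: measure on luminance
        images = images @ np.array([0.299, 0.587, 0.114])
    n = images.shape[0]
    out = np.empty(images.shape[1:] + (n,))
    for i in range(n):
        lap = ndimage.convolve(images[i], LAPLACIAN_KERNEL, mode="reflect")
        energy = ndimage.uniform_filter(lap * lap, size=window, mode="reflect")
        out[:, :, i] = energy * (window * window)
    return FocusVolume(values=np.maximum(out, 0.0), alpha_grid=stack.alpha_grid)


def initial_depth(volume: FocusVolume) -> RelativeDepthMap:
    """Per-pixel alpha of the maximal focus score (ties -> smallest alpha)."""
    idx = np.argmax(volume.values, axis=2)  # argmax returns the first (smallest) index
    return RelativeDepthMap(depth=volume.alpha_grid.alphas[idx])


def reliability_filter(
    volume: FocusVolume,
    initial: RelativeDepthMap,
    tau: float = 1.0,
    prominence_ratio: float = 1.5,
    lambda_val: float = 1e3,
) -> tuple[SparseDepth, PrecisionDiag]:
    """Keep only pixels whose focus response is strong and sharply peaked.

    A pixel survives when (a) its peak focus score is at least ``tau``
    times the global median peak and (b) the peak-to-mean ratio across the
    alpha axis is at least ``prominence_ratio``; texture-free pixels fail
    both.  Surviving pixels receive precision ``lambda_val``.
    """
    if tau <= 0 or lambda_val <= 0:
        raise ValueError("tau and lambda_val must be positive")
    peak = volume.values.max(axis=2)
    mean = volume.values.mean(axis=2)
    median_peak = np.median(peak)
    strong = peak >= tau * median_peak
    with np.errstate(divide="ignore", invalid="ignore"):
        prom = np.where(mean > 0, peak / np.maximum(mean, 1e-300), 0.0)
    keep = strong & (prom >= prominence_ratio) & (peak > 0)
    if not keep.any():
        raise ValueError(
            "reliability filter removed every pixel; lower tau or the prominence ratio"
        )
    d_tilde = np.where(keep, initial.depth, 0.0)
    lam = np.where(keep, lambda_val, 0.0)
    return SparseDepth(d_tilde=d_tilde, mask=keep), PrecisionDiag(lambda_diag=lam)


def matting_laplacian(
    image: np.ndarray, window_radius: int = 1, epsilon: float = 1e-5
) -> MattingLaplacianMatrix:
    """Closed-form-matting Laplacian of an RGB guide image.

    For every full (2r+1)x(2r+1) window ``k`` with color mean ``mu_k`` and
    covariance ``Sigma_k``, pixel pairs ``(i, j)`` inside the window
    accumulate the affinity

        w_ij += (1 + (I_i - mu_k)^T (Sigma_k + eps/|w| I)^-1 (I_j - mu_k)) / |w|

    and ``L = diag(W 1) - W``, which is symmetric, positive semidefinite
    and has exactly zero row sums (constant images lie in its null space).
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None].repeat(3, axis=2)
    if not np.all(np.isfinite(img)):
        raise ValueError("guide image contains non-finite values")
    if epsilon <= 0 or window_radius < 1:
        raise ValueError("epsilon must be > 0 and window_radius >= 1")
    h, w, _ = img.shape
    r = window_radius
    win = 2 * r + 1
    if h < win or w < win:
        raise ValueError(f"image {h}x{w} smaller than the {win}x{win} matting window")
    wsize = win * win
    n = h * w

    inds = np.arange(n).reshape(h, w)
    # all full windows, flattened: (n_win, wsize)
    win_inds = np.lib.stride_tricks.sliding_window_view(inds, (win, win)).reshape(-1, wsize)
    win_img = np.lib.stride_tricks.sliding_window_view(img, (win, win), axis=(0, 1))
    win_img = win_img.reshape(-1, 3, wsize).transpose(0, 2, 1)  # (n_win, wsize, 3)

    mu = win_img.mean(axis=1, keepdims=True)
    centered = win_img - mu
    cov = np.einsum("kwi,kwj->kij", centered, centered) / wsize
    reg = cov + (epsilon / wsize) * np.eye(3)
    inv = np.linalg.inv(reg)
    # affinity block per window: (1 + x_i^T inv x_j) / wsize
    proj = np.einsum("kij,kwj->kwi", inv, centered)
    vals = (1.0 + np.einsum("kwi,kvi->kwv", centered, proj)) / wsize

    rows = np.repeat(win_inds, wsize, axis=1).ravel()
    cols = np.tile(win_inds, (1, wsize)).ravel()
    W = sparse.coo_matrix((vals.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    W = 0.5 * (W + W.T)  # symmetric up to fp rounding; enforce exactly
    d = np.asarray(W.sum(axis=1)).ravel()
    L = sparse.diags(d) - W
    return MattingLaplacianMatrix(
        matrix=L.tocsr(), shape_hw=(h, w), window_radius=r, epsilon=epsilon
    )


def solve_map(
    L: MattingLaplacianMatrix,
    precision: PrecisionDiag,
    observations: SparseDepth,
    tol: float = 1e-8,
    direct_below: int = 10_000,
) -> RelativeDepthMap:
    """Solve ``(L + Lambda) d = Lambda d_tilde`` for the dense depth map.

    A sparse direct factorization is used for systems below
    ``direct_below`` unknowns, diagonally preconditioned conjugate
    gradients above; either way the relative residual is verified against
    ``tol``.
    """
    h, w = L.shape_hw
    lam = precision.lambda_diag.ravel()
    if lam.shape[0] != h * w:
        raise ValueError("precision shape does not match the Laplacian")
    if not np.any(lam > 0):
        raise ValueError("cannot solve: no observed pixels (all precisions are zero)")
    b = lam * observations.d_tilde.ravel()
    A = (L.matrix + sparse.diags(lam)).tocsr()
    n = h * w
    if n < direct_below:
        d = spsolve(A.tocsc(), b)
    else:
        M = sparse.diags(1.0 / A.diagonal())
        x0 = np.full(n, observations.d_tilde[observations.mask].mean())
        d, info = cg(A, b, x0=x0, rtol=tol / 10, atol=0.0, M=M, maxiter=20_000)
        if info != 0:
            d = spsolve(A.tocsc(), b)
    res = np.linalg.norm(A @ d - b) / np.linalg.norm(b)
    if not np.isfinite(res) or res > tol:
        raise RuntimeError(f"MAP solve ill-posed or unconverged: relative residual {res:.2e}")
    return RelativeDepthMap(depth=d.reshape(h, w))


@dataclass
class DepthResult:
    """All intermediate products of :func:`depth_pipeline`."""

    depth: RelativeDepthMap
    initial: RelativeDepthMap
    sparse: SparseDepth
    precision: PrecisionDiag
    volume: FocusVolume
    stack: FocalStack
    central: np.ndarray
    config: DepthConfig = field(repr=False)


def depth_pipeline(eia: ElementalImageArray, config: DepthConfig | None = None) -> DepthResult:
    """Run the full pipeline, returning every intermediate stage.

    Stages: view extraction -> focal stack -> focus volume -> initial
    depth -> reliability filter -> matting Laplacian of the central view
    -> MAP solve.  Deterministic given the input and config.
    """
    cfg = config or DepthConfig()
    stage = "view extraction"
    try:
        views = extract_views(eia)
        stage = "alpha grid"
        if cfg.alphas is not None:
            grid = AlphaGrid(cfg.alphas)
        else:
            from .refocus import default_alpha_grid

            grid = default_alpha_grid(views, n=cfg.n_alpha, beta_max=cfg.beta_max,
                                      convention=cfg.convention)
        stage = "refocusing"
        stack = build_focal_stack(
            views, grid, method=cfg.refocus_method, convention=cfg.convention,
            order=cfg.interp_order,
        )
        stage = "focus measure"
        volume = focus_measure(stack, window=cfg.focus_window)
        stage = "initial depth"
        init = initial_depth(volume)
        stage = "reliability filter"
        sp, prec = reliability_filter(
            volume, init, tau=cfg.tau, prominence_ratio=cfg.prominence_ratio,
            lambda_val=cfg.lambda_val,
        )
        stage = "matting Laplacian"
        cview = central_view(views)
        L = matting_laplacian(cview, window_radius=cfg.matting_radius,
                              epsilon=cfg.matting_epsilon)
        stage = "MAP solve"
        dense = solve_map(L, prec, sp, tol=cfg.solver_tol)
    except Exception as exc:
        raise RuntimeError(f"depth pipeline failed at stage '{stage}': {exc}") from exc
    # clip tiny overshoots of the smoothness prior back into the grid span
    lo, hi = grid.alphas[0], grid.alphas[-1]
    dense = RelativeDepthMap(depth=np.clip(dense.depth, lo, hi))
    return DepthResult(
        depth=dense, initial=init, sparse=sp, precision=prec,
        volume=volume, stack=stack, central=cview, config=cfg,
    )


def estimate_depth(
    eia: ElementalImageArray, config: DepthConfig | None = None
) -> RelativeDepthMap:
    """Dense relative depth map (alpha units) at view resolution."""
    return depth_pipeline(eia, config).depth
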
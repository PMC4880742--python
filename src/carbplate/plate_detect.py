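"""Elliptical plate detection from image edges.

The dish is assumed round, so its image under a pinhole camera is an
ellipse.  Detection extracts gradient edges and runs a sample-consensus
loop (RANSAC over 5-point algebraic conic fits) to find the ellipse with
the largest edge support, followed by a direct least-squares ellipse
refinement on the inliers.  Everything downstream of this stage operates
inside the fitted ellipse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import canny

from .errors import PlateNotFoundError
from .geometry import conic_to_ellipse_params, rc_to_uv


@dataclass(frozen=True)
class PlateEllipse:
    """The plate border: center, semi-axes (a >= b) and orientation.

    ``rotation_deg`` is the major-axis angle in [0, 180), measured from
    the +col axis toward +row.
    """

    center_px: tuple[float, float]          # (row, col)
    semi_axes_px: tuple[float, float]       # (a, b), a >= b
    rotation_deg: float

    def __post_init__(self) -> None:
        a, b = self.semi_axes_px
        if not (a >= b > 0):
            raise ValueError("semi-axes must satisfy a >= b > 0")

    def contains(self, points_rc: np.ndarray, *, margin_px: float = 0.0) -> np.ndarray:
        """Boolean inside-test for (N, 2) (row, col) points."""
        pts = np.atleast_2d(np.asarray(points_rc, dtype=float))
        uv = rc_to_uv(pts) - rc_to_uv(np.asarray(self.center_px))
        ang = np.deg2rad(self.rotation_deg)
        ca, sa = np.cos(ang), np.sin(ang)
        x = uv[:, 0] * ca + uv[:, 1] * sa
        y = -uv[:, 0] * sa + uv[:, 1] * ca
        a, b = self.semi_axes_px
        a = max(a - margin_px, 1e-9)
        b = max(b - margin_px, 1e-9)
        return (x / a) ** 2 + (y / b) ** 2 <= 1.0

    def mask(self, image_size: tuple[int, int]) -> np.ndarray:
        rows, cols = image_size
        r, c = np.mgrid[0:rows, 0:cols]
        pts = np.column_stack([r.ravel(), c.ravel()])
        return self.contains(pts).reshape(rows, cols)

    def iou(self, other: "PlateEllipse", image_size: tuple[int, int]) -> float:
        m1, m2 = self.mask(image_size), other.mask(image_size)
        union = np.logical_or(m1, m2).sum()
        if union == 0:
            return 0.0
        return float(np.logical_and(m1, m2).sum() / union)

    @property
    def area_px(self) -> float:
        return float(np.pi * self.semi_axes_px[0] * self.semi_axes_px[1])


def plate_from_ground_truth(ellipse_tuple) -> PlateEllipse:
    """Convert the renderer's analytic plate boundary to a PlateEllipse."""
    center, axes, rot = ellipse_tuple
    return PlateEllipse(center_px=tuple(np.asarray(center, dtype=float)),
                        semi_axes_px=(float(axes[0]), float(axes[1])),
                        rotation_deg=float(rot))


@dataclass
class EdgeSet:
    """Edge pixels of an image, as (N, 2) (row, col) coordinates."""

    points: np.ndarray
    gradient_dirs: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PlateDetectConfig:
    canny_sigma: float = 2.0
    canny_low: float = 0.10
    canny_high: float = 0.20
    ransac_iters: int = 600
    inlier_tol_px: float = 2.0
    min_inlier_frac: float = 0.15
    min_semi_axis_px: float = 20.0
    confidence: float = 0.995
    rng_seed: int = 0


def detect_edges(image: np.ndarray, config: PlateDetectConfig | None = None) -> EdgeSet:
    """Gradient-based edge extraction (Canny with absolute thresholds).

    A uniform image yields an empty edge set, which is not an error.
    """
    config = config or PlateDetectConfig()
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    gray = rgb2gray(img) if img.ndim == 3 else img.astype(float) / (255.0 if img.dtype == np.uint8 else 1.0)
    e = canny(gray, sigma=config.canny_sigma, low_threshold=config.canny_low,
              high_threshold=config.canny_high)
    pts = np.column_stack(np.nonzero(e)).astype(float)
    return EdgeSet(points=pts)


# --- conic algebra -------------------------------------------------------

def _conic_matrix(theta: np.ndarray) -> np.ndarray:
    A, B, C, D, E, F = theta
    return np.array([[A, B / 2, D / 2], [B / 2, C, E / 2], [D / 2, E / 2, F]])


def _fit_conic_minimal(uv: np.ndarray) -> np.ndarray | None:
    """Conic through 5 points via the SVD null space; None if degenerate."""
    u, v = uv[:, 0], uv[:, 1]
    M = np.column_stack([u * u, u * v, v * v, u, v, np.ones_like(u)])
    _, s, Vt = np.linalg.svd(M)
    theta = Vt[-1]
    A, B, C = theta[0], theta[1], theta[2]
    if B * B - 4 * A * C >= 0:       # not an ellipse
        return None
    return theta


def fit_ellipse_direct(uv: np.ndarray) -> np.ndarray:
    """Direct least-squares ellipse fit (ellipse-constrained conic).

    Numerically stable split-design variant; returns the conic 6-vector.
    """
    u, v = uv[:, 0] - uv[:, 0].mean(), uv[:, 1] - uv[:, 1].mean()
    D1 = np.column_stack([u * u, u * v, v * v])
    D2 = np.column_stack([u, v, np.ones_like(u)])
    S1 = D1.T @ D1
    S2 = D1.T @ D2
    S3 = D2.T @ D2
    T = -np.linalg.solve(S3, S2.T)
    M = S1 + S2 @ T
    Cinv = np.array([[0, 0, 0.5], [0, -1.0, 0], [0.5, 0, 0]])
    evals, evecs = np.linalg.eig(Cinv @ M)
    cond = 4 * evecs[0] * evecs[2] - evecs[1] ** 2
    idx = np.where(np.isreal(evals) & (cond > 0))[0]
    if len(idx) == 0:
        raise PlateNotFoundError("least-squares fit produced no ellipse")
    a1 = np.real(evecs[:, idx[0]])
    a2 = T @ a1
    theta = np.concatenate([a1, a2])
    # undo the centering shift
    mu, mv = uv[:, 0].mean(), uv[:, 1].mean()
    A, B, C, D, E, F = theta
    D0 = D - 2 * A * mu - B * mv
    E0 = E - 2 * C * mv - B * mu
    F0 = F + A * mu * mu + B * mu * mv + C * mv * mv - D * mu - E * mv
    return np.array([A, B, C, D0, E0, F0])


def _sampson_distance(theta: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """First-order geometric distance of points to the conic."""
    A, B, C, D, E, F = theta
    u, v = uv[:, 0], uv[:, 1]
    val = A * u * u + B * u * v + C * v * v + D * u + E * v + F
    gu = 2 * A * u + B * v + D
    gv = B * u + 2 * C * v + E
    grad = np.hypot(gu, gv)
    return np.abs(val) / np.maximum(grad, 1e-12)


def _component_groups(uv: np.ndarray) -> list[np.ndarray]:
    """Index groups of 8-connected edge-pixel chains."""
    from scipy import ndimage as ndi

    ij = np.round(uv).astype(int)
    ij -= ij.min(axis=0)
    shape = tuple(ij.max(axis=0) + 1)
    if shape[0] * shape[1] > 50_000_000:
        return []
    grid = np.zeros(shape, dtype=bool)
    grid[ij[:, 0], ij[:, 1]] = True
    labels, nlab = ndi.label(grid, structure=np.ones((3, 3), dtype=int))
    point_lab = labels[ij[:, 0], ij[:, 1]]
    order = np.argsort(point_lab, kind="stable")
    bounds = np.searchsorted(point_lab[order], np.arange(1, nlab + 1))
    groups = np.split(order, bounds[1:])
    return [g for g in groups if len(g) >= 5]


def _conic_to_plate(theta: np.ndarray) -> PlateEllipse:
    center_rc, axes, rot = conic_to_ellipse_params(_conic_matrix(theta))
    return PlateEllipse(center_px=tuple(center_rc), semi_axes_px=axes,
                        rotation_deg=rot)


def fit_plate_ellipse(edges: EdgeSet, config: PlateDetectConfig | None = None) -> PlateEllipse:
    """Highest-consensus ellipse through the edge set.

    RANSAC over 5-point minimal conic fits with a Sampson-distance
    inlier test, then direct least-squares refinement on the inliers.
    Ties in inlier count are broken toward larger area (the plate
    dominates the scene).  Seeded and reproducible; invariant to point
    order and duplication of inliers up to the deduplication applied
    before sampling.
    """
    config = config or PlateDetectConfig()
    pts = np.asarray(edges.points, dtype=float)
    if len(pts) < 5:
        raise PlateNotFoundError(f"need at least 5 edge points, got {len(pts)}")
    # canonical order + dedup -> invariance to input order/duplication
    uv_all = rc_to_uv(pts)
    uv = np.unique(uv_all, axis=0)
    n = len(uv)
    if n < 5:
        raise PlateNotFoundError("fewer than 5 distinct edge points")

    rng = np.random.default_rng(config.rng_seed)

    # Edge pixels of one physical boundary form connected chains; sampling
    # minimal sets within one chain makes the consensus loop find the plate
    # rim orders of magnitude faster than blind uniform sampling.  Half the
    # iterations stay uniform as a fallback for fragmented edges.
    groups = _component_groups(uv)
    group_sizes = np.array([len(g) for g in groups], dtype=float)
    group_p = group_sizes / group_sizes.sum() if len(groups) else None

    best = None  # (n_inliers, area, theta, inlier_mask)
    max_iters = config.ransac_iters
    it = 0
    needed = max_iters
    while it < needed and it < max_iters:
        if group_p is not None and it % 2 == 0:
            g = groups[rng.choice(len(groups), p=group_p)]
            if len(g) >= 5:
                idx = g[rng.choice(len(g), size=5, replace=False)]
            else:
                idx = rng.choice(n, size=5, replace=False)
        else:
            idx = rng.choice(n, size=5, replace=False)
        theta = _fit_conic_minimal(uv[idx])
        it += 1
        if theta is None:
            continue
        d = _sampson_distance(theta, uv)
        inl = d < config.inlier_tol_px
        ni = int(inl.sum())
        if ni < 5:
            continue
        try:
            area = _conic_to_plate(theta).area_px
        except ValueError:
            continue
        if best is None or ni > best[0] or (ni == best[0] and area > best[1]):
            best = (ni, area, theta, inl)
            w = ni / n
            if w > 0:
                denom = np.log(max(1.0 - w ** 5, 1e-12))
                needed = min(max_iters, int(np.ceil(np.log(1 - config.confidence) / denom)))
    if best is None or best[0] < config.min_inlier_frac * min(n, 4000):
        raise PlateNotFoundError("no ellipse with sufficient edge consensus")

    # refine on inliers, then one re-selection pass
    inl = best[3]
    for _ in range(2):
        theta = fit_ellipse_direct(uv[inl])
        d = _sampson_distance(theta, uv)
        inl = d < config.inlier_tol_px
    plate = _conic_to_plate(theta)
    if plate.semi_axes_px[1] < config.min_semi_axis_px:
        raise PlateNotFoundError("consensus ellipse is implausibly small")
    return plate


def detect_plate(image: np.ndarray, config: PlateDetectConfig | None = None) -> PlateEllipse:
    """Edge extraction followed by robust ellipse fitting."""
    config = config or PlateDetectConfig()
    return fit_plate_ellipse(detect_edges(image, config), config)
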
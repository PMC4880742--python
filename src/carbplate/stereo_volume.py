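"""Two-view metric reconstruction and food-volume integration.

Pipeline: sparse keypoints are detected and matched between the two
views; the relative camera pose is recovered from the matches; the pair
is rectified and densely matched to produce a disparity map, hence a 3D
point cloud up to scale; the reference card of known physical size fixes
the absolute (metric) scale; a robust plane fit to the bare-plate points
defines "height zero"; and each food region's volume is the integral of
its height field over the plate plane.

Pose estimation note: a meal scene is quasi-planar (table, plate rim and
card all lie on one plane; food relief is a few percent of the camera
distance), which is a degenerate configuration for the linear 8-point
essential-matrix algorithm.  The pose is therefore recovered from the
dominant-plane homography (RANSAC + SVD decomposition into rotation,
translation direction and plane normal), with the decomposition
ambiguity resolved by cheirality and by the epipolar support of
off-plane (food) matches, followed by a Sampson-error refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors
from skimage.transform import warp

from .errors import (
    InsufficientPlatePointsError,
    InsufficientTextureError,
    NoReferenceError,
    PoseFailureError,
    ReconstructionError,
)
from .geometry import rc_to_uv, uv_to_rc
from .plate_detect import PlateEllipse
from .segmentation import SegmentationMask


@dataclass
class StereoConfig:
    n_keypoints: int = 800
    match_max_ratio: float = 0.9
    subpixel_matches: bool = True
    plane_prefilter: bool = True
    plane_prefilter_tol_px: float = 12.0
    ransac_iters: int = 1000
    h_inlier_tol_px: float = 2.0
    h_refit_tol_px: float = 0.75
    e_inlier_tol_px: float = 1.5
    refine_pose: bool = True
    block_radius: int = 2               # (2r+1)^2 SSD window
    lr_tol_px: float = 1.25
    disparity_pad_px: int = 6
    grid_cell_cm: float = 0.2
    footprint_erode_cells: int | None = None  # None: adapt to matching-blur width
    min_plate_points: int = 50
    plane_ransac_iters: int = 300
    plane_inlier_frac_depth: float = 0.004   # inlier tol as a fraction of median depth
    rng_seed: int = 0


@dataclass
class Correspondences:
    """Matched keypoint pairs between view0 and view1, (row, col) px."""

    view0_px: np.ndarray
    view1_px: np.ndarray
    scores: np.ndarray

    def __len__(self) -> int:
        return len(self.view0_px)


@dataclass
class RelativePose:
    """Pose of camera1 relative to camera0: X1 = R @ X0 + s * t_dir."""

    rotation: np.ndarray        # (3, 3), det = +1
    translation_dir: np.ndarray  # unit vector, cam1 frame
    intrinsics: np.ndarray      # shared 3x3 K

    @property
    def essential(self) -> np.ndarray:
        t = self.translation_dir
        tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
        return tx @ self.rotation

    @property
    def fundamental(self) -> np.ndarray:
        Kinv = np.linalg.inv(self.intrinsics)
        return Kinv.T @ self.essential @ Kinv


@dataclass
class DepthCloud:
    """Scale-free reconstruction, organized by view0 pixel."""

    points: np.ndarray          # (N, 3) in the view0 camera frame, model units
    pixels_rc: np.ndarray       # (N, 2) integer view0 pixel of each point


@dataclass
class PlatePlane:
    """Plane n . X = d in the view0 camera frame (n unit, toward camera)."""

    normal: np.ndarray
    d: float

    def height_of(self, points: np.ndarray) -> np.ndarray:
        return points @ self.normal - self.d


@dataclass
class VolumeEstimate:
    region_volumes_ml: dict[int, float]

    @property
    def total_ml(self) -> float:
        return float(sum(self.region_volumes_ml.values()))


def _gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    return rgb2gray(img) if img.ndim == 3 else img.astype(float)


# ---------------------------------------------------------------------------
# Sparse matching
# ---------------------------------------------------------------------------

def match_keypoints(view0: np.ndarray, view1: np.ndarray,
                    config: StereoConfig | None = None) -> Correspondences:
    """ORB keypoints with mutual-best (cross-checked) ratio-test matching."""
    config = config or StereoConfig()
    g0, g1 = _gray(view0), _gray(view1)
    kp, desc = [], []
    for g in (g0, g1):
        orb = ORB(n_keypoints=config.n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(g)
        except RuntimeError:
            raise InsufficientTextureError("no keypoints detected")
        kp.append(orb.keypoints)
        desc.append(orb.descriptors)
    if len(kp[0]) < 8 or len(kp[1]) < 8:
        raise InsufficientTextureError("fewer than 8 keypoints in a view")
    matches = match_descriptors(desc[0], desc[1], cross_check=True,
                                max_ratio=config.match_max_ratio)
    if len(matches) < 8:
        raise InsufficientTextureError(f"only {len(matches)} matches")
    p0 = kp[0][matches[:, 0]]
    p1 = kp[1][matches[:, 1]]
    d = np.array([np.count_nonzero(desc[0][i] != desc[1][j]) for i, j in matches],
                 dtype=float)
    if config.subpixel_matches:
        p1 = _refine_matches(g0, g1, p0, p1)
    scores = 1.0 - d / desc[0].shape[1]
    if config.plane_prefilter and len(p0) >= 12:
        # periodic table textures produce gross one-period-off mismatches;
        # food parallax against the dominant (table) plane stays within a
        # few px, so a generous plane-consistency gate removes only junk
        keep = _plane_consistent(p0, p1, tol_px=config.plane_prefilter_tol_px,
                                 seed=config.rng_seed)
        if keep.sum() >= 8:
            p0, p1, scores = p0[keep], p1[keep], scores[keep]
    return Correspondences(view0_px=p0, view1_px=p1, scores=scores)


def _plane_consistent(p0: np.ndarray, p1: np.ndarray, tol_px: float,
                      seed: int = 0) -> np.ndarray:
    uv0, uv1 = rc_to_uv(p0), rc_to_uv(p1)
    rng = np.random.default_rng(seed)
    n = len(uv0)
    best = None
    for _ in range(300):
        idx = rng.choice(n, 4, replace=False)
        try:
            H = _homography_dlt(uv0[idx], uv1[idx])
        except np.linalg.LinAlgError:
            continue
        inl = _h_transfer_error(H, uv0, uv1) < 3.0
        if best is None or inl.sum() > best.sum():
            best = inl
    if best is None or best.sum() < 8:
        return np.ones(n, dtype=bool)
    H = _homography_dlt(uv0[best], uv1[best])
    return _h_transfer_error(H, uv0, uv1) < tol_px


def _refine_matches(g0: np.ndarray, g1: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                    patch: int = 4, search: int = 3) -> np.ndarray:
    """Subpixel correction of match positions by local SSD + parabola fit.

    ORB keypoints are pixel-quantized; a small template search around
    each match recovers the fractional offset, which matters because the
    whole-scene pose (hence the metric scale) is computed from these.
    """
    rows, cols = g0.shape
    out = p1.astype(float).copy()
    lim = patch + search
    offs = np.arange(-search, search + 1)
    for k in range(len(p0)):
        r0, c0 = int(round(p0[k, 0])), int(round(p0[k, 1]))
        r1, c1 = int(round(p1[k, 0])), int(round(p1[k, 1]))
        if not (lim <= r0 < rows - lim and lim <= c0 < cols - lim
                and lim <= r1 < rows - lim and lim <= c1 < cols - lim):
            continue
        tpl = g0[r0 - patch:r0 + patch + 1, c0 - patch:c0 + patch + 1]
        cost = np.empty((len(offs), len(offs)))
        for i, dr in enumerate(offs):
            for j, dc in enumerate(offs):
                win = g1[r1 + dr - patch:r1 + dr + patch + 1,
                         c1 + dc - patch:c1 + dc + patch + 1]
                cost[i, j] = np.sum((tpl - win) ** 2)
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        dr, dc = offs[i], offs[j]
        # 1-D parabola refinement in each axis at the discrete minimum
        sub_r = sub_c = 0.0
        if 0 < i < len(offs) - 1:
            a, b, c = cost[i - 1, j], cost[i, j], cost[i + 1, j]
            den = a - 2 * b + c
            if den > 1e-12:
                sub_r = float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
        if 0 < j < len(offs) - 1:
            a, b, c = cost[i, j - 1], cost[i, j], cost[i, j + 1]
            den = a - 2 * b + c
            if den > 1e-12:
                sub_c = float(np.clip(0.5 * (a - c) / den, -0.5, 0.5))
        out[k] = (r1 + dr + sub_r, c1 + dc + sub_c)
    return out


# ---------------------------------------------------------------------------
# Pose from the dominant-plane homography
# ---------------------------------------------------------------------------

def _homography_dlt(uv0: np.ndarray, uv1: np.ndarray) -> np.ndarray:
    """Normalized DLT homography uv0 -> uv1."""
    def normalize(p):
        mu = p.mean(axis=0)
        s = np.sqrt(2) / max(np.mean(np.linalg.norm(p - mu, axis=1)), 1e-12)
        T = np.array([[s, 0, -s * mu[0]], [0, s, -s * mu[1]], [0, 0, 1]])
        return (p - mu) * s, T

    q0, T0 = normalize(uv0)
    q1, T1 = normalize(uv1)
    n = len(q0)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = q0
    A[0::2, 2] = 1
    A[0::2, 6:8] = -q0 * q1[:, [0]]
    A[0::2, 8] = -q1[:, 0]
    A[1::2, 3:5] = q0
    A[1::2, 5] = 1
    A[1::2, 6:8] = -q0 * q1[:, [1]]
    A[1::2, 8] = -q1[:, 1]
    _, _, Vt = np.linalg.svd(A)
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(T1) @ Hn @ T0
    return H / H[2, 2]


def _h_transfer_error(H: np.ndarray, uv0: np.ndarray, uv1: np.ndarray) -> np.ndarray:
    ph = np.column_stack([uv0, np.ones(len(uv0))]) @ H.T
    with np.errstate(divide="ignore", invalid="ignore"):
        proj = ph[:, :2] / ph[:, 2:3]
    err = np.linalg.norm(proj - uv1, axis=1)
    return np.where(np.isfinite(err), err, np.inf)


def _decompose_homography(Hn: np.ndarray):
    """SVD (Faugeras) decomposition of a normalized-plane homography.

    Returns candidate (R, t_unit, n) triples with X1 = R X0 + t * (n.X0/d).
    """
    U, D, Vt = np.linalg.svd(Hn)
    V = Vt.T
    d1, d2, d3 = D
    if d1 / max(d3, 1e-12) < 1.0 + 1e-9:
        return []  # pure rotation; translation unrecoverable
    s = np.linalg.det(U) * np.linalg.det(V)
    out = []
    x1s = np.sqrt(max((d1 ** 2 - d2 ** 2) / (d1 ** 2 - d3 ** 2), 0.0))
    x3s = np.sqrt(max((d2 ** 2 - d3 ** 2) / (d1 ** 2 - d3 ** 2), 0.0))
    for e1 in (+1.0, -1.0):
        for e3 in (+1.0, -1.0):
            x1, x3 = e1 * x1s, e3 * x3s
            sin_t = (d1 - d3) * x1 * x3 / d2
            cos_t = (d1 * x3 ** 2 + d3 * x1 ** 2) / d2
            Rp = np.array([[cos_t, 0, -sin_t], [0, 1, 0], [sin_t, 0, cos_t]])
            tp = (d1 - d3) * np.array([x1, 0.0, -x3])
            npl = np.array([x1, 0.0, x3])
            R = s * U @ Rp @ Vt
            t = U @ tp
            nvec = V @ npl
            if np.linalg.norm(t) < 1e-12:
                continue
            out.append((R, t / np.linalg.norm(t), nvec))
    return out


def _sampson_px(F: np.ndarray, uv0: np.ndarray, uv1: np.ndarray) -> np.ndarray:
    x0 = np.column_stack([uv0, np.ones(len(uv0))])
    x1 = np.column_stack([uv1, np.ones(len(uv1))])
    Fx0 = x0 @ F.T
    Ftx1 = x1 @ F
    num = np.sum(x1 * Fx0, axis=1) ** 2
    den = Fx0[:, 0] ** 2 + Fx0[:, 1] ** 2 + Ftx1[:, 0] ** 2 + Ftx1[:, 1] ** 2
    return num / np.maximum(den, 1e-12)


def _triangulate_linear(K, R, t, uv0, uv1) -> np.ndarray:
    P0 = K @ np.hstack([np.eye(3), np.zeros((3, 1))])
    P1 = K @ np.hstack([R, t.reshape(3, 1)])
    pts = np.empty((len(uv0), 3))
    for i, (a, b) in enumerate(zip(uv0, uv1)):
        A = np.stack([
            a[0] * P0[2] - P0[0],
            a[1] * P0[2] - P0[1],
            b[0] * P1[2] - P1[0],
            b[1] * P1[2] - P1[1],
        ])
        _, _, Vt = np.linalg.svd(A)
        X = Vt[-1]
        pts[i] = X[:3] / X[3]
    return pts


def _cheirality_count(K, R, t, uv0, uv1) -> int:
    X = _triangulate_linear(K, R, t, uv0, uv1)
    z0 = X[:, 2]
    z1 = (X @ R.T + t)[:, 2]
    return int(np.sum((z0 > 0) & (z1 > 0)))


def estimate_pose(corr: Correspondences, intrinsics: np.ndarray,
                  config: StereoConfig | None = None) -> RelativePose:
    """Relative pose from matches via robust dominant-plane homography.

    RANSAC fits the homography of the dominant scene plane; its SVD
    decomposition yields candidate (R, t) pairs, ranked by cheirality and
    by epipolar (Sampson) support over *all* matches -- off-plane food
    points break the two-fold plane ambiguity.  Optionally refines
    (R, t) by minimizing the Sampson error of the implied essential
    matrix.  Raises on degenerate geometry (pure rotation).
    """
    config = config or StereoConfig()
    if len(corr) < 8:
        raise PoseFailureError(f"need >= 8 correspondences, got {len(corr)}")
    K = np.asarray(intrinsics, dtype=float)
    uv0 = rc_to_uv(corr.view0_px)
    uv1 = rc_to_uv(corr.view1_px)
    rng = np.random.default_rng(config.rng_seed)
    n = len(uv0)

    best_inl, best_H = None, None
    for _ in range(config.ransac_iters):
        idx = rng.choice(n, 4, replace=False)
        try:
            H = _homography_dlt(uv0[idx], uv1[idx])
        except np.linalg.LinAlgError:
            continue
        err = _h_transfer_error(H, uv0, uv1)
        inl = err < config.h_inlier_tol_px
        if best_inl is None or inl.sum() > best_inl.sum():
            best_inl, best_H = inl, H
    if best_H is None or best_inl.sum() < 6:
        raise PoseFailureError("no dominant plane found among the matches")
    # refit with a tightening tolerance: off-plane (food) points sit a few
    # px off the table homography and must not contaminate the plane fit
    inl = best_inl
    for tol in (config.h_inlier_tol_px, config.h_refit_tol_px):
        H = _homography_dlt(uv0[inl], uv1[inl])
        new_inl = _h_transfer_error(H, uv0, uv1) < tol
        if new_inl.sum() >= max(20, 0.05 * n):
            inl = new_inl
    H = _homography_dlt(uv0[inl], uv1[inl])

    Kinv = np.linalg.inv(K)
    Hn = Kinv @ H @ K
    cands = _decompose_homography(Hn)
    if not cands:
        raise PoseFailureError("pure-rotation geometry: baseline unrecoverable")

    scored = []
    for R, t, nvec in cands:
        chi = _cheirality_count(K, R, t, uv0, uv1)
        pose = RelativePose(rotation=R, translation_dir=t, intrinsics=K)
        sup = int(np.sum(_sampson_px(pose.fundamental, uv0, uv1)
                         < config.e_inlier_tol_px ** 2))
        scored.append((chi + sup, R, t))
    scored.sort(key=lambda s: -s[0])
    _, R, t = scored[0]

    if config.refine_pose:
        R, t = _refine_pose_sampson(K, R, t, uv0, uv1, config)
    return RelativePose(rotation=R, translation_dir=t, intrinsics=K)


def _rotvec_to_R(w: np.ndarray) -> np.ndarray:
    th = np.linalg.norm(w)
    if th < 1e-12:
        return np.eye(3)
    k = w / th
    Kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * Kx + (1 - np.cos(th)) * (Kx @ Kx)


def _R_to_rotvec(R: np.ndarray) -> np.ndarray:
    c = np.clip((np.trace(R) - 1) / 2, -1, 1)
    th = np.arccos(c)
    if th < 1e-12:
        return np.zeros(3)
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    return th * w / (2 * np.sin(th))


def _refine_pose_sampson(K, R0, t0, uv0, uv1, config: StereoConfig):
    from scipy.optimize import least_squares

    th0 = np.arccos(np.clip(t0[2], -1, 1))
    ph0 = np.arctan2(t0[1], t0[0])
    x0 = np.concatenate([_R_to_rotvec(R0), [th0, ph0]])
    Kinv = np.linalg.inv(K)

    # robust subset: inliers of the initial pose
    pose0 = RelativePose(R0, t0, K)
    d0 = _sampson_px(pose0.fundamental, uv0, uv1)
    keep = d0 < (2 * config.e_inlier_tol_px) ** 2
    if keep.sum() < 8:
        keep = np.ones(len(uv0), bool)
    a0, a1 = uv0[keep], uv1[keep]

    def resid(x):
        R = _rotvec_to_R(x[:3])
        th, ph = x[3], x[4]
        t = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
        tx = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
        F = Kinv.T @ tx @ R @ Kinv
        return np.sqrt(_sampson_px(F, a0, a1))

    sol = least_squares(resid, x0, method="lm", max_nfev=200)
    R = _rotvec_to_R(sol.x[:3])
    th, ph = sol.x[3], sol.x[4]
    t = np.array([np.sin(th) * np.cos(ph), np.sin(th) * np.sin(ph), np.cos(th)])
    return R, t


# ---------------------------------------------------------------------------
# Rectified dense matching
# ---------------------------------------------------------------------------

def _rectifying_rotations(pose: RelativePose):
    R, t = pose.rotation, pose.translation_dir
    b = -R.T @ t                    # baseline direction, cam0 frame
    r1 = b / np.linalg.norm(b)
    z = np.array([0.0, 0.0, 1.0])
    r2 = np.cross(z, r1)
    nr2 = np.linalg.norm(r2)
    if nr2 < 1e-9:
        raise PoseFailureError("baseline parallel to the optical axis")
    r2 /= nr2
    r3 = np.cross(r1, r2)
    Rrect0 = np.stack([r1, r2, r3])      # cam0 -> rect
    Rrect1 = Rrect0 @ R.T                # cam1 -> rect
    return Rrect0, Rrect1


def _warp_homography(image: np.ndarray, Hmap: np.ndarray) -> np.ndarray:
    """Warp so that out(p_new) = in(Hmap^-1 p_new); Hmap in (u,v) coords.

    skimage's ``warp`` already interprets a plain matrix in (x, y) =
    (col, row) coordinates, matching our (u, v) homographies.
    """
    Hinv = np.linalg.inv(Hmap)
    return warp(image, Hinv, order=1, mode="constant", cval=np.nan,
                preserve_range=True)


def reconstruct_depth(view0: np.ndarray, view1: np.ndarray, pose: RelativePose,
                      config: StereoConfig | None = None,
                      corr: Correspondences | None = None) -> DepthCloud:
    """Dense scale-free reconstruction in the view0 camera frame.

    Rectifies both views, block-matches along the epipolar (scan) lines
    with a left-right consistency check and sub-pixel parabola
    refinement, and triangulates each consistent pixel.  The disparity
    search range is derived from the sparse matches.  Model units: the
    camera baseline has length 1.
    """
    config = config or StereoConfig()
    K = pose.intrinsics
    Rrect0, Rrect1 = _rectifying_rotations(pose)
    H0 = K @ Rrect0 @ np.linalg.inv(K)
    H1 = K @ Rrect1 @ np.linalg.inv(K)
    g0 = _gray(view0)
    g1 = _gray(view1)
    r0 = _warp_homography(g0, H0)
    r1 = _warp_homography(g1, H1)

    if corr is None:
        corr = match_keypoints(view0, view1, config)
    uvr0 = _apply_h(H0, rc_to_uv(corr.view0_px))
    uvr1 = _apply_h(H1, rc_to_uv(corr.view1_px))
    row_ok = np.abs(uvr0[:, 1] - uvr1[:, 1]) < 2.0
    disp = uvr0[:, 0] - uvr1[:, 0]
    disp = disp[row_ok]
    if len(disp) < 8:
        raise ReconstructionError("rectification left too few row-aligned matches")
    lo = np.percentile(disp, 5) - config.disparity_pad_px
    hi = np.percentile(disp, 95) + config.disparity_pad_px
    dmin, dmax = int(np.floor(lo)), int(np.ceil(hi))

    disp_map = _block_match(r0, r1, dmin, dmax, config)

    # triangulate valid rectified pixels: Z = f * B / d with B = 1
    f = K[0, 0]
    cx, cy = K[0, 2], K[1, 2]
    rows, cols = disp_map.shape
    v, u = np.mgrid[0:rows, 0:cols]
    valid = np.isfinite(disp_map) & (disp_map > 0.5)
    d = disp_map[valid]
    Z = f / d
    X = (u[valid] - cx) * Z / f
    Y = (v[valid] - cy) * Z / f
    pts_rect = np.column_stack([X, Y, Z])
    pts_cam0 = pts_rect @ Rrect0          # = Rrect0.T applied to rows
    # original view0 pixel of each point
    uvw = pts_cam0 @ K.T
    uv = uvw[:, :2] / uvw[:, 2:3]
    rc = np.round(uv_to_rc(uv)).astype(int)
    ok = (rc[:, 0] >= 0) & (rc[:, 0] < g0.shape[0]) & \
         (rc[:, 1] >= 0) & (rc[:, 1] < g0.shape[1]) & (pts_cam0[:, 2] > 0)
    return DepthCloud(points=pts_cam0[ok], pixels_rc=rc[ok])


def _apply_h(H: np.ndarray, uv: np.ndarray) -> np.ndarray:
    ph = np.column_stack([uv, np.ones(len(uv))]) @ H.T
    return ph[:, :2] / ph[:, 2:3]


def _block_match(r0: np.ndarray, r1: np.ndarray, dmin: int, dmax: int,
                 config: StereoConfig) -> np.ndarray:
    """SSD block matching over [dmin, dmax] with LR check and subpixel fit."""
    w = 2 * config.block_radius + 1
    n_d = dmax - dmin + 1
    if n_d < 3:
        raise ReconstructionError("empty disparity range")
    rows, cols = r0.shape
    big = 1e6
    a0 = np.nan_to_num(r0, nan=big)
    costs = np.full((n_d, rows, cols), np.inf, dtype=np.float32)
    for i, d in enumerate(range(dmin, dmax + 1)):
        shifted = np.full_like(r1, big)
        if d >= 0:
            if d < cols:
                shifted[:, d:] = r1[:, :cols - d]
        else:
            shifted[:, :cols + d] = r1[:, -d:]
        shifted = np.nan_to_num(shifted, nan=big)
        diff = (a0 - shifted) ** 2
        np.clip(diff, 0, big, out=diff)
        costs[i] = ndi.uniform_filter(diff, size=w, mode="nearest")

    costs[~np.isfinite(costs)] = big
    best = np.argmin(costs, axis=0)
    cmin = np.take_along_axis(costs, best[None], axis=0)[0]
    # left-right consistency via the same cost volume
    bestR = np.full((rows, cols), -1, dtype=int)
    minR = np.full((rows, cols), np.inf, dtype=np.float32)
    u = np.arange(cols)
    for i, d in enumerate(range(dmin, dmax + 1)):
        src = u + d
        okc = (src >= 0) & (src < cols)
        c = np.full((rows, cols), np.inf, dtype=np.float32)
        c[:, okc] = costs[i][:, src[okc]]
        upd = c < minR
        minR[upd] = c[upd]
        bestR[upd] = i
    srcs = np.clip(u[None, :] - (best + dmin), 0, cols - 1)
    lr = np.abs(bestR[np.arange(rows)[:, None], srcs] - best) <= config.lr_tol_px

    # subpixel parabola around the minimum
    b = np.clip(best, 1, n_d - 2)
    c0 = np.take_along_axis(costs, (b - 1)[None], axis=0)[0]
    c1 = np.take_along_axis(costs, b[None], axis=0)[0]
    c2 = np.take_along_axis(costs, (b + 1)[None], axis=0)[0]
    denom = c0 - 2 * c1 + c2
    delta = np.where(np.abs(denom) > 1e-12, 0.5 * (c0 - c2) / np.maximum(denom, 1e-12), 0.0)
    delta = np.clip(delta, -1.0, 1.0)
    disp = best + dmin + np.where(best == b, delta, 0.0)

    good = lr & (cmin < 0.5 * big) & np.isfinite(r0)
    out = np.where(good, disp, np.nan)
    return out


# ---------------------------------------------------------------------------
# Metric scale from the reference card
# ---------------------------------------------------------------------------

def detect_card_corners(image: np.ndarray, plate: PlateEllipse | None = None
                        ) -> np.ndarray:
    """Locate the reference card's outer corners from its dark border.

    Thresholds the dark rectangular frame outside the plate, takes the
    largest connected component and returns the corners of its minimum
    rotated rectangle, ordered counter-clockwise from the corner closest
    to the image origin.  Raises when no border-like component exists.
    """
    from shapely.geometry import MultiPoint

    g = _gray(image)
    dark = g < 0.25
    if plate is not None:
        rows, cols = g.shape
        pts = np.column_stack([a.ravel() for a in np.mgrid[0:rows, 0:cols]])
        dark &= ~plate.contains(pts, margin_px=-5).reshape(rows, cols)
    lab, nlab = ndi.label(dark)
    if nlab == 0:
        raise NoReferenceError("no dark card border found")
    sizes = ndi.sum_labels(dark, lab, index=np.arange(1, nlab + 1))
    comp = int(np.argmax(sizes)) + 1
    if sizes[comp - 1] < 40:
        raise NoReferenceError("no dark card border found")
    ys, xs = np.nonzero(lab == comp)
    mp = MultiPoint(list(zip(xs.tolist(), ys.tolist())))
    rect = mp.minimum_rotated_rectangle
    try:
        coords = np.array(rect.exterior.coords[:-1], dtype=float)  # (4, 2) (x=col, y=row)
    except AttributeError:
        raise NoReferenceError("card border degenerate (not a quadrilateral)")
    if len(coords) != 4:
        raise NoReferenceError("card border degenerate (not a quadrilateral)")
    # Under projective tilt the card is a trapezoid, so the minimum
    # bounding rectangle's corners sit off the true ones.  Refine: assign
    # outer-contour points to the four sides, fit a line per side by
    # total least squares, and intersect adjacent lines.
    refined = _refine_quad(lab == comp, coords)
    if refined is not None:
        coords = refined
    corners = uv_to_rc(coords)
    # canonical order: start nearest the origin, counter-clockwise in (u, v)
    start = int(np.argmin(np.linalg.norm(corners, axis=1)))
    corners = np.roll(corners, -start, axis=0)
    c = corners.mean(axis=0)
    ang = np.arctan2(corners[:, 0] - c[0], corners[:, 1] - c[1])
    if np.diff(np.unwrap(ang)).sum() < 0:
        corners = corners[[0, 3, 2, 1]]
    return corners


def _refine_quad(component: np.ndarray, rect_uv: np.ndarray) -> np.ndarray | None:
    """Subpixel quad corners from line fits to the component's outer contour."""
    from skimage import measure

    contours = measure.find_contours(component.astype(float), 0.5)
    if not contours:
        return None
    outer = max(contours, key=len)          # (N, 2) (row, col)
    pts = outer[:, ::-1]                    # -> (x=col, y=row)
    sides = [(rect_uv[i], rect_uv[(i + 1) % 4]) for i in range(4)]
    lines = []
    for a, b in sides:
        ab = b - a
        L = np.linalg.norm(ab)
        if L < 4:
            return None
        ab = ab / L
        rel = pts - a
        t = rel @ ab
        dist = np.abs(rel[:, 0] * ab[1] - rel[:, 1] * ab[0])
        sel = (dist < 2.0) & (t > 0.15 * L) & (t < 0.85 * L)
        if sel.sum() < 6:
            return None
        p = pts[sel]
        mu = p.mean(axis=0)
        q = p - mu
        _, evecs = np.linalg.eigh(q.T @ q)
        nrm = evecs[:, 0]                   # line normal
        lines.append((nrm, float(nrm @ mu)))
    out = np.empty((4, 2))
    for i in range(4):
        (n1, c1), (n2, c2) = lines[i - 1], lines[i]
        A = np.stack([n1, n2])
        if abs(np.linalg.det(A)) < 1e-6:
            return None
        out[i] = np.linalg.solve(A, np.array([c1, c2]))
    return out


def scale_from_reference(pose: RelativePose, corners0_px: np.ndarray,
                         corners1_px: np.ndarray,
                         card_size_cm: tuple[float, float]) -> float:
    """Model-units-to-cm factor from the triangulated card corners.

    The card's four reconstructed side lengths are compared with the
    physical width/height; the factor is the mean ratio.  Corner lists
    must be in corresponding cyclic order in both views (consecutive
    corners joined by a physical side).
    """
    c0 = np.asarray(corners0_px, dtype=float)
    c1 = np.asarray(corners1_px, dtype=float)
    if c0.shape != (4, 2) or c1.shape != (4, 2):
        raise NoReferenceError("need 4 card corners per view")
    X = _triangulate_linear(pose.intrinsics, pose.rotation, pose.translation_dir,
                            rc_to_uv(c0), rc_to_uv(c1))
    if np.any(X[:, 2] <= 0):
        raise NoReferenceError("card corners triangulate behind the camera")
    sides_model = np.linalg.norm(X - np.roll(X, -1, axis=0), axis=1)
    w, h = card_size_cm
    # consecutive sides alternate between the two physical lengths; decide
    # the pairing by whichever assignment is more self-consistent
    pair_a = np.array([w, h, w, h])
    pair_b = np.array([h, w, h, w])
    ratios_a = pair_a / sides_model
    ratios_b = pair_b / sides_model
    ratios = ratios_a if np.std(ratios_a) <= np.std(ratios_b) else ratios_b
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# Plate plane and volume integration
# ---------------------------------------------------------------------------

def fit_plate_plane(cloud: DepthCloud, plate: PlateEllipse,
                    mask: SegmentationMask | None = None,
                    config: StereoConfig | None = None) -> PlatePlane:
    """Robust (consensus + least-squares) plane through bare-plate points.

    Uses cloud points whose view0 pixel lies inside the plate ellipse but
    in no food region.  The returned normal points toward the camera, so
    food heights come out positive.
    """
    config = config or StereoConfig()
    rc = cloud.pixels_rc
    sel = plate.contains(rc, margin_px=6.0)
    if mask is not None:
        sel &= mask.label_map[rc[:, 0], rc[:, 1]] == 0
    pts = cloud.points[sel]
    if len(pts) < config.min_plate_points:
        raise InsufficientPlatePointsError(
            f"{len(pts)} plate points < {config.min_plate_points}")
    tol = config.plane_inlier_frac_depth * float(np.median(pts[:, 2]))
    rng = np.random.default_rng(config.rng_seed)
    best = None
    for _ in range(config.plane_ransac_iters):
        tri = pts[rng.choice(len(pts), 3, replace=False)]
        nvec = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        nn = np.linalg.norm(nvec)
        if nn < 1e-12:
            continue
        nvec = nvec / nn
        d = nvec @ tri[0]
        err = np.abs(pts @ nvec - d)
        ninl = int(np.sum(err < tol))
        if best is None or ninl > best[0]:
            best = (ninl, nvec, d)
    if best is None or best[0] < config.min_plate_points // 2:
        raise InsufficientPlatePointsError("no plane consensus on plate points")
    _, nvec, d = best
    inl = np.abs(pts @ nvec - d) < tol
    centroid = pts[inl].mean(axis=0)
    q = pts[inl] - centroid
    _, evecs = np.linalg.eigh(q.T @ q)
    nvec = evecs[:, 0]
    d = float(nvec @ centroid)
    if d > 0:   # orient the normal toward the camera (origin side)
        nvec, d = -nvec, -d
    return PlatePlane(normal=nvec, d=d)


def compute_volumes(cloud: DepthCloud, scale_factor: float, plane: PlatePlane,
                    mask: SegmentationMask, plate: PlateEllipse,
                    config: StereoConfig | None = None,
                    intrinsics: np.ndarray | None = None) -> VolumeEstimate:
    """Integrate per-region food volume above the plate plane.

    Each region's reconstructed points are projected onto the plane and
    binned into a regular grid (``grid_cell_cm`` spacing); cell height is
    the mean point height.  When the camera intrinsics are given, the
    region footprint is obtained by intersecting the rays of *all* region
    pixels with the plate plane, so the integration area does not depend
    on which pixels survived the left-right consistency check; footprint
    cells without a reliable height take the nearest reliable one
    (silhouette walls treated as vertical).  Volume is
    sum(cell_area x height), reported in ml.
    """
    config = config or StereoConfig()
    nvec = plane.normal
    # in-plane basis
    a = np.array([1.0, 0.0, 0.0])
    if abs(nvec @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(nvec, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nvec, e1)
    origin = nvec * plane.d

    rc = cloud.pixels_rc
    labels = mask.label_map[rc[:, 0], rc[:, 1]]
    heights = plane.height_of(cloud.points) * scale_factor
    if np.any(labels > 0) and np.median(heights[labels > 0]) < 0:
        heights = -heights  # inverted plane orientation; flip once
    rel = cloud.points - origin
    uu = (rel @ e1) * scale_factor
    vv = (rel @ e2) * scale_factor

    # plane coords of every region pixel's ray/plane intersection (footprint)
    fuu = fvv = flab = None
    if intrinsics is not None:
        K = np.asarray(intrinsics, dtype=float)
        rr, cc = np.nonzero(mask.label_map > 0)
        if len(rr):
            # cast through pixel centers and corners so every grid cell a
            # pixel's square covers gets marked (cells are finer than pixels)
            offs = np.array([[0.0, 0.0], [-0.25, -0.25], [-0.25, 0.25],
                             [0.25, -0.25], [0.25, 0.25]])
            lab_px = mask.label_map[rr, cc]
            rr_s = (rr[None, :] + offs[:, 0:1]).ravel()
            cc_s = (cc[None, :] + offs[:, 1:2]).ravel()
            lab_s = np.tile(lab_px, len(offs))
            uv1 = np.column_stack([cc_s, rr_s, np.ones(len(rr_s))])
            dirs = uv1 @ np.linalg.inv(K).T
            denom = dirs @ nvec
            with np.errstate(divide="ignore", invalid="ignore"):
                tt = plane.d / denom
            pts_pl = dirs * tt[:, None]
            good = (tt > 0) & np.isfinite(tt)
            rel_f = pts_pl[good] - origin
            fuu = (rel_f @ e1) * scale_factor
            fvv = (rel_f @ e2) * scale_factor
            flab = lab_s[good]
            # samples per fully-covered cell, for fractional cell coverage
            px_cm = float(np.median(tt[good])) / K[0, 0] * scale_factor

    # the integration grid must stay coarser than a pixel's footprint on
    # the plane, or cell statistics become too sparse for the morphology
    cell = config.grid_cell_cm
    if flab is not None:
        cell = max(cell, 1.25 * px_cm)
    erode_cells = config.footprint_erode_cells
    if erode_cells is None:
        # matching-window blur extends ~(block_radius + 1) px into a region;
        # convert to grid cells so the correction tracks the physical scale
        px_cm_e = px_cm if flab is not None else cell
        erode_cells = max(1, int(round((config.block_radius + 1) * px_cm_e / cell)))
    vols: dict[int, float] = {}
    for region in range(1, mask.n_regions + 1):
        m = labels == region
        if not np.any(m):
            vols[region] = 0.0
            continue
        hu = heights[m]   # signed; negatives average out per cell
        gu, gv = uu[m], vv[m]
        if flab is not None and np.any(flab == region):
            au = np.concatenate([gu, fuu[flab == region]])
            av = np.concatenate([gv, fvv[flab == region]])
        else:
            au, av = gu, gv
        # pad the grid so morphology never touches the array border
        u0, v0 = au.min() - 2 * cell, av.min() - 2 * cell
        iu = np.floor((gu - u0) / cell).astype(int)
        iv = np.floor((gv - v0) / cell).astype(int)
        shape = (int(np.floor((au.max() - u0) / cell)) + 3,
                 int(np.floor((av.max() - v0) / cell)) + 3)
        ssum = np.zeros(shape)
        cnt = np.zeros(shape)
        np.add.at(ssum, (iu, iv), hu)
        np.add.at(cnt, (iu, iv), 1)
        have = cnt > 0
        coverage = None
        if flab is not None and np.any(flab == region):
            fu = np.floor((fuu[flab == region] - u0) / cell).astype(int)
            fv = np.floor((fvv[flab == region] - v0) / cell).astype(int)
            fcnt = np.zeros(shape)
            np.add.at(fcnt, (fu, fv), 1.0)
            full_cell = 5.0 * (cell / px_cm) ** 2   # 5 ray samples per pixel
            coverage = np.clip(fcnt / full_cell, 0.0, 1.0)
            footprint = fcnt > 0
        else:
            footprint = ndi.binary_closing(have, structure=np.ones((3, 3)), iterations=2)
        hmean = np.zeros(shape)
        hmean[have] = ssum[have] / cnt[have]
        # Matching-window blur drags heights toward the plate near the
        # silhouette; integrate from interior cells and extend them to the
        # footprint rim (silhouette sides treated as vertical walls).
        interior = ndi.binary_erosion(have, iterations=erode_cells)
        source = interior if interior.sum() >= 4 else have
        fill = footprint & ~source
        if np.any(fill):
            idx = ndi.distance_transform_edt(~source, return_distances=False,
                                             return_indices=True)
            hmean[fill] = hmean[idx[0][fill], idx[1][fill]]
        weights = coverage if coverage is not None else footprint.astype(float)
        vol = float(np.sum(np.clip(hmean, 0.0, None) * weights) * cell * cell)
        if vol < 0:
            raise ReconstructionError(f"negative volume for region {region}")
        vols[region] = vol
    return VolumeEstimate(region_volumes_ml=vols)
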
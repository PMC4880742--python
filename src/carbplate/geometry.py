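"""Pinhole-camera geometry shared by the renderer and the stereo stage.

Conventions
-----------
* World frame: the table plane is ``z = 0``, the plate center is the
  origin, and ``z`` points up.  All world lengths are centimetres.
* Camera tilt is measured from the vertical axis through the plate
  center; the camera sits in the world y-z plane at the configured
  distance and looks at the origin.
* Public pixel coordinates are 0-based ``(row, col)`` with subpixel
  positions as floats.  Internally, projective algebra uses homogeneous
  ``(u, v) = (col, row)`` vectors; :func:`rc_to_uv` / :func:`uv_to_rc`
  convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class CameraSpec:
    """An ideal pinhole camera observing the plate.

    Parameters
    ----------
    focal_length_px : float
        Focal length in pixels (square pixels, single focal).
    principal_point : tuple of float
        ``(row, col)`` of the optical axis intersection.
    image_size : tuple of int
        ``(rows, cols)``; at least ``(64, 64)``.
    tilt_deg : float
        Angle from the vertical axis through the plate center, in
        ``[0, 90)``.  The capture protocol prescribes one view at
        0 deg and one at 15 deg (each with a +/-3 deg tolerance).
    distance_cm : float
        Camera-center-to-plate-center distance.
    """

    focal_length_px: float
    principal_point: tuple[float, float]
    image_size: tuple[int, int]
    tilt_deg: float
    distance_cm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.tilt_deg < 90.0):
            raise ValueError(f"tilt_deg must be in [0, 90), got {self.tilt_deg}")
        if self.focal_length_px <= 0:
            raise ValueError("focal_length_px must be positive")
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        rows, cols = self.image_size
        if rows < 64 or cols < 64:
            raise ValueError(f"image_size must be at least (64, 64), got {self.image_size}")

    @property
    def K(self) -> np.ndarray:
        """3x3 intrinsic matrix mapping camera coords to (u, v, 1)."""
        cr, cc = self.principal_point
        f = self.focal_length_px
        return np.array([[f, 0.0, cc], [0.0, f, cr], [0.0, 0.0, 1.0]])


def default_camera(tilt_deg: float, *, image_size: tuple[int, int] = (320, 320),
                   focal_length_px: float = 280.0, distance_cm: float = 45.0) -> CameraSpec:
    """A camera framing a ~12 cm-radius plate plus reference card."""
    rows, cols = image_size
    return CameraSpec(
        focal_length_px=focal_length_px,
        principal_point=((rows - 1) / 2.0, (cols - 1) / 2.0),
        image_size=image_size,
        tilt_deg=tilt_deg,
        distance_cm=distance_cm,
    )


def rc_to_uv(points_rc: np.ndarray) -> np.ndarray:
    """(row, col) -> (u, v) = (col, row)."""
    pts = np.asarray(points_rc, dtype=float)
    return pts[..., ::-1]


def uv_to_rc(points_uv: np.ndarray) -> np.ndarray:
    """(u, v) -> (row, col)."""
    pts = np.asarray(points_uv, dtype=float)
    return pts[..., ::-1]


def camera_pose(camera: CameraSpec) -> tuple[np.ndarray, np.ndarray]:
    """World-to-camera rotation and camera center for a tilted view.

    Returns
    -------
    R_wc : (3, 3) ndarray
        Rows are the camera x/y/z axes in world coordinates, so that
        ``p_cam = R_wc @ (p_world - C)``.
    C : (3,) ndarray
        Camera center in world coordinates.
    """
    t = np.deg2rad(camera.tilt_deg)
    d = camera.distance_cm
    C = np.array([0.0, -d * np.sin(t), d * np.cos(t)])
    z_cam = np.array([0.0, np.sin(t), -np.cos(t)])  # toward the origin
    x_cam = np.array([1.0, 0.0, 0.0])
    y_cam = np.cross(z_cam, x_cam)
    R_wc = np.stack([x_cam, y_cam, z_cam])
    return R_wc, C


def project_points(points_world: np.ndarray, camera: CameraSpec) -> np.ndarray:
    """Project world points through the pinhole model to (row, col) pixels."""
    R_wc, C = camera_pose(camera)
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    p_cam = (pts - C) @ R_wc.T
    z = p_cam[:, 2]
    if np.any(z <= 0):
        raise ValueError("point behind the camera")
    uvw = p_cam @ camera.K.T
    uv = uvw[:, :2] / uvw[:, 2:3]
    return uv_to_rc(uv)


def pixel_rays(camera: CameraSpec) -> tuple[np.ndarray, np.ndarray]:
    """World-frame ray directions for every pixel center.

    Returns the camera center ``C`` and an ``(rows, cols, 3)`` array of
    (non-normalized) ray directions, suitable for analytic ray casting.
    """
    rows, cols = camera.image_size
    cr, cc = camera.principal_point
    f = camera.focal_length_px
    v, u = np.mgrid[0:rows, 0:cols]
    d_cam = np.stack([(u - cc) / f, (v - cr) / f, np.ones_like(u, dtype=float)], axis=-1)
    R_wc, C = camera_pose(camera)
    d_world = d_cam @ R_wc  # = R_wc.T applied to each direction
    return C, d_world


def table_plane_homography(camera: CameraSpec) -> np.ndarray:
    """Homography mapping table-plane coords (x, y, 1) to image (u, v, 1)."""
    R_wc, C = camera_pose(camera)
    t = -R_wc @ C
    H = camera.K @ np.column_stack([R_wc[:, 0], R_wc[:, 1], t])
    return H


def circle_conic_in_image(radius_cm: float, camera: CameraSpec,
                          center_xy: tuple[float, float] = (0.0, 0.0)) -> np.ndarray:
    """Image conic (3x3, (u,v) space) of a circle on the table plane."""
    x0, y0 = center_xy
    r = radius_cm
    # Plane conic of (x-x0)^2 + (y-y0)^2 = r^2 in homogeneous plane coords.
    Cpl = np.array([
        [1.0, 0.0, -x0],
        [0.0, 1.0, -y0],
        [-x0, -y0, x0 ** 2 + y0 ** 2 - r ** 2],
    ])
    H = table_plane_homography(camera)
    Hinv = np.linalg.inv(H)
    Q = Hinv.T @ Cpl @ Hinv
    return Q / np.linalg.norm(Q)


def conic_to_ellipse_params(Q: np.ndarray) -> tuple[np.ndarray, tuple[float, float], float]:
    """Center, semi-axes and orientation of an ellipse given as a conic.

    Parameters
    ----------
    Q : (3, 3) symmetric matrix with ``p^T Q p = 0`` on the ellipse,
        in (u, v, 1) coordinates.

    Returns
    -------
    center_rc : (2,) ndarray — ellipse center as (row, col).
    semi_axes : (a, b) with ``a >= b > 0``.
    rotation_deg : major-axis angle in degrees, in ``[0, 180)``,
        measured from the +col axis toward +row.
    """
    Q = np.asarray(Q, dtype=float)
    A33 = Q[:2, :2]
    b = Q[:2, 2]
    det = np.linalg.det(A33)
    if det <= 0:
        raise ValueError("conic is not an ellipse")
    center_uv = -np.linalg.solve(A33, b)
    # Value of the quadratic form at the center.
    c0 = center_uv @ A33 @ center_uv + 2 * b @ center_uv + Q[2, 2]
    M = A33 / (-c0)
    evals, evecs = np.linalg.eigh(M)
    if np.any(evals <= 0):
        raise ValueError("conic is not an ellipse")
    axes = 1.0 / np.sqrt(evals)  # descending axes for ascending evals
    order = np.argsort(-axes)
    axes = axes[order]
    major_uv = evecs[:, order[0]]
    ang = np.rad2deg(np.arctan2(major_uv[1], major_uv[0])) % 180.0
    return uv_to_rc(center_uv), (float(axes[0]), float(axes[1])), float(ang)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, in degrees."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.rad2deg(np.arccos(np.clip(c, -1.0, 1.0))))
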
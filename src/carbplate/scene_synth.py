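"""Synthetic two-view meal scenes with exact ground truth.

The renderer emulates the capture protocol of a plate-based meal
assessment system: one near-vertical view (0 deg) and one tilted view
(15 deg) of a round plate holding 1-3 non-occluding food items, with a
planar reference card of known physical size beside the plate.

Scenes are rendered by analytic ray casting of geometric food
primitives (spherical caps, boxes, cylinders) through an ideal pinhole
camera, so every pixel's 3D hit point, region label and depth are known
exactly.  Food appearance is a per-class base color modulated by a
procedural texture evaluated at the world-space hit point, which makes
the texture consistent between the two views (a requirement for stereo
matching) and makes classes separable by color plus texture but not by
color alone.

Rendering is pure: the scene seed drives only the additive pixel noise,
while all geometry, colors and texture phases are fixed by the scene
specification itself.

The module also generates synthetic study tables (per-meal true /
self-estimated / system-estimated carbohydrate grams) with configurable
error distributions, emulating a meal-estimation study in which each
participant assesses a set of meals served in three sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import InvalidSceneError, SchemaError
from .geometry import (
    CameraSpec,
    camera_pose,
    circle_conic_in_image,
    conic_to_ellipse_params,
    default_camera,
    pixel_rays,
    project_points,
)

FOOD_CLASSES = (
    "pasta",
    "potatoes",
    "meat",
    "breaded",
    "rice",
    "green_salad_vegetables",
    "mashed_potatoes",
    "carrots",
    "beans",
)

#: Per-class rendering style: base RGB color (0-1), texture family and
#: texture length scale in cm.  Classes deliberately share base colors in
#: pairs (pasta/potatoes, rice/mashed potatoes) so that texture features
#: carry real discriminative weight.
DEFAULT_CLASS_STYLES: dict[str, dict] = {
    "pasta": {"color": (0.93, 0.80, 0.35), "texture": "stripes", "scale": 0.5},
    "potatoes": {"color": (0.92, 0.79, 0.37), "texture": "blobs", "scale": 1.3},
    "meat": {"color": (0.45, 0.26, 0.18), "texture": "smooth", "scale": 1.4},
    "breaded": {"color": (0.72, 0.50, 0.22), "texture": "speckle", "scale": 0.35},
    "rice": {"color": (0.95, 0.94, 0.90), "texture": "speckle", "scale": 0.22},
    "green_salad_vegetables": {"color": (0.30, 0.55, 0.25), "texture": "blobs", "scale": 1.0},
    "mashed_potatoes": {"color": (0.94, 0.92, 0.86), "texture": "smooth", "scale": 1.5},
    "carrots": {"color": (0.90, 0.50, 0.15), "texture": "stripes", "scale": 0.8},
    "beans": {"color": (0.55, 0.20, 0.20), "texture": "blobs", "scale": 0.6},
}

#: Default shapes per class (kind, params in cm), jittered by the random
#: scene builder.  Sizes give volumes roughly in the 50-400 ml range of
#: realistic single-item servings.
DEFAULT_CLASS_SHAPES: dict[str, tuple[str, tuple[float, ...]]] = {
    "pasta": ("cylinder", (4.2, 2.4)),
    "potatoes": ("spherical_cap", (4.0, 3.0)),
    "meat": ("box", (6.0, 4.5, 1.8)),
    "breaded": ("box", (6.5, 5.0, 1.2)),
    "rice": ("spherical_cap", (4.2, 2.4)),
    "green_salad_vegetables": ("spherical_cap", (4.5, 2.0)),
    "mashed_potatoes": ("spherical_cap", (4.0, 2.6)),
    "carrots": ("cylinder", (3.6, 2.0)),
    "beans": ("spherical_cap", (3.8, 2.2)),
}

_FOOD_GROUPS = (
    ("pasta", "potatoes", "rice", "mashed_potatoes"),
    ("meat", "breaded", "beans"),
    ("green_salad_vegetables", "carrots"),
)

_TEXTURE_AMPLITUDE = {
    "stripes": 0.22,
    "blobs": 0.18,
    "speckle": 0.22,
    "smooth": 0.14,
    "checker": 0.25,
    "none": 0.0,
}

PLATE_COLOR = (0.55, 0.70, 0.90)
TABLE_COLOR = (0.46, 0.34, 0.22)
CARD_BORDER_CM = 0.7


# ---------------------------------------------------------------------------
# Scene specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodPrimitive:
    """One food item as a solid of revolution/extrusion on the plate.

    shape_kind / shape_params (cm):
      * ``spherical_cap``: (base_radius, height)
      * ``box``: (width_x, width_y, height), axis-aligned
      * ``cylinder``: (radius, height), vertical
    """

    shape_kind: str
    shape_params: tuple[float, ...]
    base_center: tuple[float, float]
    color: tuple[float, float, float]
    texture_kind: str
    class_label: str
    texture_scale: float = 1.0
    texture_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("spherical_cap", "box", "cylinder"):
            raise InvalidSceneError(f"unknown shape_kind {self.shape_kind!r}")
        if any(p <= 0 for p in self.shape_params):
            raise InvalidSceneError("shape_params must be positive")
        n_expect = {"spherical_cap": 2, "box": 3, "cylinder": 2}[self.shape_kind]
        if len(self.shape_params) != n_expect:
            raise InvalidSceneError(
                f"{self.shape_kind} expects {n_expect} params, got {len(self.shape_params)}")

    @property
    def volume_ml(self) -> float:
        """Closed-form volume in ml (1 ml = 1 cm^3)."""
        if self.shape_kind == "spherical_cap":
            a, h = self.shape_params
            return float(np.pi * h / 6.0 * (3 * a ** 2 + h ** 2))
        if self.shape_kind == "box":
            wx, wy, h = self.shape_params
            return float(wx * wy * h)
        r, h = self.shape_params
        return float(np.pi * r ** 2 * h)

    @property
    def height_cm(self) -> float:
        return float(self.shape_params[-1])

    @property
    def footprint_radius_cm(self) -> float:
        """Radius of the smallest vertical cylinder containing the solid."""
        if self.shape_kind == "spherical_cap":
            a, h = self.shape_params
            if h <= a:
                return float(a)
            return float((a ** 2 + h ** 2) / (2 * h))  # bulges past the base circle
        if self.shape_kind == "box":
            wx, wy, _ = self.shape_params
            return float(np.hypot(wx, wy) / 2.0)
        return float(self.shape_params[0])


@dataclass(frozen=True)
class CardPose:
    """Planar pose of the reference card on the table (cm, degrees)."""

    center_xy: tuple[float, float] = (16.5, 0.0)
    angle_deg: float = 20.0


@dataclass(frozen=True)
class SceneSpec:
    """Full description of one synthetic meal scene."""

    plate_radius_cm: float = 12.0
    plate_color: tuple[float, float, float] = PLATE_COLOR
    table_color: tuple[float, float, float] = TABLE_COLOR
    card_size_cm: tuple[float, float] = (8.5, 5.4)
    card_pose: CardPose = field(default_factory=CardPose)
    items: tuple[FoodPrimitive, ...] = ()
    noise_sigma: float = 2.0
    seed: int = 0
    texture_unit_cm: float = 1.0   # scales plate/table/card texture lengths

    def __post_init__(self) -> None:
        if not (0 <= len(self.items) <= 3):
            raise InvalidSceneError("a scene holds between 0 and 3 food items")
        if self.plate_radius_cm <= 0:
            raise InvalidSceneError("plate_radius_cm must be positive")
        if self.noise_sigma < 0:
            raise InvalidSceneError("noise_sigma must be nonnegative")
        margin = 0.4
        R = self.plate_radius_cm
        for i, it in enumerate(self.items):
            cx, cy = it.base_center
            if np.hypot(cx, cy) + it.footprint_radius_cm > R - margin:
                raise InvalidSceneError(
                    f"item {i} ({it.class_label}) extends outside the plate")
            for j in range(i):
                other = self.items[j]
                d = np.hypot(cx - other.base_center[0], cy - other.base_center[1])
                if d < it.footprint_radius_cm + other.footprint_radius_cm + margin:
                    raise InvalidSceneError(f"items {j} and {i} overlap")


@dataclass
class GroundTruth:
    """Pixel-registered ground truth for one rendered view."""

    label_map: np.ndarray                      # (rows, cols) int, 0 = background
    plate_ellipse_px: tuple                    # (center_rc, (a, b), rotation_deg)
    item_volumes_ml: np.ndarray                # (K,) closed-form volumes
    item_classes: tuple[str, ...]
    card_corners_px: np.ndarray                # (4, 2) (row, col)
    camera: CameraSpec
    hit_points: np.ndarray | None = None       # (rows, cols, 3) world cm
    depth_map: np.ndarray | None = None        # (rows, cols) camera-z cm


@dataclass
class MealScene:
    """A two-view capture of one meal with shared world ground truth."""

    images: list[np.ndarray]                   # uint8 RGB per view
    ground_truths: list[GroundTruth]
    cameras: list[CameraSpec]
    spec: SceneSpec

    @property
    def card_size_cm(self) -> tuple[float, float]:
        return self.spec.card_size_cm

    @property
    def item_volumes_ml(self) -> np.ndarray:
        return self.ground_truths[0].item_volumes_ml

    @property
    def item_classes(self) -> tuple[str, ...]:
        return self.ground_truths[0].item_classes


# ---------------------------------------------------------------------------
# Procedural textures
# ---------------------------------------------------------------------------

def _hash01(i: np.ndarray, j: np.ndarray, phase: float) -> np.ndarray:
    v = np.sin(i * 127.1 + j * 311.7 + phase * 74.7) * 43758.5453
    return v - np.floor(v)


def _value_noise(x: np.ndarray, y: np.ndarray, scale: float, phase: float) -> np.ndarray:
    """Smooth deterministic value noise in [0, 1] on a cm lattice."""
    xs, ys = x / scale, y / scale
    i0, j0 = np.floor(xs), np.floor(ys)
    fx, fy = xs - i0, ys - j0
    ux = fx * fx * (3.0 - 2.0 * fx)
    uy = fy * fy * (3.0 - 2.0 * fy)
    v00 = _hash01(i0, j0, phase)
    v10 = _hash01(i0 + 1, j0, phase)
    v01 = _hash01(i0, j0 + 1, phase)
    v11 = _hash01(i0 + 1, j0 + 1, phase)
    return (v00 * (1 - ux) + v10 * ux) * (1 - uy) + (v01 * (1 - ux) + v11 * ux) * uy


def texture_value(kind: str, x: np.ndarray, y: np.ndarray, scale: float,
                  phase: float) -> np.ndarray:
    """Texture intensity in [0, 1] as a function of world position."""
    if kind == "none":
        return np.full_like(np.asarray(x, dtype=float), 0.5)
    if kind == "stripes":
        ang = 0.9 * phase
        proj = x * np.cos(ang) + y * np.sin(ang)
        stripe = 0.5 + 0.5 * np.sin(2 * np.pi * proj / scale + phase)
        # real striped foods are irregular along the stripe direction; the
        # modulation also removes the translation ambiguity of pure stripes
        irr = _value_noise(x, y, scale * 1.6, phase + 2.13)
        return np.clip(stripe * (0.55 + 0.9 * irr), 0.0, 1.0)
    if kind == "checker":
        return ((np.floor(x / scale) + np.floor(y / scale)) % 2.0)
    if kind == "blobs":
        v = _value_noise(x, y, scale, phase)
        t = np.clip((v - 0.35) / 0.30, 0.0, 1.0)
        return t * t * (3.0 - 2.0 * t)
    if kind == "speckle":
        return _value_noise(x, y, scale, phase)
    if kind == "smooth":
        return _value_noise(x, y, scale, phase)
    raise InvalidSceneError(f"unknown texture kind {kind!r}")


def _modulate(base: tuple[float, float, float], tex: np.ndarray, amp: float) -> np.ndarray:
    rgb = np.asarray(base, dtype=float)[None, :]
    factor = 1.0 + amp * (tex[:, None] - 0.5) * 2.0
    return np.clip(rgb * factor, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Ray-primitive intersections (vectorized over all pixels)
# ---------------------------------------------------------------------------

_INF = np.inf


def _intersect_plane(C: np.ndarray, d: np.ndarray) -> np.ndarray:
    dz = d[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -C[2] / dz
    t = np.where((dz < 0) & (t > 0), t, _INF)
    return t


def _intersect_spherical_cap(C, d, item: FoodPrimitive) -> np.ndarray:
    a, h = item.shape_params
    rs = (a ** 2 + h ** 2) / (2 * h)
    s = np.array([item.base_center[0], item.base_center[1], h - rs])
    oc = C - s
    A = np.sum(d * d, axis=-1)
    B = 2.0 * np.sum(d * oc, axis=-1)
    Cq = oc @ oc - rs ** 2
    disc = B * B - 4 * A * Cq
    ok = disc > 0
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = (-B - sq) / (2 * A)
    z1 = C[2] + t1 * d[..., 2]
    valid = ok & (t1 > 0) & (z1 >= 0.0)
    return np.where(valid, t1, _INF)


def _intersect_box(C, d, item: FoodPrimitive) -> np.ndarray:
    wx, wy, h = item.shape_params
    bx, by = item.base_center
    lo = np.array([bx - wx / 2, by - wy / 2, 0.0])
    hi = np.array([bx + wx / 2, by + wy / 2, h])
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = 1.0 / d
    t_lo = (lo - C) * inv
    t_hi = (hi - C) * inv
    t_near = np.minimum(t_lo, t_hi)
    t_far = np.maximum(t_lo, t_hi)
    tmin = np.max(t_near, axis=-1)
    tmax = np.min(t_far, axis=-1)
    valid = (tmin <= tmax) & (tmin > 0)
    return np.where(valid, tmin, _INF)


def _intersect_cylinder(C, d, item: FoodPrimitive) -> np.ndarray:
    r, h = item.shape_params
    bx, by = item.base_center
    ox, oy = C[0] - bx, C[1] - by
    dx, dy = d[..., 0], d[..., 1]
    A = dx * dx + dy * dy
    B = 2 * (ox * dx + oy * dy)
    Cq = ox * ox + oy * oy - r * r
    disc = B * B - 4 * A * Cq
    ok = (disc > 0) & (A > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (-B - sq) / (2 * A)
    z1 = C[2] + t1 * d[..., 2]
    side = ok & (t1 > 0) & (z1 >= 0.0) & (z1 <= h)
    t_side = np.where(side, t1, _INF)
    # top cap
    dz = d[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_top = (h - C[2]) / dz
    x = C[0] + t_top * d[..., 0] - bx
    y = C[1] + t_top * d[..., 1] - by
    top = (t_top > 0) & (x * x + y * y <= r * r)
    t_top = np.where(top, t_top, _INF)
    return np.minimum(t_side, t_top)


def _surface_normal(item: FoodPrimitive, pts: np.ndarray) -> np.ndarray:
    """Outward normal at hit points on the item's surface."""
    if item.shape_kind == "spherical_cap":
        a, h = item.shape_params
        rs = (a ** 2 + h ** 2) / (2 * h)
        s = np.array([item.base_center[0], item.base_center[1], h - rs])
        n = pts - s
    elif item.shape_kind == "cylinder":
        r, h = item.shape_params
        n = pts - np.array([item.base_center[0], item.base_center[1], 0.0])
        n = np.where(pts[:, 2:3] > h - 1e-6,
                     np.array([0.0, 0.0, 1.0])[None, :],
                     np.column_stack([n[:, 0], n[:, 1], np.zeros(len(pts))]))
    else:  # box: pick the face whose slab boundary the point lies on
        wx, wy, h = item.shape_params
        bx, by = item.base_center
        rel = pts - np.array([bx, by, h / 2.0])
        scaled = np.abs(rel) / np.array([wx / 2, wy / 2, h / 2])
        face = np.argmax(scaled, axis=1)
        n = np.zeros_like(pts)
        n[np.arange(len(pts)), face] = np.sign(rel[np.arange(len(pts)), face])
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    return n / np.maximum(norm, 1e-12)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def card_corners_world(spec: SceneSpec) -> np.ndarray:
    """The 4 card corners on the table plane, in fixed order, (4, 3) cm."""
    w, h = spec.card_size_cm
    ang = np.deg2rad(spec.card_pose.angle_deg)
    cx, cy = spec.card_pose.center_xy
    local = np.array([[-w / 2, -h / 2], [w / 2, -h / 2], [w / 2, h / 2], [-w / 2, h / 2]])
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    xy = local @ R.T + np.array([cx, cy])
    return np.column_stack([xy, np.zeros(4)])


def _card_local_xy(spec: SceneSpec, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ang = np.deg2rad(spec.card_pose.angle_deg)
    cx, cy = spec.card_pose.center_xy
    dx, dy = x - cx, y - cy
    lx = dx * np.cos(ang) + dy * np.sin(ang)
    ly = -dx * np.sin(ang) + dy * np.cos(ang)
    return lx, ly


def render_view(scene: SceneSpec, camera: CameraSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one view of a scene and its pixel-registered ground truth.

    Returns a ``(rows, cols, 3)`` uint8 image and a :class:`GroundTruth`
    whose ``label_map`` assigns 0 to background (table, plate, card) and
    ``1..K`` to the food items.  Identical inputs produce bit-identical
    output; the scene seed only drives the additive pixel noise.
    """
    C, dirs = pixel_rays(camera)
    rows, cols = camera.image_size

    t_plane = _intersect_plane(C, dirs)
    ts = [t_plane]
    for item in scene.items:
        fn = {"spherical_cap": _intersect_spherical_cap,
              "box": _intersect_box,
              "cylinder": _intersect_cylinder}[item.shape_kind]
        ts.append(fn(C, dirs, item))
    t_all = np.stack(ts)                       # (1+K, rows, cols)
    winner = np.argmin(t_all, axis=0)
    t_hit = np.min(t_all, axis=0)
    hit = np.isfinite(t_hit)
    winner = np.where(hit, winner, -1)

    pts = C[None, None, :] + t_hit[..., None] * dirs
    pts = np.where(hit[..., None], pts, 0.0)

    img = np.zeros((rows, cols, 3), dtype=float)
    label_map = np.zeros((rows, cols), dtype=np.int32)
    light = np.array([0.25, -0.2, 0.95])
    light = light / np.linalg.norm(light)

    # --- background plane: table / plate / card ---
    plane_mask = winner == 0
    px, py = pts[..., 0][plane_mask], pts[..., 1][plane_mask]
    rgb = np.empty((plane_mask.sum(), 3))
    rad2 = px ** 2 + py ** 2
    on_plate = rad2 <= scene.plate_radius_cm ** 2
    lx, ly = _card_local_xy(scene, px, py)
    w, hcard = scene.card_size_cm
    on_card = (~on_plate) & (np.abs(lx) <= w / 2) & (np.abs(ly) <= hcard / 2)
    on_border = on_card & ((np.abs(lx) > w / 2 - CARD_BORDER_CM)
                           | (np.abs(ly) > hcard / 2 - CARD_BORDER_CM))
    on_table = ~(on_plate | on_card)

    tu = scene.texture_unit_cm
    tex_tab = texture_value("stripes", px, py, 2.4 * tu, 0.3) * 0.5 \
        + texture_value("speckle", px, py, 0.8 * tu, 1.7) * 0.5
    rgb[:] = _modulate(scene.table_color, tex_tab, 0.25)
    tex_plate = texture_value("speckle", px, py, 0.45 * tu, 2.9)
    rgb[on_plate] = _modulate(scene.plate_color, tex_plate[on_plate], 0.10)
    tex_card = texture_value("speckle", px, py, 0.5 * tu, 4.1)
    rgb[on_card] = _modulate((0.96, 0.96, 0.93), tex_card[on_card], 0.06)
    rgb[on_border] = _modulate((0.08, 0.08, 0.10), tex_card[on_border], 0.05)
    del on_table
    img[plane_mask] = rgb

    # --- food items ---
    for k, item in enumerate(scene.items, start=1):
        m = winner == k
        if not np.any(m):
            continue
        p_item = pts[m]
        tex = texture_value(item.texture_kind, p_item[:, 0], p_item[:, 1],
                            item.texture_scale, item.texture_phase)
        col = _modulate(item.color, tex, _TEXTURE_AMPLITUDE[item.texture_kind])
        n = _surface_normal(item, p_item)
        shade = 0.87 + 0.13 * np.clip(n @ light, 0.0, 1.0)
        img[m] = col * shade[:, None]
        label_map[m] = k

    img8 = np.clip(img * 255.0, 0, 255)
    if scene.noise_sigma > 0:
        rng = np.random.default_rng([int(scene.seed) & 0x7FFFFFFF,
                                     int(round(camera.tilt_deg * 1000)) & 0x7FFFFFFF])
        img8 = img8 + rng.normal(0.0, scene.noise_sigma, img8.shape)
    img8 = np.clip(np.round(img8), 0, 255).astype(np.uint8)

    ellipse = conic_to_ellipse_params(circle_conic_in_image(scene.plate_radius_cm, camera))
    corners_px = project_points(card_corners_world(scene), camera)

    R_wc, Cc = camera_pose(camera)
    depth = np.where(hit, t_hit * (dirs @ R_wc[2]), np.nan)

    gt = GroundTruth(
        label_map=label_map,
        plate_ellipse_px=ellipse,
        item_volumes_ml=np.array([it.volume_ml for it in scene.items]),
        item_classes=tuple(it.class_label for it in scene.items),
        card_corners_px=corners_px,
        camera=camera,
        hit_points=pts,
        depth_map=depth,
    )
    return img8, gt


def make_stereo_scene(scene: SceneSpec, *,
                      cameras: tuple[CameraSpec, CameraSpec] | None = None) -> MealScene:
    """Render the two protocol views (0 deg and 15 deg tilt) of a scene."""
    if cameras is None:
        cameras = (default_camera(0.0), default_camera(15.0))
    views = [render_view(scene, cam) for cam in cameras]
    return MealScene(
        images=[v[0] for v in views],
        ground_truths=[v[1] for v in views],
        cameras=list(cameras),
        spec=scene,
    )


# ---------------------------------------------------------------------------
# Randomized scene construction
# ---------------------------------------------------------------------------

def _jitter_color(rng: np.random.Generator, color, amount=0.05):
    c = np.asarray(color) + rng.uniform(-amount, amount, 3)
    return tuple(np.clip(c, 0.02, 0.98))


def _make_item(rng: np.random.Generator, class_label: str,
               base_center: tuple[float, float], size_jitter: float = 0.2) -> FoodPrimitive:
    style = DEFAULT_CLASS_STYLES[class_label]
    kind, params = DEFAULT_CLASS_SHAPES[class_label]
    params = tuple(p * rng.uniform(1 - size_jitter, 1 + size_jitter) for p in params)
    return FoodPrimitive(
        shape_kind=kind,
        shape_params=params,
        base_center=base_center,
        color=_jitter_color(rng, style["color"]),
        texture_kind=style["texture"],
        class_label=class_label,
        texture_scale=style["scale"] * rng.uniform(0.85, 1.18),
        texture_phase=rng.uniform(0.0, 2 * np.pi),
    )


def _place_items(rng: np.random.Generator, items_proto: list, plate_radius: float):
    """Rejection-sample non-overlapping base centers inside the plate."""
    margin = 0.5
    for _ in range(300):
        placed = []
        ok = True
        for radius in items_proto:
            for _ in range(80):
                rmax = plate_radius - margin - radius
                if rmax <= 0:
                    ok = False
                    break
                rr = np.sqrt(rng.uniform(0, 1)) * rmax
                th = rng.uniform(0, 2 * np.pi)
                c = (rr * np.cos(th), rr * np.sin(th))
                if all(np.hypot(c[0] - p[0][0], c[1] - p[0][1]) > radius + p[1] + margin
                       for p in placed):
                    placed.append((c, radius))
                    break
            else:
                ok = False
            if not ok:
                break
        if ok:
            return [p[0] for p in placed]
    raise InvalidSceneError("could not place items without overlap")


def random_scene_spec(rng: np.random.Generator, *, n_items: int | None = None,
                      classes: tuple[str, ...] | None = None,
                      noise_sigma: float = 2.0,
                      plate_radius_cm: float = 12.0) -> SceneSpec:
    """Build a valid randomized scene.

    When ``classes`` is not given, item classes follow the typical plated
    meal composition (one carbohydrate source, one protein source, one
    vegetable), which also guarantees distinct base colors within a scene.
    """
    if classes is None:
        if n_items is None:
            n_items = int(rng.integers(1, 4))
        groups = list(_FOOD_GROUPS)
        rng.shuffle(groups)
        classes = tuple(str(rng.choice(g)) for g in groups[:n_items])
    # dummy pass to size footprints before placing
    proto = []
    specs = []
    for cl in classes:
        item = _make_item(rng, cl, (0.0, 0.0))
        specs.append(item)
        proto.append(item.footprint_radius_cm)
    centers = _place_items(rng, proto, plate_radius_cm)
    items = tuple(replace(it, base_center=c) for it, c in zip(specs, centers))
    card_angle = rng.uniform(0, 60)
    return SceneSpec(
        plate_radius_cm=plate_radius_cm,
        items=items,
        noise_sigma=noise_sigma,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
        card_pose=CardPose(center_xy=(16.5, float(rng.uniform(-1.5, 1.5))),
                           angle_deg=float(card_angle)),
    )


def single_item_scene(rng: np.random.Generator, class_label: str,
                      noise_sigma: float = 2.0) -> SceneSpec:
    """A one-item scene for classifier training/evaluation renders."""
    return random_scene_spec(rng, classes=(class_label,), noise_sigma=noise_sigma)


# ---------------------------------------------------------------------------
# Serialization: PNG views + PNG label maps + JSON sidecar
# ---------------------------------------------------------------------------

def save_scene(scene: MealScene, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta: dict = {
        "card_size_cm": list(scene.card_size_cm),
        "item_classes": list(scene.item_classes),
        "item_volumes_ml": [float(v) for v in scene.item_volumes_ml],
        "views": [],
    }
    for i, (img, gt, cam) in enumerate(zip(scene.images, scene.ground_truths,
                                           scene.cameras)):
        iio.imwrite(d / f"view{i}.png", img)
        iio.imwrite(d / f"label{i}.png", gt.label_map.astype(np.uint8))
        center, axes, rot = gt.plate_ellipse_px
        meta["views"].append({
            "camera": {
                "focal_length_px": cam.focal_length_px,
                "principal_point": list(cam.principal_point),
                "image_size": list(cam.image_size),
                "tilt_deg": cam.tilt_deg,
                "distance_cm": cam.distance_cm,
            },
            "card_corners_px": np.asarray(gt.card_corners_px).tolist(),
            "plate_ellipse_px": {"center_rc": np.asarray(center).tolist(),
                                 "semi_axes": list(axes), "rotation_deg": rot},
        })
    (d / "scene.json").write_text(json.dumps(meta, indent=1))
    return d


def load_scene(directory: str | Path) -> MealScene:
    d = Path(directory)
    meta = json.loads((d / "scene.json").read_text())
    images, gts, cams = [], [], []
    for i, v in enumerate(meta["views"]):
        img = iio.imread(d / f"view{i}.png")
        label = iio.imread(d / f"label{i}.png").astype(np.int32)
        cam = CameraSpec(
            focal_length_px=v["camera"]["focal_length_px"],
            principal_point=tuple(v["camera"]["principal_point"]),
            image_size=tuple(v["camera"]["image_size"]),
            tilt_deg=v["camera"]["tilt_deg"],
            distance_cm=v["camera"]["distance_cm"],
        )
        e = v["plate_ellipse_px"]
        gts.append(GroundTruth(
            label_map=label,
            plate_ellipse_px=(np.array(e["center_rc"]), tuple(e["semi_axes"]),
                              e["rotation_deg"]),
            item_volumes_ml=np.array(meta["item_volumes_ml"]),
            item_classes=tuple(meta["item_classes"]),
            card_corners_px=np.array(v["card_corners_px"]),
            camera=cam,
        ))
        images.append(img)
        cams.append(cam)
    spec = SceneSpec(card_size_cm=tuple(meta["card_size_cm"]),
                     items=(), noise_sigma=0.0, seed=0)
    return MealScene(images=images, ground_truths=gts, cameras=cams, spec=spec)


# ---------------------------------------------------------------------------
# Synthetic study tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyTableParams:
    """Configuration of a synthetic meal-estimation study table.

    Emulates a study design in which participants each estimate a block
    of meals served in three sizes, once on their own (``self``) and
    once with the system (``system``).  Errors are additive Gaussian on
    the true grams; a configurable fraction of participants are extreme
    over-estimators (constant extra bias on every one of their meals).
    """

    n_meals: int = 114
    true_carb_range_g: tuple[float, float] = (20.0, 80.0)
    self_error_sd_g: float = 35.0
    system_error_sd_g: float = 12.0
    self_bias_g: float = -5.0
    outlier_fraction: float = 0.0
    outlier_bias_g: float = 150.0
    size_categories: tuple[tuple[str, float], ...] = (
        ("small", 0.7), ("medium", 1.0), ("large", 1.4))
    meals_per_participant: int = 6
    seed: int = 0


def make_study_table(params: StudyTableParams) -> pd.DataFrame:
    """Generate a per-meal estimate table.

    Returns a DataFrame with columns ``meal_id, participant_id, size,
    true_g, self_g, system_g``; estimates are clamped at 0 g.
    """
    if params.n_meals <= 0:
        raise SchemaError("n_meals must be positive")
    rng = np.random.default_rng(params.seed)
    n = params.n_meals
    sizes = [params.size_categories[i % len(params.size_categories)] for i in range(n)]
    lo, hi = params.true_carb_range_g
    base = rng.uniform(lo, hi, n)
    true_g = base * np.array([m for _, m in sizes])
    participant = np.arange(n) // max(params.meals_per_participant, 1)
    n_participants = int(participant.max()) + 1
    n_outliers = int(round(params.outlier_fraction * n_participants))
    outlier_ids = rng.choice(n_participants, size=n_outliers, replace=False) \
        if n_outliers else np.array([], dtype=int)
    self_err = rng.normal(params.self_bias_g, params.self_error_sd_g, n)
    self_err = self_err + np.where(np.isin(participant, outlier_ids),
                                   params.outlier_bias_g, 0.0)
    sys_err = rng.normal(0.0, params.system_error_sd_g, n)
    return pd.DataFrame({
        "meal_id": np.arange(n),
        "participant_id": participant,
        "size": [s for s, _ in sizes],
        "true_g": true_g,
        "self_g": np.maximum(true_g + self_err, 0.0),
        "system_g": np.maximum(true_g + sys_err, 0.0),
    })
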
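"""Food-item segmentation inside the plate ellipse.

The scheme follows a grow-then-merge design: homogeneous color regions
are grown from seed points (a regular grid for the automatic mode, or
user-supplied points for the interactive mode) by best-first accretion
of 4-connected pixels, then adjacent regions are merged on the basis of
their color distance and mutual border length.  Finally, regions whose
mean color matches the plate are excluded, leaving the food items.

Color distances are Euclidean in CIELAB, computed on a lightly smoothed
image so that pixel noise and fine texture do not fragment the regions.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.color import rgb2lab

from .errors import InvalidSeedError
from .plate_detect import PlateEllipse


@dataclass
class SegmentationConfig:
    color_space: str = "lab"            # only CIELAB is implemented
    smooth_sigma: float = 1.2
    grow_tol: float = 16.0              # max Delta-E of a pixel to its region mean
    beta_border: float = 1.0            # border-fraction boost in the merge cost
    border_frac_cap: float = 0.5
    merge_cost_max: float = 12.0        # merge adjacent pairs below this cost
    min_region_area_frac: float = 0.025  # of the plate-ellipse area
    max_regions: int = 6
    grid_spacing_frac: float = 1.0 / 12.0  # of the plate major axis
    bg_tol: float = 8.0                 # Delta-E to plate color for background
    rim_margin_px: float = 3.0


@dataclass
class SegmentationMask:
    """Integer label map over the plate interior.

    0 marks non-food (plate background); 1..K are food regions with
    consecutive labels.
    """

    label_map: np.ndarray
    region_areas_px: np.ndarray            # (K,) pixel counts, index = label-1
    seed_points: list[tuple[float, float]] | None = None

    @property
    def n_regions(self) -> int:
        return len(self.region_areas_px)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.label_map == region_id


@dataclass
class RegionAdjacency:
    """Adjacent region pairs with shared border length and color distance."""

    pairs: dict  # (a, b) a < b -> {"border_px": int, "color_dist": float}
    mean_colors: dict = field(default_factory=dict)  # region id -> Lab mean
    perimeters: dict = field(default_factory=dict)   # region id -> border px


def _smooth_lab(image: np.ndarray, sigma: float) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    if sigma > 0:
        img = np.stack([ndi.gaussian_filter(img[..., c], sigma) for c in range(3)], axis=-1)
    return rgb2lab(img)


def grow_regions(image: np.ndarray, plate: PlateEllipse,
                 seeds: list[tuple[float, float]],
                 config: SegmentationConfig | None = None,
                 *, _lab: np.ndarray | None = None) -> SegmentationMask:
    """Best-first seeded region growing inside the plate ellipse.

    Each seed starts a region; the pixel/region pair with the smallest
    color distance to the region's running mean is expanded first, and a
    pixel is claimed by at most one region.  Growth stops at pixels whose
    Delta-E to the claiming region's running mean exceeds ``grow_tol``.
    Deterministic given inputs: ties break on (distance, pixel index,
    region id).
    """
    config = config or SegmentationConfig()
    if len(seeds) == 0:
        raise InvalidSeedError("at least one seed is required")
    rows, cols = np.asarray(image).shape[:2]
    lab = _smooth_lab(image, config.smooth_sigma) if _lab is None else _lab
    inside = plate.contains(
        np.column_stack([g.ravel() for g in np.mgrid[0:rows, 0:cols]]),
        margin_px=config.rim_margin_px).reshape(rows, cols)

    labels = np.zeros((rows, cols), dtype=np.int32)
    sums = np.zeros((len(seeds) + 1, 3))
    counts = np.zeros(len(seeds) + 1, dtype=np.int64)
    flat_lab = lab.reshape(-1, 3)
    heap: list[tuple[float, int, int]] = []

    def push_neighbors(r: int, c: int, region: int) -> None:
        mean = sums[region] / counts[region]
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if 0 <= rr < rows and 0 <= cc < cols and inside[rr, cc] and labels[rr, cc] == 0:
                fi = rr * cols + cc
                d = float(np.linalg.norm(flat_lab[fi] - mean))
                heapq.heappush(heap, (d, fi, region))

    for region, (sr, sc) in enumerate(seeds, start=1):
        r, c = int(round(sr)), int(round(sc))
        if not (0 <= r < rows and 0 <= c < cols) or not inside[r, c]:
            raise InvalidSeedError(f"seed {region - 1} at ({sr}, {sc}) is outside the plate")
        if labels[r, c] != 0:
            continue  # duplicate seed location; first one wins
        labels[r, c] = region
        sums[region] += lab[r, c]
        counts[region] += 1
        push_neighbors(r, c, region)

    while heap:
        _, fi, region = heapq.heappop(heap)
        r, c = divmod(fi, cols)
        if labels[r, c] != 0:
            continue
        mean = sums[region] / counts[region]
        d = float(np.linalg.norm(flat_lab[fi] - mean))
        if d > config.grow_tol:
            continue
        labels[r, c] = region
        sums[region] += lab[r, c]
        counts[region] += 1
        push_neighbors(r, c, region)

    areas = np.bincount(labels.ravel(), minlength=len(seeds) + 1)[1:]
    return SegmentationMask(label_map=labels, region_areas_px=areas,
                            seed_points=[tuple(map(float, s)) for s in seeds])


def region_adjacency(image: np.ndarray, mask: SegmentationMask,
                     config: SegmentationConfig | None = None,
                     *, _lab: np.ndarray | None = None) -> RegionAdjacency:
    """Shared border lengths and inter-region color distances."""
    config = config or SegmentationConfig()
    lab = _smooth_lab(image, config.smooth_sigma) if _lab is None else _lab
    lm = mask.label_map
    ids = [i for i in range(1, mask.n_regions + 1) if (lm == i).any()]
    means = {i: lab[lm == i].mean(axis=0) for i in ids}

    pairs: dict[tuple[int, int], dict] = {}
    perims: dict[int, int] = {i: 0 for i in ids}
    for a, b in ((lm[:-1, :], lm[1:, :]), (lm[:, :-1], lm[:, 1:])):
        diff = a != b
        la, lb = a[diff], b[diff]
        for x, y in zip(la.tolist(), lb.tolist()):
            if x > 0:
                perims[x] = perims.get(x, 0) + 1
            if y > 0:
                perims[y] = perims.get(y, 0) + 1
            if x > 0 and y > 0:
                key = (min(x, y), max(x, y))
                rec = pairs.setdefault(key, {"border_px": 0, "color_dist": 0.0})
                rec["border_px"] += 1
    for (x, y), rec in pairs.items():
        rec["color_dist"] = float(np.linalg.norm(means[x] - means[y]))
    return RegionAdjacency(pairs=pairs, mean_colors=means, perimeters=perims)


def _merge_cost(rec: dict, perim_a: int, perim_b: int, config: SegmentationConfig) -> float:
    bf = rec["border_px"] / max(min(perim_a, perim_b), 1)
    boost = 1.0 + config.beta_border * min(bf, config.border_frac_cap)
    return rec["color_dist"] / boost


def merge_regions(mask: SegmentationMask, adjacency: RegionAdjacency,
                  config: SegmentationConfig | None = None,
                  *, plate_area_px: float | None = None) -> SegmentationMask:
    """Iteratively merge adjacent regions.

    The adjacent pair with the smallest cost (color distance, boosted
    down by a large mutual border) is merged while any of these hold:
    the best cost is below ``merge_cost_max``; the region count exceeds
    ``max_regions``; or some region is smaller than the minimum area (in
    which case the cheapest pair involving such a region is merged).
    Non-adjacent regions are never merged.  Undersized regions with no
    neighbor are dissolved into the background.  Labels are relabeled
    consecutively, ordered by decreasing area.
    """
    config = config or SegmentationConfig()
    lm = mask.label_map.copy()
    areas = {i: int(a) for i, a in enumerate(mask.region_areas_px, start=1) if a > 0}
    if plate_area_px is None:
        plate_area_px = float((lm >= 0).size)
    min_area = config.min_region_area_frac * plate_area_px

    pairs = {k: dict(v) for k, v in adjacency.pairs.items()}
    means = {i: np.array(v) for i, v in adjacency.mean_colors.items()}
    perims = dict(adjacency.perimeters)
    # alias table: region -> representative after merges
    parent = {i: i for i in areas}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def live_pairs():
        return {k: v for k, v in pairs.items() if k[0] in areas and k[1] in areas}

    while True:
        lp = live_pairs()
        costs = {k: _merge_cost(v, perims[k[0]], perims[k[1]], config) for k, v in lp.items()}
        best_key = min(costs, key=lambda k: (costs[k], k)) if costs else None
        small = sorted(i for i, a in areas.items() if a < min_area)
        do_key = None
        if best_key is not None and (costs[best_key] < config.merge_cost_max
                                     or len(areas) > config.max_regions):
            do_key = best_key
        elif small:
            cand = {k: c for k, c in costs.items() if k[0] in small or k[1] in small}
            if cand:
                do_key = min(cand, key=lambda k: (cand[k], k))
            else:
                # isolated undersized fragments dissolve into background
                for s in small:
                    lm[lm == s] = 0
                    del areas[s]
                break
        if do_key is None:
            break
        a, b = do_key
        keep, gone = (a, b) if areas[a] >= areas[b] else (b, a)
        w_keep, w_gone = areas[keep], areas[gone]
        means[keep] = (means[keep] * w_keep + means[gone] * w_gone) / (w_keep + w_gone)
        areas[keep] = w_keep + w_gone
        shared = pairs.pop(do_key)["border_px"]
        perims[keep] = perims[keep] + perims[gone] - 2 * shared
        del areas[gone]
        parent[gone] = keep
        lm[lm == gone] = keep
        # re-route the neighbor records of the vanished region
        for k in list(pairs):
            if gone in k:
                other = k[0] if k[1] == gone else k[1]
                rec = pairs.pop(k)
                if other == keep:
                    continue
                nk = (min(keep, other), max(keep, other))
                tgt = pairs.setdefault(nk, {"border_px": 0, "color_dist": 0.0})
                tgt["border_px"] += rec["border_px"]
        for k in list(pairs):
            if keep in k and k[0] in areas and k[1] in areas:
                pairs[k]["color_dist"] = float(np.linalg.norm(means[k[0]] - means[k[1]]))

    return _relabel(lm, mask.seed_points)


def _relabel(lm: np.ndarray, seed_points=None) -> SegmentationMask:
    ids = [i for i in np.unique(lm) if i > 0]
    ids.sort(key=lambda i: (-(lm == i).sum(), i))
    out = np.zeros_like(lm)
    areas = []
    for new, old in enumerate(ids, start=1):
        m = lm == old
        out[m] = new
        areas.append(int(m.sum()))
    return SegmentationMask(label_map=out, region_areas_px=np.array(areas, dtype=np.int64),
                            seed_points=seed_points)


def _complete_assignment(lm: np.ndarray, lab: np.ndarray, inside: np.ndarray,
                         means: dict, bg_mean: np.ndarray | None) -> np.ndarray:
    """Assign leftover plate-interior pixels to the closest region mean.

    Region growing leaves a thin unclaimed halo of color-mixture pixels
    at region boundaries.  With all region means frozen, each unclaimed
    pixel goes to the closest mean (the plate background competes with
    its own mean color), which places the boundary at the color midpoint.
    Assignments not connected to their region are reverted to background.
    """
    ids = sorted(means)
    if not ids:
        return lm
    unclaimed = inside & (lm == 0)
    if not np.any(unclaimed):
        return lm
    px = lab[unclaimed]
    cand = np.stack([means[i] for i in ids])
    d = np.linalg.norm(px[:, None, :] - cand[None, :, :], axis=2)
    choice = np.array(ids)[np.argmin(d, axis=1)]
    if bg_mean is not None:
        d_bg = np.linalg.norm(px - bg_mean, axis=1)
        choice = np.where(d_bg <= d.min(axis=1), 0, choice)
    out = lm.copy()
    out[unclaimed] = choice
    # connectivity filter: keep only additions attached to the original region
    for i in ids:
        gained = (out == i) & (lm != i)
        if not gained.any():
            continue
        comp, _ = ndi.label(out == i)
        keep = np.unique(comp[(lm == i)])
        bad = gained & ~np.isin(comp, keep[keep > 0])
        out[bad] = 0
    return out


def _refine_boundaries(mask: SegmentationMask, image: np.ndarray,
                       plate: PlateEllipse, config: SegmentationConfig) -> SegmentationMask:
    """Re-decide pixels near region boundaries on the unsmoothed image.

    The smoothing that stabilizes region growing also blurs the region
    silhouettes by ~1 px; boundary-band pixels are reassigned to the
    closest mean (regions or plate background) in unsmoothed CIELAB.
    """
    lm = mask.label_map
    if mask.n_regions == 0:
        return mask
    img = np.asarray(image, dtype=float)
    if img.max() > 1.5:
        img = img / 255.0
    lab0 = rgb2lab(img)
    rows, cols = lm.shape
    inside = plate.contains(
        np.column_stack([g.ravel() for g in np.mgrid[0:rows, 0:cols]]),
        margin_px=config.rim_margin_px).reshape(rows, cols)
    food = lm > 0
    band = ndi.binary_dilation(food, iterations=2) & ~ndi.binary_erosion(food, iterations=2)
    band &= inside
    if not band.any():
        return mask
    ids = [i for i in range(1, mask.n_regions + 1) if (lm == i).any()]
    means = np.stack([lab0[lm == i].mean(axis=0) for i in ids])
    bgpx = inside & (lm == 0) & ~band
    labels = np.array(ids)
    px = lab0[band]
    d = np.linalg.norm(px[:, None, :] - means[None, :, :], axis=2)
    choice = labels[np.argmin(d, axis=1)]
    if bgpx.any():
        bg_mean = lab0[bgpx].mean(axis=0)
        choice = np.where(np.linalg.norm(px - bg_mean, axis=1) < d.min(axis=1), 0, choice)
    out = lm.copy()
    out[band] = choice
    return _relabel(out, mask.seed_points)


def _grid_seeds(plate: PlateEllipse, image_shape, config: SegmentationConfig):
    spacing = max(2.0 * plate.semi_axes_px[0] * config.grid_spacing_frac, 4.0)
    r0, c0 = plate.center_px
    a = plate.semi_axes_px[0]
    offsets = np.arange(-a, a + spacing / 2, spacing)
    seeds = []
    for dr in offsets:
        for dc in offsets:
            p = (r0 + dr, c0 + dc)
            if (0 <= p[0] < image_shape[0] and 0 <= p[1] < image_shape[1]
                    and plate.contains(np.array([p]),
                                       margin_px=config.rim_margin_px + 2)[0]):
                seeds.append(p)
    return seeds


def _exclude_background(mask: SegmentationMask, lab: np.ndarray,
                        plate: PlateEllipse, config: SegmentationConfig,
                        *, reference: str = "largest") -> SegmentationMask:
    """Remove plate-colored regions, keeping food labels consecutive."""
    lm = mask.label_map
    if mask.n_regions == 0:
        return mask
    means = {i: lab[lm == i].mean(axis=0) for i in range(1, mask.n_regions + 1)
             if (lm == i).any()}
    if reference == "largest":
        ref_id = max(means, key=lambda i: (lm == i).sum())
        ref = means[ref_id]
    else:  # mean color of unclaimed plate pixels, when enough are visible
        unclaimed = (lm == 0) & plate.mask(lm.shape)
        if unclaimed.sum() < 0.10 * plate.area_px:
            return mask
        ref = lab[unclaimed].mean(axis=0)
    out = lm.copy()
    for i, mu in means.items():
        if np.linalg.norm(mu - ref) < config.bg_tol:
            out[lm == i] = 0
    return _relabel(out, mask.seed_points)


def auto_segment(image: np.ndarray, plate: PlateEllipse,
                 config: SegmentationConfig | None = None) -> SegmentationMask:
    """Grid-seeded growth, merging, and plate-background exclusion.

    Returns an empty mask (K = 0) when only plate-colored regions are
    found; that is a reported outcome, not an error.
    """
    config = config or SegmentationConfig()
    lab = _smooth_lab(image, config.smooth_sigma)
    rows, cols = np.asarray(image).shape[:2]
    inside = plate.contains(
        np.column_stack([g.ravel() for g in np.mgrid[0:rows, 0:cols]]),
        margin_px=config.rim_margin_px).reshape(rows, cols)
    seeds = _grid_seeds(plate, image.shape[:2], config)
    mask = grow_regions(image, plate, seeds, config, _lab=lab)
    lm = mask.label_map
    means = {i: lab[lm == i].mean(axis=0) for i in range(1, mask.n_regions + 1)
             if (lm == i).any()}
    lm = _complete_assignment(lm, lab, inside, means, None)
    mask = SegmentationMask(label_map=lm,
                            region_areas_px=np.bincount(
                                lm.ravel(), minlength=mask.n_regions + 1)[1:],
                            seed_points=mask.seed_points)
    adj = region_adjacency(image, mask, config, _lab=lab)
    merged = merge_regions(mask, adj, config, plate_area_px=plate.area_px)
    excl = _exclude_background(merged, lab, plate, config, reference="largest")
    return _refine_boundaries(excl, image, plate, config)


def seeded_segment(image: np.ndarray, plate: PlateEllipse,
                   seeds: list[tuple[float, float]],
                   config: SegmentationConfig | None = None) -> SegmentationMask:
    """Interactive-mode segmentation from one user seed per food item."""
    config = config or SegmentationConfig()
    lab = _smooth_lab(image, config.smooth_sigma)
    mask = grow_regions(image, plate, seeds, config, _lab=lab)
    rows, cols = np.asarray(image).shape[:2]
    inside = plate.contains(
        np.column_stack([g.ravel() for g in np.mgrid[0:rows, 0:cols]]),
        margin_px=config.rim_margin_px).reshape(rows, cols)
    lm = mask.label_map
    means = {i: lab[lm == i].mean(axis=0) for i in range(1, mask.n_regions + 1)
             if (lm == i).any()}
    unclaimed = inside & (lm == 0)
    bg_mean = lab[unclaimed].mean(axis=0) if unclaimed.sum() > 0.10 * plate.area_px else None
    lm0 = lm
    for _ in range(3):  # refresh means: growth may have covered one color mode only
        lm = _complete_assignment(lm0, lab, inside, means, bg_mean)
        means = {i: lab[lm == i].mean(axis=0) for i in means if (lm == i).any()}
        bg = inside & (lm == 0)
        if bg_mean is not None and bg.sum() > 0.05 * plate.area_px:
            bg_mean = lab[bg].mean(axis=0)
    mask = SegmentationMask(label_map=lm,
                            region_areas_px=np.bincount(
                                lm.ravel(), minlength=mask.n_regions + 1)[1:],
                            seed_points=mask.seed_points)
    excl = _exclude_background(mask, lab, plate, config, reference="unclaimed")
    return _refine_boundaries(excl, image, plate, config)
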
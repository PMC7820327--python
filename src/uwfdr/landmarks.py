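"""Optic-disc candidate search and macula detection.

The detection strategy exploits two facts about UWF fundus photographs: the
optic disc is the brightest coherent retinal structure (in both the green and
red channels), and the macula is the darkest retinal neighbourhood, roughly
level with the disc and temporal to it.

Pipeline:

1. Gaussian-weight the green channel about the image center to suppress
   bright non-retinal structures near the frame border (skin, eyelid).
2. Threshold the weighted map at ``tau = mu - sigma``, where mu/sigma are
   pooled statistics of reference optic-disc regions.
3. Connected components, area filtering, and merging of components whose
   centroids lie within a merge distance (150 px at native device scale).
4. Per candidate, refine with the red channel (centroid of red pixels > 50
   inside a circular neighbourhood) and fuse: 0.75 * green + 0.25 * red.
5. Disc geometry by moment-based ellipse fitting of a disc mask; macula by
   the darkest pixel (CMYK K channel) in a rectangular search band around
   the disc row, excluding the disc itself.

Pixel-unit defaults (merge 150, macula band 500 x 30, crop 614, red radius
307, disc exclusion 250) are native-resolution (3072 x 3900) values and are
rescaled proportionally for other raster sizes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .errors import DegenerateMaskError, ValidationError
from .synthetic import NATIVE_SHAPE
from .types import LandmarkSet, Point, require_rgb


def native_scale(shape: Sequence[int]) -> float:
    """Isotropic scale factor of ``shape`` relative to the native device raster."""
    h, w = shape[0], shape[1]
    return math.sqrt((h * w) / (NATIVE_SHAPE[0] * NATIVE_SHAPE[1]))


@dataclass
class ThresholdStats:
    """Pooled green-channel statistics of reference optic-disc regions."""

    mu: float
    sigma: float

    @property
    def tau(self) -> float:
        return self.mu - self.sigma

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass
class CandidateRegion:
    """One surviving optic-disc candidate blob."""

    pixel_coords: np.ndarray  # (n, 2) int array of (row, col)
    green_center: Point
    red_center: Point

    @property
    def area(self) -> int:
        return int(self.pixel_coords.shape[0])

    @property
    def fused_center(self) -> Point:
        g, r = np.asarray(self.green_center), np.asarray(self.red_center)
        f = 0.75 * g + 0.25 * r
        return (float(f[0]), float(f[1]))

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixel_coords[:, 0], self.pixel_coords[:, 1]] = True
        return m


@dataclass
class LandmarkConfig:
    """Tunable knobs of the landmark detector.

    Pixel distances are native-scale values; ``scaled`` converts them for a
    concrete image.  Areas are fractions of the image area.
    """

    sigma_frac: float = 0.35          # Gaussian weight sigma as fraction of min(H, W)
    min_area_frac: float = 1e-4
    max_area_frac: float = 1e-2
    merge_dist: float = 150.0
    red_threshold: float = 50.0       # raw 8-bit red channel
    red_radius: float = 307.0
    macula_h_range: float = 500.0
    macula_v_range: float = 30.0
    disc_exclusion_radius: float = 250.0
    k_polarity: str = "max"           # "max": darkest pixel has the largest K
    connectivity: int = 2             # skimage connectivity (2 = 8-connected)

    def scaled(self, shape: Sequence[int]) -> "LandmarkConfig":
        s = native_scale(shape)
        return LandmarkConfig(
            sigma_frac=self.sigma_frac,
            min_area_frac=self.min_area_frac,
            max_area_frac=self.max_area_frac,
            merge_dist=self.merge_dist * s,
            red_threshold=self.red_threshold,
            red_radius=self.red_radius * s,
            macula_h_range=self.macula_h_range * s,
            macula_v_range=self.macula_v_range * s,
            disc_exclusion_radius=self.disc_exclusion_radius * s,
            k_polarity=self.k_polarity,
            connectivity=self.connectivity,
        )


def gaussian_weight_green(image: np.ndarray, sigma_frac: float = 0.35) -> np.ndarray:
    """Green channel attenuated by a centered Gaussian.

    ``out(r, c) = green(r, c) * exp(-d^2 / (2 s^2))`` with ``d`` the distance
    from the image center and ``s = sigma_frac * min(H, W)``.  Suppresses
    bright periocular structures near the frame border.
    """
    arr = require_rgb(image)
    if sigma_frac <= 0:
        raise ValidationError("sigma_frac must be > 0")
    h, w = arr.shape[:2]
    s = sigma_frac * min(h, w)
    rr, cc = np.mgrid[0:h, 0:w]
    d2 = (rr - (h - 1) / 2.0) ** 2 + (cc - (w - 1) / 2.0) ** 2
    weight = np.exp(-d2 / (2.0 * s * s))
    return arr[..., 1].astype(np.float64) * weight


def estimate_threshold(disc_patches: Sequence[np.ndarray]) -> ThresholdStats:
    """Pooled mean / population SD over reference disc-region pixel collections."""
    if len(disc_patches) == 0:
        raise ValidationError("need at least one reference patch")
    pooled = np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in disc_patches])
    if pooled.size == 0:
        raise ValidationError("reference patches are all empty")
    return ThresholdStats(mu=float(pooled.mean()), sigma=float(pooled.std()))


def _merge_components(centroids: np.ndarray, merge_dist: float) -> List[List[int]]:
    """Group component indices by transitive closure of centroid proximity.

    Groups are recomputed against merged centroids until a fixpoint, so the
    result is independent of component discovery order.
    """
    groups = [[i] for i in range(len(centroids))]
    cents = [centroids[i] for i in range(len(centroids))]
    sizes = [1.0] * len(centroids)
    changed = True
    while changed:
        changed = False
        n = len(groups)
        # adjacency by current centroid distance
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(cents[i] - cents[j])) <= merge_dist:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[max(ri, rj)] = min(ri, rj)
                        changed = True
        if changed:
            buckets = {}
            for i in range(n):
                buckets.setdefault(find(i), []).append(i)
            new_groups, new_cents, new_sizes = [], [], []
            for root in sorted(buckets):
                idxs = buckets[root]
                members = sorted(m for i in idxs for m in groups[i])
                wsum = sum(sizes[i] for i in idxs)
                cent = sum(cents[i] * sizes[i] for i in idxs) / wsum
                new_groups.append(members)
                new_cents.append(cent)
                new_sizes.append(wsum)
            groups, cents, sizes = new_groups, new_cents, new_sizes
    return groups


def find_candidates(image: np.ndarray, stats: ThresholdStats,
                    min_area: Optional[float] = None, max_area: Optional[float] = None,
                    merge_dist: Optional[float] = None,
                    config: Optional[LandmarkConfig] = None) -> List[CandidateRegion]:
    """Optic-disc candidate regions, largest first.

    Binarizes the Gaussian-weighted green map at ``stats.tau``, labels
    8-connected components, drops those with area outside
    ``[min_area, max_area]``, merges components whose centroids lie within
    ``merge_dist`` of each other (to a fixpoint), then refines each survivor
    with the red-channel centroid (> red_threshold inside a circular
    neighbourhood) and fuses centers 0.75 green + 0.25 red.
    """
    arr = require_rgb(image)
    h, w = arr.shape[:2]
    cfg = (config or LandmarkConfig()).scaled((h, w))
    if min_area is None:
        min_area = cfg.min_area_frac * h * w
    if max_area is None:
        max_area = cfg.max_area_frac * h * w
    if merge_dist is None:
        merge_dist = cfg.merge_dist
    if min_area > max_area:
        raise ValidationError("min_area must be <= max_area")
    if merge_dist < 0:
        raise ValidationError("merge_dist must be >= 0")

    weighted = gaussian_weight_green(arr, cfg.sigma_frac)
    binary = weighted > stats.tau
    labels = measure.label(binary, connectivity=cfg.connectivity)
    comps = []
    for region in measure.regionprops(labels):
        if min_area <= region.area <= max_area:
            comps.append((np.array(region.centroid), region.coords))
    if not comps:
        return []

    centroids = np.array([c for c, _ in comps])
    groups = _merge_components(centroids, merge_dist)

    red = arr[..., 0].astype(np.float64)
    rr, cc = np.mgrid[0:h, 0:w]
    out: List[CandidateRegion] = []
    for members in groups:
        coords = np.concatenate([comps[i][1] for i in members], axis=0)
        green_center = coords.mean(axis=0)
        d2 = (rr - green_center[0]) ** 2 + (cc - green_center[1]) ** 2
        sel = (d2 <= cfg.red_radius ** 2) & (red > cfg.red_threshold)
        if sel.any():
            red_center = np.array([rr[sel].mean(), cc[sel].mean()])
        else:
            red_center = green_center
        out.append(CandidateRegion(
            pixel_coords=coords,
            green_center=(float(green_center[0]), float(green_center[1])),
            red_center=(float(red_center[0]), float(red_center[1])),
        ))
    out.sort(key=lambda c: (-c.area, c.green_center))
    return out


def crop_candidate(image: np.ndarray, center: Point, crop_diameter: int = 614,
                   out_size: int = 512) -> np.ndarray:
    """Circular crop around a candidate center, resized for the segmenter.

    A square window of side ``crop_diameter`` is cut centered at ``center``
    (zero-padded where it leaves the image), pixels outside the inscribed
    circle are zeroed, and the result is resized to ``out_size`` with bicubic
    interpolation.
    """
    arr = require_rgb(image)
    h, w = arr.shape[:2]
    if crop_diameter <= 0 or out_size <= 0:
        raise ValidationError("crop_diameter and out_size must be > 0")
    r, c = center
    if not (0 <= r < h and 0 <= c < w):
        raise ValidationError(f"center {center} outside image bounds {(h, w)}")
    side = int(round(crop_diameter))
    r0 = int(round(r)) - side // 2
    c0 = int(round(c)) - side // 2
    patch = np.zeros((side, side, 3), dtype=arr.dtype)
    rs0, cs0 = max(0, r0), max(0, c0)
    rs1, cs1 = min(h, r0 + side), min(w, c0 + side)
    if rs1 > rs0 and cs1 > cs0:
        patch[rs0 - r0:rs1 - r0, cs0 - c0:cs1 - c0] = arr[rs0:rs1, cs0:cs1]
    yy, xx = np.mgrid[0:side, 0:side]
    mid = (side - 1) / 2.0
    circle = (yy - mid) ** 2 + (xx - mid) ** 2 <= (side / 2.0) ** 2
    patch[~circle] = 0
    out = resize(patch, (out_size, out_size), order=3, preserve_range=True,
                 anti_aliasing=side > out_size)
    return np.clip(out, 0, 255).astype(np.uint8)


def crop_candidate_mask(mask: np.ndarray, center: Point, crop_diameter: int = 614,
                        out_size: int = 512) -> np.ndarray:
    """Binary-mask companion of :func:`crop_candidate` (nearest resize).

    Applies the identical window, circular zeroing and output size so
    (image, mask) pairs stay registered for segmenter training.
    """
    m = (np.asarray(mask) > 0).astype(np.uint8)
    h, w = m.shape
    side = int(round(crop_diameter))
    r, c = center
    r0 = int(round(r)) - side // 2
    c0 = int(round(c)) - side // 2
    patch = np.zeros((side, side), dtype=np.uint8)
    rs0, cs0 = max(0, r0), max(0, c0)
    rs1, cs1 = min(h, r0 + side), min(w, c0 + side)
    if rs1 > rs0 and cs1 > cs0:
        patch[rs0 - r0:rs1 - r0, cs0 - c0:cs1 - c0] = m[rs0:rs1, cs0:cs1]
    yy, xx = np.mgrid[0:side, 0:side]
    mid = (side - 1) / 2.0
    patch[(yy - mid) ** 2 + (xx - mid) ** 2 > (side / 2.0) ** 2] = 0
    out = resize(patch.astype(float), (out_size, out_size), order=0, preserve_range=True)
    return (out > 0.5).astype(np.uint8)


def fit_ellipse(mask: np.ndarray) -> Tuple[Point, Tuple[float, float], float]:
    """Moment-equivalent ellipse of a binary mask.

    Returns ``(center, (semi_major, semi_minor), angle_deg)`` where the angle
    is measured from the +col axis toward +row, in [0, 180).  Uses the
    region's second-order central moments (the ellipse with the same
    normalized moments as the foreground).
    """
    m = np.asarray(mask) > 0
    coords = np.argwhere(m)
    if coords.shape[0] < 5:
        raise DegenerateMaskError(
            f"need >= 5 foreground pixels for ellipse fitting, got {coords.shape[0]}")
    center = coords.mean(axis=0)
    d = coords - center
    cov = d.T @ d / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)  # ascending
    semi_minor = 2.0 * math.sqrt(max(evals[0], 0.0))
    semi_major = 2.0 * math.sqrt(max(evals[1], 0.0))
    vr, vc = evecs[:, 1]  # (row, col) direction of major axis
    angle = math.degrees(math.atan2(vr, vc)) % 180.0
    return ((float(center[0]), float(center[1])),
            (float(semi_major), float(semi_minor)), float(angle))


def rgb_to_k(image: np.ndarray) -> np.ndarray:
    """CMYK key (black) channel: ``K = 1 - max(R, G, B) / 255``."""
    arr = require_rgb(image)
    return 1.0 - arr.max(axis=2).astype(np.float64) / 255.0


def detect_macula(image: np.ndarray, disc_center: Point,
                  h_range: Optional[float] = None, v_range: Optional[float] = None,
                  exclusion_radius: Optional[float] = None,
                  polarity: str = "max") -> Point:
    """Locate the macula as the darkest pixel near the disc row.

    Searches rows within ``disc_row +- v_range`` and columns within
    ``disc_col +- h_range`` (clipped to the image), excluding a circular zone
    of ``exclusion_radius`` around the disc, and returns the pixel with
    extremal K-channel value (default polarity ``"max"``: the darkest pixel).
    Ties break toward the smallest row, then smallest column.
    """
    arr = require_rgb(image)
    h, w = arr.shape[:2]
    cfg = LandmarkConfig().scaled((h, w))
    if h_range is None:
        h_range = cfg.macula_h_range
    if v_range is None:
        v_range = cfg.macula_v_range
    if exclusion_radius is None:
        exclusion_radius = cfg.disc_exclusion_radius
    if h_range <= 0 or v_range <= 0:
        raise ValidationError("h_range and v_range must be > 0")
    dr, dc = disc_center
    if not (0 <= dr < h and 0 <= dc < w):
        raise ValidationError(f"disc_center {disc_center} outside image bounds")
    r0, r1 = int(math.floor(dr - v_range)), int(math.ceil(dr + v_range)) + 1
    c0, c1 = int(math.floor(dc - h_range)), int(math.ceil(dc + h_range)) + 1
    r0, r1 = max(0, r0), min(h, r1)
    c0, c1 = max(0, c0), min(w, c1)
    if r0 >= r1 or c0 >= c1:
        raise ValidationError("macula search window lies entirely outside the image")
    k = rgb_to_k(arr)[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]
    excluded = (rr - dr) ** 2 + (cc - dc) ** 2 <= exclusion_radius ** 2
    score = k if polarity == "max" else -k
    score = np.where(excluded, -np.inf, score)
    if not np.isfinite(score).any():
        raise ValidationError("disc exclusion zone covers the whole search window")
    # argmax with (row, col) tie-breaking: flat argmax scans row-major order
    idx = int(np.argmax(score))
    return (float(rr.ravel()[idx]), float(cc.ravel()[idx]))


def reference_threshold(images_with_masks: Sequence[Tuple[np.ndarray, np.ndarray]],
                        sigma_frac: float = 0.35) -> ThresholdStats:
    """ThresholdStats pooled from reference (image, disc mask) pairs.

    Statistics are taken on the Gaussian-weighted green channel — the same
    domain the threshold is later applied in — so that the center-weighting
    attenuation is reflected in mu and sigma.
    """
    patches = []
    for img, mask in images_with_masks:
        weighted = gaussian_weight_green(img, sigma_frac)
        patches.append(weighted[np.asarray(mask) > 0])
    return estimate_threshold(patches)


def detect_landmarks(image: np.ndarray, stats: ThresholdStats,
                     config: Optional[LandmarkConfig] = None) -> LandmarkSet:
    """Heuristic landmark detection (no learned segmenter).

    Takes the largest fused candidate, refines the disc boundary by Otsu
    thresholding of the raw green channel inside the candidate neighbourhood,
    fits the moment ellipse, then finds the macula in the search band.
    """
    arr = require_rgb(image)
    h, w = arr.shape[:2]
    cfg_s = (config or LandmarkConfig()).scaled((h, w))
    candidates = find_candidates(arr, stats, config=config)
    if not candidates:
        raise ValidationError("no optic-disc candidate survived filtering")
    best = candidates[0]
    center = np.asarray(best.fused_center)

    # local Otsu refinement of the disc boundary on the raw green channel
    rr, cc = np.mgrid[0:h, 0:w]
    local = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= cfg_s.red_radius ** 2
    green = arr[..., 1]
    thr = threshold_otsu(green[local])
    blob = local & (green > thr)
    labels = measure.label(blob, connectivity=cfg_s.connectivity)
    if labels.max() == 0:
        disc_mask = best.mask((h, w))
    else:
        largest = max(measure.regionprops(labels), key=lambda rg: rg.area)
        disc_mask = labels == largest.label
    disc_center, axes, angle = fit_ellipse(disc_mask)
    macula = detect_macula(arr, disc_center, cfg_s.macula_h_range,
                           cfg_s.macula_v_range, cfg_s.disc_exclusion_radius,
                           cfg_s.k_polarity)
    return LandmarkSet(disc_center=disc_center, disc_axes=axes,
                       disc_angle=angle, macula_center=macula)
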
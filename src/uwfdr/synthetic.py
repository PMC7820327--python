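"""Synthetic ultra-wide-field (UWF) fundus images with known ground truth.

Real UWF scans (scanning-laser ophthalmoscopy, ~200 degrees of retina) show a
dark reddish circular retinal field on a black background, a bright elliptical
optic disc, a locally dark macula temporal to the disc, curvilinear vessels
radiating from the disc, and frequently eyelash/eyelid artefacts at the image
border.  This module draws images with exactly those features from a fully
specified :class:`SyntheticSpec`, so every downstream stage (landmark
detection, segmentation, field geometry, classification) can be exercised
against exact ground truth without any external data.

The generator is deterministic: the same spec (including its seed) always
produces byte-identical images.  Landmark coordinates in the returned
:class:`~uwfdr.types.LandmarkSet` are the coordinates the image was drawn
from, never re-estimated.

The default canvas is 768 x 975, a quarter-scale version of the 3072 x 3900
rasters produced by a UWF device, which keeps tests fast; any size can be
requested and all geometry scales with it.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .types import LandmarkSet, Point

# Native raster size of the emulated device; pixel-unit constants elsewhere in
# the package are expressed at this scale and rescaled proportionally.
NATIVE_SHAPE = (3072, 3900)

DEFAULT_HEIGHT = 768
DEFAULT_WIDTH = 975

# Base colours (R, G, B) of the drawn structures, 8-bit scale.
RETINA_RGB = (150.0, 72.0, 30.0)
DISC_RGB = (235.0, 185.0, 80.0)
VESSEL_FACTOR = 0.55      # multiplicative darkening along vessels
MACULA_MIN_FACTOR = 0.35  # darkening at the macula center
EYELASH_RGB = (18.0, 12.0, 10.0)


@dataclass
class SyntheticSpec:
    """Complete description of one synthetic fundus image."""

    image_height: int = DEFAULT_HEIGHT
    image_width: int = DEFAULT_WIDTH
    retina_center: Point = (384.0, 487.0)
    retina_radius: float = 342.0
    disc_center: Point = (382.0, 537.0)
    disc_axes: Tuple[float, float] = (30.0, 26.0)
    disc_angle: float = 0.0
    macula_center: Point = (388.0, 437.0)
    laterality: str = "OD"
    vessel_count: int = 6
    occluder: str = "none"
    noise_sd: float = 2.0
    seed: int = 0
    # extras beyond the canonical fields, all with safe defaults
    macula_radius: float = 22.0
    disc_red_margin: float = 60.0
    disc_blur_sigma: float = 3.0
    texture_amplitude: float = 6.0

    def validate(self) -> None:
        h, w = self.image_height, self.image_width
        rc = np.asarray(self.retina_center, float)
        for name, p in (("disc_center", self.disc_center),
                        ("macula_center", self.macula_center)):
            pr = np.asarray(p, float)
            if not (0 <= pr[0] < h and 0 <= pr[1] < w):
                raise ValidationError(f"{name} {p} outside image bounds {(h, w)}")
            if np.hypot(*(pr - rc)) >= self.retina_radius:
                raise ValidationError(f"{name} {p} not strictly inside the retina circle")
        if self.laterality not in ("OD", "OS"):
            raise ValidationError(f"laterality must be 'OD' or 'OS', got {self.laterality!r}")
        dc, mc = self.disc_center[1], self.macula_center[1]
        if self.laterality == "OD" and not dc > mc:
            raise ValidationError("laterality OD requires disc column > macula column")
        if self.laterality == "OS" and not dc < mc:
            raise ValidationError("laterality OS requires disc column < macula column")
        if self.occluder not in ("none", "eyelash", "eyelid"):
            raise ValidationError(f"unknown occluder {self.occluder!r}")
        if self.vessel_count < 0:
            raise ValidationError("vessel_count must be >= 0")
        a, b = self.disc_axes
        if not (a >= b > 0):
            raise ValidationError("disc_axes must satisfy semi-major >= semi-minor > 0")

    def landmarks(self) -> LandmarkSet:
        return LandmarkSet(
            disc_center=tuple(map(float, self.disc_center)),
            disc_axes=tuple(map(float, self.disc_axes)),
            disc_angle=float(self.disc_angle),
            macula_center=tuple(map(float, self.macula_center)),
        )

    def to_dict(self) -> dict:
        return asdict(self)


def make_spec(height: int = DEFAULT_HEIGHT, width: int = DEFAULT_WIDTH, *,
              seed: int = 0, laterality: str = "OD", jitter: bool = True,
              **overrides) -> SyntheticSpec:
    """Build a plausible spec for a canvas of the given size.

    All geometry is derived from ``min(height, width)`` so the same relative
    layout is produced at any scale.  With ``jitter=True`` (default) landmark
    positions, disc axes/angle and the disc-macula baseline are randomized
    within realistic ranges from ``seed``; with ``jitter=False`` the layout is
    the deterministic centered default.
    """
    rng = np.random.default_rng(seed)
    m = float(min(height, width))
    rc = np.array([height / 2.0, width / 2.0])
    retina_radius = 0.445 * m

    # disc-macula baseline length; the macula sits close to the retina center
    baseline = 0.13 * m
    if jitter:
        baseline *= rng.uniform(0.9, 1.1)
        mac = rc + rng.uniform(-0.025 * m, 0.025 * m, size=2)
        row_off = rng.uniform(-0.0075 * m, 0.0075 * m)
    else:
        mac = rc + np.array([0.005 * m, -0.06 * m])
        row_off = -0.006 * m
    sign = 1.0 if laterality == "OD" else -1.0
    disc = mac + np.array([row_off, sign * baseline])

    axes_major = 0.039 * m
    axes_minor = 0.034 * m
    angle = 0.0
    if jitter:
        axes_major *= rng.uniform(0.85, 1.15)
        axes_minor = axes_major * rng.uniform(0.8, 0.95)
        angle = rng.uniform(0.0, 180.0)

    spec = SyntheticSpec(
        image_height=int(height), image_width=int(width),
        retina_center=(float(rc[0]), float(rc[1])),
        retina_radius=float(retina_radius),
        disc_center=(float(disc[0]), float(disc[1])),
        disc_axes=(float(axes_major), float(axes_minor)),
        disc_angle=float(angle),
        macula_center=(float(mac[0]), float(mac[1])),
        laterality=laterality,
        macula_radius=0.029 * m,
        seed=int(seed),
        **overrides,
    )
    spec.validate()
    return spec


def ellipse_mask(shape: Tuple[int, int], center: Point, axes: Tuple[float, float],
                 angle_deg: float) -> np.ndarray:
    """Boolean raster of a filled rotated ellipse (pixel-center inequality)."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dr = rr - center[0]
    dc = cc - center[1]
    t = np.deg2rad(angle_deg)
    # major axis along +col rotated by angle toward +row
    u = dc * np.cos(t) + dr * np.sin(t)
    v = -dc * np.sin(t) + dr * np.cos(t)
    a, b = axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _draw_vessels(img: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> None:
    """Dark curvilinear vessel-like strokes radiating from the disc."""
    h, w = img.shape[:2]
    m = float(min(h, w))
    disc = np.asarray(spec.disc_center, float)
    mac = np.asarray(spec.macula_center, float)
    toward_mac = np.sign(mac[1] - disc[1]) or 1.0
    dark = np.ones((h, w), dtype=np.float32)
    thickness = max(1, int(round(0.004 * m)))
    for _ in range(spec.vessel_count):
        # arcade-like arc: leaves the disc vertically, bends temporally
        updown = rng.choice([-1.0, 1.0])
        curl = rng.uniform(0.5, 1.2)
        length = rng.uniform(0.5, 0.95) * spec.retina_radius
        phase = rng.uniform(-0.2, 0.2)
        ts = np.linspace(0.0, 1.0, 160)
        rows = disc[0] + updown * length * np.sin(np.pi / 2 * ts + phase) * 0.8
        cols = disc[1] + toward_mac * curl * length * (1 - np.cos(np.pi / 2 * ts))
        for r, c in zip(rows, cols):
            ri, ci = int(round(r)), int(round(c))
            if 0 <= ri < h and 0 <= ci < w:
                r0, r1 = max(0, ri - thickness), min(h, ri + thickness + 1)
                c0, c1 = max(0, ci - thickness), min(w, ci + thickness + 1)
                dark[r0:r1, c0:c1] = VESSEL_FACTOR
    # keep vessels out of the immediate macula neighbourhood so the macula
    # remains the darkest local structure
    rr, cc = np.mgrid[0:h, 0:w]
    near_mac = (rr - mac[0]) ** 2 + (cc - mac[1]) ** 2 <= (1.6 * spec.macula_radius) ** 2
    dark[near_mac] = 1.0
    img *= gaussian_filter(dark, 0.8)[..., None]


def _draw_occluder(img: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator) -> None:
    h, w = img.shape[:2]
    rc = np.asarray(spec.retina_center, float)
    top_row = rc[0] - spec.retina_radius
    if spec.occluder == "eyelash":
        # dark strokes crossing the superior retina border
        n = rng.integers(6, 12)
        for _ in range(n):
            c0 = rng.uniform(rc[1] - 0.8 * spec.retina_radius, rc[1] + 0.8 * spec.retina_radius)
            sway = rng.uniform(-0.3, 0.3)
            length = rng.uniform(0.35, 0.6) * spec.retina_radius
            ts = np.linspace(0, 1, 120)
            rows = top_row - 0.15 * spec.retina_radius + ts * length
            cols = c0 + sway * length * ts ** 2
            for r, c in zip(rows, cols):
                ri, ci = int(round(r)), int(round(c))
                if 0 <= ri < h and 0 <= ci < w:
                    img[max(0, ri - 2):ri + 3, max(0, ci - 2):ci + 3] = EYELASH_RGB
    elif spec.occluder == "eyelid":
        # smooth bright-skin band over the superior part of the frame
        band_h = int(0.25 * h)
        rr = np.arange(h)[:, None]
        lid = np.clip((band_h - rr) / band_h, 0, 1).astype(np.float32)
        skin = np.array([180.0, 120.0, 95.0], dtype=np.float32)
        img[:] = img * (1 - lid[..., None]) + skin * lid[..., None]


def generate_fundus(spec: SyntheticSpec) -> Tuple[np.ndarray, LandmarkSet]:
    """Render the image described by ``spec``.

    Returns the 8-bit RGB image and the ground-truth landmark set (the exact
    coordinates drawn, no re-estimation).  Identical spec => byte-identical
    output.
    """
    spec.validate()
    # independent substreams so toggling one feature (e.g. the occluder)
    # leaves the others' randomness untouched
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng_texture, rng_vessel, rng_occ, rng_noise = (np.random.default_rng(s) for s in ss)
    h, w = spec.image_height, spec.image_width
    img = np.zeros((h, w, 3), dtype=np.float32)

    rr, cc = np.mgrid[0:h, 0:w]
    rc = np.asarray(spec.retina_center, float)
    retina = (rr - rc[0]) ** 2 + (cc - rc[1]) ** 2 <= spec.retina_radius ** 2

    # retinal field with low-amplitude smooth texture
    base = np.array(RETINA_RGB, dtype=np.float32)
    texture = gaussian_filter(rng_texture.normal(0.0, 1.0, size=(h, w)).astype(np.float32),
                              0.012 * min(h, w))
    texture *= spec.texture_amplitude / max(texture.std(), 1e-9)
    img[retina] = base[None, :] + texture[retina, None] * np.array([1.0, 0.7, 0.4])

    if spec.vessel_count > 0:
        _draw_vessels(img, spec, rng_vessel)
        img[~retina] = 0.0

    # macula: smooth multiplicative dark dip, darkest at its center
    mac = np.asarray(spec.macula_center, float)
    d2 = (rr - mac[0]) ** 2 + (cc - mac[1]) ** 2
    dip = 1.0 - (1.0 - MACULA_MIN_FACTOR) * np.exp(-d2 / (2 * (spec.macula_radius / 1.5) ** 2))
    img *= dip[..., None].astype(np.float32)

    # optic disc: bright soft-edged ellipse, brightest structure in R and G
    disc = ellipse_mask((h, w), spec.disc_center, spec.disc_axes, spec.disc_angle)
    disc_soft = gaussian_filter(disc.astype(np.float32), spec.disc_blur_sigma)
    disc_rgb = np.array(DISC_RGB, dtype=np.float32)
    disc_rgb[0] = max(disc_rgb[0], RETINA_RGB[0] + spec.disc_red_margin)
    img = img * (1 - disc_soft[..., None]) + disc_rgb[None, None, :] * disc_soft[..., None]

    if spec.occluder != "none":
        _draw_occluder(img, spec, rng_occ)

    if spec.noise_sd > 0:
        img += rng_noise.normal(0.0, spec.noise_sd, size=img.shape).astype(np.float32)

    out = np.clip(img, 0, 255).astype(np.uint8)
    return out, spec.landmarks()


def generate_disc_mask_pairs(n: int, base_spec: SyntheticSpec, seed: int,
                             ) -> List[Tuple[np.ndarray, np.ndarray]]:
    """(image, binary disc mask) pairs for segmentation training.

    Disc position, axes and angle are randomized around ``base_spec`` while
    keeping all spec invariants; the mask is the exact rasterized disc ellipse
    (pixel-center inequality), not the blurred drawn edge.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    base_spec.validate()
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(n):
        spec = SyntheticSpec(**base_spec.to_dict())
        rc = np.asarray(base_spec.retina_center, float)
        mac = np.asarray(base_spec.macula_center, float)
        sign = 1.0 if base_spec.laterality == "OD" else -1.0
        baseline = np.hypot(*(np.asarray(base_spec.disc_center) - mac))
        for _attempt in range(100):
            b = baseline * rng.uniform(0.85, 1.15)
            row_off = rng.uniform(-0.06, 0.06) * baseline
            disc = mac + np.array([row_off, sign * b])
            if np.hypot(*(disc - rc)) < 0.85 * base_spec.retina_radius:
                break
        a = base_spec.disc_axes[0] * rng.uniform(0.8, 1.2)
        spec.disc_center = (float(disc[0]), float(disc[1]))
        spec.disc_axes = (float(a), float(a * rng.uniform(0.8, 0.98)))
        spec.disc_angle = float(rng.uniform(0.0, 180.0))
        spec.seed = int(rng.integers(0, 2 ** 31 - 1))
        spec.validate()
        img, _ = generate_fundus(spec)
        mask = ellipse_mask((spec.image_height, spec.image_width),
                            spec.disc_center, spec.disc_axes, spec.disc_angle)
        pairs.append((img, mask.astype(np.uint8)))
    return pairs


@dataclass
class LabeledImage:
    """One synthetic screening image with its binary label and ground truth."""

    image: np.ndarray
    label: int  # 1 = DR, 0 = healthy
    landmarks: LandmarkSet
    spec: SyntheticSpec
    lesions: List[Tuple[float, float, str]] = field(default_factory=list)


def _sample_lesion_sites(spec: SyntheticSpec, rng: np.random.Generator, count: int,
                         annulus: Optional[Tuple[float, float]]) -> List[Tuple[float, float]]:
    """Lesion positions inside the retina.

    ``annulus=(r_in, r_out)`` restricts sites to a ring around the macula in
    units of the disc-macula distance D, additionally excluding the
    disc/macula region itself (a peripheral-lesion configuration: sites fall
    outside the two central ETDRS fields but inside the 7-standard-field
    region).
    """
    rc = np.asarray(spec.retina_center, float)
    mac = np.asarray(spec.macula_center, float)
    disc = np.asarray(spec.disc_center, float)
    D = float(np.hypot(*(disc - mac)))
    sites: List[Tuple[float, float]] = []
    guard = 0
    while len(sites) < count and guard < 20000:
        guard += 1
        if annulus is None:
            ang = rng.uniform(0, 2 * np.pi)
            rad = spec.retina_radius * 0.92 * np.sqrt(rng.uniform(0, 1))
            p = rc + rad * np.array([np.sin(ang), np.cos(ang)])
        else:
            ang = rng.uniform(0, 2 * np.pi)
            rad = D * rng.uniform(*annulus)
            p = mac + rad * np.array([np.sin(ang), np.cos(ang)])
        if np.hypot(*(p - rc)) > 0.92 * spec.retina_radius:
            continue
        if np.hypot(*(p - disc)) < 2.2 * spec.disc_axes[0]:
            continue
        if np.hypot(*(p - mac)) < 2.0 * spec.macula_radius:
            continue
        if annulus is not None:
            # keep clear of the two central fields (disc- and macula-centered
            # circles of radius D/2, with margin for the alignment rotation)
            lo_c = min(mac[1], disc[1]) - 0.65 * D
            hi_c = max(mac[1], disc[1]) + 0.65 * D
            if abs(p[0] - mac[0]) <= 0.85 * D and lo_c <= p[1] <= hi_c:
                continue
        if not (0 <= p[0] < spec.image_height and 0 <= p[1] < spec.image_width):
            continue
        sites.append((float(p[0]), float(p[1])))
    return sites


def _stamp_lesions(img: np.ndarray, sites: Sequence[Tuple[float, float]],
                   rng: np.random.Generator, contrast: float, radius_scale: float,
                   ) -> List[Tuple[float, float, str]]:
    h, w = img.shape[:2]
    out = img.astype(np.float32)
    placed = []
    for (r, c) in sites:
        kind = "bright" if rng.uniform() < 0.5 else "dark"
        rad = rng.uniform(6.0, 11.0) * radius_scale
        rr, cc = np.mgrid[max(0, int(r - 3 * rad)):min(h, int(r + 3 * rad) + 1),
                          max(0, int(c - 3 * rad)):min(w, int(c + 3 * rad) + 1)]
        blob = np.exp(-((rr - r) ** 2 + (cc - c) ** 2) / (2 * (rad / 1.5) ** 2)).astype(np.float32)
        region = (slice(rr.min(), rr.max() + 1), slice(cc.min(), cc.max() + 1))
        if kind == "bright":
            # exudate-like: bright yellowish dot
            out[region] += blob[..., None] * np.array([contrast, contrast * 0.9, contrast * 0.2],
                                                      dtype=np.float32)
        else:
            # hemorrhage-like: dark reddish dot
            out[region] *= (1.0 - 0.65 * blob)[..., None]
        placed.append((r, c, kind))
    img[:] = np.clip(out, 0, 255)
    return placed


def generate_labeled_dataset(n_dr: int, n_healthy: int, seed: int, *,
                             height: int = DEFAULT_HEIGHT, width: int = DEFAULT_WIDTH,
                             lesion_count: int = 25, lesion_contrast: float = 70.0,
                             lesion_annulus: Optional[Tuple[float, float]] = None,
                             occluder_fraction: float = 0.0) -> List[LabeledImage]:
    """Binary-labeled screening set: DR images carry lesion blobs, healthy do not.

    With ``lesion_count=0`` the DR class degenerates to the healthy
    distribution.  ``lesion_annulus`` (in units of disc-macula distance D
    around the macula) confines lesions to the retinal periphery.  Laterality
    is randomized per image.
    """
    if n_dr < 0 or n_healthy < 0:
        raise ValidationError("class counts must be >= 0")
    if n_dr + n_healthy < 1:
        raise ValidationError("at least one image must be requested")
    rng = np.random.default_rng(seed)
    items: List[LabeledImage] = []
    labels = [1] * n_dr + [0] * n_healthy
    m = float(min(height, width))
    for label in labels:
        img_seed = int(rng.integers(0, 2 ** 31 - 1))
        laterality = "OD" if rng.uniform() < 0.5 else "OS"
        occluder = "eyelash" if rng.uniform() < occluder_fraction else "none"
        spec = make_spec(height, width, seed=img_seed, laterality=laterality,
                         occluder=occluder)
        img, lm = generate_fundus(spec)
        lesions: List[Tuple[float, float, str]] = []
        if label == 1 and lesion_count > 0:
            les_rng = np.random.default_rng(img_seed + 1)
            sites = _sample_lesion_sites(spec, les_rng, lesion_count, lesion_annulus)
            lesions = _stamp_lesions(img, sites, les_rng, lesion_contrast,
                                     radius_scale=m / 768.0)
        items.append(LabeledImage(image=img, label=label, landmarks=lm,
                                  spec=spec, lesions=lesions))
    return items


def save_fundus(directory, stem: str, image: np.ndarray, spec: SyntheticSpec,
                landmarks: LandmarkSet, *, label: Optional[int] = None,
                mask: Optional[np.ndarray] = None) -> None:
    """Write ``<stem>.png`` (+ optional ``<stem>_mask.png``) and a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", image)
    if mask is not None:
        iio.imwrite(directory / f"{stem}_mask.png", (mask.astype(np.uint8) * 255))
    sidecar = {
        "landmarks": landmarks.to_dict(),
        "laterality": spec.laterality,
        "spec": spec.to_dict(),
    }
    if label is not None:
        sidecar["label"] = int(label)
    (directory / f"{stem}.json").write_text(json.dumps(sidecar, indent=2))
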
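"""Laterality normalization, rotational alignment, and ETDRS field extraction.

Left-eye (OS) images are mirrored so the optic disc always sits temporal-right
of the macula; the image is then rotated about the disc center until disc and
macula share a row.  From the aligned image two regions of interest are cut:

* **SF7** — an approximation of the ETDRS 7-standard-field region, a window
  centered on the macula spanning a configurable multiple of the disc-macula
  distance D (default 4 D wide), resized to 896 x 1024;
* **F1F2** — the two central fields (disc-centered Field 1 and macula-centered
  Field 2), the bounding box of two circles of radius ``field_radius_factor*D``
  (default 0.5 D) around the two landmarks, resized to 448 x 640.

Both windows are expanded symmetrically to the target aspect ratio before
resizing, and out-of-bounds source pixels are zero-filled.  The exact extent
of the 7-standard-field window is parameterized because only the two landmark
points are available to define a scale; the defaults approximate the ~90
degree region the seven 30-degree fields cover, relative to the two central
fields.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import resize

from .errors import DegenerateGeometryError
from .types import AlignmentTransform, FieldCrop, LandmarkSet, require_rgb

SF7_SIZE = (896, 1024)
F1F2_SIZE = (448, 640)


@dataclass
class FieldGeometryConfig:
    """Crop-window extents in units of the disc-macula distance D."""

    field_radius_factor: float = 0.5   # F1/F2 circle radius = factor * D
    sf7_width_factor: float = 4.0      # SF7 window width = factor * D


def normalize_laterality(image: np.ndarray, landmarks: LandmarkSet,
                         ) -> Tuple[np.ndarray, LandmarkSet, bool]:
    """Mirror OS images horizontally so the disc lies right of the macula.

    Column coordinates map ``col -> W - 1 - col``; the disc-ellipse angle is
    mirrored accordingly.  Applying the operation twice restores the input
    exactly.
    """
    arr = require_rgb(image)
    h, w = arr.shape[:2]
    dc, mc = landmarks.disc_center[1], landmarks.macula_center[1]
    if dc == mc:
        raise DegenerateGeometryError("disc and macula columns coincide; laterality undefined")
    if dc > mc:
        return arr, landmarks, False
    flipped = arr[:, ::-1].copy()
    new = LandmarkSet(
        disc_center=(landmarks.disc_center[0], w - 1 - dc),
        disc_axes=landmarks.disc_axes,
        disc_angle=(-landmarks.disc_angle) % 180.0,
        macula_center=(landmarks.macula_center[0], w - 1 - mc),
    )
    return flipped, new, True


def align_rotation(image: np.ndarray, landmarks: LandmarkSet, *, order: int = 3,
                   ) -> Tuple[np.ndarray, LandmarkSet, AlignmentTransform]:
    """Rotate about the disc center until the macula lies on the disc row.

    Requires laterality-normalized input (disc right of macula).  The content
    rotation angle alpha satisfies: rotating the macula point by alpha about
    the disc center zeroes its row offset.  Bicubic resampling, zero fill;
    the disc center is a fixed point of the transform.
    """
    arr = require_rgb(image)
    d = np.asarray(landmarks.disc_center, float)
    m = np.asarray(landmarks.macula_center, float)
    u = m - d
    if np.allclose(u, 0):
        raise DegenerateGeometryError("disc and macula centers coincide")
    # current angle of the disc->macula direction; target is (0, -1) (pure -col)
    alpha = math.pi - math.atan2(u[0], u[1])
    alpha = (alpha + math.pi) % (2 * math.pi) - math.pi
    transform = AlignmentTransform(flipped=False, rotation_deg=math.degrees(alpha),
                                   pivot=(float(d[0]), float(d[1])),
                                   source_size=(arr.shape[0], arr.shape[1]))
    # output(p) = input(R(-alpha) (p - pivot) + pivot)
    rot = transform._matrix(inverse=True)
    offset = d - rot @ d
    channels = [ndi.affine_transform(arr[..., ch].astype(np.float32), rot, offset=offset,
                                     order=order, mode="constant", cval=0.0)
                for ch in range(3)]
    rotated = np.clip(np.stack(channels, axis=-1), 0, 255).astype(np.uint8)
    new_mac = transform.apply(m)[0]
    new_lm = LandmarkSet(
        disc_center=landmarks.disc_center,
        disc_axes=landmarks.disc_axes,
        disc_angle=(landmarks.disc_angle + math.degrees(alpha)) % 180.0,
        macula_center=(float(new_mac[0]), float(new_mac[1])),
    )
    return rotated, new_lm, transform


def _window_for(kind: str, landmarks: LandmarkSet, geometry: FieldGeometryConfig,
                ) -> Tuple[float, float, float, float]:
    d = np.asarray(landmarks.disc_center, float)
    m = np.asarray(landmarks.macula_center, float)
    D = float(np.hypot(*(d - m)))
    if D == 0:
        raise DegenerateGeometryError("disc and macula centers coincide")
    if kind == "F1F2":
        r = geometry.field_radius_factor * D
        r0, r1 = min(d[0], m[0]) - r, max(d[0], m[0]) + r
        c0, c1 = min(d[1], m[1]) - r, max(d[1], m[1]) + r
        target_h, target_w = F1F2_SIZE
    elif kind == "SF7":
        half_w = geometry.sf7_width_factor * D / 2.0
        r0, r1 = m[0], m[0]  # rows grow to the target aspect below
        c0, c1 = m[1] - half_w, m[1] + half_w
        target_h, target_w = SF7_SIZE
    else:
        raise DegenerateGeometryError(f"unknown field kind {kind!r}")
    # expand symmetrically to the target aspect ratio (H:W)
    cur_h, cur_w = r1 - r0, c1 - c0
    aspect = target_h / target_w
    if cur_h / cur_w < aspect:
        pad = (cur_w * aspect - cur_h) / 2.0
        r0, r1 = r0 - pad, r1 + pad
    else:
        pad = (cur_h / aspect - cur_w) / 2.0
        c0, c1 = c0 - pad, c1 + pad
    return (r0, c0, r1, c1)


def extract_field_crop(image: np.ndarray, landmarks: LandmarkSet, kind: str,
                       geometry: Optional[FieldGeometryConfig] = None,
                       out_size: Optional[Tuple[int, int]] = None) -> FieldCrop:
    """Cut and resize the SF7 or F1F2 region from an aligned image.

    ``out_size`` defaults to the standard sizes (896x1024 for SF7, 448x640
    for F1F2); reduced-scale experiments may request a smaller raster of the
    same window directly.
    """
    arr = require_rgb(image)
    geometry = geometry or FieldGeometryConfig()
    r0, c0, r1, c1 = _window_for(kind, landmarks, geometry)
    if out_size is None:
        out_size = SF7_SIZE if kind == "SF7" else F1F2_SIZE
    h, w = arr.shape[:2]
    ir0, ic0 = int(math.floor(r0)), int(math.floor(c0))
    ir1, ic1 = int(math.ceil(r1)), int(math.ceil(c1))
    win = np.zeros((ir1 - ir0, ic1 - ic0, 3), dtype=arr.dtype)
    sr0, sc0 = max(0, ir0), max(0, ic0)
    sr1, sc1 = min(h, ir1), min(w, ic1)
    if sr1 > sr0 and sc1 > sc0:
        win[sr0 - ir0:sr1 - ir0, sc0 - ic0:sc1 - ic0] = arr[sr0:sr1, sc0:sc1]
    out = resize(win.astype(np.float32), out_size, order=3, preserve_range=True,
                 anti_aliasing=win.shape[0] > out_size[0])
    crop = FieldCrop(
        image=np.clip(out, 0, 255).astype(np.uint8),
        field_kind=kind,
        out_size=out_size,
        source_window=(float(ir0), float(ic0), float(ir1), float(ic1)),
    )
    pts = crop.map_to_crop(np.array([landmarks.disc_center, landmarks.macula_center]))
    crop.landmarks_in_crop = {"disc": tuple(map(float, pts[0])),
                              "macula": tuple(map(float, pts[1]))}
    return crop


def flag_occlusion(crop: FieldCrop, dark_level: float = 30.0,
                   max_dark_fraction: float = 0.2,
                   band: Tuple[float, float] = (0.25, 0.75)) -> bool:
    """Advisory QC flag for eyelid/eyelash-contaminated crops.

    True when the fraction of near-black pixels (max channel below
    ``dark_level``) within the central row band exceeds ``max_dark_fraction``.
    Mirrors a manual exclusion step: contaminated fields should not enter
    evaluation.
    """
    img = crop.image
    h = img.shape[0]
    r0, r1 = int(band[0] * h), int(band[1] * h)
    region = img[r0:r1].max(axis=2)
    frac = float((region < dark_level).mean())
    return frac > max_dark_fraction
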
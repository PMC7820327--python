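"""Shared domain types.

Coordinate convention (used repo-wide): 0-based ``(row, col)`` with row 0 at
the top of the image and pixel centers at integer coordinates.  Angles are in
degrees.  Images are ``H x W x 3`` uint8 RGB numpy arrays; masks are ``H x W``
arrays with values in {0, 1}.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

import numpy as np

from .errors import FormatError, ValidationError

Point = Tuple[float, float]  # (row, col)


def require_rgb(image: np.ndarray) -> np.ndarray:
    """Validate an 8-bit RGB raster and return it unchanged."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"expected HxWx3 RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise FormatError(f"expected uint8 image, got dtype {arr.dtype}")
    return arr


@dataclass
class LandmarkSet:
    """Optic-disc ellipse and macula center in image coordinates.

    ``disc_axes`` are semi-axes (semi-major first); ``disc_angle`` is the
    orientation of the major axis in degrees, measured from the +col axis
    toward +row (mod 180).
    """

    disc_center: Point
    disc_axes: Tuple[float, float]
    disc_angle: float
    macula_center: Point

    def __post_init__(self) -> None:
        a, b = self.disc_axes
        if not (a >= b > 0):
            raise ValidationError(
                f"disc semi-axes must satisfy semi-major >= semi-minor > 0, got {self.disc_axes}"
            )

    def validate_bounds(self, shape: Tuple[int, int]) -> None:
        h, w = shape[:2]
        for name, (r, c) in (("disc_center", self.disc_center),
                             ("macula_center", self.macula_center)):
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError(f"{name} {(r, c)} outside image bounds {(h, w)}")

    def to_dict(self) -> dict:
        return {
            "disc_center": list(map(float, self.disc_center)),
            "disc_axes": list(map(float, self.disc_axes)),
            "disc_angle": float(self.disc_angle),
            "macula_center": list(map(float, self.macula_center)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            disc_center=tuple(d["disc_center"]),
            disc_axes=tuple(d["disc_axes"]),
            disc_angle=float(d["disc_angle"]),
            macula_center=tuple(d["macula_center"]),
        )


@dataclass
class AlignmentTransform:
    """Record of the laterality flip + rotation applied to an image.

    ``rotation_deg`` is the angle by which image content was rotated about
    ``pivot`` (the disc center), positive from +col toward +row (i.e.
    clockwise on screen with row increasing downward).  The transform maps
    *original* (post-flip) coordinates to aligned coordinates.
    """

    flipped: bool
    rotation_deg: float
    pivot: Point
    source_size: Tuple[int, int]

    def _matrix(self, inverse: bool = False) -> np.ndarray:
        a = np.deg2rad(self.rotation_deg)
        if inverse:
            a = -a
        return np.array([[np.cos(a), np.sin(a)], [-np.sin(a), np.cos(a)]])

    def apply_flip(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)).copy()
        if self.flipped:
            pts[:, 1] = self.source_size[1] - 1 - pts[:, 1]
        return pts

    def apply(self, points: np.ndarray, *, include_flip: bool = False) -> np.ndarray:
        """Map (n, 2) ``(row, col)`` points through the transform."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if include_flip:
            pts = self.apply_flip(pts)
        pivot = np.asarray(self.pivot, dtype=float)
        return (pts - pivot) @ self._matrix().T + pivot

    def invert(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        pivot = np.asarray(self.pivot, dtype=float)
        return (pts - pivot) @ self._matrix(inverse=True).T + pivot

    def to_dict(self) -> dict:
        return {
            "flipped": bool(self.flipped),
            "rotation_deg": float(self.rotation_deg),
            "pivot": list(map(float, self.pivot)),
            "source_size": list(map(int, self.source_size)),
        }


@dataclass
class FieldCrop:
    """An extracted ETDRS field crop plus its source geometry.

    ``source_window`` is ``(row0, col0, row1, col1)`` in aligned-image
    coordinates (row1/col1 exclusive); ``landmarks_in_crop`` holds the disc
    and macula centers mapped into crop pixel coordinates.
    """

    image: np.ndarray
    field_kind: str  # "SF7" | "F1F2"
    out_size: Tuple[int, int]
    source_window: Tuple[float, float, float, float]
    landmarks_in_crop: dict = field(default_factory=dict)

    def map_to_crop(self, points: np.ndarray) -> np.ndarray:
        """Map aligned-image (row, col) points into crop coordinates."""
        r0, c0, r1, c1 = self.source_window
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        sr = self.out_size[0] / (r1 - r0)
        sc = self.out_size[1] / (c1 - c0)
        return np.column_stack(((pts[:, 0] - r0) * sr, (pts[:, 1] - c0) * sc))
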
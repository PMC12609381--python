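"""Digitization chain: silhouette image -> calibrated, standardized profile.

Mirrors the photographic workflow for fruit morphometrics: a binary
silhouette photograph is read, the outer boundary of the fruit is traced,
the pixel scale is calibrated against a caliper-measured fruit length, and
the boundary is standardized — longest chord on the x-axis, centred,
resampled to a fixed number of approximately equidistant points (1000 by
default) — ready for curve fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from PIL import Image
from scipy.spatial import ConvexHull
from skimage import measure

from .epe_model import ProfileCoordinates, polygon_area, resample_closed

__all__ = [
    "RawBoundary",
    "read_binary_image",
    "extract_boundary",
    "calibrate_scale",
    "standardize_profile",
    "standardize_points",
    "longest_chord",
    "raw_max_halfwidth",
    "read_profile_csv",
    "write_profile_csv",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RawBoundary:
    """Ordered outer boundary of one silhouette, in pixel coordinates.

    ``pixel_points`` is an (n, 2) array of (row, col) positions tracing a
    single closed chain; ``scale`` (cm per pixel) is None until
    :func:`calibrate_scale` has run.
    """

    pixel_points: np.ndarray
    image_shape: tuple
    scale: Optional[float] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.pixel_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("pixel_points must be an (n, 2) array")
        if pts.shape[0] < 50:
            raise ValueError("boundary must contain at least 50 points")
        object.__setattr__(self, "pixel_points", pts)


def read_binary_image(path) -> np.ndarray:
    """Read a BMP/PNG silhouette and return the foreground mask.

    Pixels are binarized at the 50% grey level.  The fruit silhouette is
    taken to be whichever phase does *not* touch the image border (the
    photographic background always reaches the border).
    """
    img = Image.open(path).convert("L")
    arr = np.asarray(img, dtype=float)
    bright = arr >= 127.5
    candidates = []
    for phase in (bright, ~bright):
        if not phase.any():
            continue
        touches = (phase[0, :].any() or phase[-1, :].any()
                   or phase[:, 0].any() or phase[:, -1].any())
        if not touches:
            candidates.append(phase)
    if not candidates:
        if bright.all() or (~bright).all():
            raise ValueError(f"{path}: empty foreground (single-phase image)")
        raise ValueError(
            f"{path}: both phases touch the image border; cannot decide which "
            "is the fruit — re-crop so the silhouette has a clear margin"
        )
    if len(candidates) > 1:  # only possible for exotic masks; prefer the larger
        candidates.sort(key=lambda m: m.sum(), reverse=True)
    return candidates[0]


def extract_boundary(mask: np.ndarray) -> RawBoundary:
    """Trace the outer contour of the largest connected foreground component.

    Returns a single closed ordered pixel chain (subpixel positions from
    marching squares at the 0.5 level).  Smaller components are discarded
    and counted in the log.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask: no foreground to trace")
    labels = measure.label(mask, connectivity=2)
    n_comp = labels.max()
    if n_comp > 1:
        sizes = np.bincount(labels.ravel())[1:]
        keep = int(np.argmax(sizes)) + 1
        logger.info("extract_boundary: discarding %d smaller component(s)",
                    n_comp - 1)
    else:
        keep = 1
    comp = labels == keep
    padded = np.pad(comp, 1).astype(float)
    contours = measure.find_contours(padded, 0.5)
    contour = max(contours, key=len) - 1.0  # undo padding offset
    if np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    if len(contour) < 50:
        raise ValueError(
            f"largest component's boundary has only {len(contour)} points "
            "(< 50): silhouette too small or degenerate"
        )
    return RawBoundary(pixel_points=contour, image_shape=mask.shape)


def longest_chord(points: np.ndarray) -> tuple:
    """Indices (i, j) of the farthest point pair of a closed boundary.

    Searches convex-hull vertices only (the diameter pair always lies on
    the hull).  Ties are broken in favour of the chord making the smallest
    angle with the horizontal axis, then by index order, for determinism.
    """
    pts = np.asarray(points, dtype=float)
    hull_idx = ConvexHull(pts).vertices
    hp = pts[hull_idx]
    d2 = ((hp[:, None, :] - hp[None, :, :]) ** 2).sum(axis=2)
    best = np.max(d2)
    cand = np.argwhere(d2 >= best * (1.0 - 1e-12))
    cand = cand[cand[:, 0] < cand[:, 1]]

    def tie_key(ij):
        p, q = hp[ij[0]], hp[ij[1]]
        dx, dy = abs(q[0] - p[0]), abs(q[1] - p[1])
        ang = np.arctan2(dy, dx)
        return (ang, hull_idx[ij[0]], hull_idx[ij[1]])

    i, j = min(cand, key=tie_key)
    return int(hull_idx[i]), int(hull_idx[j])


def calibrate_scale(boundary: RawBoundary, measured_length: float) -> RawBoundary:
    """Set the cm-per-pixel scale from a caliper-measured fruit length.

    The pixel extent of the longest chord of the boundary is equated to the
    measured length; the same isotropic factor applies to both axes.
    """
    if measured_length <= 0:
        raise ValueError("measured_length must be positive (cm)")
    i, j = longest_chord(boundary.pixel_points)
    chord_px = float(np.linalg.norm(boundary.pixel_points[i]
                                    - boundary.pixel_points[j]))
    if chord_px <= 0:
        raise ValueError("degenerate boundary: zero-length longest chord")
    return replace(boundary, scale=measured_length / chord_px)


def standardize_points(xy: np.ndarray, n: int = 1000) -> ProfileCoordinates:
    """Standardize a closed boundary polygon given in cm coordinates.

    Rotates the longest chord onto the x-axis, centres its midpoint at the
    origin, starts the traversal at the left chord endpoint (-L/2, 0),
    orients it counterclockwise and resamples to ``n`` arc-length
    equidistant points.
    """
    xy = np.asarray(xy, dtype=float)
    i, j = longest_chord(xy)
    p, q = xy[i], xy[j]
    if q[0] < p[0] or (q[0] == p[0] and q[1] < p[1]):
        i, j = j, i
        p, q = q, p
    mid = 0.5 * (p + q)
    direction = (q - p) / np.linalg.norm(q - p)
    rot = np.array([[direction[0], direction[1]],
                    [-direction[1], direction[0]]])
    aligned = (xy - mid) @ rot.T
    aligned = np.roll(aligned, -i, axis=0)
    if polygon_area(aligned) < 0:
        aligned = np.vstack([aligned[:1], aligned[1:][::-1]])
    pts = resample_closed(aligned, n)
    return ProfileCoordinates(pts, standardized=True)


def standardize_profile(boundary, n: int = 1000) -> ProfileCoordinates:
    """Convert a calibrated boundary to a standardized profile of ``n`` points.

    Accepts a :class:`RawBoundary` (requires :func:`calibrate_scale` first)
    or an already-standardized :class:`ProfileCoordinates`, which is
    returned unchanged when the point count matches (standardization is
    idempotent by construction).
    """
    if isinstance(boundary, ProfileCoordinates):
        if boundary.standardized and boundary.n_points == n:
            return boundary
        return standardize_points(boundary.points, n)
    if boundary.scale is None:
        raise ValueError("boundary must be calibrated before standardization")
    rows, cols = boundary.pixel_points[:, 0], boundary.pixel_points[:, 1]
    # pixel centres; image row axis flipped so y increases upward
    x = cols * boundary.scale
    y = (boundary.image_shape[0] - 1 - rows) * boundary.scale
    return standardize_points(np.column_stack([x, y]), n)


def raw_max_halfwidth(profile: ProfileCoordinates) -> float:
    """Diagnostic: max |y| of the raw digitized points of a standardized profile.

    The analysis width W is taken from the fitted curve; this raw-point
    maximum is exposed for comparison only.
    """
    return float(np.abs(profile.y).max())


def read_profile_csv(path) -> ProfileCoordinates:
    """Read a two-column (x_cm, y_cm) coordinate file (header required)."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["x_cm", "y_cm"]:
        raise ValueError(f"{path}: expected columns x_cm,y_cm, got {list(df.columns)}")
    return ProfileCoordinates(df.iloc[:, :2].to_numpy(float), standardized=False)


def write_profile_csv(profile: ProfileCoordinates, path) -> None:
    """Write a profile as a two-column (x_cm, y_cm) CSV, 6 significant digits."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("x_cm,y_cm\n")
        for x, y in profile.points:
            fh.write(f"{x:.6g},{y:.6g}\n")
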
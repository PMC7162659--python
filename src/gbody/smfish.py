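"""smFISH colocalization of mRNA spots with G bodies.

The granule is segmented from the background-subtracted maximum-intensity
projection of the GFP channel by Otsu thresholding within the cell
outline, its center taken as the intensity-weighted centroid of the
dominant component, and its most in-focus slice picked by the variance of
the Laplacian.  Spots within one slice of that plane contribute in-plane
Euclidean distances (µm) from the G-body center, either for every pixel of
each spot footprint (default) or the nearest pixel only.  Distance ECDFs
feed a fold-change curve against a control mRNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as label_components

__all__ = [
    "GBodySegmentation",
    "DistanceProfile",
    "segment_gbody",
    "select_spots_near_plane",
    "spot_footprints",
    "distance_profile",
    "cdf_fold_change",
]


@dataclass
class GBodySegmentation:
    found: bool
    center: tuple[float, float] | None = None  # (row, col)
    slice_index: int | None = None
    mask: np.ndarray | None = None


def segment_gbody(
    gfp_stack: np.ndarray,
    cell_outline: np.ndarray,
    background: float | None = None,
) -> GBodySegmentation:
    """Locate the G body inside one cell.

    ``gfp_stack`` is (n_slices, H, W); ``cell_outline`` a boolean mask.
    ``background`` defaults to the median intensity outside the outline
    (or inside, when the outline covers the whole image).  A cell whose
    in-outline signal cannot be thresholded (constant intensity, or no
    above-threshold component) yields ``found=False`` rather than an
    error.
    """
    if not cell_outline.any():
        raise ValueError("cell outline is empty")
    proj = gfp_stack.max(axis=0).astype(float)
    outside = ~cell_outline
    if background is None:
        background = float(np.median(proj[outside])) if outside.any() else float(
            np.median(proj)
        )
    corrected = np.clip(proj - background, 0.0, None)

    vals = corrected[cell_outline]
    if np.allclose(vals, vals[0]):
        return GBodySegmentation(found=False)
    thresh = threshold_otsu(vals)
    binary = (corrected > thresh) & cell_outline
    if not binary.any():
        return GBodySegmentation(found=False)

    comps = label_components(binary)
    best_lab, best_key = None, None
    for lab in range(1, comps.max() + 1):
        m = comps == lab
        key = (int(m.sum()), float(corrected[m].sum()))  # area, then intensity
        if best_key is None or key > best_key:
            best_lab, best_key = lab, key
    mask = comps == best_lab
    w = corrected[mask]
    rr, cc = np.nonzero(mask)
    center = (float((rr * w).sum() / w.sum()), float((cc * w).sum() / w.sum()))

    # most in-focus slice: variance of the Laplacian within the outline
    focus = [
        float(np.var(ndimage.laplace(sl.astype(float))[cell_outline]))
        for sl in gfp_stack
    ]
    return GBodySegmentation(
        found=True,
        center=center,
        slice_index=int(np.argmax(focus)),
        mask=mask,
    )


def select_spots_near_plane(spots: np.ndarray, gbody_slice: int) -> np.ndarray:
    """Retain (row, col, z) spots with \\|z - gbody_slice\\| <= 1."""
    spots = np.asarray(spots, dtype=float).reshape(-1, 3)
    return spots[np.abs(spots[:, 2] - gbody_slice) <= 1]


def spot_footprints(
    image: np.ndarray,
    peaks: np.ndarray,
    threshold: float,
) -> list[np.ndarray]:
    """Footprint of each spot: the maximum pixel plus its 8-connected
    neighbors above ``threshold``.  Returns one (k, 2) pixel array per
    peak."""
    H, W = image.shape
    out = []
    for r, c in np.asarray(peaks, dtype=int).reshape(-1, 2):
        pts = [(r, c)]
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                rr, cc = r + dr, c + dc
                if 0 <= rr < H and 0 <= cc < W and image[rr, cc] > threshold:
                    pts.append((rr, cc))
        out.append(np.array(pts, dtype=int))
    return out


@dataclass
class DistanceProfile:
    """Sorted in-plane distances (µm) from the G-body center."""

    distances: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.distances = np.sort(np.asarray(self.distances, dtype=float))
        if self.distances.size and self.distances[0] < 0:
            raise ValueError("distances must be >= 0")

    @property
    def n(self) -> int:
        return int(self.distances.size)

    @property
    def percent_within_one_pixel(self) -> float:
        """Percent of points with distance <= one pixel (boundary
        inclusive)."""
        if self.n == 0:
            return float("nan")
        return 100.0 * float(
            (self.distances <= self.pixel_size + 1e-12).sum()
        ) / self.n

    def ecdf(self, d) -> np.ndarray:
        """Right-continuous ECDF evaluated at distances ``d``."""
        return np.searchsorted(self.distances, np.atleast_1d(d), side="right") / max(
            self.n, 1
        )

    @staticmethod
    def pooled(profiles: list["DistanceProfile"]) -> "DistanceProfile":
        """Pool distance distributions across experiments."""
        if not profiles:
            raise ValueError("nothing to pool")
        px = {p.pixel_size for p in profiles}
        if len(px) != 1:
            raise ValueError("cannot pool profiles with differing pixel sizes")
        return DistanceProfile(
            distances=np.concatenate([p.distances for p in profiles]),
            pixel_size=profiles[0].pixel_size,
        )


def distance_profile(
    center: tuple[float, float],
    points: np.ndarray,
    pixel_size: float,
    nearest_only: bool = False,
) -> DistanceProfile:
    """In-plane Euclidean distances (µm) from the G-body center.

    ``points`` is an (n, 2) array of (row, col) pixel coordinates — every
    pixel of every spot footprint by default.  With ``nearest_only`` the
    caller should pass per-spot footprints via :func:`spot_footprints` and
    reduce beforehand; here the flag simply keeps the single nearest point
    of the provided set per call.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if pts.size == 0:
        return DistanceProfile(distances=np.empty(0), pixel_size=pixel_size)
    d = np.hypot(pts[:, 0] - center[0], pts[:, 1] - center[1]) * pixel_size
    if nearest_only:
        d = d[[int(np.argmin(d))]]
    return DistanceProfile(distances=d, pixel_size=pixel_size)


def cdf_fold_change(
    target: DistanceProfile,
    control: DistanceProfile,
    grid: np.ndarray,
) -> np.ndarray:
    """ECDF_target(d) / ECDF_control(d) on ``grid``; NaN where the control
    ECDF is zero."""
    if target.n == 0 or control.n == 0:
        raise ValueError("profiles must be non-empty")
    grid = np.asarray(grid, dtype=float)
    num = target.ecdf(grid)
    den = control.ecdf(grid)
    out = np.full(grid.shape, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out
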
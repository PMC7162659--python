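"""Fluorescent puncta detection and rotated 2D-Gaussian fitting.

A focus is modeled as

    f(x, y) = b + A * exp(-(a*(x-x0)^2 + 2*c*(x-x0)*(y-y0) + d*(y-y0)^2))

with a = cos^2(th)/(2 sx^2) + sin^2(th)/(2 sy^2),
     c = -sin(2 th)/(4 sx^2) + sin(2 th)/(4 sy^2),
     d = sin^2(th)/(2 sx^2) + cos^2(th)/(2 sy^2),

the standard rotated-Gaussian quadratic form: b baseline, A peak
amplitude, (x0, y0) center, (sx, sy) axis standard deviations and th the
rotation.  Fitting is by bounded nonlinear least squares; th is reported
modulo pi and zeroed (with a flag) for circular puncta where it is
unidentifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from skimage.feature import peak_local_max

__all__ = [
    "PunctumFit",
    "gaussian2d",
    "detect_maxima",
    "extract_patch",
    "subtract_background",
    "fit_gaussian2d",
    "classify_cells",
    "compare_conditions",
]


def gaussian2d(x, y, b, A, x0, y0, sigma_x, sigma_y, theta):
    """Evaluate the rotated 2D Gaussian at coordinates (x, y)."""
    ct, st = np.cos(theta), np.sin(theta)
    s2 = np.sin(2.0 * theta)
    a = ct**2 / (2.0 * sigma_x**2) + st**2 / (2.0 * sigma_y**2)
    c = -s2 / (4.0 * sigma_x**2) + s2 / (4.0 * sigma_y**2)
    d = st**2 / (2.0 * sigma_x**2) + ct**2 / (2.0 * sigma_y**2)
    dx = x - x0
    dy = y - y0
    return b + A * np.exp(-(a * dx**2 + 2.0 * c * dx * dy + d * dy**2))


def robust_noise_sd(image: np.ndarray) -> float:
    """Noise scale from the median absolute deviation (normal-consistent)."""
    if image.size == 0:
        return 0.0
    return float(stats.median_abs_deviation(image, axis=None, scale="normal"))


def detect_maxima(
    image: np.ndarray,
    prominence: float | None = None,
    min_distance: int = 3,
) -> np.ndarray:
    """Strict local maxima exceeding the image baseline by >= prominence.

    ``prominence`` defaults to five times the MAD-based noise sd; the
    baseline is the image median.  Maxima within ``min_distance`` px of a
    brighter maximum are merged into it.  Returns (n, 2) array of
    (row, col) coordinates, possibly empty.
    """
    image = np.asarray(image, dtype=float)
    if prominence is None:
        prominence = 5.0 * robust_noise_sd(image)
    baseline = float(np.median(image))
    peaks = peak_local_max(
        image,
        min_distance=min_distance,
        threshold_abs=baseline + prominence,
        exclude_border=False,
    )
    # peak_local_max admits plateau maxima; keep only strictly dominant peaks
    out = []
    H, W = image.shape
    for r, c in peaks:
        lo_r, hi_r = max(0, r - 1), min(H, r + 2)
        lo_c, hi_c = max(0, c - 1), min(W, c + 2)
        patch = image[lo_r:hi_r, lo_c:hi_c]
        if np.sum(patch == image[r, c]) == 1:
            out.append((r, c))
    return np.array(out, dtype=int).reshape(-1, 2)


def extract_patch(
    image: np.ndarray,
    center: tuple[int, int],
    side_um: float = 4.9,
    pixel_size: float = 0.13,
) -> tuple[np.ndarray, tuple[int, int], bool]:
    """Square patch of side ``round(side_um / pixel_size)`` px around a
    maximum, clipped at the borders.

    Returns (patch, (row_origin, col_origin), clipped_flag).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    H, W = image.shape
    r, c = center
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError("center outside image")
    side = max(1, round(side_um / pixel_size))
    half = side // 2
    r0, r1 = r - half, r - half + side
    c0, c1 = c - half, c - half + side
    clipped = r0 < 0 or c0 < 0 or r1 > H or c1 > W
    r0, c0 = max(0, r0), max(0, c0)
    r1, c1 = min(H, r1), min(W, c1)
    return image[r0:r1, c0:c1], (r0, c0), clipped


def subtract_background(
    image: np.ndarray,
    boxes: list[tuple[int, int, int, int]],
) -> tuple[np.ndarray, float]:
    """Subtract the mean intensity over background boxes, flooring at 0.

    Boxes are (row0, row1, col0, col1), half-open.  Overlapping boxes only
    warn.  Returns (corrected image, background value).
    """
    H, W = image.shape
    masks = []
    for (r0, r1, c0, c1) in boxes:
        if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
            raise ValueError(f"background box {(r0, r1, c0, c1)} outside image")
        m = np.zeros((H, W), dtype=bool)
        m[r0:r1, c0:c1] = True
        masks.append(m)
    for i in range(len(masks)):
        for j in range(i + 1, len(masks)):
            if (masks[i] & masks[j]).any():
                warnings.warn("background boxes overlap", stacklevel=2)
    union = np.zeros((H, W), dtype=bool)
    pixels = []
    for m in masks:
        pixels.append(image[m])
        union |= m
    background = float(np.mean(np.concatenate(pixels)))
    return np.clip(image - background, 0.0, None), background


@dataclass
class PunctumFit:
    """Fitted rotated-Gaussian parameters for one focus."""

    b: float
    A: float
    x0: float
    y0: float
    sigma_x: float  # px
    sigma_y: float  # px
    theta: float  # radians in [0, pi)
    residual_norm: float
    converged: bool
    circular: bool = False
    pixel_size: float | None = None

    @property
    def sigma_x_um(self) -> float | None:
        return None if self.pixel_size is None else self.sigma_x * self.pixel_size

    @property
    def sigma_y_um(self) -> float | None:
        return None if self.pixel_size is None else self.sigma_y * self.pixel_size

    @property
    def integrated_intensity(self) -> float:
        """Total fitted signal above baseline: 2*pi*A*sigma_x*sigma_y."""
        return 2.0 * np.pi * self.A * self.sigma_x * self.sigma_y


def fit_gaussian2d(
    patch: np.ndarray,
    pixel_size: float | None = None,
    circular_tol: float = 0.01,
) -> PunctumFit:
    """Nonlinear least-squares fit of the rotated 2D Gaussian to a patch.

    Initialization: b = patch border median, A = max - b, (x0, y0) =
    centroid of the top-decile pixels, sigma_x = sigma_y = side/6,
    theta = 0.  Bounds: sigma in [0.5 px, side], A >= 0.  Non-convergence
    is flagged, never raised; when the fitted axes differ by less than
    ``circular_tol`` relative, theta is reported as 0 with
    ``circular=True``.
    """
    patch = np.asarray(patch, dtype=float)
    if patch.shape[0] < 5 or patch.shape[1] < 5:
        raise ValueError("patch must be at least 5x5 px")
    H, W = patch.shape
    side = float(max(H, W))
    yy, xx = np.mgrid[0:H, 0:W].astype(float)

    border = np.concatenate([patch[0], patch[-1], patch[1:-1, 0], patch[1:-1, -1]])
    b0 = float(np.median(border))
    A0 = max(float(patch.max() - b0), 1e-6)
    top = patch >= np.quantile(patch, 0.9)
    x0 = float((xx[top] * patch[top]).sum() / patch[top].sum())
    y0 = float((yy[top] * patch[top]).sum() / patch[top].sum())
    p0 = [b0, A0, x0, y0, side / 6.0, side / 6.0, 0.0]
    lower = [-np.inf, 0.0, -side, -side, 0.5, 0.5, -np.pi]
    upper = [np.inf, np.inf, 2 * side, 2 * side, side, side, np.pi]

    def residuals(p):
        return (gaussian2d(xx, yy, *p) - patch).ravel()

    result = optimize.least_squares(
        residuals, p0, bounds=(lower, upper), xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    b, A, cx, cy, sx, sy, th = result.x
    th = float(np.mod(th, np.pi))
    circular = abs(sx - sy) / max(sx, 1e-12) < circular_tol
    if circular:
        th = 0.0
    return PunctumFit(
        b=float(b),
        A=float(A),
        x0=float(cx),
        y0=float(cy),
        sigma_x=float(sx),
        sigma_y=float(sy),
        theta=th,
        residual_norm=float(np.linalg.norm(result.fun)),
        converged=bool(result.success),
        circular=bool(circular),
        pixel_size=pixel_size,
    )


def classify_cells(
    cell_masks: np.ndarray,
    detections: np.ndarray,
    min_cells: int = 100,
) -> tuple[pd.Series, dict[str, float], int]:
    """Classify cells as single / multiple / none by accepted puncta count.

    ``cell_masks`` is a label image (0 = background); ``detections`` is an
    (n, 2) array of (row, col) puncta coordinates.  Returns the per-cell
    counts, the fractions over {single, multiple, none} (summing to 1),
    and the number of detections falling outside every cell.
    """
    labels = np.unique(cell_masks)
    labels = labels[labels != 0]
    if labels.size < min_cells:
        warnings.warn(
            f"only {labels.size} cells; at least {min_cells} per replicate "
            "are recommended",
            stacklevel=2,
        )
    counts = pd.Series(0, index=pd.Index(labels, name="cell"), dtype=int)
    outside = 0
    for r, c in np.asarray(detections, dtype=int).reshape(-1, 2):
        lab = int(cell_masks[r, c])
        if lab == 0:
            outside += 1
        else:
            counts[lab] += 1
    n = max(len(counts), 1)
    fractions = {
        "single": float((counts == 1).sum()) / n,
        "multiple": float((counts >= 2).sum()) / n,
        "none": float((counts == 0).sum()) / n,
    }
    return counts, fractions, outside


def compare_conditions(
    fractions: dict[str, np.ndarray],
    comparisons: list[tuple[str, str]] | None = None,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Unpaired two-sided t-tests on replicate-level fractions with a
    Bonferroni correction over the requested comparisons."""
    if comparisons is None:
        import itertools

        comparisons = list(itertools.combinations(sorted(fractions), 2))
    m = len(comparisons)
    rows = []
    for a, b in comparisons:
        xa = np.asarray(fractions[a], dtype=float)
        xb = np.asarray(fractions[b], dtype=float)
        if xa.size < 2 or xb.size < 2:
            raise ValueError("need >= 2 replicates per condition")
        res = stats.ttest_ind(xa, xb, equal_var=equal_var)
        p = 1.0 if not np.isfinite(res.pvalue) else float(res.pvalue)
        rows.append((a, b, float(res.statistic) if np.isfinite(res.statistic) else 0.0,
                     p, min(1.0, m * p)))
    return pd.DataFrame(
        rows, columns=["cond_a", "cond_b", "t", "p", "p_bonferroni"]
    )
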
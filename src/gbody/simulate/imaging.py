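"""Synthetic fluorescence image stacks with planted puncta and mRNA spots.

A stack is rendered slice by slice: disk-shaped cells contribute a uniform
baseline, each punctum contributes a rotated 2D Gaussian modulated by a
Gaussian axial profile (so the in-focus slice evaluates to ``b + A`` at the
punctum center in the noiseless limit), and mRNA spots contribute small
circular Gaussians in a second channel.  Poisson noise and Gaussian read
noise are applied last, reproducibly from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gbody.puncta import gaussian2d

__all__ = ["CellDescriptor", "PunctumTruth", "SyntheticStack", "simulate_image_stack"]


@dataclass(frozen=True)
class CellDescriptor:
    """A disk-shaped cell: center (row, col) in px, radius in px, baseline."""

    center: tuple[float, float]
    radius: float
    baseline: float = 0.0
    label: int = 1


@dataclass(frozen=True)
class PunctumTruth:
    """Ground-truth parameters of one planted punctum.

    ``b`` is the local baseline at the punctum (cell baseline plus global
    background); ``x0, y0`` are (col, row)-style center coordinates in px
    to match the fitted parameterization; ``z0``/``sigma_z`` give the axial
    position and extent in slices.
    """

    A: float
    x0: float
    y0: float
    sigma_x: float
    sigma_y: float
    theta: float = 0.0
    b: float = 0.0
    z0: float = 0.0
    sigma_z: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0 or self.sigma_z <= 0:
            raise ValueError("sigma must be > 0")
        if self.A < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass
class SyntheticStack:
    """Rendered stack(s) plus the truth records used to render them."""

    channels: dict[str, np.ndarray]  # each (n_slices, H, W) float
    pixel_size: float  # µm
    cells: list[CellDescriptor] = field(default_factory=list)
    puncta: list[PunctumTruth] = field(default_factory=list)
    spots: list[tuple[float, float, int]] = field(default_factory=list)

    def cell_label_image(self, shape: tuple[int, int]) -> np.ndarray:
        rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
        labels = np.zeros(shape, dtype=int)
        for cell in self.cells:
            mask = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= cell.radius**2
            labels[mask] = cell.label
        return labels


def _render_base(shape, cells):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape, dtype=float)
    for cell in cells:
        mask = (rr - cell.center[0]) ** 2 + (cc - cell.center[1]) ** 2 <= cell.radius**2
        img[mask] += cell.baseline
    return img


def simulate_image_stack(
    cells: list[CellDescriptor],
    puncta: list[PunctumTruth],
    spots: list[tuple[float, float, int]] | None = None,
    shape: tuple[int, int, int] = (5, 128, 128),
    noise_model: tuple[float, bool] = (0.0, False),
    pixel_size: float = 0.13,
    background: float = 0.0,
    spot_amplitude: float = 300.0,
    spot_sigma: float = 1.0,
    seed: int | None = None,
) -> SyntheticStack:
    """Render a multi-slice stack (and a FISH channel when ``spots`` given).

    ``noise_model`` is ``(gaussian_sd, poisson_flag)``.  ``pixel_size``
    defaults to 0.13 µm.  Punctum centers must lie inside image bounds.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    n_slices, H, W = shape
    for p in puncta:
        if not (0 <= p.x0 < W and 0 <= p.y0 < H):
            raise ValueError("punctum center outside image bounds")

    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    base = _render_base((H, W), cells) + background

    gfp = np.empty((n_slices, H, W), dtype=float)
    for z in range(n_slices):
        img = base.copy()
        for p in puncta:
            axial = np.exp(-((z - p.z0) ** 2) / (2.0 * p.sigma_z**2))
            img += axial * gaussian2d(
                xx, yy, 0.0, p.A, p.x0, p.y0, p.sigma_x, p.sigma_y, p.theta
            )
        gfp[z] = img

    channels = {"gfp": gfp}
    if spots is not None:
        fish = np.tile(base, (n_slices, 1, 1))
        for (sx, sy, sz) in spots:
            if not (0 <= sx < W and 0 <= sy < H and 0 <= sz < n_slices):
                raise ValueError("spot outside stack bounds")
            fish[int(sz)] += gaussian2d(
                xx, yy, 0.0, spot_amplitude, sx, sy, spot_sigma, spot_sigma, 0.0
            )
        channels["fish"] = fish

    sd, poisson = noise_model
    for name, stack in channels.items():
        noisy = stack
        if poisson:
            noisy = rng.poisson(np.clip(noisy, 0, None)).astype(float)
        if sd > 0:
            noisy = noisy + rng.normal(0.0, sd, size=noisy.shape)
        channels[name] = noisy

    return SyntheticStack(
        channels=channels,
        pixel_size=pixel_size,
        cells=list(cells),
        puncta=list(puncta),
        spots=list(spots) if spots is not None else [],
    )
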
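"""Synthetic FRAP traces with acquisition photobleaching.

The bleached granule follows I(t) = I_post + (I_pre - I_post) * A * (1 -
exp(-tau * t)) after the bleach frame; every acquired frame (bleached and
control series alike) is additionally attenuated by a per-frame
multiplicative acquisition-bleaching factor, offset by a constant
background, and corrupted by Gaussian noise.
"""

from __future__ import annotations

import numpy as np

from gbody.frap import FrapTrace

__all__ = ["simulate_frap_trace"]


def simulate_frap_trace(
    A_true: float,
    tau_true: float,
    bleach_depth: float = 0.8,
    acquisition_bleach_rate: float = 0.0,
    n_controls: int = 3,
    noise_sd: float = 0.0,
    n_frames: int = 46,
    dt: float = 1.0,
    pre_bleach_frames: int = 5,
    background: float = 50.0,
    intensity_scale: float = 1000.0,
    seed: int | None = None,
) -> FrapTrace:
    """Simulate one bleached trace plus ``n_controls`` unbleached controls.

    ``A_true`` is the mobile (recovered) fraction of the bleached signal,
    ``tau_true`` the recovery rate per minute, ``bleach_depth`` the
    fraction of signal destroyed by the bleach pulse, and
    ``acquisition_bleach_rate`` the per-frame fractional loss applied
    multiplicatively to all series.  Times are in minutes at ``dt``
    spacing with the bleach at frame ``pre_bleach_frames``.
    """
    if not 0.0 <= A_true <= 1.0:
        raise ValueError("A_true must be in [0, 1]")
    if tau_true <= 0:
        raise ValueError("tau_true must be > 0")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")

    rng = np.random.default_rng(seed)
    times = np.arange(n_frames, dtype=float) * dt
    decay = (1.0 - acquisition_bleach_rate) ** np.arange(n_frames)

    I_pre, I_post = 1.0, 1.0 - bleach_depth
    truth = np.full(n_frames, I_pre)
    t_rel = times[pre_bleach_frames:] - times[pre_bleach_frames]
    truth[pre_bleach_frames:] = I_post + (I_pre - I_post) * A_true * (
        1.0 - np.exp(-tau_true * t_rel)
    )

    def corrupt(series):
        out = intensity_scale * series * decay + background
        if noise_sd > 0:
            out = out + rng.normal(0.0, noise_sd * intensity_scale, size=n_frames)
        return out

    intensity = corrupt(truth)
    controls = np.vstack([corrupt(np.full(n_frames, I_pre)) for _ in range(n_controls)])
    return FrapTrace(
        times=times,
        intensity=intensity,
        controls=controls,
        background=background,
        bleach_index=pre_bleach_frames,
    )
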
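"""FRAP trace correction and exponential recovery fitting.

A trace records granule intensity at 1-min frames with a bleach pulse at
``bleach_index``.  Correction subtracts background, divides frame-wise by
the mean of (at least three) unbleached control cells — each control first
normalized to its own pre-bleach mean — and rescales so the pre-bleach
level is 1 and the first post-bleach frame is 0.  Recovery is fit to

    I(t) = A * (1 - exp(-tau * t))

over post-bleach frames within the fit window (40 min by default, 25 min
in plasmid mode); the half-time is ln(2) / tau.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

__all__ = [
    "FrapTrace",
    "RecoveryFit",
    "correct_trace",
    "average_traces",
    "filter_bleach_depth",
    "fit_recovery",
    "track_granule",
]


@dataclass
class FrapTrace:
    times: np.ndarray  # minutes, strictly increasing
    intensity: np.ndarray  # raw bleached-granule intensities (A.U.)
    controls: np.ndarray  # (n_controls, n_frames) raw control intensities
    background: float
    bleach_index: int
    corrected: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.controls = np.atleast_2d(np.asarray(self.controls, dtype=float))
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not 0 < self.bleach_index < self.times.size:
            raise ValueError("bleach index out of range")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)


def correct_trace(trace: FrapTrace) -> FrapTrace:
    """Background-subtract, photobleach-correct and 0–1 rescale a trace."""
    if trace.controls.shape[0] < 3:
        raise ValueError("need >= 3 unbleached control series")
    sig = trace.intensity - trace.background
    ctrl = trace.controls - trace.background
    pre = slice(0, trace.bleach_index)
    ctrl_norm = ctrl / ctrl[:, pre].mean(axis=1, keepdims=True)
    decay = ctrl_norm.mean(axis=0)
    corrected = sig / decay
    pre_level = corrected[pre].mean()
    post0 = corrected[trace.bleach_index]
    if pre_level == post0:
        raise ValueError("no bleach detected: pre- and post-bleach levels equal")
    normalized = (corrected - post0) / (pre_level - post0)
    return replace(trace, corrected=normalized)


def average_traces(traces: list[FrapTrace]) -> FrapTrace:
    """Frame-wise mean of corrected, normalized traces (replicate
    averaging precedes the recovery fit)."""
    if not traces:
        raise ValueError("nothing to average")
    corrected = []
    for tr in traces:
        if tr.corrected is None:
            tr = correct_trace(tr)
        corrected.append(tr.corrected)
    first = traces[0]
    for tr in traces[1:]:
        if tr.n_frames != first.n_frames or tr.bleach_index != first.bleach_index:
            raise ValueError("traces must share frame grid and bleach index")
    return replace(first, corrected=np.mean(corrected, axis=0))


def filter_bleach_depth(trace: FrapTrace, max_remaining: float = 0.40) -> bool:
    """Keep a trace only when < ``max_remaining`` of the fluorescence
    remains right after the bleach (background-subtracted, before the
    0–1 rescaling); the boundary is strict."""
    sig = trace.intensity - trace.background
    pre_level = sig[: trace.bleach_index].mean()
    remaining = sig[trace.bleach_index] / pre_level
    return bool(remaining < max_remaining)


@dataclass
class RecoveryFit:
    A: float  # recovered fraction of the bleached signal
    tau: float  # per minute
    half_time: float  # ln(2)/tau, minutes
    t_max: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.tau > 0 and not np.isclose(self.half_time, np.log(2.0) / self.tau):
            raise ValueError("half_time must equal ln(2)/tau")


def fit_recovery(
    trace: FrapTrace,
    t_max: float = 40.0,
    plasmid_mode: bool = False,
    min_points: int = 5,
) -> RecoveryFit:
    """Least-squares fit of A(1 - exp(-tau t)) to post-bleach frames.

    Times are measured from the bleach frame; only frames with
    t <= ``t_max`` enter the fit (25 min when ``plasmid_mode`` — the
    shortened window for acquisitions that photobleach too fast to trust
    later frames).  A flat trace leaves tau unidentifiable: flagged
    unconverged, parameters retained.
    """
    if trace.corrected is None:
        trace = correct_trace(trace)
    if plasmid_mode:
        t_max = min(t_max, 25.0)
    t = trace.times[trace.bleach_index :] - trace.times[trace.bleach_index]
    y = trace.corrected[trace.bleach_index :]
    keep = t <= t_max
    t, y = t[keep], y[keep]
    if t.size < min_points:
        raise ValueError(f"need >= {min_points} post-bleach frames within t_max")

    A0 = float(np.clip(y[-3:].mean(), 1e-3, 1.5))
    half_guess = t[np.argmax(y >= 0.5 * A0)] if np.any(y >= 0.5 * A0) else t[-1] / 2
    tau0 = np.log(2.0) / max(float(half_guess), t[1] if t.size > 1 else 1.0)

    def model(tt, A, tau):
        return A * (1.0 - np.exp(-tau * tt))

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            y,
            p0=[A0, tau0],
            bounds=([0.0, 1e-9], [1.5, np.inf]),
            maxfev=10_000,
        )
        A_fit, tau_fit = float(popt[0]), float(popt[1])
    except RuntimeError:
        converged = False
        A_fit, tau_fit = A0, tau0
    if A_fit < 1e-3:  # tau unidentifiable on a flat trace
        converged = False
    return RecoveryFit(
        A=A_fit,
        tau=tau_fit,
        half_time=float(np.log(2.0) / tau_fit),
        t_max=float(t_max),
        converged=converged,
        n_points=int(t.size),
    )


def _disk_sum(frame: np.ndarray, center: tuple[int, int], radius: int) -> float:
    H, W = frame.shape
    r0, c0 = center
    rr, cc = np.mgrid[0:H, 0:W]
    return float(frame[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2].sum())


def track_granule(
    stack_series: np.ndarray,
    initial_center: tuple[int, int],
    bleach_index: int,
    search_radius: int = 3,
    radius_grid: range = range(1, 11),
    noise_floor: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Track a granule and measure per-frame intensity in a circle.

    Per frame, the circle is re-centered on the brightest pixel within
    ``search_radius`` of the previous center.  The radius is chosen once,
    on the bleach frame, as the argmax over ``radius_grid`` of the percent
    of signal bleached (1 - post/pre within the circle).  Returns
    (intensities, centers, radius); the trace is truncated with the
    remaining frames NaN when the local maximum falls below
    ``noise_floor``.
    """
    T, H, W = stack_series.shape
    centers = np.zeros((T, 2), dtype=int)
    center = tuple(initial_center)

    def recenter(frame, c):
        r0, c0 = c
        lo_r, hi_r = max(0, r0 - search_radius), min(H, r0 + search_radius + 1)
        lo_c, hi_c = max(0, c0 - search_radius), min(W, c0 + search_radius + 1)
        sub = frame[lo_r:hi_r, lo_c:hi_c]
        idx = np.unravel_index(np.argmax(sub), sub.shape)
        return (lo_r + int(idx[0]), lo_c + int(idx[1])), float(sub.max())

    # radius chosen once, on the bleach frame, maximizing the bleached
    # fraction; ties within 2% resolve to the largest radius so the circle
    # covers the whole granule
    pre_center, _ = recenter(stack_series[bleach_index - 1], center)
    post_center, _ = recenter(stack_series[bleach_index], pre_center)
    fracs = []
    for r in radius_grid:
        pre = _disk_sum(stack_series[bleach_index - 1], pre_center, r)
        post = _disk_sum(stack_series[bleach_index], post_center, r)
        fracs.append(1.0 - post / pre if pre > 0 else -np.inf)
    best = max(fracs)
    radius = int(max(r for r, f in zip(radius_grid, fracs) if f >= best - 0.02 * abs(best)))

    intensities = np.full(T, np.nan)
    lost = False
    for f in range(T):
        if lost:
            break
        center, peak = recenter(stack_series[f], center)
        if peak < noise_floor:
            lost = True
            break
        centers[f] = center
        intensities[f] = _disk_sum(stack_series[f], center, radius)
    return intensities, centers, radius
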
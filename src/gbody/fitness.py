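"""Competition-fitness estimation from G-body phenotype frequencies.

Mixing a G-body-forming strain (GB+) with a non-forming strain (GB-) and
scoring the percent of cells with G bodies in the mixed and pure cultures
identifies the GB+ fraction of the mix:

    f_GB+ = (%mix - %GB-) / (%GB+ - %GB-)

Generations of growth come from the optical-density increase,
n = log2(OD_end / OD_start).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompetitionObservation",
    "FractionEstimate",
    "fraction_gb_plus",
    "generations",
]


@dataclass
class CompetitionObservation:
    """G-body percentages in the mixed and pure cultures.

    ``n_cells`` (cells scored per arm) enables bootstrap intervals;
    OD/CFU fields are optional metadata.
    """

    pct_mix: float
    pct_gb_plus: float
    pct_gb_minus: float
    n_cells: int | None = None
    od_start: float | None = None
    od_end: float | None = None
    cfu_per_ml: float | None = None

    def __post_init__(self) -> None:
        for name in ("pct_mix", "pct_gb_plus", "pct_gb_minus"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be a percentage in [0, 100]")


@dataclass
class FractionEstimate:
    f_gb_plus: float
    clipped: bool
    ci_low: float | None = None
    ci_high: float | None = None


def _point_estimate(pct_mix, pct_plus, pct_minus):
    denom = pct_plus - pct_minus
    if denom == 0:
        raise ValueError("non-identifiable: pct_gb_plus equals pct_gb_minus")
    return (pct_mix - pct_minus) / denom


def fraction_gb_plus(
    obs: CompetitionObservation,
    n_boot: int = 1000,
    ci: float = 0.95,
    seed: int | None = None,
) -> FractionEstimate:
    """Estimate the GB+ fraction of the mixed culture.

    The point estimate follows the closed-form inversion above; estimates
    pushed outside [0, 1] by sampling noise are clipped with a warning and
    flag.  When ``obs.n_cells`` is known, a percentile bootstrap over
    cell-level Bernoulli counts supplies an interval.
    """
    f = _point_estimate(obs.pct_mix, obs.pct_gb_plus, obs.pct_gb_minus)
    clipped = not (0.0 <= f <= 1.0)
    if clipped:
        warnings.warn(
            f"estimate {f:.3f} outside [0, 1]; clipped (sampling noise)",
            stacklevel=2,
        )
        f = float(np.clip(f, 0.0, 1.0))
    lo = hi = None
    if obs.n_cells is not None and n_boot > 0:
        rng = np.random.default_rng(seed)
        n = obs.n_cells
        boots = np.empty(n_boot)
        for i in range(n_boot):
            mix = rng.binomial(n, obs.pct_mix / 100.0) / n * 100.0
            plus = rng.binomial(n, obs.pct_gb_plus / 100.0) / n * 100.0
            minus = rng.binomial(n, obs.pct_gb_minus / 100.0) / n * 100.0
            if plus == minus:
                boots[i] = np.nan
                continue
            boots[i] = np.clip((mix - minus) / (plus - minus), 0.0, 1.0)
        alpha = (1.0 - ci) / 2.0
        lo = float(np.nanquantile(boots, alpha))
        hi = float(np.nanquantile(boots, 1.0 - alpha))
    return FractionEstimate(f_gb_plus=float(f), clipped=clipped, ci_low=lo, ci_high=hi)


def generations(od_start: float, od_end: float) -> float:
    """Generations of growth from the OD increase: log2(OD_end/OD_start)."""
    if od_start <= 0 or od_end <= 0:
        raise ValueError("ODs must be positive")
    if od_end < od_start:
        raise ValueError("od_end must be >= od_start")
    return float(np.log2(od_end / od_start))
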
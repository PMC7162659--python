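"""Binomially sampled growth-competition observations.

Each culture arm (mixed, GB+ alone, GB- alone) scores ``n_cells`` cells
for the presence of G bodies.  The expected mixed-culture percentage is
``f_true * pct_gb_plus + (1 - f_true) * pct_gb_minus``.
"""

from __future__ import annotations

import numpy as np

from gbody.fitness import CompetitionObservation

__all__ = ["simulate_competition"]


def simulate_competition(
    f_true: float,
    pct_gb_plus: float = 90.0,
    pct_gb_minus: float = 10.0,
    n_cells: int = 1000,
    seed: int | None = None,
) -> CompetitionObservation:
    """Draw one competition observation with binomial counting noise."""
    if not 0.0 <= f_true <= 1.0:
        raise ValueError("f_true must be in [0, 1]")
    if pct_gb_plus == pct_gb_minus:
        raise ValueError("pct_gb_plus must differ from pct_gb_minus")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    p_mix = (f_true * pct_gb_plus + (1.0 - f_true) * pct_gb_minus) / 100.0
    k_mix = int(rng.binomial(n_cells, p_mix))
    k_plus = int(rng.binomial(n_cells, pct_gb_plus / 100.0))
    k_minus = int(rng.binomial(n_cells, pct_gb_minus / 100.0))
    return CompetitionObservation(
        pct_mix=100.0 * k_mix / n_cells,
        pct_gb_plus=100.0 * k_plus / n_cells,
        pct_gb_minus=100.0 * k_minus / n_cells,
        n_cells=n_cells,
    )
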
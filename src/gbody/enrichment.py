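"""G-body RIP-seq enrichment, qPCR percent-of-input, and overlap tests.

Gene tables are pandas DataFrames indexed by gene_id with one column per
replicate library.  RPM normalization, replicate averaging, fold/p
computation, the two-screen high-confidence intersection, the chi-square
overlap test against CLIP target sets, and the spectral-count mRBP
membership rule all live here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CqRecord",
    "normalize_rpm",
    "replicate_correlation",
    "enrichment_test",
    "high_confidence_set",
    "overlap_chisq",
    "qpcr_percent_input",
    "classify_mrbp",
]


def normalize_rpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Reads-per-million normalization within each library (column).

    RPM_g = count_g * 1e6 / sum(counts); columns sum to 1e6.
    """
    if (counts < 0).any().any():
        raise ValueError("counts must be non-negative")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = list(totals.index[totals == 0])
        raise ValueError(f"all-zero libraries: {bad}")
    return counts * 1e6 / totals


def replicate_correlation(rpm: pd.DataFrame, pseudo: float = 0.5) -> pd.DataFrame:
    """Pairwise Pearson r of log10(RPM + pseudo) across replicate columns.

    Reported, never used as a gate.
    """
    log = np.log10(rpm + pseudo)
    rows = []
    for a, b in itertools.combinations(log.columns, 2):
        r = float(np.corrcoef(log[a], log[b])[0, 1])
        rows.append((a, b, r))
    return pd.DataFrame(rows, columns=["lib_a", "lib_b", "pearson_r"])


def enrichment_test(
    ip: pd.DataFrame,
    ref: pd.DataFrame,
    pseudo: float = 0.5,
    log_scale: bool = True,
    equal_var: bool = True,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change and two-sided unpaired t-test of IP vs reference.

    Inputs are RPM tables (one column per replicate).  The fold is the
    ratio of replicate-mean RPMs with ``pseudo`` added to both arms; the
    p-value is an unpaired Student's t-test (pooled variance; set
    ``equal_var=False`` for Welch) across replicates on log2(RPM + pseudo)
    (or linear RPM when ``log_scale=False``).  Genes with zero variance in
    both arms and equal means return p = 1 with ``zero_variance=True``
    rather than NaN.  ``bh=True`` adds a Benjamini–Hochberg ``p_adj``
    column (the screen itself keys on raw p by default).
    """
    if set(ip.index) != set(ref.index):
        diff = sorted(set(ip.index).symmetric_difference(ref.index))
        raise ValueError(f"mismatched gene universes: {diff[:10]}")
    if ip.shape[1] < 2 or ref.shape[1] < 2:
        raise ValueError("need >= 2 replicates per arm")
    ref = ref.loc[ip.index]

    ip_m = ip.mean(axis=1).to_numpy()
    ref_m = ref.mean(axis=1).to_numpy()
    fold = (ip_m + pseudo) / (ref_m + pseudo)

    a = np.log2(ip.to_numpy() + pseudo) if log_scale else ip.to_numpy()
    b = np.log2(ref.to_numpy() + pseudo) if log_scale else ref.to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = ~np.isfinite(p)
    p = np.where(zero_var, 1.0, p)
    out = pd.DataFrame(
        {"fold": fold, "p": p, "zero_variance": zero_var},
        index=ip.index,
    )
    if bh:
        out["p_adj"] = stats.false_discovery_control(p, method="bh")
    return out


def enriched_flags(
    result: pd.DataFrame, fold_thresh: float = 2.0, alpha: float = 0.05
) -> pd.Series:
    """Boolean enrichment call: fold > fold_thresh and p < alpha."""
    return (result["fold"] > fold_thresh) & (result["p"] < alpha)


def high_confidence_set(
    vs_ft: pd.DataFrame,
    vs_total: pd.DataFrame,
    fold_thresh: float = 2.0,
    alpha: float = 0.05,
) -> tuple[set[str], dict[str, int]]:
    """Genes passing both enrichment screens, plus per-screen counts."""
    ft_set = set(vs_ft.index[enriched_flags(vs_ft, fold_thresh, alpha)])
    tot_set = set(vs_total.index[enriched_flags(vs_total, fold_thresh, alpha)])
    both = ft_set & tot_set
    counts = {
        "vs_flow_through": len(ft_set),
        "vs_total": len(tot_set),
        "high_confidence": len(both),
    }
    return both, counts


def overlap_chisq(
    hits: set[str],
    universe: set[str],
    reference: set[str],
    correction: bool = False,
) -> dict[str, float]:
    """Chi-square test of the hits/reference overlap within a gene universe.

    Expected overlap = \\|hits\\| * \\|reference\\| / \\|universe\\|; the test is the
    1-df chi-square on the 2x2 membership table, without Yates continuity
    correction unless ``correction=True``.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not reference <= universe:
        raise ValueError("hits and reference must be subsets of the universe")
    n = len(universe)
    obs = len(hits & reference)
    expected = len(hits) * len(reference) / n
    table = np.array(
        [
            [obs, len(hits) - obs],
            [len(reference) - obs, n - len(hits) - len(reference) + obs],
        ],
        dtype=float,
    )
    col = table.sum(axis=0)
    row = table.sum(axis=1)
    exp_tab = np.outer(row, col) / n
    if correction:
        chi2 = float((((np.abs(table - exp_tab) - 0.5) ** 2) / exp_tab).sum())
    else:
        chi2 = float((((table - exp_tab) ** 2) / exp_tab).sum())
    p = float(stats.chi2.sf(chi2, df=1))
    return {
        "observed": float(obs),
        "expected": expected,
        "fold": obs / expected if expected > 0 else math.inf,
        "chi2": chi2,
        "p": p,
    }


@dataclass(frozen=True)
class CqRecord:
    """qPCR quantification cycles for one probe.

    ``ft_fraction`` is the fraction of the total flow-through that was
    assayed; its Cq is corrected downward by log2(1/fraction) cycles
    (2 cycles for the standard 25% aliquot) before the delta-Cq.
    """

    probe_id: str
    cq_eluate: float
    cq_flow_through: float
    ft_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.ft_fraction <= 1.0):
            raise ValueError("ft_fraction must be in (0, 1]")
        if not (
            math.isfinite(self.cq_eluate) and math.isfinite(self.cq_flow_through)
        ):
            raise ValueError("Cq values must be finite")
        if self.cq_eluate <= 0 or self.cq_flow_through <= 0:
            raise ValueError("Cq values must be positive")


def qpcr_cycle_correction(ft_fraction: float) -> float:
    """Cycles subtracted from the flow-through Cq for a partial aliquot."""
    if ft_fraction <= 0:
        raise ValueError("ft_fraction must be > 0")
    return math.log2(1.0 / ft_fraction)


def qpcr_percent_input(rec: CqRecord) -> float:
    """Percent of input recovered in the eluate, assuming efficiency-2
    amplification: 100 * 2^(corrected flow-through Cq - eluate Cq)."""
    corrected_ft = rec.cq_flow_through - qpcr_cycle_correction(rec.ft_fraction)
    return 100.0 * 2.0 ** (corrected_ft - rec.cq_eluate)


def classify_mrbp(
    spec_uv: int, spec_ctrl: int, fdr: float | None = None
) -> bool:
    """Spectral-count mRBP membership: (>2 counts with UV and 0 without)
    or FDR < 10% when an FDR is available."""
    if spec_uv < 0 or spec_ctrl < 0:
        raise ValueError("spectral counts must be >= 0")
    rule1 = spec_uv > 2 and spec_ctrl == 0
    rule2 = fdr is not None and fdr < 0.10
    return bool(rule1 or rule2)
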
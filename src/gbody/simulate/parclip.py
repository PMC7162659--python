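"""Simulated PAR-CLIP aligned reads with planted binding sites.

Two generators live here:

* :func:`simulate_parclip_reads` emits an aligned-read table (the BED-like
  TSV dialect the site caller consumes) in which reads covering planted
  sites carry T-to-C conversions at a stated per-read probability and
  diffuse background reads carry them at a lower rate.

* :func:`simulate_site_rpm_mixture` builds binding-site lists directly with
  RPM values drawn from a two-component mixture (low-coverage noise sites
  vs high-coverage signal sites), the planted input for threshold-recovery
  experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gbody.simulate.annotation import ToyAnnotation

__all__ = [
    "PlantedSiteTruth",
    "make_site_truth",
    "simulate_parclip_reads",
    "simulate_site_rpm_mixture",
]

READ_COLUMNS = [
    "chrom",
    "start",
    "end",
    "name",
    "conversion_count",
    "strand",
    "read_length",
    "dataset",
]


@dataclass
class PlantedSiteTruth:
    """Ground truth for one simulated PAR-CLIP dataset.

    ``signal_sites`` and ``noise_sites`` are lists of
    (chrom, strand, start, end).  Depths are mean per-position read
    coverage; conversion probabilities are the per-Bernoulli-trial rates
    used when drawing each read's conversion count (two trials per read,
    plus a rare third conversion at ``extra_conversion_rate`` of the
    site rate, so a probability-1 site yields conversion counts >= 2).
    """

    signal_sites: list[tuple[str, str, int, int]]
    noise_sites: list[tuple[str, str, int, int]] = field(default_factory=list)
    signal_depth: float = 50.0
    noise_depth: float = 2.0
    conversion_prob: float = 0.7
    background_conversion_prob: float = 0.005  # free parameter, see docs
    extra_conversion_rate: float = 0.05
    dataset_id: str = "sim"

    def __post_init__(self) -> None:
        if self.signal_depth <= self.noise_depth:
            raise ValueError("signal depth must exceed noise depth")
        for p in (self.conversion_prob, self.background_conversion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("conversion probabilities must be in [0, 1]")


def make_site_truth(
    annot: ToyAnnotation,
    n_signal: int,
    n_noise: int = 0,
    site_length: int = 40,
    seed: int | None = None,
    **kwargs,
) -> PlantedSiteTruth:
    """Plant non-overlapping sites inside genes of ``annot``."""
    rng = np.random.default_rng(seed)
    usable = [g for g in annot.genes if g.end - g.start > site_length]
    n = n_signal + n_noise
    if not usable:
        raise ValueError("no gene long enough to host a site")
    picks = rng.choice(len(usable), size=n, replace=n > len(usable))
    sites = []
    for gi in picks:
        g = usable[gi]
        start = int(rng.integers(g.start, g.end - site_length))
        sites.append((g.chrom, g.strand, start, start + site_length))
    return PlantedSiteTruth(
        signal_sites=sites[:n_signal], noise_sites=sites[n_signal:], **kwargs
    )


def _draw_conversions(rng: np.random.Generator, n: int, p: float, p_extra: float):
    base = rng.binomial(2, p, size=n)
    extra = rng.random(n) < p_extra
    return base + extra.astype(int)


def simulate_parclip_reads(
    annot: ToyAnnotation,
    truth: PlantedSiteTruth,
    total_reads: int | None = 100_000,
    read_length: int = 30,
    flank: int = 10,
    seed: int | None = None,
) -> pd.DataFrame:
    """Emit a coordinate-sorted aligned-read table.

    Reads over each planted site are Poisson in number (targeting the
    truth's mean per-position depth) with starts uniform inside the site,
    so the mean coverage over site positions matches the planted depth.
    Reads not assigned to sites are scattered uniformly over genes with the
    background conversion rate, topping the table up to ``total_reads``
    (``None`` emits site reads only).  Planted sites demanding more reads
    than ``total_reads`` raise an error.
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    p_extra_sig = truth.extra_conversion_rate * truth.conversion_prob

    def emit_site_reads(site, depth, p_conv, p_extra):
        chrom, strand, start, end = site
        length = end - start
        if read_length > length + flank:
            raise ValueError(
                f"read_length {read_length} exceeds site length {length} + flank {flank}"
            )
        n_reads = rng.poisson(depth * length / read_length)
        lo, hi = start, max(start + 1, end - read_length + 1)
        starts = rng.integers(lo, hi, size=n_reads)
        convs = _draw_conversions(rng, n_reads, p_conv, p_extra)
        for s, c in zip(starts, convs):
            rows.append((chrom, int(s), int(s) + read_length, strand, int(c)))

    for site in truth.signal_sites:
        emit_site_reads(site, truth.signal_depth, truth.conversion_prob, p_extra_sig)
    for site in truth.noise_sites:
        emit_site_reads(site, truth.noise_depth, truth.conversion_prob, p_extra_sig)

    n_background = 0 if total_reads is None else total_reads - len(rows)
    if n_background < 0:
        raise ValueError("planted sites demand more reads than total_reads")
    if n_background:
        genes = annot.genes
        gi = rng.integers(0, len(genes), size=n_background)
        convs = _draw_conversions(
            rng, n_background, truth.background_conversion_prob, 0.0
        )
        for g_idx, c in zip(gi, convs):
            g = genes[g_idx]
            hi = max(g.start + 1, g.end - read_length)
            s = int(rng.integers(g.start, hi))
            rows.append((g.chrom, s, s + read_length, g.strand, int(c)))

    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "conversion_count"])
    df = df.sort_values(["chrom", "start", "end", "strand"], kind="mergesort")
    df = df.reset_index(drop=True)
    df["name"] = [f"read{i}" for i in range(len(df))]
    df["read_length"] = read_length
    df["dataset"] = truth.dataset_id
    return df[READ_COLUMNS]


def simulate_site_rpm_mixture(
    n_noise: int = 300,
    n_signal: int = 100,
    noise_scale: float = 1.0,
    signal_offset: float = 10.0,
    signal_scale: float = 5.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a planted RPM mixture: noise ~ Exp(noise_scale), signal ~
    signal_offset + Exp(signal_scale).

    Returns ``(rpm, is_signal)`` arrays; ``is_signal`` is the ground-truth
    component label.  The defaults (300 noise, 100 signal) emulate a
    noise-dominated site list at desk scale.
    """
    rng = np.random.default_rng(seed)
    noise = rng.exponential(noise_scale, size=n_noise)
    signal = signal_offset + rng.exponential(signal_scale, size=n_signal)
    rpm = np.concatenate([noise, signal])
    labels = np.concatenate(
        [np.zeros(n_noise, dtype=bool), np.ones(n_signal, dtype=bool)]
    )
    order = rng.permutation(len(rpm))
    return rpm[order], labels[order]
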
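"""PAR-CLIP binding-site calling and the empirical RPM threshold.

The stages here mirror a crosslink-site pipeline for 4SU PAR-CLIP data:
raw-read QC filters, assembly of overlapping conversion-bearing aligned
reads into binding sites scored in mean-coverage RPM, selection of a
per-library RPM threshold by subsampling two-sample Kolmogorov–Smirnov
stabilization, cross-dataset overlap classification, genic-region
annotation, and site-RPM/gene-RPKM enrichment.

Coordinates are 0-based half-open throughout.  A read's T-to-C conversion
count is taken from the aligned-read table; reads with more than two
conversions are excluded before site assembly, and only sites containing
at least one conversion-bearing read are retained (high-confidence sites).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from gbody.simulate.annotation import Gene, ToyAnnotation

__all__ = [
    "QCParams",
    "BindingSite",
    "ThresholdCurve",
    "filter_raw_reads",
    "assemble_binding_sites",
    "filter_sites_by_rpm",
    "ks_two_sample",
    "empirical_rpm_threshold",
    "classify_site_overlap",
    "annotate_sites",
    "site_expression_enrichment",
    "unpaired_ttests",
    "target_gene_sets",
]

GENIC_REGIONS = ("5'UTR", "CDS", "3'UTR", "ncRNA", "intergenic")


# ---------------------------------------------------------------------------
# Raw-read QC
# ---------------------------------------------------------------------------

@dataclass
class QCParams:
    """Raw-read removal rules.

    A read is removed if, after 3' adapter trimming, it is shorter than
    ``min_length``, is a homopolymer-A, lacked the 3' adapter, is a 5'-3'
    or 5'-5' adapter ligation product, has more than ``max_low_q10`` bases
    below quality 10, or more than ``max_low_q13`` bases below quality 13.
    """

    min_length: int = 18
    max_low_q10: int = 4
    max_low_q13: int = 6
    three_prime_adapter: str = "TCGTATGCCGTCTTCTGCTTG"
    five_prime_adapter: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    quality_offset: int = 33

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_low_q10 < 0 or self.max_low_q13 < 0:
            raise ValueError("quality counts must be >= 0")


QC_RULES = (
    "min_length",
    "homopolymer_A",
    "missing_3p_adapter",
    "adapter_ligation",
    "low_quality_q10",
    "low_quality_q13",
)


def _iter_fastq(source):
    """Yield (title, seq, qual) triples; raise with record index on damage."""
    if isinstance(source, (str,)) or hasattr(source, "read"):
        from Bio.SeqIO.QualityIO import FastqGeneralIterator

        handle = open(source) if isinstance(source, str) else source
        it = FastqGeneralIterator(handle)
        i = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record {i}: {exc}") from exc
            yield rec
            i += 1
        if isinstance(source, str):
            handle.close()
    else:
        for i, rec in enumerate(source):
            if len(rec) != 3 or len(rec[1]) != len(rec[2]):
                raise ValueError(f"malformed FASTQ record {i}")
            yield rec


def filter_raw_reads(reads, params: QCParams | None = None):
    """Apply the raw-read removal rules.

    Parameters
    ----------
    reads
        A FASTQ path, an open handle, or an iterable of
        ``(title, sequence, quality_string)`` triples.
    params
        :class:`QCParams`; defaults match the pipeline's standard filters.

    Returns
    -------
    (survivors, report)
        ``survivors`` is a list of adapter-trimmed
        ``(title, seq, qual)`` triples; ``report`` maps each rule name to
        the number of reads removed by it (a read counts once, under the
        first failing rule in the documented order) plus ``"passed"``.
    """
    params = params or QCParams()
    report = {rule: 0 for rule in QC_RULES}
    report["passed"] = 0
    survivors = []
    for title, seq, qual in _iter_fastq(reads):
        seq_u = seq.upper()
        pos = seq_u.find(params.three_prime_adapter.upper())
        has_adapter = pos >= 0
        trimmed_seq = seq_u[:pos] if has_adapter else seq_u
        trimmed_qual = qual[: len(trimmed_seq)]
        phred = [ord(c) - params.quality_offset for c in trimmed_qual]

        failing = None
        if len(trimmed_seq) < params.min_length:
            failing = "min_length"
        elif trimmed_seq and set(trimmed_seq) == {"A"}:
            failing = "homopolymer_A"
        elif not has_adapter:
            failing = "missing_3p_adapter"
        elif params.five_prime_adapter.upper() in trimmed_seq or seq_u.startswith(
            params.five_prime_adapter.upper()
        ):
            failing = "adapter_ligation"
        elif sum(q < 10 for q in phred) > params.max_low_q10:
            failing = "low_quality_q10"
        elif sum(q < 13 for q in phred) > params.max_low_q13:
            failing = "low_quality_q13"

        if failing is None:
            report["passed"] += 1
            survivors.append((title, trimmed_seq, trimmed_qual))
        else:
            report[failing] += 1
    return survivors, report


# ---------------------------------------------------------------------------
# Site assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSite:
    """A strand-aware binding site with mean-coverage RPM."""

    chrom: str
    strand: str
    start: int
    end: int
    rpm: float
    n_conversion_reads: int
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if self.rpm < 0:
            raise ValueError("rpm must be >= 0")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def assemble_binding_sites(
    reads: pd.DataFrame,
    total_mapped: int,
    max_conversions: int = 2,
    dataset_id: str | None = None,
) -> list[BindingSite]:
    """Aggregate overlapping same-strand reads into binding sites.

    Reads with more than ``max_conversions`` T-to-C conversions are
    discarded first.  Maximal sets of transitively overlapping reads form
    one site spanning their union; the site RPM is the mean per-position
    read coverage over the site divided by ``total_mapped / 1e6``.  Sites
    with no conversion-bearing read are dropped.
    """
    if len(reads) == 0:
        return []
    if (reads["start"] < 0).any():
        raise ValueError("negative read coordinates")
    if total_mapped < len(reads):
        raise ValueError("total_mapped smaller than the number of input reads")
    if dataset_id is None:
        dataset_id = str(reads["dataset"].iloc[0]) if "dataset" in reads else ""

    kept = reads[reads["conversion_count"] <= max_conversions]
    per_million = total_mapped / 1e6
    sites: list[BindingSite] = []
    for (chrom, strand), grp in kept.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values(["start", "end"], kind="mergesort")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        convs = grp["conversion_count"].to_numpy()
        i = 0
        n = len(grp)
        while i < n:
            span_start = starts[i]
            span_end = ends[i]
            j = i + 1
            while j < n and starts[j] <= span_end:  # touching reads share a coverage run
                span_end = max(span_end, ends[j])
                j += 1
            block = slice(i, j)
            n_conv = int((convs[block] >= 1).sum())
            if n_conv >= 1:
                covered = float((ends[block] - starts[block]).sum())
                mean_cov = covered / (span_end - span_start)
                sites.append(
                    BindingSite(
                        chrom=str(chrom),
                        strand=str(strand),
                        start=int(span_start),
                        end=int(span_end),
                        rpm=mean_cov / per_million,
                        n_conversion_reads=n_conv,
                        dataset_id=dataset_id,
                    )
                )
            i = j
    return sites


def filter_sites_by_rpm(sites: list[BindingSite], threshold: float) -> list[BindingSite]:
    """Sites with ``rpm >= threshold`` (monotone in the threshold)."""
    return [s for s in sites if s.rpm >= threshold]


# ---------------------------------------------------------------------------
# Two-sample K-S statistic and the subsampling threshold
# ---------------------------------------------------------------------------

def ks_two_sample(x, y) -> float:
    """Exact two-sample Kolmogorov–Smirnov statistic.

    D = sup over pooled points of \\|ECDF_x - ECDF_y\\|, in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    xs = np.sort(x)
    ys = np.sort(y)
    pooled = np.concatenate([xs, ys])
    cdf_x = np.searchsorted(xs, pooled, side="right") / xs.size
    cdf_y = np.searchsorted(ys, pooled, side="right") / ys.size
    return float(np.abs(cdf_x - cdf_y).max())


def _ks_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row-wise two-sample K-S statistics for (k, m) sample matrices.

    Ties across the two samples are handled by evaluating the ECDF
    difference only at the last occurrence of each distinct pooled value.
    """
    k, m = x.shape
    m2 = y.shape[1]
    z = np.concatenate([x, y], axis=1)
    weights = np.concatenate([np.full(m, 1.0 / m), np.full(m2, -1.0 / m2)])
    order = np.argsort(z, axis=1, kind="stable")
    zs = np.take_along_axis(z, order, axis=1)
    cum = np.cumsum(weights[order], axis=1)
    valid = np.ones_like(zs, dtype=bool)
    valid[:, :-1] = zs[:, 1:] != zs[:, :-1]
    return np.abs(np.where(valid, cum, 0.0)).max(axis=1)


@dataclass
class ThresholdCurve:
    """Mean subsampling K-S statistic per candidate RPM threshold."""

    grid: np.ndarray
    mean_stat: np.ndarray
    n_sites: np.ndarray
    chosen: float
    n_iter: int
    frac: float
    seed: int | None
    stabilized: bool = True
    rel_tol: float = 0.02
    window: int = 3

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        finite = self.mean_stat[np.isfinite(self.mean_stat)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("mean K-S statistics must lie in [0, 1]")
        if not np.any(np.isclose(self.grid, self.chosen)):
            raise ValueError("chosen threshold must be a grid value")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.grid, "mean_ks": self.mean_stat, "n_sites": self.n_sites}
        )


def _mean_subsample_ks(
    vals: np.ndarray,
    frac: float,
    n_iter: int,
    rng: np.random.Generator,
    replace: bool = False,
    disjoint: bool = False,
) -> float:
    n = vals.size
    m = math.ceil(frac * n)
    if disjoint and 2 * m > n:
        raise ValueError("disjoint subsampling needs frac <= 0.5")
    if replace:
        xi = rng.integers(0, n, size=(n_iter, m))
        yi = rng.integers(0, n, size=(n_iter, m))
    elif disjoint:
        perm = np.argsort(rng.random((n_iter, n)), axis=1)
        xi, yi = perm[:, :m], perm[:, m : 2 * m]
    else:
        xi = np.argsort(rng.random((n_iter, n)), axis=1)[:, :m]
        yi = np.argsort(rng.random((n_iter, n)), axis=1)[:, :m]
    return float(_ks_rows(vals[xi], vals[yi]).mean())


def empirical_rpm_threshold(
    sites: list[BindingSite] | np.ndarray,
    grid: np.ndarray | None = None,
    n_iter: int = 10_000,
    frac: float = 0.20,
    seed: int | None = None,
    rel_tol: float = 0.02,
    window: int = 3,
    replace: bool = False,
    disjoint: bool = False,
    min_sites: int = 25,
) -> ThresholdCurve:
    """Select an RPM threshold by subsampling K-S stabilization.

    For each candidate threshold t, the site RPMs >= t are repeatedly
    (``n_iter`` times) split into two independent subsamples of
    ``ceil(frac * n)`` values each, the two-sample K-S statistic is
    computed, and its mean recorded.  The chosen threshold is the first
    grid value whose mean statistic changes by less than ``rel_tol``
    (relative) at each of the next ``window`` grid values; if no grid
    value satisfies this, the value with the smallest maximal relative
    change is returned with ``stabilized=False`` and a warning.

    The default grid is 36 values spanning 0–25 RPM.
    """
    if grid is None:
        grid = np.linspace(0.0, 25.0, 36)
    grid = np.asarray(grid, dtype=float)
    if isinstance(sites, list) and sites and isinstance(sites[0], BindingSite):
        rpm = np.asarray([s.rpm for s in sites], dtype=float)
    else:
        rpm = np.asarray(sites, dtype=float)
    n0 = int((rpm >= grid[0]).sum())
    if n0 < min_sites:
        raise ValueError(
            f"only {n0} sites pass the smallest grid value {grid[0]:g}; "
            f"need >= {min_sites}"
        )
    rng = np.random.default_rng(seed)
    mean_stat = np.full(grid.size, np.nan)
    n_sites = np.zeros(grid.size, dtype=int)
    for k, t in enumerate(grid):
        vals = rpm[rpm >= t]
        n_sites[k] = vals.size
        if vals.size >= 5:
            mean_stat[k] = _mean_subsample_ks(vals, frac, n_iter, rng, replace, disjoint)

    chosen = None
    stabilized = True
    tiny = 1e-12
    best_k, best_change = None, np.inf
    for k in range(grid.size - window):
        seg = mean_stat[k : k + window + 1]
        if not np.all(np.isfinite(seg)):
            continue
        rel = np.abs(seg[1:] - seg[0]) / max(seg[0], tiny)
        if seg[0] < tiny and np.all(seg[1:] < tiny):
            rel = np.zeros(window)
        change = float(rel.max())
        if change < best_change:
            best_k, best_change = k, change
        if change < rel_tol:
            chosen = float(grid[k])
            break
    if chosen is None:
        stabilized = False
        if best_k is None:
            raise ValueError("too few sites at every grid value to assess stability")
        chosen = float(grid[best_k])
        warnings.warn(
            "K-S statistic never stabilized below rel_tol; returning the grid "
            "value with the smallest change (stabilized=False)",
            stacklevel=2,
        )
    return ThresholdCurve(
        grid=grid,
        mean_stat=mean_stat,
        n_sites=n_sites,
        chosen=chosen,
        n_iter=n_iter,
        frac=frac,
        seed=seed,
        stabilized=stabilized,
        rel_tol=rel_tol,
        window=window,
    )


# ---------------------------------------------------------------------------
# Overlap classes, annotation, expression enrichment, target sets
# ---------------------------------------------------------------------------

def classify_site_overlap(
    site_sets: dict[str, list[BindingSite]],
    identical_tol: int = 0,
) -> dict[str, list[str]]:
    """Label each site identical / overlapping / unique across datasets.

    A site is *identical* when some site of another dataset matches both
    endpoints within ``identical_tol`` nt on the same strand; otherwise
    *overlapping* when it intersects >= 1 nt of any other dataset's site
    on the same strand; otherwise *unique*.
    """
    if len(site_sets) < 2:
        warnings.warn("single dataset: all sites labeled unique", stacklevel=2)
        return {ds: ["unique"] * len(sites) for ds, sites in site_sets.items()}

    trees: dict[tuple[str, str, str], IntervalTree] = {}
    for ds, sites in site_sets.items():
        for s in sites:
            trees.setdefault((ds, s.chrom, s.strand), IntervalTree()).addi(
                s.start, s.end, s
            )

    labels: dict[str, list[str]] = {}
    for ds, sites in site_sets.items():
        out = []
        for s in sites:
            label = "unique"
            for other in site_sets:
                if other == ds:
                    continue
                tree = trees.get((other, s.chrom, s.strand))
                if tree is None:
                    continue
                for hit in tree.overlap(s.start, s.end):
                    if (
                        abs(hit.begin - s.start) <= identical_tol
                        and abs(hit.end - s.end) <= identical_tol
                    ):
                        label = "identical"
                        break
                    label = "overlapping"
                if label == "identical":
                    break
            out.append(label)
        labels[ds] = out
    return labels


def overlap_class_percentages(labels: dict[str, list[str]]) -> pd.DataFrame:
    """Per-dataset percentage of identical / overlapping / unique sites."""
    rows = {}
    for ds, lab in labels.items():
        n = len(lab) or 1
        rows[ds] = {
            c: 100.0 * sum(x == c for x in lab) / n
            for c in ("identical", "overlapping", "unique")
        }
    return pd.DataFrame(rows).T


def _effective_regions(gene: Gene, utr_fallback: tuple[int, int], chrom_len: int):
    """Gene regions with fallback UTR extents when UTRs are unannotated."""
    five, cds, three = gene.five_utr, gene.cds, gene.three_utr
    f5, f3 = utr_fallback
    if five[1] - five[0] == 0:
        if gene.strand == "+":
            five = (max(0, cds[0] - f5), cds[0])
        else:
            five = (cds[1], min(chrom_len, cds[1] + f5))
    if three[1] - three[0] == 0:
        if gene.strand == "+":
            three = (cds[1], min(chrom_len, cds[1] + f3))
        else:
            three = (max(0, cds[0] - f3), cds[0])
    return five, cds, three


def annotate_sites(
    sites: list[BindingSite],
    annot: ToyAnnotation,
    utr_fallback: tuple[int, int] = (100, 200),
) -> tuple[list[str], dict[str, float]]:
    """Assign each site a genic region by its midpoint and report
    rpm-weighted region fractions (normalized to sum to 1).
    """
    labels: list[str] = []
    weights: dict[str, float] = {r: 0.0 for r in GENIC_REGIONS}
    for s in sites:
        chrom_len = annot.chrom_lengths.get(s.chrom)
        if chrom_len is None or not (0 <= s.midpoint < chrom_len):
            raise ValueError(f"site midpoint {s.chrom}:{s.midpoint} beyond chromosomes")
        label = "intergenic"
        gene = annot.gene_at(s.chrom, s.midpoint, strand=s.strand)
        if gene is not None:
            if gene.is_ncRNA:
                label = "ncRNA"
            else:
                five, cds, three = _effective_regions(gene, utr_fallback, chrom_len)
                for name, (lo, hi) in (("5'UTR", five), ("CDS", cds), ("3'UTR", three)):
                    if lo <= s.midpoint < hi:
                        label = name
                        break
        labels.append(label)
        weights[label] += s.rpm
    total = sum(weights.values())
    fractions = {r: (w / total if total > 0 else 0.0) for r, w in weights.items()}
    return labels, fractions


def site_gene_assignment(
    sites: list[BindingSite],
    annot: ToyAnnotation,
    by: str = "midpoint",
) -> list[str | None]:
    """Gene id per site (midpoint rule by default, max-overlap optional)."""
    out: list[str | None] = []
    for s in sites:
        if by == "midpoint":
            gene = annot.gene_at(s.chrom, s.midpoint, strand=s.strand)
        elif by == "max_overlap":
            best, best_ov = None, 0
            for g in annot.genes:
                if g.chrom != s.chrom or g.strand != s.strand:
                    continue
                ov = min(g.end, s.end) - max(g.start, s.start)
                if ov > best_ov:
                    best, best_ov = g, ov
            gene = best
        else:
            raise ValueError("by must be 'midpoint' or 'max_overlap'")
        out.append(gene.gene_id if gene is not None else None)
    return out


def site_expression_enrichment(
    sites: list[BindingSite],
    rpkm: pd.DataFrame,
    annot: ToyAnnotation,
    rpkm_column: str = "rpkm",
) -> tuple[pd.DataFrame, int]:
    """Per-site log10(site RPM / gene RPKM).

    Sites mapping to no gene or to a gene with RPKM <= 0 are excluded;
    the excluded count is returned alongside.
    """
    if rpkm_column not in rpkm.columns:
        raise ValueError(f"RPKM table lacks required column {rpkm_column!r}")
    genes = site_gene_assignment(sites, annot)
    rows = []
    excluded = 0
    for s, g in zip(sites, genes):
        if g is None or g not in rpkm.index:
            excluded += 1
            continue
        val = float(rpkm.loc[g, rpkm_column])
        if not (val > 0) or s.rpm <= 0:
            excluded += 1
            continue
        rows.append((g, s.chrom, s.start, s.end, s.rpm, val, np.log10(s.rpm / val)))
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "rpm", "rpkm", "log10_ratio"],
    )
    return df, excluded


def unpaired_ttests(
    groups: dict[str, np.ndarray], equal_var: bool = False
) -> pd.DataFrame:
    """Two-sided unpaired t-tests between every pair of groups.

    Welch's unequal-variance form by default; set ``equal_var=True`` for
    the pooled-variance test.
    """
    rows = []
    for a, b in itertools.combinations(sorted(groups), 2):
        res = stats.ttest_ind(groups[a], groups[b], equal_var=equal_var)
        rows.append((a, b, float(res.statistic), float(res.pvalue)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])


def target_gene_sets(
    site_sets: dict[str, list[BindingSite]],
    annot: ToyAnnotation,
) -> tuple[dict[str, set[str]], dict[str, int]]:
    """Bound-gene sets per dataset and exclusive Venn-region counts.

    A gene is a target when at least one site maps to it (sites are
    expected to be thresholded, high-confidence sites).  Venn keys join
    dataset names with ``&``; each count is exclusive to that region.
    """
    gene_sets = {
        ds: {g for g in site_gene_assignment(sites, annot) if g is not None}
        for ds, sites in site_sets.items()
    }
    names = sorted(gene_sets)
    venn: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(gene_sets[n] for n in combo))
            outside = set().union(
                *(gene_sets[n] for n in names if n not in combo), set()
            )
            venn["&".join(combo)] = len(inside - outside)
    return gene_sets, venn
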
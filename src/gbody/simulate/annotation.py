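"""Toy genome annotation for exercising the genomic stages.

A :class:`ToyAnnotation` holds a set of non-overlapping genes on a small
number of chromosomes.  Each gene carries contiguous 5'UTR, CDS and 3'UTR
intervals in transcription order on its annotated strand, plus an ncRNA
flag.  All intervals are 0-based half-open genomic coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Gene", "ToyAnnotation", "make_annotation"]


@dataclass(frozen=True)
class Gene:
    """One annotated gene.

    ``five_utr``, ``cds`` and ``three_utr`` are (start, end) tuples in
    genomic coordinates.  On the minus strand the 5'UTR occupies the
    high-coordinate end of the gene.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    five_utr: tuple[int, int]
    cds: tuple[int, int]
    three_utr: tuple[int, int]
    is_ncRNA: bool = False

    @property
    def start(self) -> int:
        return min(self.five_utr[0], self.cds[0], self.three_utr[0])

    @property
    def end(self) -> int:
        return max(self.five_utr[1], self.cds[1], self.three_utr[1])

    def region_of(self, pos: int) -> str | None:
        """Genic region containing genomic position ``pos``, or ``None``."""
        if not (self.start <= pos < self.end):
            return None
        if self.is_ncRNA:
            return "ncRNA"
        for name, (lo, hi) in (
            ("5'UTR", self.five_utr),
            ("CDS", self.cds),
            ("3'UTR", self.three_utr),
        ):
            if lo <= pos < hi:
                return name
        return None


@dataclass
class ToyAnnotation:
    genes: list[Gene]
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.start < 0:
                raise ValueError(f"{g.gene_id}: negative coordinate")
            if g.end > self.chrom_lengths.get(g.chrom, 0):
                raise ValueError(
                    f"{g.gene_id}: extends past chromosome {g.chrom}"
                )
            # UTR/CDS/UTR contiguous in transcription order
            if g.strand == "+":
                order = (g.five_utr, g.cds, g.three_utr)
            else:
                order = (g.three_utr, g.cds, g.five_utr)
            for (a, b), (c, d) in zip(order, order[1:]):
                if b != c:
                    raise ValueError(f"{g.gene_id}: non-contiguous segments")

    def __len__(self) -> int:
        return len(self.genes)

    def gene_by_id(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_at(self, chrom: str, pos: int, strand: str | None = None) -> Gene | None:
        """Gene whose span contains ``pos`` (optionally strand-matched)."""
        for g in self.genes:
            if g.chrom != chrom:
                continue
            if strand is not None and g.strand != strand:
                continue
            if g.start <= pos < g.end:
                return g
        return None


def make_annotation(
    n_genes: int,
    chrom_length: int = 100_000,
    utr_lengths: tuple[int, int] = (100, 200),
    cds_length: int = 600,
    ncrna_fraction: float = 0.1,
    min_gap: int = 50,
    chrom: str = "chrI",
    seed: int | None = None,
) -> ToyAnnotation:
    """Place ``n_genes`` non-overlapping genes on one chromosome.

    Genes alternate strand pseudo-randomly (both strands are represented
    whenever ``n_genes >= 2``), gaps between genes are drawn uniformly from
    the slack, and roughly ``ncrna_fraction`` of genes are flagged ncRNA.
    Deterministic for a fixed ``seed``.

    Raises
    ------
    ValueError
        If the requested genes cannot be placed without overlap.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    utr5, utr3 = utr_lengths
    gene_len = utr5 + cds_length + utr3
    needed = n_genes * gene_len + (n_genes + 1) * min_gap
    if needed > chrom_length:
        raise ValueError(
            f"cannot place {n_genes} genes of {gene_len} nt on a "
            f"{chrom_length} nt chromosome (need {needed} nt)"
        )
    slack = chrom_length - needed
    # split the slack into n_genes+1 extra gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_genes))
    extra = np.diff(np.concatenate([[0], cuts, [slack]]))
    strands = np.array(["+", "-"])[rng.integers(0, 2, size=n_genes)]
    if n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[0] == "+" else "+"
    is_nc = rng.random(n_genes) < ncrna_fraction

    genes: list[Gene] = []
    pos = min_gap + int(extra[0])
    for i in range(n_genes):
        s = pos
        strand = str(strands[i])
        if strand == "+":
            five = (s, s + utr5)
            cds = (s + utr5, s + utr5 + cds_length)
            three = (s + utr5 + cds_length, s + gene_len)
        else:
            three = (s, s + utr3)
            cds = (s + utr3, s + utr3 + cds_length)
            five = (s + utr3 + cds_length, s + gene_len)
        genes.append(
            Gene(
                gene_id=f"G{i + 1:04d}",
                chrom=chrom,
                strand=strand,
                five_utr=five,
                cds=cds,
                three_utr=three,
                is_ncRNA=bool(is_nc[i]),
            )
        )
        pos += gene_len + min_gap + int(extra[i + 1])
    return ToyAnnotation(genes=genes, chrom_lengths={chrom: chrom_length})
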
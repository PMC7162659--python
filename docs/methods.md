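# Methods

`gbody` reimplements, as tested library code, the quantitative analyses
used to characterize G bodies — non-membrane-bound granules of glycolysis
enzymes that form in hypoxic yeast and whose assembly is nucleated by RNA.
Six analysis families are covered: PAR-CLIP binding-site calling with an
empirically stabilized RPM threshold, RIP-seq/qPCR G-body enrichment
statistics, rotated-Gaussian puncta quantification, smFISH colocalization
distances, FRAP recovery kinetics, and competition-fitness estimation.
Because the original raw data live in external repositories, every stage
is exercised on synthetic data with known ground truth; the generators in
`gbody.simulate` are first-class, tested code.

## PAR-CLIP site calling

Aligned reads carry an explicit per-read T-to-C conversion count (the 4SU
crosslink signature; on the minus strand this is A-to-G in reference
coordinates, stored already resolved so downstream code never re-derives
strandness). Reads with more than two conversions are discarded; maximal
runs of covered positions (transitively overlapping or book-ended reads)
form one binding site; a site's score is its mean per-position coverage
divided by mapped millions (RPM); sites without at least one
conversion-bearing read are dropped (the high-confidence rule). Raw-read
QC removes, in order: inserts shorter than 18 nt after 3'-adapter
trimming, homopolymer-A inserts, reads lacking the 3' adapter, adapter
ligation products, reads with more than four bases below quality 10, and
reads with more than six below quality 13.

### The empirical RPM threshold

For each candidate threshold t on a 36-value grid spanning 0–25 RPM, the
sites with RPM ≥ t are repeatedly (10,000×) split into two independent 20%
subsamples, and the two-sample Kolmogorov–Smirnov statistic between the
two RPM subsamples is averaged. The threshold is chosen where this mean
curve stabilizes. "Stabilized" is operationalized as: the first grid value
whose mean statistic changes by less than 2% (relative) at each of the
next three grid values; both knobs are exposed (`rel_tol`, `window`), and
a run that never meets the rule returns the flattest grid value flagged
`stabilized=False`. Subsamples are drawn independently without
replacement and may overlap (disjoint and with-replacement sampling are
config options).

A structural property worth knowing: because both subsamples come from
the same empirical set, the K-S statistic is a rank statistic — its
distribution depends only on the number of sites passing t (and the
subsample overlap), not on the RPM values themselves. The mean-D curve is
therefore a monotone transform of the site-count survival curve, and the
procedure stabilizes where the RPM histogram empties — on a planted
noise/signal mixture, just past the top of the noise component. It is a
noise-exhaustion detector, not a component-density crossover estimator:
on the planted mixture (300 noise sites ~ Exp(1 RPM), 100 signal sites ~
10 + Exp(5 RPM), a noise-dominated composition at desk scale) the chosen
threshold excludes ~99% of noise and keeps ~99% of signal, yet typically
sits 1–4 grid steps above the smallest grid value that already achieves
95/95 separation. The separation property is the tested contract; the
offset from the 95/95 point is inherent to the procedure.

Downstream, sites are classified across enzyme datasets as identical
(both endpoints match within a tolerance, default exact), overlapping
(≥ 1 nt same-strand intersection), or unique; annotated to 5'UTR / CDS /
3'UTR / ncRNA / intergenic by site midpoint (genes lacking UTR annotation
receive fallback extents); and scored as log10(site RPM / gene RPKM) with
Welch t-tests between overlap classes (pooled-variance by flag).

## RIP-seq enrichment and qPCR

Counts are RPM-normalized per library; fold change is the ratio of
replicate-mean RPMs with a 0.5-RPM pseudocount; significance is a
two-sided unpaired Student's t-test (pooled variance) on log2(RPM + 0.5)
across replicates. Pooled variance is both the printed test and
calibrated at 3v3 replicates, where the Welch form is conservative
(~0.034 at nominal 0.05); Welch and linear-scale variants sit behind
flags. Identical replicates (zero variance) return p = 1 with a flag
rather than NaN. The high-confidence set intersects two screens
(IP vs flow-through and IP vs total RNA) at fold > 2 and p < 0.05;
overlap against a CLIP target set uses the 1-df 2×2 chi-square without
continuity correction (Yates by flag). qPCR percent-of-input subtracts
log2(1/fraction) cycles from the flow-through Cq (2 cycles for the
standard 25% aliquot) and reports 100·2^(ΔCq), assuming efficiency-2
amplification. The mRBP membership rule is: more than 2 spectral counts
with UV crosslinking and 0 without, or FDR < 10%.

The count simulator draws gamma–Poisson (negative binomial) counts around
log-normal gene abundances (dispersion 0.05 by default; the source data
specify no noise model). The planted fold multiplies a gene's expected
abundance before drawing; note that RPM re-normalization attenuates the
realized RPM ratio by the composition factor c = Σ p_g·fold_g, so a
4-fold planting over 10% of library mass is observed at ~3.1-fold. This
is intrinsic to RPM ratios, not a simulator artifact.

## Puncta quantification

Foci are strict local maxima on the maximum-intensity projection
exceeding the image median by a prominence (default 5× the MAD-based
noise sd; explicit values recommended for structured backgrounds). A
square patch of side 4.9 µm (38 px at 0.13 µm/px) is cut around each
maximum; the mean of three user-placed background boxes is subtracted
(floored at zero); and each focus is fit by bounded nonlinear least
squares to

    f(x, y) = b + A·exp(−(a·Δx² + 2c·Δx·Δy + d·Δy²)),
    a = cos²θ/2σx² + sin²θ/2σy²,
    c = −sin2θ/4σx² + sin2θ/4σy²,
    d = sin²θ/2σx² + cos²θ/2σy²,

the standard rotated-Gaussian quadratic form (the typographically
ambiguous printed exponent is resolved to this form, explicitly, not
silently; σ is a standard deviation, not FWHM). Initialization: b =
border median, A = max − b, center = top-decile centroid, σ = side/6,
θ = 0; bounds σ ∈ [0.5 px, side], A ≥ 0. θ is reported modulo π and
zeroed (flagged `circular`) when the axes differ by < 1%, where it is
unidentifiable. Noiseless self-generated patches are recovered to
machine precision; at SNR ≈ 10 (Poisson plus read noise) the median σ
error is ~2%. Cells are classified single/multiple/none by accepted
puncta count, and condition-level fractions are compared by unpaired
t-tests with Bonferroni correction over the requested comparisons.

## smFISH colocalization

Within a cell outline, the G body is segmented by Otsu thresholding of
the background-subtracted maximum projection; the center is the
intensity-weighted centroid of the dominant component (ties on area break
toward total intensity); the most in-focus slice maximizes the variance
of the Laplacian within the outline (a standard, parameter-free focus
metric the source procedure leaves unspecified). Spots within one slice
of that plane contribute in-plane Euclidean distances (µm) from the
center — by default every pixel of each spot footprint (maximum pixel
plus 8-connected above-threshold neighbors); a nearest-point flag exists
because the printed description is ambiguous between the two readings.
"Within one pixel" (0.13 µm) is boundary-inclusive, a documented choice.
Distance profiles pool across experiments; the fold-change curve is
ECDF_target/ECDF_control on a distance grid, undefined (reported missing)
where the control ECDF is zero. Under the null the curve sits inside a
pooled two-sample bootstrap 95% band at ~95% of grid points.

## FRAP

Traces (1-min frames, bleach pulse after a pre-bleach baseline) are
corrected by subtracting background, dividing frame-wise by the mean of
at least three unbleached control cells (each first normalized to its own
pre-bleach mean — the averaging order is a documented choice), and
rescaling so pre-bleach = 1 and the first post-bleach frame = 0. Traces
with ≥ 40% of fluorescence remaining after the bleach (strict boundary,
evaluated before rescaling) are discarded. Recovery is fit to
I(t) = A(1 − e^(−τt)) over post-bleach frames within the window (40 min;
25 min in plasmid mode, where late frames photobleach too heavily to
trust), and the half-time is reported as ln(2)/τ — the printed ln(0.5)/τ
is negative for τ > 0 and is treated as a sign typo. Replicate traces are
averaged after correction and before fitting, which is also how the
recovery statistics are computed here (10 granules per condition in the
validation runs). Identifiability degrades for small amplitudes with
half-times approaching the window (A = 0.1 at 25 min is barely
half-complete at 40 min); the pooled median error across the
(0.1–0.9) × (2–25 min) grid is < 10% for both parameters, but that
corner alone is worse. Granule tracking re-centers a circle on the local
brightest pixel per frame; the radius is fixed on the bleach frame by
maximizing the bleached fraction, ties within 2% resolving to the largest
radius so the circle covers the whole granule.

## Competition fitness

With %mix, %GB+ and %GB− the percentages of G-body-positive cells in the
mixed and pure cultures, the GB+ fraction of the mix is
f = (%mix − %GB−)/(%GB+ − %GB−); equal pure-culture rates are
non-identifiable and rejected. Estimates pushed outside [0, 1] by
counting noise are clipped with a warning. When the cells-per-arm count
is known, a 1,000-resample percentile bootstrap over binomial counts
supplies an interval. Generations of growth are log2(OD_end/OD_start).
The simulator draws per-arm binomial counts; the estimator inverts it
with |bias| < 10⁻⁴ at 10⁵ cells.

## What the synthetic data do and do not show

The generators emulate the statistical structure the analyses rely on —
planted conversion-bearing reads over a toy annotation, negative-binomial
counts, Gaussian puncta with Poisson/read noise, exponential recovery
under multiplicative acquisition bleaching, binomial phenotype counts —
with seeds controlling every draw (one global seed fans out per stage via
CRC-32). They do not model mappability, multi-mapping, GC or length
biases, optical aberrations, chromatic shifts, cell-to-cell expression
heterogeneity, or granule motility beyond simple drift. Passing tests
therefore certify the correctness and calibration of the computations,
not the biological accuracy of any particular dataset. Problem sizes in
the validation runs (hundreds of sites/genes, tens to hundreds of seeds)
are chosen to make Monte-Carlo checks reproducible on a single CPU; all
are parameters.

## Known limitations

- The RPM threshold procedure detects noise exhaustion, not the
  component-density crossover (see above); its chosen threshold is
  conservative (higher) relative to the minimal separating value.
- Per-probe qPCR amplification efficiencies are fixed at 2.
- Site→gene assignment is by midpoint (max-overlap behind a flag);
  straddling sites get a single gene.
- No FASTQ-level error/adapter simulation beyond what the QC filters
  need, and no aligner: the pipeline consumes aligned-read tables.
- The volcano screen uses raw p < 0.05 as printed; a Benjamini–Hochberg
  flag exists but is off by default.
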
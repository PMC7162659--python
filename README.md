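# gbody

Quantitative analyses for G-body biology. G bodies are non-membrane-bound
cytoplasmic granules into which yeast glycolysis enzymes coalesce under
hypoxia; their assembly is nucleated by RNA. Studying them quantitatively
takes a heterogeneous toolkit — CLIP-style binding-site calling,
immunoprecipitation enrichment statistics, fluorescence-image
quantification, photobleaching kinetics, and growth-competition
estimation — and `gbody` packages those analyses as tested, reusable
library code with a thin CLI, for researchers who want to run or audit
them without reassembling one-off scripts.

## What's inside

| Module | Analysis |
| --- | --- |
| `gbody.parclip` | PAR-CLIP QC filters, binding-site assembly (mean-coverage RPM over runs of overlapping conversion-bearing reads), empirical RPM threshold by subsampling two-sample K-S stabilization, overlap classes, genic annotation, site-RPM/gene-RPKM enrichment |
| `gbody.enrichment` | RIP-seq RPM normalization, fold/p enrichment screens (Student's t on log2 RPM), high-confidence two-screen intersection, 2×2 chi-square overlap tests, qPCR percent-of-input with aliquot cycle correction, the spectral-count mRBP rule |
| `gbody.puncta` | Maxima detection, background subtraction, rotated 2D-Gaussian fitting f(x,y) = b + A·exp(−(aΔx² + 2cΔxΔy + dΔy²)), cell classification, Bonferroni-corrected comparisons |
| `gbody.smfish` | Otsu G-body segmentation, in-focus slice selection, spot-to-granule distance profiles, ECDF fold-change curves vs a control mRNA |
| `gbody.frap` | Background/photobleach correction, <40%-remaining trace filter, I(t) = A(1−e^(−τt)) recovery fits with half-time ln(2)/τ, granule tracking |
| `gbody.fitness` | Mixed-culture composition f_GB+ = (%mix − %GB−)/(%GB+ − %GB−) with bootstrap intervals; generations from OD |
| `gbody.simulate` | Ground-truth generators for every input: planted binding sites, negative-binomial counts, Gaussian puncta stacks, FRAP traces, binomial competition counts |
| `gbody.pipeline` | Seeded end-to-end demo runs with a single reproducible report |

The scientific model behind each stage, its assumptions, numerical
choices and known limitations are documented in
[docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from gbody import simulate as sim, parclip, frap, fitness

# 1. RPM threshold selection on a planted site mixture
rpm, labels = sim.simulate_site_rpm_mixture(seed=1)   # 300 noise + 100 signal
curve = parclip.empirical_rpm_threshold(rpm, n_iter=1000, seed=2)
noise, signal = rpm[~labels], rpm[labels]
print(f"chosen threshold: {curve.chosen:.2f} RPM (stabilized={curve.stabilized})")
print(f"noise excluded: {100*(noise < curve.chosen).mean():.1f}%"
      f"  signal kept: {100*(signal >= curve.chosen).mean():.1f}%")

# 2. FRAP recovery on a simulated trace (30% mobile, 10-min half-time)
tr = sim.simulate_frap_trace(A_true=0.3, tau_true=np.log(2)/10, bleach_depth=0.8,
                             acquisition_bleach_rate=0.01, noise_sd=0.02, seed=5)
fit = frap.fit_recovery(frap.correct_trace(tr))
print(f"FRAP: A={fit.A:.3f} half_time={fit.half_time:.1f} min")

# 3. Competition composition from G-body phenotype frequencies
obs = sim.simulate_competition(0.65, 90.0, 10.0, n_cells=10_000, seed=3)
est = fitness.fraction_gb_plus(obs, seed=4)
print(f"f_GB+ = {est.f_gb_plus:.3f} (95% CI {est.ci_low:.3f}-{est.ci_high:.3f})")
```

Output:

```
chosen threshold: 5.00 RPM (stabilized=True)
noise excluded: 99.0%  signal kept: 100.0%
FRAP: A=0.277 half_time=9.8 min
f_GB+ = 0.651 (95% CI 0.638-0.665)
```

The K-S procedure picks 5.0 RPM, which removes 99% of planted
low-coverage noise sites while keeping every planted signal site; the
recovery fit returns the planted mobile fraction and half-time within
noise; and the competition estimator inverts the planted 65% GB+ mix with
a tight binomial bootstrap interval.

The same stages are available from the shell:

```bash
gbody demo --seed 11 --out demo_run          # all six analyses, one report
gbody parclip call --reads reads.tsv --total-mapped 1000000 --seed 1
gbody ripseq enrich --ip ip.tsv --ft ft.tsv --total total.tsv
gbody frap fit --trace trace.tsv --t-max 40
gbody compete --pct-mix 60 --pct-gb-plus 90 --pct-gb-minus 10 --n-cells 10000
```

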
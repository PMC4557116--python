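# fitflow

Analysis toolkit for growth-rate heterogeneity in isogenic microbial
populations and its transcriptomic consequences. It is aimed at groups who
(a) estimate RNA-level error rates from bulk RNA-seq pileups, (b) compare
gene expression between fast- and slow-growing cells — whether sorted
subpopulations of one culture or whole cultures grown at different
chemostat dilution rates — and (c) quantify slow-growing subpopulations
from brightfield time-lapse imaging of yeast microcolonies.

## What it computes

**Transcriptome error rate.** From samtools-mpileup text, with positions
where more than half the reads mismatch discarded as genomic variants:

    rate = Σ mismatches / Σ depth        (over retained positions)

plus per-transcript rates (GFF), rates per coverage bin (≥ 100 000
positions per bin), conservation-stratified rates, and per-lab
baseline-relative rates `rateᵢ / mean(lab rates)` for cross-lab comparison.

**Growth-correlated expression.** Per gene,
`log2(FPKM_fast + 0.1) − log2(FPKM_slow + 0.1)` for sorted subpopulations,
and mean log2 ratio at dilution rate 0.3 h⁻¹ minus mean at 0.05 h⁻¹ for
chemostat data; metric comparison (Pearson r, quadrants), signed
Kolmogorov–Smirnov gene-set shifts, expressed-gene counts per FPKM band,
transcriptome concentration curves, ±1 s.d. high/low expression classes,
and per-replicon fold-change z-scores.

**Microcolony imaging.** Per-frame foreground = pixels beyond
mean ± 2.5 s.d. or on strong Sobel edges; 8-connected clustering; mutual-
nearest-centroid tracking; an at-least-doubling filter; truncation of
touching colonies at the touch time; per-colony sum/mean/max GFP.

**Growth statistics.** Per-colony rate = maximum slope of ln(area) vs time
over windows of ≥ 3 points spanning ≥ 180 min with R² ≥ 0.95. The
slow-growing fraction comes from a tangent at the steepest point of the
rate CDF: `fraction_slow = max(0, F(x_lo) − (1 − F(x_hi)))` where x_lo and
x_hi are the tangent's 0- and 1-intercepts. A uniform rate distribution is
100 % explained; a single Gaussian cancels to ≈ 0.

A `fitflow.simulate` module generates all inputs synthetically (pileups
with planted error rates and variants, FPKM/chemostat tables with planted
gene-set effects, rendered brightfield/GFP stacks, Gaussian-mixture rate
samples) with truth tables, so the whole pipeline is testable offline.
See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import numpy as np
from fitflow import simulate, pileup
from fitflow.growth import slow_fraction

# error rate: 200 kb genome, depth ~30, planted rate 1e-4, 50 variants
text, truth = simulate.gen_pileup(200_000, (30, 0.3), error_rate=1e-4,
                                  n_variant_positions=50, seed=7)
est = pileup.estimate_error_rate(text)
print(f"error rate: {est.rate:.3e} over {est.total_bases:,} bases "
      f"({est.n_sites_discarded} sites discarded as variants)")

# slow fraction: 90% of colonies at 0.35/h, 10% slow at 0.15/h
rates, _ = simulate.gen_growth_rates(
    [(0.9, 0.35, 0.02), (0.1, 0.15, 0.02)], 10_000, seed=7)
res = slow_fraction(rates)
print(f"mode {res.x0:.3f} /h, tangent slope {res.slope:.1f}, "
      f"slow fraction {res.fraction_slow:.3f} "
      f"({100*res.unexplained_slow:.1f}% unexplained slow, "
      f"{100*res.unexplained_fast:.1f}% unexplained fast)")
```

prints

```
error rate: 1.024e-04 over 6,003,631 bases (50 sites discarded as variants)
mode 0.346 /h, tangent slope 19.4, slow fraction 0.052 (16.9% unexplained slow, 11.6% unexplained fast)
```

The recovered error rate sits within sampling noise of the planted 10⁻⁴
(binomial s.e. ≈ 4 × 10⁻⁶ here) and all 50 planted variants are filtered.
The tangent at the CDF's steepest point (the 0.35 h⁻¹ mode) leaves 16.9 %
of colonies below its zero-intercept and 11.6 % above its one-intercept;
the excess, 5.2 %, is the estimated slow-growing fraction — a conservative
reading of the planted 10 % (see `docs/methods.md`).

The same steps are available from the shell:

```
fitflow simulate rates --n 10000 --slow-weight 0.1 --seed 7 --out sim/
fitflow slowfrac --rates sim/rates.tsv --out results/
```

Each run writes a `manifest.json` (version, configuration, input
checksums) sufficient to reproduce it.

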
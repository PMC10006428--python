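# gymnome

An analysis toolkit for the bespoke computational layer of giga-scale
gymnosperm genome projects. Conifer-lineage genomes run to tens of
gigabases, are dominated by ancient LTR retrotransposons, carry unusually
high CG/CHG methylation, and sit far enough from model angiosperms that the
standard annotation stacks leave a tail of custom statistics to the
analyst: dating transposon insertions, locating whole-genome duplications
in Ks space, calibrating a bisulfite methylation caller against a lambda
spike-in, finding demethylation valleys in seed tissue, and screening for
horizontally transferred genes. `gymnome` implements those statistics as a
tested, reusable library with a thin CLI, plus seeded synthetic-data
generators so every stage can be exercised against known ground truth
without touching real (and enormous) datasets.

## What it computes

* **Assembly QC arithmetic** (`gymnome.assembly_qc`) — N50, sequencing
  coverage folds, Phred-QV → base accuracy (1 − 10^(−QV/10)), anchoring and
  repeat percentages, genome size from a k-mer depth histogram
  (total k-mers above the error trough ÷ homozygous-peak depth), telomere
  motif (5′-TTTAGGG-3′) scans of chromosome ends, and centromeric tandem
  monomer summaries.
* **LTR retrotransposon dating** (`gymnome.ltr_dynamics`) — global
  alignment of the 5′/3′ LTRs of an intact element, Kimura two-parameter
  distance K = −½·ln[(1−2P−Q)√(1−2Q)] from transition/transversion
  proportions P and Q, insertion age T = K/2r with r = 2.2×10⁻⁹
  substitutions·site⁻¹·yr⁻¹ by default, age histograms, and the
  solo:intact LTR ratio.
* **Ks-mixture WGD detection** (`gymnome.wgd_ks`) — EM-fitted Gaussian
  mixtures over paralog Ks tables (restart-seeded, BIC model selection,
  per-iteration log-likelihood monotonicity asserted) and the fitted-density
  summit that marks a whole-genome duplication.
* **Bisulfite methylome statistics** (`gymnome.methylome`) — conversion
  rate from the unmethylated lambda spike-in; one-sided binomial site
  calling against non-conversion noise with per-context
  Benjamini–Hochberg FDR (q < 0.05); count-pooled methylation levels at any
  aggregation scale (10-kb bins, gene metaprofiles, expression-ranked
  gene-body methylation); demethylation-valley (DMV) discovery (<5%
  pooled level in every context) and cross-sample DMV intersection;
  2×2 χ² enrichment.
* **HGT screening** (`gymnome.hgt_screen`) — the three-database
  average-bitscore screen: per query and database keep one (best) hit per
  species, cap at 100 hits, average the bitscores (ABV), and flag queries
  whose out-group ABV exceeds their mid-group ABV.
* **Expression-side summaries** (`gymnome.expression_stats`) — 2^(−ΔΔCt)
  relative expression, descriptive fold changes, small-RNA length spectra.
* **Synthetic data** (`gymnome.synthetic_data`) — seeded generators for all
  of the above, with truth tables (byte-identical outputs per seed).

## Worked example

Date a burst of simulated LTR elements and recover a planted WGD summit:

```python
import numpy as np
from gymnome import synthetic_data as sd, ltr_dynamics as ltr, wgd_ks

alns, truth = sd.simulate_ltr_pairs(sd.LtrSimParams(
    n_elements=200, ltr_length=2000, true_age=1.0e7, seed=42))
ages, saturated = ltr.date_elements(alns)
print(f"dated {len(ages)} elements ({len(saturated)} saturated)")
print(f"mean K = {np.mean([a.K for a in ages]):.4f}")
print(f"mean insertion age = {np.mean([a.T for a in ages])/1e6:.2f} Myr")

recs = sd.simulate_ks(sd.KsSimParams(seed=42))
fit = wgd_ks.fit_ks_mixture(recs, n_components=2, seed=0)
print(f"mixture means = {fit.means[0]:.3f}, {fit.means[1]:.3f}; "
      f"summit in (1,2) = {wgd_ks.density_summit(fit, (1.0, 2.0)):.2f}")
```

prints

```
dated 200 elements (0 saturated)
mean K = 0.0443
mean insertion age = 10.08 Myr
mixture means = 0.303, 1.404; summit in (1,2) = 1.40
```

The mean LTR divergence K ≈ 0.044 corresponds to 10 Myr at the gymnosperm
clock rate (K/2r), recovering the planted age within 1%; the mixture fit
recovers the planted recent-duplicate (0.3) and ancient-WGD (1.4)
components, and the density summit lands on the WGD mode.

The same pipelines are reachable from the shell, e.g.

```
gymnome simulate ks --seed 3 --out-dir /tmp/ks
gymnome ks-fit /tmp/ks/ks.tsv --k-max 3
gymnome simulate methylome --seed 1 --out-dir /tmp/wgbs
gymnome methylome dmv /tmp/wgbs/genome.cx.tsv --out /tmp/wgbs/dmv.bed
```

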
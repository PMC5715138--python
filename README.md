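# aneuhic

CNV-aware Hi-C analysis for aneuploid cancer genomes.

Cancer genomes are rarely diploid: whole and partial chromosome gains and
losses change how often each locus is sampled in a Hi-C library, so raw
contact matrices of aneuploid cells are biased by copy number — a bin pair
with copy numbers $c_i$ and $c_j$ collects roughly $c_i c_j / p^2$ times the
contacts of a baseline-ploidy pair. This package implements, as a tested
reusable pipeline, the integrated analysis this situation calls for:

- **Copy-number bias diagnosis.** For each CNV block (a maximal run of
  constant estimated copy number) the median diagonal interaction value is
  regressed on the block copy number; a significantly positive slope
  (F-test on the OLS fit) flags residual bias. Applied to raw, covariate-
  normalized (HiCNorm-style Poisson regression on effective length / GC /
  mappability) and ICE-balanced matrices, it shows that matrix balancing
  removes the copy-number bias while covariate regression does not.
- **CNV and translocation detection from Hi-C.** A transparent segmentation
  caller (median normalization → running-median smoothing → integer
  rounding → short-run absorption) turns binned WGS depth *or* Hi-C
  marginal coverage into integer copy-number profiles, blocks and
  breakpoints. Inter-chromosomal translocations show up as high-contact
  blocks; candidate junctions (support/total read counts at both sides)
  are filtered by strict support rules (>10% support fraction on both
  sides, summed support >40) and tested for enrichment among the top
  inter-chromosomal contact-bin pairs with a one-sided Fisher
  (hypergeometric) test.
- **TADs and insulation.** Insulation score of bin $i$: mean signal in the
  square window $(i-w..i-1)\times(i+1..i+w)$, log2-ratioed to the
  chromosome mean; boundaries at valleys (sign changes of a left/right
  delta vector), domains assembled between boundaries with a 200-kb
  minimum size and gap filtering, conserved domains by ≥70% reciprocal
  overlap.
- **A/B compartments and expression.** Per chromosome, the leading
  eigenvector of the Pearson correlation of the observed/expected matrix
  splits bins into compartments; the gene-dense side is A. Compartment
  switch classes across (normal, tumor, tumor) triples are associated
  with per-bin expression changes by Welch t-tests against stable bins.
- **Breakpoint–boundary association.** Distances from CNV breakpoints to
  the nearest TAD boundary, compared with location-randomized sites
  (one-sided Wilcoxon rank-sum), plus averaged insulation profiles
  around site sets.

Because the analyses target properties of aneuploid genomes with known
truth, the package ships a first-class synthetic-data module: an
aneuploid multi-chromosome genome with integer copy-number blocks,
distance-decay contacts scaled by copy-number products
($E_{ij} = s\,(c_i c_j/p^2)(1+|i-j|)^{-\alpha}\,\tau^{[\text{same TAD}]}\,\pi^{[\text{same compartment}]}$,
Poisson noise), chimeric-chromosome contact stripes, depth tracks,
junction-candidate tables with planted decoys, and compartment-dependent
expression.

## Worked example

```python
from aneuhic import (SimConfig, simulate_genome_model, simulate_hic,
                     simulate_wgs_depth, mask_zero_coverage,
                     call_cnv_from_depth, ice_normalize, cnv_bias_regression)
from aneuhic.simulate import stage_rng

cfg = SimConfig(seed=0)                      # 4 x 20 Mb toy genome, ploidy 2
model = simulate_genome_model(cfg)           # planted CNVs, TADs, compartments
raw = mask_zero_coverage(simulate_hic(model, cfg, stage_rng(0, "hic")))
depth = simulate_wgs_depth(model, cfg, stage_rng(0, "depth"))
profile = call_cnv_from_depth(depth, ploidy=cfg.ploidy)

for name, mat in [("raw", raw), ("ice", ice_normalize(raw)[0])]:
    res = cnv_bias_regression(mat, profile)
    print(f"{name:4s} slope={res.slope:8.2f}  F={res.f_statistic:8.2f}  p={res.p_value:.3g}")
```

prints

```
raw  slope=  212.48  F=  582.10  p=2.93e-16
ice  slope=   -2.80  F=    1.61  p=0.219
```

i.e. on the raw matrix the per-block median diagonal count rises by ~212
counts per copy (the planted copy-number bias, overwhelmingly significant),
while after ICE balancing the slope is statistically indistinguishable
from zero — the bias is gone.

The full pipeline (simulate → normalize → CNV → translocations → TADs →
compartments → expression association) runs from the shell:

```sh
aneuhic run --outdir run0            # seeded, writes report.json + artifacts
aneuhic simulate --outdir data       # benchmark inputs + truth files only
aneuhic cnv --depth data/depth.bedgraph --ploidy 2 --out cn.bedgraph
```

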
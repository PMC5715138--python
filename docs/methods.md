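# Methods

This note documents the models and procedures implemented in `aneuhic`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show
about real data.

## Coordinate conventions and masking

All coordinates are 0-based half-open (BED convention). A genome is
tiled into fixed-resolution bins; the last bin of a chromosome may be
short. A bin is *masked* when it overlaps a declared gap interval
(telomere/centromere stand-in) by at least 1 bp, or when it has zero
marginal coverage in the raw contact matrix. Masked bins are excluded
from normalization, insulation scoring, compartment PCA and all
regressions. Whole-genome matrices are stored dense — the package
targets desk-scale genomes (thousands of bins); per-chromosome views
are read-only numpy slices. Text writers round to 6 significant digits,
so round-trips are lossless at that precision.

## Synthetic aneuploid benchmark

The generator plants every structure the pipeline measures, so each
analysis can be scored against known truth.

**Genome.** Default: 4 chromosomes × 20 Mb, 40-kb fine bins (500 per
chromosome), 500-kb compartment bins, 2-Mb structural-variant bins,
baseline ploidy p = 2. Each chromosome carries one 400-kb gap starting
at its midpoint; starting the gap exactly at the (bin-aligned) midpoint
keeps it inside a single coarse bin at the 500-kb and 2-Mb analysis
scales, so masking removes one coarse bin per chromosome rather than
two. The 2-Mb SV bins are a scaled stand-in for the 5-Mb bins one would
use on a full-size genome; with only 4 toy chromosomes the inter-
chromosomal pair universe is 486 unmasked pairs, and the default number
of top-ranked pairs examined is scaled down accordingly (K = 20; on
real genomes K = 100 is the conventional choice and is the function
default in `top_interchrom_pairs`).

**Copy number.** CNV blocks alternate with baseline-ploidy runs along
each chromosome (chromosomes start at baseline), with breakpoints
jittered around an even grid so block lengths stay comparable
(default 4–6 blocks per chromosome, minimum 25 bins ≈ 1 Mb). Altered
blocks cycle a shuffled list of the non-baseline levels from
{1, 2, 3, 4}, so every level appears genome-wide. Two properties of
real tumor genomes motivated this layout: most of the genome stays at
the baseline ploidy, and median-based depth normalization (below)
presumes the median bin is at baseline. Copy number 0 is allowed by
the data model but excluded from regression fits.

A configurable fraction of CNV breakpoints
(`boundary_alignment_fraction`, default 0.5) is snapped exactly onto
TAD boundary coordinates; the rest are placed strictly inside TADs.

**TADs and compartments.** TADs tile each chromosome arm with sizes
uniform in 10–25 bins (400 kb–1 Mb); a short terminal remainder is
absorbed into the preceding domain. Compartment labels alternate A/B
in runs of 2–6 coarse bins. Gene density per coarse bin is Poisson
with mean 12 (A) or 4 (B) genes — A is gene-dense, which is what
orients the compartment eigenvector.

**Contacts.** Expected counts follow

    cis:   E_ij = s (c_i c_j / p^2) (1+|i-j|)^(-alpha) * tau^[same TAD] * pi^[same label]
    trans: E_ij = beta (c_i c_j / p^2) + stripes

with defaults s = 60, alpha = 1, tau = 1.8, pi = 1.5, beta = 0.3. Each
translocation adds a decaying stripe sigma (1+d)^(-alpha) centered on
the junction bin pair (d = L1 bin distance, capped at 25 bins for
speed; sigma = 150). These values give near-diagonal counts of order
10²(typical for 40-kb maps at moderate depth) and an intra/inter
contact split of ~74/26, close to the ~70/30 split expected of
mammalian Hi-C. Observed counts are independent Poisson draws of E on
the upper triangle, symmetrized. Poisson (not negative binomial) noise
is a deliberate simplification: at toy depth the count nature
dominates and overdispersion is out of scope.

**Depth, junctions, expression.** WGS-style depth per bin is
Poisson(λ c/p) with λ = 500. The junction-candidate table contains one
record per true translocation with support fractions in 0.25–0.45 and
totals of 90–180 reads (comfortably passing the support filters), plus
6 decoys alternately violating the fraction rule (2–8% on one side) or
the support-sum rule (sum ≤ 40). Log2 expression per coarse bin is
base + δ·1[label = A] + N(0, sd) per condition with that condition's
labels (base 5, δ = 1, sd = 0.3). Companion conditions are derived by
flipping a fraction of compartment labels (15% for the "normal"
condition, 5% for a second tumor).

**Determinism.** Every simulator takes a `numpy.random.Generator`; the
pipeline derives per-stage child seeds by hashing `"stage:seed"`
(CRC32, taken modulo 2³¹), so adding a stage never perturbs the
randomness of existing stages.

**What the benchmark does not emulate.** Restriction-fragment
structure, mappability/GC bias in depth (the caller therefore omits GC
correction), overdispersed counts, subclonal or allele-specific copy
number, intra-chromosomal SVs, and distance-dependent TAD nesting.
Passing tests demonstrate correctness of the measurement machinery on
genomes whose generative structure matches these assumptions; they do
not certify performance on real libraries, where fragment-level
filtering and heterogeneity add noise modes the generator does not
produce.

## Normalization and the bias diagnostic

**ICE.** Iterative correction divides the matrix by its marginal sums
until the coefficient of variation of unmasked row sums falls below
`tol` = 1e-5 (max 200 iterations; non-convergence warns and flags the
bias vector). The output is rescaled to the input's mean unmasked
entry; the returned per-bin bias vector has geometric mean 1. On the
benchmark, convergence takes ~25–30 iterations; re-running ICE on its
own output changes entries by < 1e-5 (idempotence).

**Covariate (HiCNorm-style) normalization.** Per chromosome, counts of
unmasked cis bin pairs are regressed with a Poisson log link on the
log product of each per-bin covariate (effective fragment length, GC,
mappability); trans pairs get one genome-wide fit. Normalized value =
count / fitted mean, rescaled to the input mean. On pair sets larger
than 200k the IRLS fit uses a deterministic stride subsample;
prediction uses all pairs. Constant covariate columns carry no
information and are dropped; genuinely collinear covariates raise an
error naming them. Copy number is not a covariate, so this
normalization cannot remove copy-number bias — which is the point of
the comparison.

**Bias regression.** For each CNV block, the block statistic is the
median of the diagonal values of unmasked bins inside the block
(`band_width` = 0; the band is exposed as a parameter). We chose the
distance-0 diagonal rather than a ±1 band after observing that a
band mixing distances 0 and 1 contributes two value modes a factor
2^alpha apart in near-equal numbers, making the block median a
knife-edge between modes — with band 0 every block statistic is
measured at the same contact distance. Whether medians are computed on
counts or counts per bin pair is likewise parameterized. OLS of block
medians on block copy number uses the closed-form ANOVA F-test of zero
slope (equivalent to the two-sided t-test on the slope, 1 numerator
df); the implementation is verified against `scipy.stats.linregress`
to 1e-10.

## CNV calling

Per-bin raw copy number = ploidy × depth / median(depth over defined
bins), smoothed per chromosome with a centered running median
(window 5 bins), rounded half-to-even for determinism, then runs
shorter than 5 bins are absorbed into the flanking run whose copy
number is closer to the run's mean raw value. The caller is
scale-invariant in the depth. Blocks are maximal same-CN runs over
unmasked bins (masked interior bins do not split a block when the CN
matches across them); a breakpoint sits at the start coordinate of the
downstream block; chromosome ends are not breakpoints. The same caller
serves WGS-style depth and Hi-C marginal coverage — marginal coverage
is our declared proxy for read-level Hi-C depth, which cannot be
reconstructed from binned matrices. Note the Hi-C marginal scales
super-linearly in the local copy number (contacts within a gained
block scale with c²), so Hi-C-derived integer profiles are a monotone
but not identity transform of the truth; agreement with depth-derived
profiles is assessed by Pearson correlation (≈ 0.97 on the benchmark).

## Translocations

Filters on junction candidates are strict inequalities: both support
fractions > 10% and summed support > 40 reads; records with a zero
total are rejected with reason "zero coverage". Ranking takes the K
largest unmasked inter-chromosomal upper-triangle entries of the
SV-resolution matrix, ties broken lexicographically by
(chromA, startA, chromB, startB). A coarse pair is "marked" if any
passing junction falls in it (either orientation; unordered
chromosome pairs). The universe is the set of unmasked
inter-chromosomal coarse bin pairs (its size is logged in the result);
expected overlap = n_marked × K / n_universe, and the p-value is the
one-sided hypergeometric tail, verified against exact enumeration
with binomial coefficients on small universes.

## Insulation and TADs

Window 480 kb (12 bins at 40 kb) and delta window 120 kb (3 bins),
boundary strength minimum 0.1 — the insulation method's parameters are
conventions, so all are exposed as flags. The score at bin i is the
mean of unmasked entries in the square (i−w..i−1)×(i+1..i+w),
log2-ratioed to the chromosome mean of defined scores; missing where
the window leaves the chromosome, at masked bins, and where > 50% of
window entries involve masked bins. Boundary calls: the delta vector
(mean over the right delta-window minus mean over the left) crosses
from negative to non-negative at a valley; strength = (max delta over
the following delta-window) − (min delta over the preceding one); the
boundary lands on the bin with minimal score within ±1 bin of the
crossing. Domains are intervals between consecutive boundaries,
dropping those < 200 kb or overlapping a declared gap. Conservation
between samples requires overlap ≥ 70% of *both* domain lengths
(reciprocal rule); matching is greedy by overlap, ties to the leftmost
partner.

Boundary-recovery scoring on the benchmark counts a planted boundary
as evaluable only where the insulation score is defined at its bin —
boundaries inside the edge/gap dead zones (within w bins) cannot be
called by any insulation method and are excluded from the denominator.

## Breakpoint–boundary association

Per breakpoint, the distance to the nearest same-chromosome boundary
(missing if the chromosome has none); summaries report the fraction at
distance 0 (same bin edge) and the fraction ≤ 120 kb ("within" is
inclusive). The null is location-randomized sites drawn uniformly over
unmasked bin starts, count-matched per chromosome (matching per
chromosome, rather than genome-wide, keeps chromosome-specific
boundary densities from confounding the comparison). The test is the
one-sided Wilcoxon rank-sum (observed < null). Averaged insulation
profiles around site sets span ±1 Mb; sites near chromosome ends
contribute only their defined offsets.

## Compartments and expression

Per chromosome (never genome-wide), the ICE-normalized coarse matrix
is converted to observed/expected by dividing each diagonal by its
mean over unmasked entries (diagonals with < 3 entries fall back to
the chromosome-wide mean); the Pearson correlation matrix of unmasked
bins is formed; and its leading eigenvector — the standard stand-in
for the first principal component — is oriented so the positive side
has the higher mean gene density: positive = A, negative = B.
Chromosomes with < 10 usable bins, or constant matrices whose
correlation is undefined, yield undefined labels and a logged warning.
The eigenvector step is verified against a power-iteration oracle to
1e-8.

Switch classes over (normal, tumor1, tumor2) label triples: stable A/B,
A→B in one/both, B→A in one/both; any undefined label makes the bin
undefined. Reported proportions are bin fractions (not base-pair
fractions) and are labelled as such. Expression association: per-bin
Δ = tumor − normal log2 expression; each switch category is compared
against the pooled stable bins with a Welch (unequal-variance) t-test;
categories with < 3 bins report a missing p-value. Gene-level values
are aggregated to bins by the mean of overlapping genes' log values.

## Numerical and degenerate-input choices

- Banker's rounding (half-to-even) wherever integers are derived.
- Median of an even count = mean of the two middle values.
- ICE on an all-zero matrix, regression with < 2 distinct copy-number
  levels, correlation of a constant profile, enrichment with a universe
  smaller than K, and profiles over empty site sets all raise typed
  errors rather than returning degenerate numbers.
- Fully masked blocks return a missing median and are silently excluded
  from the bias regression.

## Benchmark problem sizes

The standard benchmark genome (2,000 fine bins) was sized so that a
full pipeline run — simulation, ICE, covariate GLM, insulation,
compartments, association tests — completes in seconds and the
20-seed detection-rate sweeps in the test suite complete in about a
minute, while still containing ~20 CNV blocks, ~100 TADs per
condition, 160 coarse bins and 3 translocations: enough structure for
every statistic to have a meaningful sample size.

## Known limitations

- The dense-matrix representation does not scale to full mammalian
  genomes at 40 kb; the intended scale is benchmark/teaching/method
  development, with sparse or chunked backends as future adapters.
- Hi-C-derived copy numbers inherit the quadratic local-coverage
  effect described above; treat them as relative, not absolute, calls.
- The covariate normalizer implements the spirit of covariate Poisson
  regression, not any specific published tool's implementation details.
- Binary Hi-C container formats (.hic/.cool) are not read or written.
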
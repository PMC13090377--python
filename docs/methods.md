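# Methods

## Scope and data model

`singulor` operates on a cohort triple: a sparse cells × genes matrix of
non-negative integer transcript counts (Matrix Market coordinate format on
disk) plus tab-delimited gene and cell annotation tables. Gene annotations
carry an OR flag, OR class (I/II), chromosome, and a marker role
(`xist`, `y_linked`, `hemoglobin`, `mitochondrial`); cell annotations carry
donor, developmental stage, cell type, modality, and — for spatial cells —
x/y centroids in µm. Raw counts and log-normalized expression
(`log(1 + s·count/total)`, default scale s = 10,000, a community convention)
are distinct immutable objects: the dominance score and the low-count
spatial filter are defined on raw counts, while sex and erythroid QC scores
are defined on log-normalized values. Both Matrix Market orientations are
accepted on read (resolved against the sidecar row counts); the writer
emits cells-as-rows with the orientation recorded in a header comment.

## The dominance score

For a cell restricted to OR genes, with x1 ≥ x2 the two largest counts,

    D = ((x1 − x2) / (x1 + x2 + ε)) · ln(1 + x1),   ε = 1e−9.

The first factor is the relative gap between the top two receptors (1 for a
pure monogenic cell, 0 at a tie); the logarithmic factor penalizes cells
whose apparent dominance rests on one or two stray molecules. Choices worth
stating explicitly:

- **Log base.** Natural log. The score is used ordinally (bins, thresholds),
  so the base only rescales it; the base is exposed through the formula, not
  a flag, and every threshold in the package is calibrated to natural log.
- **Zero rule.** A cell with no detected OR scores exactly 0, and a cell
  with a single expressed OR is scored with x2 = 0 (giving D ≈ ln(1+x1)).
  The alternative — scoring only cells with at least two expressed ORs — is
  sensible for high-noise spatial data but would leave the most monogenic
  cells unscored; the package scores every cell and lets the ≥12-transcript
  filter handle noisy spatial cells.
- **Ties.** x1 = x2 gives D = 0; a dominant gene label is still assigned
  (lexicographically smallest among the argmax genes) so frequency tables
  remain deterministic. The label has no effect on any score.
- **Bins and the high-dominance rule.** Bins are (−, 0.5], (0.5, 1],
  (1, 1.5], (1.5, 2], (2, ∞): boundary values fall in the lower-labelled
  bin. High-dominance cells satisfy the conjunction D > 1 (strict),
  x1 ≥ 1, and n_expressed ≤ 3.

## Contingency statistics

The 2 × 4 table of cell identity (INP, iOSN) against OR-count category
(0/1/2/3+) is tested with Pearson χ² without continuity correction;
effect size is Cramér's V = √(χ²/(N·min(r−1, c−1))). The test statistic is
one-tailed in the χ² distribution even when quoted for a two-sided
hypothesis; the package records it as such and does not alter the
computation.

Post-hoc per-bin tests are **bin-vs-rest**: for category j, a 2×2 table of
(column j | pooled other columns) × identity, Pearson χ² without
correction, BH-adjusted across the c bins, with stars at adjusted
p < 0.05/0.01/0.001. This construction was fixed after hand-verification
against the worked example bundled with the package, where it reproduces
three of the four published adjusted p-values at printed precision. The
fourth (the single-OR bin) computes to ≈9.7e−11 where the published value
reads 9.7e−1 with an "ns" label — internally inconsistent with the other
three bins under any correction we are aware of, and most plausibly a
truncated exponent in the source. The package reports the computed value
and leaves the discrepancy documented rather than resolved.

The published 95% CI for V in the worked example has an upper bound equal
to the point estimate and no stated method; `bootstrap_v_ci` is therefore
the package's own declared construction — a percentile interval over
multinomial resamples of the table at fixed grand total (default B =
10,000, seeded). Resamples with a zero margin are discarded.

BH adjustment is the standard step-up procedure (statsmodels
implementation) with monotonicity enforcement and capping at 1.

## Contamination QC

Per-cell sex score S = log2((XIST + c)/(ΣY + c)) on log-normalized values,
with the Y panel UTY, RPS4Y1, ZFY, DDX3Y, KDM5D. The pseudocount c = 1 and
the symmetric thresholds (female-like at S ≥ 1, male-like at S ≤ −1,
boundary-inclusive) are package defaults — the procedure this implements
names "predefined thresholds" without stating them — and are configurable.
Sample sex is a strict majority vote (>50% of *all* cells, ambiguous calls
included in the denominator). The erythroid score sums log-normalized
expression of HBB, HBA1, HBA2, HBE1, HBG1, HBG2, HBM; cells strictly above
the global 95th percentile (linear-interpolation definition) are
erythroid-high. A cell is contaminated iff its call is discordant with its
sample's inferred sex AND it is erythroid-high; ambiguous cells are never
discordant and are optionally dropped. By construction, flagged cells are a
subset of erythroid-high cells, and on a clean sex-concordant cohort the
flag count is zero.

Basic filters: remove cells with <500 detected genes, <500 UMIs, >5%
mitochondrial reads, or >5 MADs from the median in log10 UMIs, log10 genes,
or mitochondrial percentage (the scale for the MAD rule is unstated in the
source procedure; log10 library-size metrics are the conventional choice).
All inequalities are strict as printed, so boundary cells pass.

## Composition

Pseudobulk proportions P(d,c) = N(d,c)/Σ_c' N(d,c') give each donor one
independent composition estimate. Stage-wise differences per cell type use
Kruskal–Wallis on donor proportions; a cell type enters only if present in
at least three donors in every stage. The default p-value is the asymptotic
χ² approximation (matching common practice); `method="permutation"`
computes an exact permutation p-value by enumeration for small donor
counts, and serves as the oracle route in the tests. Sex differences use
two-sided Wilcoxon rank-sum tests: exact enumeration when there are no
ties, tie-corrected normal approximation without continuity correction
otherwise (so identical groups give p = 1). Stage tests are BH-adjusted
across cell types (reported as an `fdr` column; the source procedure is
silent on multiplicity for composition, so this is a package decision).
The log10(P + 1e−4) transform exists only for plotting; rank tests make
the inference invariant to it.

## Spatial binning

Cells with fewer than 12 detected transcripts are removed (a 12-transcript
cell stays). Remaining cells are projected to the nearest point of a
user-supplied axis polyline — the anatomical axis is drawn by the user, not
inferred — and the normalized arc length s ∈ [0,1] is cut into 50
equal-width bins, half-open with the last bin closed ("equally sized" is
read as equal arc length, not equal cell count; quantile binning is not
offered because no analysis here needs it). Ties between segments go to the
lower-s segment. Cell-type profiles are raw counts per (type, bin) plus a
row-scaled copy (each type's row divided by its maximum, all-zero rows kept
at zero; z-scoring available as `scale="z"`). Gene profiles are per-bin
*means* of log-normalized expression (sums would confound abundance with
occupancy); empty bins yield NaN, not 0. The OR density map is a 2-D
histogram of summed OR transcripts at the cell centroids with optional
Gaussian smoothing (σ in µm); the unsmoothed grid conserves the transcript
total exactly. Spatially resolved dominance reuses the identical score
implementation on raw counts; the per-type summary counts cells with
D strictly above a threshold (default 3) inside a domain mask.

## The synthetic cohort generator

The generator emulates the *statistical* structure the analyses assume and
nothing more. Per cell, in documented draw order: a housekeeping depth
(lognormal-Poisson, mean 1,500 UMIs over 800 background genes with fixed
Dirichlet weights, ~1.5% mitochondrial), a donor-sex signature
(XIST ~ Poisson(5) in female donors, a 5-gene Y panel totalling
Poisson(5) in male donors, leak 0.05 on the opposite side), ambient
hemoglobin (Poisson(0.02) total over 7 genes), and the OR program: an iOSN
commits to one of 169 ORs with stage-dependent probability π, giving it a
zero-truncated Poisson(5) count; with probability ρ = 0.1 a distinct second
OR gets zero-truncated Poisson(5/4) counts (the 4:1 ratio creates the
top-vs-second gap the dominance score measures and is configurable); every
cell receives Poisson(0.02) stray OR transcripts on uniformly random ORs.
INP run the same program with commitment probability 0.33 and a weaker
dominant mean (2), matching their mostly-OR-negative, low-expression
profile. The default stage ramp lets π rise linearly 0.2 → 0.9 across
PCW7 → PCW12 — a stand-in that reproduces the qualitative finding that
high-dominance cells are nearly absent at the earliest stage and abundant
by the latest, without claiming the real per-stage rates. Default cohort:
4 stages × 2 donors (5 female / 3 male overall) × ~530 cells.

Planted contamination selects round(fraction·N) cells, adds zero-truncated
Poisson(20) hemoglobin counts, and swaps the sex signature (XIST count ↔
Y-panel total; the old XIST count lands on the first Y gene, conserving
totals). The spatial strip places cells on [0, L] × width with per-type
axial densities (respiratory types ∝ 1−s, olfactory types ∝ s by default;
any gridded profile accepted, sampled by inverse CDF), per-cell totals
floor + Poisson(mean 89), and the same OR program for iOSN over a 57-OR
panel.

Because background OR placement is "total ~ Poisson(λ), each transcript on
a uniform random OR", per-gene background counts are independent
Poisson(λ/n) by thinning, which gives the closed form used by
`expected_single_or_fraction`: among OR-positive iOSN,

    P(1 OR) = [π(1−ρ)e^{−λ(n−1)/n} + (1−π)·n·p(1−p)^{n−1}] /
              [π + (1−π)(1 − (1−p)^n)],      p = 1 − e^{−λ/n},

stage-weighted by configured iOSN counts. The tests verify this against a
brute-force Monte-Carlo implementation of the generative rule (400,000
cells, agreement within 3 SE) and against cohorts drawn by the generator
itself.

**What passing tests do and do not show.** The generator has no batch
effects, no doublets, no ambient-RNA bleed beyond the planted hemoglobin,
no gene-length or capture biases, and conditionally independent Poisson
counts (no overdispersion in the OR block). Recovery results on synthetic
cohorts therefore demonstrate the correctness of the estimators under the
stated model, not their robustness to real-data artifacts; on real data the
contamination thresholds and the sex-score pseudocount in particular should
be inspected against the observed score distributions.

## Problem sizes and numerics

The test suite runs cohorts of ~2,000–3,000 cells with an 800-gene
(or reduced 200–250-gene) background panel, 400,000-cell vectorized
Monte-Carlo checks, 200-table χ² oracle sweeps, and 200,001-point dense
projection oracles; the full suite completes in well under a minute. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`. Degenerate inputs are handled as stated
per operation: zero-total cells normalize to zero rows, zero-MAD metrics
flag nothing, constant erythroid vectors flag nothing, undetermined sample
sex yields zero contamination flags with a warning, empty gene selections
warn rather than fail, and zero-margin contingency tables are rejected
(post-hoc bins degrade to p = 1 with a warning instead of failing the
whole table).
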
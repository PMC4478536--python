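# Methods

`dosagecomp` measures how *Drosophila melanogaster* genes respond to a halved
gene dose.  Flies heterozygous for a multi-gene deletion (a deficiency,
Df/+) carry one copy of every gene inside the deleted segment; if
transcription were strictly proportional to copy number, those genes would
be expressed at half the wild-type level.  The analysis quantifies the
departure from proportionality — dosage compensation — per gene, per Df
line, and per chromosome arm, and asks whether the X chromosome behaves
differently from an autosome (3L) once the male-specific MSL system is
taken out of the picture by working in XX heads and in XX heads somatically
transformed to male by *tra2* mutation.

## The compensation statistic

For a gene g hemizygous in Df line L and profiled in class k (karyotype x
sex-transformation class), the ratio

    r = median over L's class-k samples of normalized expression
        -----------------------------------------------------------
        median over all class-k samples in which g is two-dose

is doubled to give the compensation fold c = 2r.  c = 1 means the gene
simply tracks its dose (one-dose expression is half the reference); c = 2
means expression is fully restored.  The reference median's uncertainty is
assessed with a percentile bootstrap (samples resampled with replacement;
B = 1000 by default; 2.5/97.5 percentiles).  Within one line and class all
hemizygous genes share the same reference sample pool, so the bootstrap is
vectorized per block; one resampling-index matrix is shared within a block,
which leaves each gene's marginal CI untouched.

Design choices around the statistic:

* **Class-stratified references.**  The reference pool is restricted to
  samples of the same karyotype/tra2 class.  Sex-biased genes differ
  between classes, so pooling across classes would contaminate the
  denominator; within a class the pool still spans all genotypes ("all
  lines").  X-linked genes have no two-dose male samples, so the male-X
  category is evaluated against the XX female reference — the orientation
  reported by the pipeline.
* **Containment rule.**  A gene is one-dose only if its span lies fully
  inside the Df interval.  Genes straddling a Df boundary are excluded from
  the analysis everywhere (partial deletion makes dose ill-defined), not
  prorated.
* **Matched controls.**  For every (line, class) block, as many control
  genes as there are cutoff-passing hemizygous genes are drawn without
  replacement from the same arm outside all deficiencies and pushed through
  the identical computation against the identical reference pool.  Their
  pseudo-compensation centers on 2 by construction and provides the
  negative control distribution for the boxplots.
* **Summaries.**  Per-arm distributions are summarized as boxplot notches
  (median +/- 1.57 x IQR / sqrt(N); quartiles by linear interpolation).
  Arms are compared with a two-sided Mann-Whitney U (normal approximation,
  tie-corrected; Welch's t on log2 c available).  The relation between a
  line's median compensation and its deletion extent is measured by
  Spearman rank correlation.

## Normalization

Counts are normalized by median-of-ratios size factors: each sample's
factor is the median ratio of its counts to the per-gene geometric-mean
pseudo-reference, computed over genes positive in every sample.  The median
uses the arithmetic midpoint for even counts (determinism).  Spike-ins and
intergenic regions are excluded from factor estimation — their input mass
is fixed rather than proportional to the mRNA pool — but are scaled by the
resulting factors.  FPKM is provided for absolute-expression summaries:
count / (kb of exon-union length x millions of mapped reads).

Note a scale consequence used throughout: because size factors have
geometric mean near one, one *normalized count* corresponds to roughly one
raw read at the typical library.

## Low-expression cutoff

Ratiometric analysis near zero expression manufactures compensation (an
unexpressed gene looks perfectly compensated), so genes enter the
compensation table only when their reference-pool mean exceeds an
empirically derived cutoff.  The cutoff comes from two noise sources
measured as replicate coefficients of variation (CV% = 100 x sd/mean,
n−1 denominator), computed per replicate group and pooled:

1. **Intergenic regions** set a CV threshold: the 5th percentile of the
   intergenic CV distribution, i.e. the noise level that 95% of non-genic
   signal exceeds (default percentile 5, linear interpolation).
2. **Spike-ins** translate that threshold into a count scale: CV is
   regressed on log10 mean normalized count by local polynomial regression
   (degree 2, tricube weights, span 0.75, 512-point grid — conventional
   defaults, all exposed), and the cutoff is the smallest mean at which the
   fitted curve drops to the threshold (linear interpolation between grid
   points).

Triplicate CV estimates are biased low (the c4 ≈ 0.886 factor for the
standard deviation) and noisy (two degrees of freedom), so the expected
*measured* CV at a given count is well below the asymptotic NB value
100 x sqrt(1/m + alpha).  `calibrate_noise` provides the closed-form NB
calibration; `calibrate_cutoff_study` calibrates the generator against the
measured quantities by seeded pilot simulation and bisection (intergenic
mean range for the threshold, spike dispersion for the curve crossing).
With the defaults this places the pipeline's operating point at a CV
threshold near 36% and a cutoff near 6 normalized counts.

## Sex-biased expression

XX-vs-XY differential expression gates the dosage analysis and is tested
with a deliberately compact negative-binomial Wald test: log2 fold change
of group means of normalized counts (+0.5 pseudocount), delta-method
standard error var(log2 mean) = (1/m + alpha)/(n ln^2 2) summed over
groups, and Benjamini–Hochberg FDR over genes passing the expression cutoff
in both groups.  There is no dispersion shrinkage or outlier refitting.

The dispersion entering the SE is, by default, a single *common* value: the
1%-trimmed mean over genes of the per-gene method-of-moments values
(pooled within-group variance after per-group centering).  At triplicate
scale a per-gene moment estimate carries ~4 df, and its noise in the Wald
denominator inflates the type-I error to ~0.10 at nominal 0.05; the common
dispersion is effectively exact when genes share a dispersion, restoring
calibration (empirical type-I ~0.05) with full power.  For data with
strongly heterogeneous dispersions a per-gene mode is available: it floors
the dispersion at 0.005 and replaces the normal reference with Student's t
at a Satterthwaite-style effective df, df = ((P+A)/A)^2 x (n_tot−2)/2
(P = Poisson, A = dispersion part of the variance).  Both constants were
fixed by null-calibration simulation across dispersions 0–0.1; the
per-gene mode calibrates the 5% tail but pays with extreme-tail power.

Orientation: "XX-biased" always means higher in the XX group, stated in
the output header.

## Df-presence QC

A Df/+ stock can silently lose its deletion.  Each line is scanned: for
every expressed gene inside the annotated interval (control mean above the
cutoff), the log2 ratio of the line's mean to the class-matched no-Df
control mean is computed, and the median over genes and classes is compared
to log2(0.75) — the midpoint, on the compensated scale, between no effect
(0) and uncompensated halving (−1).  Verdicts: `df_confirmed` at or below
the threshold, `df_absent` above it, `indeterminate` with fewer than three
expressed genes.  `df_absent` lines and replicate-less samples are dropped
before the sex-bias and compensation stages; the manifest records every
exclusion and asserts samples_in − excluded = samples_analyzed.

## The synthetic-data generator

`simulate.build_table1_design` reproduces the published sampling frame
exactly: 22 X-linked and 12 3L-linked Df/+ genotypes, four karyotype/tra2
classes with the published per-cell replicate counts, 249 libraries in
total, including the line later shown to carry no deficiency and the
replicate-less samples that QC removes.  Df intervals are placeholders
placed one per equal-width slot along each arm (non-overlapping, extents
300–800 kb log-uniform) — they are not reconstructions of the real DrosDel
coordinates, which the source does not list.

`simulate_counts` draws NB counts with expectation

    mu_gs = lib_s x base_g x sexfactor_g(s) x dosefactor_gs

where `lib_s` varies log-uniformly over a 4-fold range (exercising size
factor estimation), `base_g` is log-normal (log2 mean 6, sd 1.5 — a
realistic bulk count distribution), and `dosefactor` is 1 at two doses and
0.5 x c_g at one dose.  Defaults: gene dispersion 0.02 (biological
replicates), true compensation c = 1.1 on one-dose genes, male X fully
compensated (2.0), 10% sex-biased genes with N(0,1) log2 effects plus five
roX-like genes whose strong XY bias follows karyotype rather than somatic
sex (tra2-insensitive), 96 spike-ins spanning five decades of input
concentration with near-technical dispersion 0.002, and 500 intergenic
regions with low log-uniform means calibrated as described above.
Spike-in *normalized* expectations are sample-independent (raw counts scale
with library depth, as sequencing does); a literal fixed-raw-count reading
would let size-factor spread dominate spike CVs and destroy the
mean-variance curve.  Genes inside an interval listed in `absent_df_ids`
stay two-dose in the carriers — the annotated-but-absent deficiency that
the QC scan must catch.

What the generator does **not** emulate: batch effects, GC/length bias,
isoform structure, mapping artifacts, genuinely heterogeneous per-gene
dispersions, or gene-specific compensation variance.  Passing recovery
tests therefore demonstrates correctness of the estimators under the
study's statistical model, not robustness to every failure mode of real
RNA-seq.

## Problem sizes and numerics

Test and acceptance runs use 400 genes per arm (about 300–700 hemizygous
gene x line pairs passing the cutoff per study), 500 intergenic regions, 96
spike-ins, and the full 249-sample design; bootstrap B is reduced to
100–300 where only medians (not CIs) are consumed, since the point
estimates are independent of B.  Recovery of the cohort median compensation
is accurate to well under 0.01 at this scale; the CV threshold is recovered
to a few percent over 50 seeds.  Degenerate inputs are handled explicitly:
zero-mean features are skipped in CV computation, constant vectors yield
undefined correlations (reported missing), fully tied comparisons return
p = 1, and curves that never reach the CV threshold raise an error naming
the curve range.

## Known limitations

* Per-gene compensation values from the original deposited data are not
  reproduced — that requires the deposited count matrices and the original
  software versions; the package reproduces the design and the method.
* The common-dispersion default of the DE test miscalibrates per-gene
  p-values if true dispersions vary strongly across genes (use
  `dispersion="per-gene"` there).
* The QC threshold log2(0.75) is a heuristic midpoint; lines with strong
  true compensation (c near 1.5) inside small segments could in principle
  be misflagged.  It is configurable.
* Whether intergenic CVs should be computed on counts or on replicate fold
  differences is ambiguous in the source description; counts-based CV is
  implemented.
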
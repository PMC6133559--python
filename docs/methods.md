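# Methods

This note records the models, estimators, conventions and defaults the
package implements, the reasoning behind choices that were genuinely
open, and what the synthetic data do and do not establish.

## Expression quantification from flow cytometry

**Event filtering.** Events with non-positive scatter or fluorescence
are always removed (they cannot be log-transformed). Two configurable
gates follow: quantile bounds on log FSC.A, log FSC.H and log FL1
(default 0.0005/0.9995 — the "extreme values" cut), and a singlet gate
keeping events whose smoothed 2-D histogram density on
(log FSC.A, log FSC.H) is at least 0.5% of the density maximum. The
original analysis used a model-based clustering package for singlet
gating; the density gate is a deliberate, simpler substitution. Its
defaults are chosen to retain ≥ 99% of a homogeneous singlet cloud.
Quantile bounds are data-relative, so they cannot remove a doublet
subpopulation of a few percent; we accept residual doublets on the
expression side because the size normalization below nearly cancels
them (a doublet roughly doubles FL1 *and* FSC, moving it along, not
off, the size axis), which we quantified at < 1% inflation of the
expression SD for a 2% doublet fraction. Doublets matter on the
fitness-counting side and are handled there explicitly.

**Size normalization.** A PCA is computed on (log₁₀ FSC.A, log₁₀ FL1).
Both eigenvectors pass through the data centroid, so their
"intersection" is the centroid; ν is the vector from the origin to it.
The cloud is rotated about the centroid by the angle θ between the
first eigenvector and ν, and the rotated fluorescence coordinate is
divided by the rotated scatter coordinate. The construction does not
fix signs, so we adopt: the first eigenvector is the larger-eigenvalue
direction taken with positive dot product with ν, and the rotation
maps it exactly onto ν. When the major axis already lies along the
centroid ray, θ = 0 and the output reduces to the plain ratio of log
channels.

A property worth knowing: the rotation attributes the cloud's major
axis to cell size. Expression noise contributes variance orthogonal to
the size axis, so a small part of it is absorbed by the rotation; the
attenuation grows with the squared ratio of expression to size
variance (≈ 1% of noise strength at CV 0.1 and ≈ 10–15% at CV 0.28
under the generator's default size spread of 0.3 decades). This is a
property of the method, not of the implementation; it compresses noise
estimates smoothly and monotonically and therefore preserves the
ordering that the residual analysis uses.

**mRNA calibration.** Relative mRNA level is
y = 10^(a·log₁₀ x + b) with the study's least-squares estimates
a = 10.469, b = −9.586 as defaults; the map is strictly increasing and
exactly log-log linear.

**Sample summaries.** Median m and SD s of per-cell expression are
computed from at least 1000 cells (configurable floor; thinner samples
are flagged, not summarized). Four noise metrics are derived, all with
the median in the denominator: noise strength s²/m (the Fano-factor
analogue), SD, CV s/m, and log₁₀ CV. The identities
noise_strength = CV²·m and log_cv = log₁₀(CV) hold exactly.

**Batch correction.** Flow-run (and optionally plate-row) effects are
estimated on control samples with fixed-effects OLS on two scales that
are linear in log fluorescence: u = log₁₀ m, and v = s/(m·ln 10),
which first-order error propagation (σ²_f(x) ≈ σ²·f′(x)², f = log)
identifies with the SD of log₁₀ of the signal. Fitted effects, centred
on the control mean, are subtracted from every sample and the result
is back-transformed. Identical controls across runs give an identity
correction.

**Autofluorescence** is removed by subtracting the mean (m, s) of a
non-fluorescent strain's replicates. Because the calibration exponent
is large, autofluorescence that is small relative to the reporter
signal becomes vanishingly small on the mRNA scale; the correction
mainly matters for null-expression genotypes.

**Replicate filtering and aggregation.** Within each genotype,
replicates whose m or s deviates from the replicate median by more
than 4 raw MADs (median absolute deviation without a consistency
constant) are discarded; fitness replicates use 5 MADs. With MAD = 0
only strictly positive deviations drop. Surviving replicates are
divided by the reference-strain replicate mean, expressed as percent,
averaged, and given 95% Student-t CIs when at least four replicates
survive (the CI method is a choice; the data only warrant a generic
small-sample interval).

## Competitive fitness

**Two-color classification.** After removing extreme values, a PCA on
(log FL1, log FL2) separates a size axis (first component) from a
color axis (second component). A Gaussian KDE (Silverman bandwidth) of
the second-component scores is cut at the two deepest minima between
the three largest modes: YFP low, GFP high, mixed doublets in between.
With fewer than three modes the sample is treated as doublet-free
(warning); one- and two-mode samples are labelled by the sign of
log(FL1/FL2). A valley must fall below 70% of the smaller adjacent
mode to count, so wiggles of a unimodal density are not split.

**Doublet correction.** Same-color doublets are invisible, but with
random pairing the mixed-doublet count obeys DYG = 2·√(DY·DG)
(the Hardy-Weinberg p² : 2pq : q² analogy) and doublet proportions are
equal across colors, DY/TY = DG/TG. The unique solution is
DY = (DYG/2)·√(TY/TG) and DG = (DYG/2)·√(TG/TY), giving
NY = TY + DY + DYG and NG = TG + DG + DYG. The identities are enforced
to 1e-9 relative error in the tests.

**Generations.** Per cycle, g = log₂(D_end·f / D_start) from densities
measured before each dilution and the dilution factor f; the
plate-level value is the median across wells and cumulative sums give
per-timepoint generations.

**Fitness regression.** w = exp(slope) from an unweighted OLS of
ln(NY/NG) (or ln(f_H/f_L) for the pyrosequencing assays, after
excluding samples with mean peak height below 5) on generations, with
a free intercept and all timepoints included. The per-series t-CI
(df = timepoints − 2) is *conditional on the trajectory*: genetic
drift at bottlenecks makes residuals a correlated random walk and
the per-series interval under-covers (≈ 88% measured under the
default assay design). The interval to report is the across-replicate
t-CI computed by `relative_fitness`, whose empirical coverage is 95%
under the same conditions. Relative fitness divides each replicate's w
by the mean reference-strain w after 5-MAD filtering of both sets, and
a one-sample t-test against 1 is provided.

**Doubling time** is the inverse slope of log₂(density) on time over
user-selected log-phase points.

## Pyrosequencing quantification

Peak-height frequency: freq = h_G / (h_G + 0.86·h_A); the conventional
0.86 factor multiplies A peaks (the stated alternative — dividing —
would be the inverse convention; multiplication is adopted and the
synthetic pyrograms encode its exact inverse). Two bias corrections
are available: the printed linear map y = x·(0.5/0.45) − 0.111
(calibrated so the single-copy control's observed 0.55 maps to 0.5),
clipped to [0, 1]; and a monotone smoothing fit through control
strains of known frequency (isotonic averaging followed by a monotone
PCHIP cubic, linear extension outside the calibrated range, clipped to
[0, 1] — out-of-range behaviour is unspecified by the source, so
clipping is a package choice). Relative mRNA abundance follows
C = A·G/(A·G + (1−G)) inverted to A = (1−G)·C/((1−C)·G); the pair
round-trips exactly. Copy-number calls pick the candidate whose
expected frequency n/(n+1) is nearest the replicate mean and flag
strains whose frequency is significantly *above* the claimed
expectation (one-sample t-test, p < 0.05), the pattern produced by
undetected extra tandem insertions. When a pyrogram reads two variable
positions, their frequencies are averaged by the caller.

## ΔNoise / ΔFitness analysis

**LOESS.** Tricube-weighted local polynomial regression, local
quadratic by default, neighbourhood of ⌊n·span⌋ points, distance ties
broken by input order. The implementation was validated to ~1e-12
against an independent reference smoother on a frozen fixture
(`tests/data/loess_oracle.csv`) for all five grid spans; exactness on
globally quadratic data at span 1 follows because a weighted quadratic
fit interpolates data lying exactly on a quadratic.

**Residuals and the optimum split.** Genotypes above 125% of wild-type
expression are excluded before fitting. ΔNoise and ΔFitness are the
residuals of span-2/3 LOESS fits of noise and fitness on median
expression. The fitted fitness curve is evaluated on a 2001-point grid
over the observed expression range (the threshold is therefore
resolved to about 0.06% expression); the optimum threshold is the
lowest expression left of the curve's maximum at which the prediction
reaches (max − 0.005). Genotypes below it are "far" from the optimum.
If the curve never drops that much on the low side, all genotypes are
"close" and a warning is raised.

**Tests.** Pearson correlations between ΔNoise and ΔFitness are
computed per optimum class, with p from the t-distribution (n−2 df) or
from permutations of one margin. Group comparisons (ΔNoise < −1 "low"
vs > +1 "high", middle band excluded) use permutation tests: values
are shuffled between groups 10⁵ times and p is the proportion of
shuffles whose absolute difference of medians (or means/SDs, for the
single-cell doubling-time comparisons) is **at least** the observed
difference. The non-strict inequality is deliberate: it is the valid
permutation convention, it makes identical groups give p = 1, and it
reproduces the exhaustive-enumeration result (e.g. p = 1/3 for
{1,2} vs {3,4} on medians). Zero exceedances are reported as
p < 1/n_perm. The robustness grid repeats the whole analysis over
5 noise-spans × 5 fitness-spans × 4 fitness drops = 100 combinations.

## Individual-based growth model

Each cell draws expression E from N(μ_E, σ_E²) at every division
(mother and daughter independently — deliberately ignoring any
inheritance of expression state), and E sets the doubling time through
DT = −40E + 160 (linear) or DT = −160·exp(−(E−1)²/0.18) + 240
(inverted Gaussian, optimum at E = 1, DT 80 at the optimum and 240 far
from it). Defaults: experiment duration T = 1000 min, 10³ founders,
100 replicates, reference genotype μ = 1, σ = 0.1 sharing the focal
genotype's DT function (overridable). Noise can be specified as SD
(σ = ν), CV (σ = ν·μ) or Fano factor (σ = √(ν·μ)).

Numerical choices the source leaves open:

* **Negative draws** are redrawn until E ≥ 0 (truncated normal); at
  noise values up to 3 the untruncated normal would produce
  biologically meaningless negative expression and break the linear
  DT map.
* **DT floor** of 1 min (configurable) keeps the linear function
  positive at E ≥ 4, reachable after truncation at high σ.
* **Desynchronization** multiplies the first DT of every founder by a
  uniform(0,1) draw, in the seed run and again for the main run's
  founders.
* The **seed run** grows 10³ cells for the full duration and the main
  run's founders are sampled from its final population, inheriting a
  stationary expression composition (fast-dividing states are
  over-represented, as they should be).
* A **hard population cap** (default 5×10⁷) raises an error rather
  than silently subsampling.

Fitness is exp(ln(N_i/N_ref)/T) as defined by the model — the division
by T in minutes makes values sit very close to 1; a per-generation
variant is available as a convenience. Replicates are paired: each
replicate of every genotype shares its reference run, so contrasts are
computed under common demographic noise. Population counts are exact
(every division adds one cell), and runs are bit-reproducible for a
fixed seed.

Expected behaviour, asserted in the tests at scaled settings (T = 600,
200 founders, 30 paired replicates): with the inverted-Gaussian DT,
noise raises fitness far below the optimum and lowers it at the
optimum, and high noise flattens the fitness-vs-mean landscape; with
the linear DT, noise never hurts (growth rate 1/DT is convex in E).

## Power analysis of the competition design

Each simulated assay: deterministic enrichment of the log-odds by the
selection coefficient per generation, binomial drift at every dilution
(the bottleneck transfers n_final/2^g cells — growth to a fixed final
count, then a 2^g-fold dilution), and binomial counting noise at each
of n_cycles + 1 assessments. Drift is modelled as binomial rather than
hypergeometric (the transferred volume is small relative to the
culture). The selection coefficient is re-estimated by the same
log-odds-slope estimator the fitness module uses, for consistency —
the source does not specify its internal estimator. The SD over 5000
simulations (configurable) feeds a two-sample t-test power inversion
(noncentral t via statsmodels, significance 0.05, power 0.95) giving
the minimum detectable difference. The full 20,160-combination design
grid is supported through configuration; the default demonstration
sweeps generations-per-cycle at fixed total growth, where precision
peaks at intermediate spacing: frequent mild dilutions buy assessments
but cost little, while rare harsh dilutions impose severe bottleneck
drift.

## Synthetic data: what it emulates, and what it does not

The generators are exact inverses of the pipeline's transformations
wherever the pipeline is deterministic: zero-noise flow events invert
to the true expression exactly, noise-free competition series give the
true slope exactly, and noise-free pyrograms undo the 0.86 and linear
PCR corrections exactly. Study conditions are the defaults: 43
genotypes spanning 5–125% of wild-type expression, six expression
replicates of 10,000 events, eight competition replicates with four
timepoints at seven generations per cycle, 50,000 events counted and
10⁴-cell bottlenecks, five pyrosequencing replicates; the fitness
truth is a plateau with a 5% deficit at null expression (the
approximate growth cost of deleting the focal gene) and a planted
noise effect (default 0.001 fitness per percentage point of ΔNoise)
applied only below the plateau's analytic 0.005-drop point.

Assumptions a user should know:

* **Log-normal single-cell expression**, parameterized by median and
  SD. The empirical distribution family is not constrained by the
  data the pipeline sees; only positivity and unimodality matter for
  the round trips.
* **Doublets pair cells at random with respect to color** (so the
  Hardy-Weinberg relations hold in expectation) but with correlated
  partner sizes, reflecting that clumps are mostly mother–daughter
  pairs; fully independent sizes would smear the mixed-doublet
  population along the color axis far more than real pyrogram-side
  data suggest.
* **Batch effects are off by default** (labels are emitted and the
  correction path is exercised, but no run offsets are planted unless
  requested), and autofluorescence is a small additive background.
* The generators do **not** emulate instrument metadata, spectral
  spillover/compensation, cell-cycle or age structure, inheritance of
  expression between generations, or non-transitive competition.

Consequently, passing tests show that the estimators recover the
truth of *this* data-generating process at the study's sample sizes —
including its known self-distortions such as the rotation attenuation
— not that the process matches any particular instrument.

## Problem sizes in the test suite

The suite runs at desk scale by design: simulator checks use T = 600
min, 200 founders and 30 paired replicates; estimator-recovery checks
use 1000 simulated competition series; power sweeps use 1500–2000
simulations per point; the end-to-end panel uses the full 43 genotypes
at 10,000 events per sample; permutation checks use 10⁵ shuffles.
Coverage of the fitness CI is assessed on 250 four-replicate panels
(four being the floor at which CIs are reported).

## Known limitations

* FCS binary files are not parsed; event tables are read from CSV
  (channel-name mapping supported). The upstream raw-data repositories
  are not required by any analysis here.
* The per-series fitness CI ignores drift correlation (documented
  above); use replicate-level intervals.
* LOESS standard errors are not computed — the analysis only uses
  fitted values and residuals.
* The batch-correction model is fixed-effects OLS; it does not model
  random run effects or interactions.
* `infer_copies` assumes a single unmarked native copy unless told
  otherwise and tests only against the claimed candidate.
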
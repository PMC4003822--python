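# Methods

## Model

`bcrgt` genotypes SNP-array data one SNP at a time from the summarized
A- and B-allele log-intensities `x_i`, `y_i` of the samples
`i = 1..n`.  Because a genotype is determined by the *relative*
behaviour of the two allelic signals, the model regresses one channel
on the other: each sample belongs to an unobserved genotype cluster
`C_i ∈ {AA, AB, BB}` with mixing proportions `π`, and within cluster
`k`

```
y_i = β_k0 + β_k1 x_i (+ CN_i β_kCN) + ε_i,     ε_i ~ N(0, (c_k σ)²)
```

with a single base error scale `σ` shared across clusters and fixed
multipliers `c = (2, 1, 2)`: the homozygous clouds are visibly about
twice as wide as the heterozygous cloud on real arrays, and tying the
scales stabilizes SNPs in which a cluster is thin or absent.  `σ²` is
estimated frequentist; no prior is placed on it.

Each cluster's coefficient vector carries a conjugate normal prior
`N(β_prior,k, σ²V)` with diagonal `V`, giving the closed-form
posterior-mean update

```
β_k = (V⁻¹ + X'WX)⁻¹ (V⁻¹ β_prior,k + X'Wy),   W = diag(resp_k / c_k²).
```

The prior is the point of the method: for a SNP whose cohort happens to
contain only one or two genotypes, an unpenalized mixture fit would
hallucinate clusters, while the prior keeps the missing clusters parked
at their population-typical lines.

Fitting alternates an E-step (responsibilities
`resp_ik ∝ π_k N(y_i; X_iβ_k, (c_kσ)²)`, computed in log space) with the
M-step above, plus

* `σ² ← Σ_ik resp_ik r_ik²/c_k² / Σ_ik resp_ik` (pooled, de-scaled
  residuals),
* `π_k ∝ Σ_i resp_ik · w_k` with cluster weights `w = (1, w_AB, 1)`.

Iteration stops when the largest absolute parameter change falls below
`tol` (default 1e-6) or after 30 iterations; the last iterate is the
estimate.  A sample is called by its maximum-responsibility cluster
(clusters relabeled by intercept order, lowest intercept → AA), or
NoCall when that responsibility is below the confidence threshold
(default 0.999; `threshold=0` forces a 100% call rate).

### Heterozygote down-weighting and EM monotonicity

`w_AB < 1` (default 0.5) counteracts the engine's tendency to over-fill
the narrow AB cluster with borderline points; it deliberately biases
the `π` update away from the Q-maximizer, so the penalized
log-likelihood is guaranteed non-decreasing only at `w_AB = 1`.  The
ascent property is therefore verified (tests, acceptance script) with
`w_AB = 1`; production calling keeps the default 0.5.

### Interpretation of V

The posterior-mean formula corresponds to a prior covariance `σ²V`,
yet the prior variances are calibrated directly from OLS sampling
variances, which already include `σ²`.  We use the formula literally
with `V = diag(v_intercept, v_slope[, v_cn])`: `σ` then cancels from
the coefficient update and the prior's strength is fixed in units of
observations, which keeps behaviour stable across SNPs whose `σ`
differ.  (The alternative — dividing `V` by an estimate of `σ²` —
changes the effective prior weight by a SNP-dependent constant; at the
calibrated magnitudes the calls are insensitive to the choice.)

## Prior construction

**Generic prior.**  A pool of 5,000–50,000 random (SNP, sample) pairs
is drawn (default 5,000).  Sorted by the log-ratio `d = x − y`, the
pool separates into BB / AB / AA bands.  First differences of sorted
`d` are smoothed by a trailing moving average of `window` points
(default 25); the largest smoothed jump with rank in (25%, 50%] and the
largest in (50%, 75%] locate the two gaps, and the cut is then placed
at the largest single first difference inside the winning window
(the trailing average peaks up to a window *after* a gap, so using its
argmax directly would clip the edge of the next cluster — measurably
tilting the pooled OLS fits).  Per labeled cluster, OLS of `y` on `x`
yields the prior intercepts; slopes default to 1 (`slope_mode="unit"`,
the pooled clouds being symmetric about the 45° line) with
`slope_mode="fitted"` available.  In unit mode the intercepts are kept
from the full OLS fit: at the pooled scale fitted slopes are within
~1e-2 of 1, so the induced intercept offset is negligible.

**Prior variances.**  100 monomorphic SNPs (≥99% of a SNP's `d` values
beyond the pooled homozygote cut on one side; sampled under seed) are
fitted by single-cluster OLS; the average sampling variance of the
slope is divided by 3 (informative: slopes are pulled toward the pooled
value) and that of the intercept multiplied by 3 (diffuse: intercepts
follow the data).  Cohorts with 10–99 such SNPs proceed with what
exists (warning); below 10 the calibration refuses.

**Per-SNP trained priors.**  Given a training cohort with known
genotypes (disjoint samples, enforced by id check), each SNP's clusters
present with ≥3 samples are fitted by OLS; absent clusters keep the
generic entries, and SNPs whose trained intercepts violate the
AA < AB < BB ordering fall back to the generic prior entirely.

## Copy-number covariate

Upstream CNA status (loss/normal/gain per SNP and sample) enters as a
fixed covariate, never re-estimated inside EM:

* `constant` = max(|2.5th|, |97.5th| percentile) of pooled `d` — the
  typical homozygote offset;
* loss: `CN = +constant` when `x > y` (B-allele loss), else
  `−constant`; gain: `±constant/5`, the five-fold attenuation
  reflecting probe saturation; normal: 0.  Ties `x = y` take the B-loss
  branch.
* each cluster's prior gains a CN coefficient with mean 1 and variance
  `100 × v_slope` — weak, so the data set the magnitude; mean 1 makes
  `CN` approximate the literal vertical displacement.

Because a true heterozygote cannot survive a hemizygous deletion, the
fraction of AB calls among called SNPs in loss regions is a
retrospective diagnostic of the upstream CNA segmentation: samples
above 1% are flagged.  The diagnostic is most informative in forced-call
mode (threshold 0); at the 0.999 threshold the ambiguous loss-region
points largely become NoCall and leave the proportion undefined or
deflated.

## Simulator

The generator mirrors the calling model: per SNP a minor allele
frequency is drawn from `maf_range` (default U(0.05, 0.5)), a fraction
`monomorphic_fraction` (default 0.1) of SNPs is cohort-monomorphic
(these also feed the prior-variance calibration), genotypes follow
Hardy–Weinberg proportions, and the A/B probe labeling is randomized
per SNP so the pooled clouds are symmetric about the 45° line, as on
real arrays.  Points lie on cluster lines with intercepts (−3, 0, +3)
(log units), unit slopes, `σ_het = 0.15`, hom noise `2σ_het`; `x` is
placed at genotype centers (+1, 0, −1) with spread 0.3 — a simulator
convention, since the model conditions on `x`.  Optional per-SNP
intercept jitter (`intercept_jitter_sd`) emulates probe-affinity
heterogeneity; it is what makes per-SNP training outperform the generic
prior, and the trained-prior experiments enable it (0.3).

**Copy loss** replaces an observation by its hemizygous version: the
surviving allele (homozygotes keep theirs; heterozygotes lose one by
fair coin) is drawn as that allele's homozygous-cluster point whose own
channel is then reduced by `loss_shift` (default 2.25), so hemizygous
points land between the AB and homozygous clouds — the regime where a
CNA-naive caller produces spurious AB calls.  `loss_shift` must stay
below the homozygote offset (3) for the observed-direction rule to
keep its sign; 2.25 ≈ 0.66 × the estimated `constant` (≈3.4).  Truth
records the surviving allele's homozygous code for scoring, and the
pre-CNA genotype separately (the "paired normal"), which defines the
genotyping-error rate: an AB call on a homozygous germline, or opposite
homozygous calls.  **Gain** adds `gain_shift` (default 0.3, saturation-
attenuated) to the gained allele's channel; truth genotypes are
unchanged.  **Contamination** mixes tumor and germline signal on the
raw intensity scale before re-logging.

What the simulator does *not* emulate: probe-level background and
cross-hybridization, batch effects, the intensity compression of real
hemizygous signals (a fixed shift is used), minor-clone mosaicism, and
array-specific saturation curves beyond the fixed 1/5 gain factor.
Passing tests therefore demonstrate correctness of the algorithmic
machinery under the model's own assumptions, not field performance on
any particular array generation.

## Numerical choices

* Natural logs everywhere; a different base rescales all coefficients
  jointly without changing calls.
* Even sample counts: median = mean of the two central order
  statistics.
* Responsibilities in log space with log-sum-exp; a sample whose three
  densities all underflow gets uniform responsibilities (counted).
* Quantile normalization pools a sample's A and B channels (one
  physical array), runs on the raw scale (exp of stored logs), re-logs,
  and gives ties the mean reference value of the tied ranks.  It
  refuses cohorts with CNA calls unless forced.
* Empty clusters (responsibility mass < 1e-8) freeze at the prior mean
  for that iteration.
* SNPs with < 4 samples skip EM and classify by nearest prior line.
* Non-finite parameters abort that SNP with a NoCall-all row and a
  warning.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run on simulated cohorts of
100–1,000 SNPs (5,000 for the clean-cohort concordance check) with
80–270 samples, 20 replicates for the paired trained-vs-generic
comparison, and 1,000 random instances for the closed-form
posterior-mean oracle — sizes chosen so the full suite completes in a
few minutes on one CPU while keeping every rate estimate's Monte-Carlo
error well below the margins being asserted.

## Known limitations

* CNA *detection* is out of scope; the covariate is only as good as
  the upstream status calls, though the heterozygosity diagnostic
  catches global mislabeling.
* A single `constant` is used genome-wide; focal events with unusual
  magnitudes are absorbed by the weak `β_kCN` prior rather than
  modeled.
* Normal-cell contamination is not modeled as a covariate; heavy
  contamination shrinks CNA shifts toward diploid positions and
  degrades loss-region suppression.
* Gain regions keep diploid genotype notation; no triploid calls are
  attempted.
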
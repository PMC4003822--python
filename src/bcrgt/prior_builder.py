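"""Construction of prior distributions for the cluster-regression coefficients.

The calling engine fits, per SNP, a three-component mixture of linear
regressions of the B-allele log-intensity y on the A-allele
log-intensity x (clusters = genotypes AA, AB, BB).  Its Bayesian layer
needs, per cluster, a prior mean for (intercept, slope) and a prior
variance per coefficient.  Two prior flavours exist:

* a *generic* prior, shared by all SNPs, estimated from a large random
  pool of (x, y) points across SNPs and samples: the pooled log-ratio
  d = x - y is sorted, its first differences are smoothed with a
  trailing moving average, and the two largest smoothed jumps — one
  searched between the 25th and 50th and one between the 50th and 75th
  percentiles — split the pool into BB / AB / AA groups, each of which
  is then fitted by ordinary least squares;
* *per-SNP trained* priors, fitted by OLS per genotype cluster on a
  training cohort with known genotypes, falling back to the generic
  prior for clusters absent from training.

Prior variances are calibrated from SNPs carrying a single genotype
(monomorphic, hence a single regression line): the slope prior variance
is one third of the average OLS slope sampling variance (a deliberately
informative prior pulling slopes toward the pooled estimate), and the
intercept prior variance is three times the average OLS intercept
sampling variance (letting intercepts follow the data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import CALL_CODES, GenotypeCalls, IntensityDataset

__all__ = [
    "PriorSpec",
    "PooledPoints",
    "pool_subset",
    "split_three_clusters",
    "estimate_generic_prior",
    "estimate_prior_variances",
    "build_generic_prior",
    "train_per_snp_priors",
    "write_prior",
    "read_prior",
]

# cluster index convention used everywhere: 0=AA, 1=AB, 2=BB,
# with intercepts ordered beta_AA,0 < beta_AB,0 < beta_BB,0
CLUSTER_NAMES = CALL_CODES


@dataclass
class PriorSpec:
    """Per-cluster prior means and per-coefficient prior variances.

    ``beta_mean`` has shape (3, p) with rows AA, AB, BB and columns
    (intercept, slope[, cn]); ``v_diag`` is the diagonal of V in the
    posterior-mean formula (V^-1 + X'WX)^-1 (V^-1 beta_prior + X'Wy);
    ``pi`` is the initial mixing proportion of each cluster.
    """

    beta_mean: np.ndarray
    v_diag: np.ndarray | None = None
    pi: np.ndarray = field(default_factory=lambda: np.full(3, 1.0 / 3.0))

    def __post_init__(self) -> None:
        self.beta_mean = np.asarray(self.beta_mean, dtype=float)
        if self.beta_mean.shape[0] != 3:
            raise ValueError("exactly 3 clusters required")
        if not (self.beta_mean[0, 0] < self.beta_mean[1, 0] < self.beta_mean[2, 0]):
            raise ValueError("cluster intercepts must be strictly increasing (AA < AB < BB)")
        if self.v_diag is not None:
            self.v_diag = np.asarray(self.v_diag, dtype=float)
            if self.v_diag.shape != (self.beta_mean.shape[1],):
                raise ValueError("v_diag length must match coefficient count")
            if (self.v_diag <= 0).any():
                raise ValueError("prior variances must be positive")
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (3,) or (self.pi <= 0).any():
            raise ValueError("pi must be 3 positive proportions")
        self.pi = self.pi / self.pi.sum()

    @property
    def n_coef(self) -> int:
        return self.beta_mean.shape[1]

    @property
    def has_cn(self) -> bool:
        return self.n_coef == 3


@dataclass
class PooledPoints:
    """A random pool of (x, y) points across SNPs and samples.

    ``labels`` (filled by :func:`split_three_clusters`) holds cluster
    indices 0/1/2 = AA/AB/BB; ``cut_d`` the two log-ratio values at the
    BB|AB and AB|AA boundaries.
    """

    x: np.ndarray
    y: np.ndarray
    labels: np.ndarray | None = None
    cut_d: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")

    @property
    def d(self) -> np.ndarray:
        """Allelic log-ratio d = x - y."""
        return self.x - self.y


def pool_subset(dataset: IntensityDataset, size: int, seed: int | None = None) -> PooledPoints:
    """Draw ``size`` (SNP, sample) pairs uniformly without replacement."""
    if not dataset.centered:
        raise ValueError("pool_subset expects a centered dataset")
    total = dataset.n_snps * dataset.n_samples
    if size > total:
        raise ValueError(f"requested {size} points but only {total} available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=size, replace=False)
    return PooledPoints(x=dataset.a_log.ravel()[idx], y=dataset.b_log.ravel()[idx])


def _trailing_moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Un-weighted mean of the previous ``window`` points (partial at the start)."""
    c = np.concatenate(([0.0], np.cumsum(values)))
    n = len(values)
    out = np.empty(n)
    for t in range(n):
        lo = max(0, t - window + 1)
        out[t] = (c[t + 1] - c[lo]) / (t + 1 - lo)
    return out


def split_three_clusters(points: PooledPoints, window: int = 25) -> PooledPoints:
    """Label pooled points as BB / AB / AA by the first-difference jump search.

    The sorted log-ratios d are differenced; the differences are smoothed
    by a trailing moving average of ``window`` points; the largest
    smoothed jump with rank in (25%, 50%] and the largest with rank in
    (50%, 75%] define the two cluster boundaries.  Points below the
    first cut are BB (lowest d), above the second cut AA.
    """
    d = points.d
    n = len(d)
    if n < 3 * window:
        raise ValueError(f"need at least {3 * window} points for window={window}")
    order = np.argsort(d, kind="stable")
    d_sorted = d[order]
    diffs = np.diff(d_sorted)  # diffs[t-1] = d_(t) - d_(t-1), t = 1..n-1
    smoothed = _trailing_moving_average(diffs, window)

    def _band_argmax(frac_lo: float, frac_hi: float) -> int:
        t_lo = int(np.floor(frac_lo * n)) + 1
        t_hi = min(int(np.floor(frac_hi * n)), n - 1)
        if t_lo > t_hi:
            raise ValueError(
                "percentile band contains no candidate cut; use a larger subset"
            )
        band = smoothed[t_lo - 1 : t_hi]  # smoothed[t-1] corresponds to cut at t
        best = np.flatnonzero(band == band.max()) + t_lo
        center = 0.5 * (t_lo + t_hi)
        t = int(best[np.argmin(np.abs(best - center))])
        # the trailing average peaks up to a window past the jump; place the
        # cut at the largest single first difference inside that window
        lo = max(1, t - window + 1)
        return lo + int(np.argmax(diffs[lo - 1 : t]))

    cut1 = _band_argmax(0.25, 0.50)
    cut2 = _band_argmax(0.50, 0.75)

    labels_sorted = np.empty(n, dtype=int)
    labels_sorted[:cut1] = 2  # BB: lowest d
    labels_sorted[cut1:cut2] = 1  # AB
    labels_sorted[cut2:] = 0  # AA: highest d
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    cut_d = (
        float(0.5 * (d_sorted[cut1 - 1] + d_sorted[cut1])),
        float(0.5 * (d_sorted[cut2 - 1] + d_sorted[cut2])),
    )
    return PooledPoints(x=points.x, y=points.y, labels=labels, cut_d=cut_d)


def _ols(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """(intercept, slope) of ordinary least squares of y on x."""
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return coef


def estimate_generic_prior(
    points: PooledPoints,
    slope_mode: str = "unit",
    v_diag: np.ndarray | None = None,
) -> PriorSpec:
    """OLS per labeled cluster -> generic prior means and mixing proportions.

    ``slope_mode="unit"`` replaces all fitted slopes by 1 (the pooled
    clouds are symmetric about the 45-degree line, and unit slopes work
    well in practice); ``"fitted"`` keeps the OLS slopes.
    """
    if points.labels is None:
        raise ValueError("points must be labeled; run split_three_clusters first")
    if slope_mode not in ("unit", "fitted"):
        raise ValueError(f"unknown slope_mode {slope_mode!r}")
    beta = np.empty((3, 2))
    pi = np.empty(3)
    for k in range(3):
        mask = points.labels == k
        if mask.sum() < 3:
            raise ValueError(f"cluster {CLUSTER_NAMES[k]} has fewer than 3 points")
        beta[k] = _ols(points.x[mask], points.y[mask])
        pi[k] = mask.mean()
    if slope_mode == "unit":
        beta[:, 1] = 1.0
    order = np.argsort(beta[:, 0])  # relabel by intercept: lowest -> AA
    return PriorSpec(beta_mean=beta[order], v_diag=v_diag, pi=pi[order])


def _ols_sampling_variances(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(intercept, slope) sampling variances of the OLS fit of y on x."""
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 observations for OLS sampling variances")
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    s2 = float(resid @ resid) / (n - 2)
    xtx_inv = np.linalg.inv(X.T @ X)
    return s2 * xtx_inv[0, 0], s2 * xtx_inv[1, 1]


def find_monomorphic_snps(
    dataset: IntensityDataset,
    cut_d: tuple[float, float],
    purity: float = 0.99,
) -> np.ndarray:
    """Row indices of SNPs whose samples are (almost) all one homozygote.

    A SNP counts as monomorphic when at least ``purity`` of its
    log-ratios fall beyond the pooled AB|AA cut (all AA) or below the
    pooled BB|AB cut (all BB).
    """
    d = dataset.log_ratio()
    lo, hi = cut_d
    frac_aa = (d > hi).mean(axis=1)
    frac_bb = (d < lo).mean(axis=1)
    return np.flatnonzero((frac_aa >= purity) | (frac_bb >= purity))


def estimate_prior_variances(
    dataset: IntensityDataset,
    cut_d: tuple[float, float],
    n_mono: int = 100,
    seed: int | None = None,
) -> tuple[float, float]:
    """Calibrate (v_slope, v_intercept) from monomorphic SNPs.

    Per selected SNP, the single-cluster OLS fit of y on x yields
    sampling variances of slope and intercept; their averages are scaled
    by 1/3 (slope: informative prior) and 3 (intercept: diffuse prior).
    """
    if not dataset.centered:
        raise ValueError("estimate_prior_variances expects a centered dataset")
    candidates = find_monomorphic_snps(dataset, cut_d)
    if len(candidates) < 10:
        raise ValueError(
            f"only {len(candidates)} monomorphic SNPs found; need at least 10"
        )
    if len(candidates) < n_mono:
        warnings.warn(
            f"only {len(candidates)} monomorphic SNPs available "
            f"(requested {n_mono}); proceeding with all of them",
            stacklevel=2,
        )
        chosen = candidates
    else:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=n_mono, replace=False)
    var_i = np.empty(len(chosen))
    var_s = np.empty(len(chosen))
    for j, snp in enumerate(chosen):
        var_i[j], var_s[j] = _ols_sampling_variances(dataset.a_log[snp], dataset.b_log[snp])
    return float(var_s.mean() / 3.0), float(3.0 * var_i.mean())


def build_generic_prior(
    dataset: IntensityDataset,
    subset_size: int = 5000,
    window: int = 25,
    slope_mode: str = "unit",
    n_mono: int = 100,
    seed: int | None = None,
) -> PriorSpec:
    """One-stop generic prior: pool, split, fit, calibrate variances."""
    size = min(subset_size, dataset.n_snps * dataset.n_samples)
    points = split_three_clusters(pool_subset(dataset, size, seed=seed), window=window)
    v_slope, v_intercept = estimate_prior_variances(
        dataset, points.cut_d, n_mono=n_mono, seed=None if seed is None else seed + 1
    )
    return estimate_generic_prior(
        points, slope_mode=slope_mode, v_diag=np.array([v_intercept, v_slope])
    )


def _genotype_matrix(known) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(known, GenotypeCalls):
        return known.snp_ids, known.sample_ids, known.calls
    raise TypeError("known_genotypes must be a GenotypeCalls (truth labels)")


def train_per_snp_priors(
    training: IntensityDataset,
    known_genotypes: GenotypeCalls,
    generic: PriorSpec,
    target_sample_ids=None,
    allow_overlap: bool = False,
    min_points: int = 3,
) -> dict:
    """Per-SNP prior means from a training cohort with known genotypes.

    Per SNP and genotype cluster present in training (with at least
    ``min_points`` samples), an OLS fit supplies that cluster's prior
    mean; absent clusters keep the generic entries.  Prior variances and
    an intercept-order consistency requirement come from the generic
    prior; SNPs whose trained intercepts violate the AA < AB < BB order
    fall back to the generic prior entirely.
    """
    if target_sample_ids is not None and not allow_overlap:
        overlap = set(training.sample_ids) & set(target_sample_ids)
        if overlap:
            raise ValueError(
                f"{len(overlap)} sample(s) appear in both training and target sets; "
                "training must use disjoint biological samples (allow_overlap=True to override)"
            )
    snp_ids, sample_ids, calls = _genotype_matrix(known_genotypes)
    if not np.array_equal(snp_ids, training.snp_ids) or not np.array_equal(
        sample_ids, training.sample_ids
    ):
        raise ValueError("known_genotypes must align with the training dataset")

    priors: dict = {}
    for i, snp in enumerate(training.snp_ids):
        beta = generic.beta_mean.copy()
        counts = np.zeros(3)
        for k, name in enumerate(CLUSTER_NAMES):
            mask = calls[i] == name
            counts[k] = mask.sum()
            if counts[k] >= min_points:
                x, y = training.a_log[i, mask], training.b_log[i, mask]
                if np.ptp(x) > 0:
                    beta[k] = _ols(x, y)
        pi = np.maximum(counts, 0.5)
        if not (beta[0, 0] < beta[1, 0] < beta[2, 0]):
            beta = generic.beta_mean.copy()
        priors[snp] = PriorSpec(beta_mean=beta, v_diag=generic.v_diag, pi=pi / pi.sum())
    return priors


# ---------------------------------------------------------------------------
# serialization (plain-text key-value / TSV)


def write_prior(prior: PriorSpec, path) -> None:
    coef_names = ["intercept", "slope", "cn"][: prior.n_coef]
    with open(path, "w") as fh:
        fh.write("key\tcluster\tcoefficient\tvalue\n")
        for k, cname in enumerate(CLUSTER_NAMES):
            for j, coef in enumerate(coef_names):
                fh.write(f"mean\t{cname}\t{coef}\t{prior.beta_mean[k, j]:.12g}\n")
        if prior.v_diag is not None:
            for j, coef in enumerate(coef_names):
                fh.write(f"variance\t.\t{coef}\t{prior.v_diag[j]:.12g}\n")
        for k, cname in enumerate(CLUSTER_NAMES):
            fh.write(f"pi\t{cname}\t.\t{prior.pi[k]:.12g}\n")


def read_prior(path) -> PriorSpec:
    df = pd.read_csv(path, sep="\t")
    coef_names = ["intercept", "slope", "cn"]
    means = df[df["key"] == "mean"]
    n_coef = means["coefficient"].nunique()
    beta = np.empty((3, n_coef))
    for k, cname in enumerate(CLUSTER_NAMES):
        for j in range(n_coef):
            row = means[(means["cluster"] == cname) & (means["coefficient"] == coef_names[j])]
            beta[k, j] = float(row["value"].iloc[0])
    var_rows = df[df["key"] == "variance"]
    v_diag = None
    if len(var_rows):
        v_diag = np.array(
            [float(var_rows[var_rows["coefficient"] == coef_names[j]]["value"].iloc[0])
             for j in range(n_coef)]
        )
    pi_rows = df[df["key"] == "pi"]
    pi = np.array(
        [float(pi_rows[pi_rows["cluster"] == cname]["value"].iloc[0]) for cname in CLUSTER_NAMES]
    )
    return PriorSpec(beta_mean=beta, v_diag=v_diag, pi=pi)
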
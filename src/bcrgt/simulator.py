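"""Synthetic allelic-intensity data with known genotypes and CNA segments.

The generator mirrors the calling engine's model: per SNP, a minor
allele frequency is drawn uniformly from ``maf_range``, genotypes follow
Hardy-Weinberg proportions, and each sample's (x, y) log-intensity pair
lies on its genotype's regression line

    y = beta_k0 + beta_k1 * x + Normal(0, (c_k sigma_het)^2),

with cluster intercepts (-3, 0, +3) for (AA, AB, BB) by default, unit
slopes, and homozygote noise twice the heterozygote noise (c = 2, 1, 2).
The engine models y given x only; the simulator additionally places x
around genotype-specific centers (+1, 0, -1 for AA, AB, BB, spread
``sigma_x``) — a simulator convention, not part of the calling model.

Copy-number loss replaces the observation by its hemizygous version:
the surviving allele (AA -> A, BB -> B, AB -> A or B by fair coin) is
drawn as that allele's homozygous-cluster point whose own channel is
then reduced by ``loss_shift``, so hemizygous points fall between the
heterozygote and homozygote clouds — the regime in which CNA-naive
callers start making AB errors.  Copy-number gain adds the (saturation-
attenuated) ``gain_shift`` to the gained allele's channel.  Normal-cell
contamination mixes tumor and germline signal on the raw intensity
scale before re-logging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import CALL_CODES, GenotypeCalls, IntensityDataset
from .cna_covariate import CNAMatrix, GAIN, LOSS, NORMAL

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "segments_covering",
    "evaluate_concordance",
    "write_truth",
    "read_truth",
]

_CODES = np.array(CALL_CODES, dtype=object)  # 0=AA, 1=AB, 2=BB


@dataclass
class SimConfig:
    """Study-design parameters of one simulated cohort.

    ``cna_segments`` is a tuple of (sample_index, snp_start, snp_stop,
    status) half-open intervals; segments of one sample must not
    overlap.  ``contamination`` is a per-sample normal-cell fraction in
    [0, 1) (scalar broadcast allowed).
    """

    n_snps: int = 1000
    n_samples: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    monomorphic_fraction: float = 0.1
    cluster_intercepts: tuple[float, float, float] = (-3.0, 0.0, 3.0)
    slopes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    sigma_het: float = 0.15
    intercept_jitter_sd: float = 0.0
    x_centers: tuple[float, float, float] = (1.0, 0.0, -1.0)
    sigma_x: float = 0.3
    loss_shift: float = 2.25
    gain_shift: float = 0.3
    cna_segments: tuple = ()
    contamination: float | np.ndarray = 0.0
    seed: int | None = None

    @property
    def sigma_hom(self) -> float:
        return 2.0 * self.sigma_het

    def __post_init__(self) -> None:
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        if not (
            self.cluster_intercepts[0] < self.cluster_intercepts[1] < self.cluster_intercepts[2]
        ):
            raise ValueError("cluster intercepts must be strictly increasing")
        if self.sigma_het <= 0:
            raise ValueError("sigma_het must be positive")
        per_sample: dict[int, list[tuple[int, int]]] = {}
        for s, lo, hi, st in self.cna_segments:
            if not (0 <= lo < hi <= self.n_snps) or not (0 <= s < self.n_samples):
                raise ValueError(f"segment out of bounds: {(s, lo, hi, st)}")
            if st not in (LOSS, GAIN):
                raise ValueError(f"segment status must be -1 or +1, got {st}")
            for plo, phi in per_sample.get(s, ()):
                if lo < phi and plo < hi:
                    raise ValueError(f"overlapping segments for sample {s}")
            per_sample.setdefault(s, []).append((lo, hi))


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort.

    ``genotypes`` are the scoring genotypes (post-CNA: in loss regions
    the surviving allele's homozygous code); ``germline`` the pre-CNA
    genotypes, playing the role of a paired normal sample; ``maf`` the
    per-SNP minor (B) allele frequency.
    """

    genotypes: np.ndarray
    germline: np.ndarray
    maf: np.ndarray
    intercepts: np.ndarray | None = None  # (n_snps, 3) generating intercepts
    config: SimConfig = None


def segments_covering(
    n_snps: int,
    n_samples: int,
    snp_fraction: float,
    status: int = LOSS,
    sample_fraction: float = 0.5,
) -> tuple:
    """Segments putting the first ``snp_fraction`` of SNPs under one CNA
    (a recurrent alteration) for the first ``sample_fraction`` of samples."""
    stop = int(round(snp_fraction * n_snps))
    n_aff = int(round(sample_fraction * n_samples))
    return tuple((s, 0, stop, status) for s in range(n_aff))


def simulate_dataset(config: SimConfig) -> tuple[IntensityDataset, CNAMatrix, SimTruth]:
    """Generate (IntensityDataset, CNAMatrix, SimTruth) under ``config``."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n_snps, config.n_samples
    b0 = np.asarray(config.cluster_intercepts)
    b1 = np.asarray(config.slopes)
    xc = np.asarray(config.x_centers)
    c_k = np.array([2.0, 1.0, 2.0])

    maf = rng.uniform(*config.maf_range, size=n)
    # a share of array SNPs shows a single genotype in any given cohort;
    # these monomorphic SNPs also calibrate the prior variances
    mono = rng.random(n) < config.monomorphic_fraction
    maf[mono] = 0.0
    mono_allele = rng.random(n) < 0.5  # True -> all AA, False -> all BB
    # the array's A/B probe labeling is arbitrary with respect to the
    # major/minor allele, so the minor allele is B for half the SNPs:
    # the pooled clouds come out symmetric about the 45-degree line
    flip = rng.random(n) < 0.5
    p_b = np.where(flip, 1.0 - maf, maf)  # B allele frequency
    p_a = 1.0 - p_b
    p_aa = (p_a**2)[:, None]
    p_ab = (2 * p_a * p_b)[:, None]
    u = rng.random((n, m))
    g = ((u > p_aa).astype(int) + (u > p_aa + p_ab)).astype(int)  # 0/1/2
    g[mono] = np.where(mono_allele[mono], 0, 2)[:, None]

    # per-SNP intercept heterogeneity: real probes differ in affinity, so
    # each SNP's cluster lines sit at slightly different offsets
    B0 = b0 + rng.normal(0.0, config.intercept_jitter_sd, size=(n, 3)) \
        if config.intercept_jitter_sd > 0 else np.broadcast_to(b0, (n, 3))
    rows = np.arange(n)[:, None]
    x0 = xc[g] + rng.normal(0.0, config.sigma_x, size=(n, m))
    y0 = B0[rows, g] + b1[g] * x0 + rng.normal(size=(n, m)) * c_k[g] * config.sigma_het

    status = np.zeros((n, m), dtype=int)
    for s, lo, hi, st in config.cna_segments:
        status[lo:hi, s] = st

    x_t, y_t = x0.copy(), y0.copy()
    geno_score = g.copy()

    loss = status == LOSS
    if loss.any():
        # surviving allele: homozygotes keep theirs, hets lose one at random
        coin = rng.random((n, m)) < 0.5
        surv = np.where(g == 1, np.where(coin, 0, 2), g)  # 0 => A survives, 2 => B
        idx = np.nonzero(loss)
        sv = surv[idx]
        xh = xc[sv] + rng.normal(0.0, config.sigma_x, size=len(sv))
        yh = B0[idx[0], sv] + b1[sv] * xh + rng.normal(size=len(sv)) * c_k[sv] * config.sigma_het
        # reduce the surviving allele's own channel: hemizygous < homozygous signal
        a_side = sv == 0
        x_t[idx] = np.where(a_side, xh - config.loss_shift, xh)
        y_t[idx] = np.where(a_side, yh, yh - config.loss_shift)
        geno_score[idx] = sv

    gain = status == GAIN
    if gain.any():
        coin = rng.random((n, m)) < 0.5
        gained = np.where(g == 1, np.where(coin, 0, 2), g)
        idx = np.nonzero(gain)
        gn = gained[idx]
        x_t[idx] = x_t[idx] + np.where(gn == 0, config.gain_shift, 0.0)
        y_t[idx] = y_t[idx] + np.where(gn == 2, config.gain_shift, 0.0)

    f = np.broadcast_to(np.asarray(config.contamination, dtype=float), (m,))
    if (f < 0).any() or (f >= 1).any():
        raise ValueError("contamination fractions must lie in [0, 1)")
    if (f > 0).any():
        x_t = np.log((1 - f) * np.exp(x_t) + f * np.exp(x0))
        y_t = np.log((1 - f) * np.exp(y_t) + f * np.exp(y0))

    snp_ids = np.array([f"snp{i:06d}" for i in range(n)], dtype=object)
    sample_ids = np.array([f"s{j:04d}" for j in range(m)], dtype=object)
    dataset = IntensityDataset(
        snp_ids=snp_ids, sample_ids=sample_ids, a_log=x_t, b_log=y_t, centered=False
    )
    cna = CNAMatrix(snp_ids=snp_ids, sample_ids=sample_ids, status=status)
    truth = SimTruth(
        genotypes=_CODES[geno_score], germline=_CODES[g], maf=maf,
        intercepts=np.array(B0), config=config,
    )
    return dataset, cna, truth


# ---------------------------------------------------------------------------
# scoring


def _safe_rate(num: int, den: int) -> float:
    return num / den if den else float("nan")


def evaluate_concordance(
    calls: GenotypeCalls, truth: SimTruth, status: CNAMatrix | None = None
) -> dict:
    """Call rates, concordance rates and CNA-stratum error metrics.

    Concordance compares calls with the scoring genotypes (in loss
    regions: the surviving allele's homozygote).  The stratified
    genotyping-error rate follows the paired-normal definition: an
    error is an AB call where the germline is homozygous, or a
    homozygous call opposite to a homozygous germline.  Rates are
    fractions in [0, 1]; empty denominators yield NaN.
    """
    called = calls.is_called()
    agree = calls.calls == truth.genotypes
    het_truth = truth.genotypes == "AB"
    hom_truth = ~het_truth

    out = {
        "call_rate": _safe_rate(int(called.sum()), called.size),
        "homo_call_rate": _safe_rate(int((called & hom_truth).sum()), int(hom_truth.sum())),
        "hetero_call_rate": _safe_rate(int((called & het_truth).sum()), int(het_truth.sum())),
        "concordance": _safe_rate(int((agree & called).sum()), int(called.sum())),
        "homo_concordance": _safe_rate(
            int((agree & called & hom_truth).sum()), int((called & hom_truth).sum())
        ),
        "hetero_concordance": _safe_rate(
            int((agree & called & het_truth).sum()), int((called & het_truth).sum())
        ),
    }

    if status is not None:
        germ_hom = truth.germline != "AB"
        ab_call = calls.calls == "AB"
        opposite_hom = ((calls.calls == "AA") & (truth.germline == "BB")) | (
            (calls.calls == "BB") & (truth.germline == "AA")
        )
        error = germ_hom & (ab_call | opposite_hom)
        for name, code in (("loss", LOSS), ("gain", GAIN), ("normal", NORMAL)):
            stratum = status.status == code
            n_called = int((stratum & called).sum())
            out[f"{name}_ab_call_rate"] = _safe_rate(
                int((stratum & called & ab_call).sum()), n_called
            )
            out[f"{name}_error_rate"] = _safe_rate(
                int((stratum & called & error).sum()), n_called
            )
            out[f"{name}_concordance"] = _safe_rate(
                int((stratum & called & agree).sum()), n_called
            )
    return out


def write_truth(truth: SimTruth, path, germline_path=None) -> None:
    n, m = truth.genotypes.shape
    ids = [f"snp{i:06d}" for i in range(n)]
    cols = [f"s{j:04d}" for j in range(m)]
    pd.DataFrame(truth.genotypes, index=ids, columns=cols).to_csv(
        path, sep="\t", index_label="snp_id"
    )
    if germline_path is not None:
        pd.DataFrame(truth.germline, index=ids, columns=cols).to_csv(
            germline_path, sep="\t", index_label="snp_id"
        )


def read_truth(path, germline_path=None) -> SimTruth:
    geno = pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=object)
    germ = (
        pd.read_csv(germline_path, sep="\t", index_col=0).to_numpy(dtype=object)
        if germline_path is not None
        else geno.copy()
    )
    return SimTruth(genotypes=geno, germline=germ, maf=np.full(geno.shape[0], np.nan))
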
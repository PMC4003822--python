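"""Copy-number covariate construction and the retrospective het diagnostic.

Upstream CNA callers supply, per SNP and sample, a copy-number status in
{loss = -1, normal = 0, gain = +1}.  A copy-number change moves the
affected observation vertically in the (x, y) plane, so the engine's
regression gains a per-cluster covariate term CN * beta_kCN where CN is
a fixed signed value:

=========  ==================  =====================
status     direction (x vs y)  CN value
=========  ==================  =====================
loss       x > y (B lost)      +constant
loss       x <= y (A lost)     -constant
gain       x > y (A gained)    +constant / 5
gain       x <= y (B gained)   -constant / 5
normal     any                 0
=========  ==================  =====================

Gains are attenuated five-fold relative to losses: probe saturation caps
the intensity increase an extra copy can produce.  ``constant`` is
estimated from the data as the larger absolute value of the 2.5th and
97.5th percentiles of the pooled log-ratio d = x - y, i.e. the typical
homozygote offset.

Because true heterozygotes cannot exist where one chromosome copy is
lost, the fraction of AB calls inside loss regions is a retrospective
quality check on the upstream CNA calls: more than 1% AB flags a sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import GenotypeCalls, IntensityDataset
from .prior_builder import PriorSpec

__all__ = [
    "CNAMatrix",
    "read_cna_calls",
    "write_cna_calls",
    "estimate_cn_constant",
    "assign_cn_covariate",
    "extend_prior_with_cn",
    "heterozygosity_check",
]

LOSS, NORMAL, GAIN = -1, 0, 1


@dataclass
class CNAMatrix:
    """SNP x sample copy-number status codes and derived covariate values."""

    snp_ids: np.ndarray
    sample_ids: np.ndarray
    status: np.ndarray  # int codes {-1, 0, +1}
    cn_value: np.ndarray | None = None
    constant: float | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.status = np.asarray(self.status, dtype=int)
        if not np.isin(self.status, (LOSS, NORMAL, GAIN)).all():
            raise ValueError("status codes must be -1 (loss), 0 (normal) or +1 (gain)")
        if self.cn_value is not None:
            self.cn_value = np.asarray(self.cn_value, dtype=float)
            if self.cn_value.shape != self.status.shape:
                raise ValueError("cn_value shape must match status")

    @property
    def any_alteration(self) -> bool:
        return bool((self.status != NORMAL).any())


def read_cna_calls(path) -> CNAMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CNAMatrix(
        snp_ids=df.index.to_numpy(),
        sample_ids=df.columns.to_numpy(),
        status=df.to_numpy(dtype=int),
    )


def write_cna_calls(cna: CNAMatrix, path) -> None:
    pd.DataFrame(cna.status, index=cna.snp_ids, columns=cna.sample_ids).to_csv(
        path, sep="\t", index_label="snp_id"
    )


def estimate_cn_constant(dataset: IntensityDataset) -> float:
    """max(|2.5th pct|, |97.5th pct|) of the pooled log-ratio d = x - y."""
    if not dataset.centered:
        raise ValueError("estimate_cn_constant expects a centered dataset")
    d = dataset.log_ratio().ravel()
    if d.size < 40:
        raise ValueError("need at least 40 observations for stable 2.5/97.5 percentiles")
    lo, hi = np.quantile(d, [0.025, 0.975])
    return float(max(abs(lo), abs(hi)))


def assign_cn_covariate(
    dataset: IntensityDataset, status: CNAMatrix, constant: float
) -> CNAMatrix:
    """Fill ``cn_value`` from status codes and the observed A/B direction.

    The affected allele is inferred from the data: under loss, x > y
    means the B allele was lost (the A signal survives); under gain,
    x > y means the A allele was gained.  Ties (x == y) follow the x > y
    branch by convention.
    """
    if constant <= 0:
        raise ValueError("constant must be positive")
    if dataset.a_log.shape != status.status.shape:
        raise ValueError("dataset and CNA matrix shapes differ")
    a_side = dataset.a_log >= dataset.b_log  # x > y branch; ties -> B-loss / A-gain
    cn = np.zeros_like(dataset.a_log)
    loss = status.status == LOSS
    gain = status.status == GAIN
    cn[loss & a_side] = constant  # B allele loss
    cn[loss & ~a_side] = -constant  # A allele loss
    cn[gain & a_side] = constant / 5.0  # A allele gain
    cn[gain & ~a_side] = -constant / 5.0  # B allele gain
    return CNAMatrix(
        snp_ids=status.snp_ids,
        sample_ids=status.sample_ids,
        status=status.status,
        cn_value=cn,
        constant=constant,
    )


def extend_prior_with_cn(
    prior: PriorSpec, cn_mean: float = 1.0, cn_var_factor: float = 100.0
) -> PriorSpec:
    """Append a weak prior on the per-cluster CN coefficient.

    The CN covariate already carries the magnitude of the shift, so a
    coefficient near 1 reproduces the literal vertical displacement; its
    prior variance is ``cn_var_factor`` times the slope prior variance,
    keeping the prior weak so the data decide.
    """
    if prior.has_cn:
        raise ValueError("prior already has a CN coefficient")
    if prior.v_diag is None:
        raise ValueError("prior variances must be set before extending with CN")
    beta = np.column_stack([prior.beta_mean, np.full(3, cn_mean)])
    v = np.append(prior.v_diag, cn_var_factor * prior.v_diag[1])
    return PriorSpec(beta_mean=beta, v_diag=v, pi=prior.pi)


def heterozygosity_check(calls: GenotypeCalls, status: CNAMatrix) -> pd.DataFrame:
    """Per-sample AB proportion among called SNPs in copy-loss regions.

    Returns a frame with columns sample_id, n_loss_snps, n_called,
    prop_ab, flagged.  A proportion above 1% suggests the upstream CNA
    segmentation mislabeled those regions and should be examined.
    Samples with no called loss-region SNPs get NaN and are unflagged.
    """
    if calls.calls.shape != status.status.shape:
        raise ValueError("calls and CNA matrix shapes differ")
    loss = status.status == LOSS
    called = calls.is_called()
    rows = []
    for j, sample in enumerate(calls.sample_ids):
        in_loss = loss[:, j]
        n_loss = int(in_loss.sum())
        n_called = int((in_loss & called[:, j]).sum())
        if n_called == 0:
            prop = np.nan
            flagged = False
        else:
            n_ab = int((in_loss & (calls.calls[:, j] == "AB")).sum())
            prop = n_ab / n_called
            flagged = prop > 0.01
        rows.append((sample, n_loss, n_called, prop, flagged))
    return pd.DataFrame(
        rows, columns=["sample_id", "n_loss_snps", "n_called", "prop_ab", "flagged"]
    )
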
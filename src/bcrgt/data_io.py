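"""Tabular I/O, probe summarization and per-SNP centering.

The calling engine works on SNP x sample matrices of summarized A- and
B-allele log-intensities.  Raw probe-level measurements (typically 6-10
allele-specific probes per SNP on a 500K-style array) are averaged on the
raw intensity scale and then log-transformed.  Before genotyping, each
SNP row is centered at the median of its A-allele log-intensities; the
same shift is applied to both channels so the A-B contrast is preserved.

All on-disk formats are plain UTF-8 tab-delimited text: one header row of
sample ids, first column ``snp_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "IntensityDataset",
    "GenotypeCalls",
    "summarize_probe_measurements",
    "center_snp",
    "read_intensity_matrix",
    "write_intensity_matrix",
    "read_genotype_calls",
    "write_genotype_calls",
]

#: genotype call codes used throughout the package
CALL_CODES = ("AA", "AB", "BB")
NOCALL = "NoCall"


@dataclass
class IntensityDataset:
    """SNP x sample matrices of A- and B-allele log-intensities.

    Parameters
    ----------
    snp_ids, sample_ids
        Ordered identifiers for rows and columns.
    a_log, b_log
        ``(n_snps, n_samples)`` float arrays of natural-log intensities
        (``x`` and ``y`` in the model).
    centered
        True once each row has been centered at the median of its
        A-allele log-intensities.
    """

    snp_ids: np.ndarray
    sample_ids: np.ndarray
    a_log: np.ndarray
    b_log: np.ndarray
    centered: bool = False

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.a_log = np.asarray(self.a_log, dtype=float)
        self.b_log = np.asarray(self.b_log, dtype=float)
        if self.a_log.shape != self.b_log.shape:
            raise ValueError(
                f"A and B matrices differ in shape: {self.a_log.shape} vs {self.b_log.shape}"
            )
        if self.a_log.shape != (len(self.snp_ids), len(self.sample_ids)):
            raise ValueError("matrix shape does not match id vectors")
        if not (np.isfinite(self.a_log).all() and np.isfinite(self.b_log).all()):
            raise ValueError("non-finite log-intensities")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids")

    @property
    def n_snps(self) -> int:
        return self.a_log.shape[0]

    @property
    def n_samples(self) -> int:
        return self.a_log.shape[1]

    def log_ratio(self) -> np.ndarray:
        """d = x - y, the allelic log-ratio separating genotype clusters."""
        return self.a_log - self.b_log


@dataclass
class GenotypeCalls:
    """SNP x sample genotype calls with per-call maximum posterior."""

    snp_ids: np.ndarray
    sample_ids: np.ndarray
    calls: np.ndarray  # object array of {"AA","AB","BB","NoCall"} (or A/B/0)
    max_posterior: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.calls = np.asarray(self.calls, dtype=object)
        self.max_posterior = np.asarray(self.max_posterior, dtype=float)
        if self.calls.shape != self.max_posterior.shape:
            raise ValueError("calls / max_posterior shape mismatch")
        if ((self.max_posterior < 0) | (self.max_posterior > 1)).any():
            raise ValueError("max_posterior outside [0, 1]")

    @property
    def call_rate(self) -> float:
        """Fraction of entries with a genotype call (non-NoCall)."""
        return 1.0 - float(np.mean(self.calls == NOCALL))

    def is_called(self) -> np.ndarray:
        return self.calls != NOCALL


def summarize_probe_measurements(probe_table: pd.DataFrame) -> IntensityDataset:
    """Average probe-level intensities per (SNP, sample, allele) and log.

    Averaging happens on the raw intensity scale; the log transform is
    applied to the mean.  Pairs lacking one of the two alleles are
    dropped with a warning (their count is reported in the message).

    Parameters
    ----------
    probe_table
        Columns ``snp_id``, ``sample_id``, ``allele`` (``"A"``/``"B"``)
        and ``intensity`` (strictly positive raw scale).
    """
    required = {"snp_id", "sample_id", "allele", "intensity"}
    missing = required - set(probe_table.columns)
    if missing:
        raise ValueError(f"probe table missing columns: {sorted(missing)}")
    bad = probe_table["intensity"] <= 0
    if bad.any():
        row = probe_table.index[bad][0]
        raise ValueError(f"non-positive intensity at row {row}")
    if not probe_table["allele"].isin(["A", "B"]).all():
        raise ValueError("allele column must contain only 'A' or 'B'")

    means = (
        probe_table.groupby(["snp_id", "sample_id", "allele"], sort=False)["intensity"]
        .mean()
        .unstack("allele")
    )
    incomplete = means.isna().any(axis=1)
    if incomplete.any():
        warnings.warn(
            f"dropped {int(incomplete.sum())} (snp, sample) pairs missing one allele",
            stacklevel=2,
        )
        means = means[~incomplete]

    a_wide = np.log(means["A"]).unstack("sample_id")
    b_wide = np.log(means["B"]).unstack("sample_id")
    # preserve first-appearance order of ids from the input table
    snp_order = probe_table["snp_id"].drop_duplicates()
    snp_order = snp_order[snp_order.isin(a_wide.index)]
    sample_order = probe_table["sample_id"].drop_duplicates()
    sample_order = sample_order[sample_order.isin(a_wide.columns)]
    a_wide = a_wide.loc[snp_order, sample_order]
    b_wide = b_wide.loc[snp_order, sample_order]
    if a_wide.isna().any().any() or b_wide.isna().any().any():
        raise ValueError("incomplete (snp, sample) grid after summarization")

    return IntensityDataset(
        snp_ids=a_wide.index.to_numpy(),
        sample_ids=a_wide.columns.to_numpy(),
        a_log=a_wide.to_numpy(),
        b_log=b_wide.to_numpy(),
        centered=False,
    )


def center_snp(dataset: IntensityDataset) -> IntensityDataset:
    """Center both channels of each SNP at the median A log-intensity.

    Subtracting one per-SNP constant from both x and y leaves the
    log-ratio d = x - y (and, for unit slopes, the cluster intercepts)
    unchanged while removing SNP-specific overall brightness.
    """
    if dataset.n_samples < 1:
        raise ValueError("cannot center a dataset with no samples")
    med = np.median(dataset.a_log, axis=1, keepdims=True)
    return replace(
        dataset,
        a_log=dataset.a_log - med,
        b_log=dataset.b_log - med,
        centered=True,
    )


# ---------------------------------------------------------------------------
# readers / writers


def _read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate SNP id {dup!r}")
    return df


def read_intensity_matrix(a_path, b_path, centered: bool = False) -> IntensityDataset:
    """Read paired A/B log-intensity matrices (``<prefix>_A.tsv`` / ``_B.tsv``)."""
    a = _read_matrix(a_path)
    b = _read_matrix(b_path)
    if a.shape != b.shape or not a.index.equals(b.index) or not a.columns.equals(b.columns):
        raise ValueError(f"A and B matrices disagree in shape or ids: {a_path}, {b_path}")
    n_bad = int(a.isna().any(axis=1).sum() + b.isna().any(axis=1).sum())
    if n_bad:
        keep = ~(a.isna().any(axis=1) | b.isna().any(axis=1))
        warnings.warn(f"dropped {int((~keep).sum())} SNP rows with missing cells", stacklevel=2)
        a, b = a[keep], b[keep]
    return IntensityDataset(
        snp_ids=a.index.to_numpy(),
        sample_ids=a.columns.to_numpy(),
        a_log=a.to_numpy(dtype=float),
        b_log=b.to_numpy(dtype=float),
        centered=centered,
    )


def write_intensity_matrix(dataset: IntensityDataset, a_path, b_path) -> None:
    for mat, path in ((dataset.a_log, a_path), (dataset.b_log, b_path)):
        pd.DataFrame(mat, index=dataset.snp_ids, columns=dataset.sample_ids).to_csv(
            path, sep="\t", index_label="snp_id", float_format="%.10g"
        )


def write_genotype_calls(calls: GenotypeCalls, path) -> None:
    """Write calls in long form: snp_id, sample_id, call, posterior."""
    n_snps, n_samples = calls.calls.shape
    df = pd.DataFrame(
        {
            "snp_id": np.repeat(calls.snp_ids, n_samples),
            "sample_id": np.tile(calls.sample_ids, n_snps),
            "call": calls.calls.ravel(),
            "posterior": calls.max_posterior.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_genotype_calls(path) -> GenotypeCalls:
    df = pd.read_csv(path, sep="\t")
    snp_ids = df["snp_id"].drop_duplicates().to_numpy()
    sample_ids = df["sample_id"].drop_duplicates().to_numpy()
    calls = df.pivot(index="snp_id", columns="sample_id", values="call")
    post = df.pivot(index="snp_id", columns="sample_id", values="posterior")
    calls = calls.loc[snp_ids, sample_ids]
    post = post.loc[snp_ids, sample_ids]
    return GenotypeCalls(
        snp_ids=snp_ids,
        sample_ids=sample_ids,
        calls=calls.to_numpy(dtype=object),
        max_posterior=post.to_numpy(dtype=float),
    )
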
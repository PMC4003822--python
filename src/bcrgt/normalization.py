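"""Quantile normalization across arrays for CNA-free cohorts.

Quantile normalization (QN) forces every array to share one intensity
distribution: each sample's values are replaced by the mean, across
samples, of the order statistics at the same rank.  QN assumes the
underlying DNA-abundance distributions are exchangeable across samples,
which fails when samples carry copy-number alterations — so this step is
only applied to cohorts declared CNA-free (``cna_present=False``), and
refuses otherwise unless forced.

The A and B channels of one sample come from one physical array, so they
are pooled into a single per-sample vector before normalization.  QN is
performed on the raw intensity scale (exp of the stored logs) and the
result re-logged.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .data_io import IntensityDataset

__all__ = ["quantile_normalize"]


def _qn_columns(mat: np.ndarray) -> np.ndarray:
    """Classic quantile normalization of the columns of ``mat``.

    Ties within a column receive the mean of the reference values at the
    tied ranks (midrank interpolation), so equal inputs map to equal
    outputs and within-column rank order is preserved.
    """
    n, _ = mat.shape
    reference = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        order = np.argsort(col, kind="stable")
        ranks = np.empty(n, dtype=float)
        ranks[order] = np.arange(n, dtype=float)
        # average ranks over tied groups
        sorted_col = col[order]
        uniq, inverse, counts = np.unique(sorted_col, return_inverse=True, return_counts=True)
        if len(uniq) < n:
            start = np.concatenate(([0], np.cumsum(counts)[:-1]))
            midrank = start + (counts - 1) / 2.0
            ranks[order] = midrank[inverse]
        out[:, j] = np.interp(ranks, np.arange(n, dtype=float), reference)
    return out


def quantile_normalize(
    dataset: IntensityDataset,
    cna_present: bool = False,
    force: bool = False,
) -> IntensityDataset:
    """Quantile-normalize all sample arrays of a CNA-free cohort.

    Parameters
    ----------
    dataset
        Uncentered log-intensity dataset.
    cna_present
        Declare that the cohort carries CNAs.  QN then refuses to run
        unless ``force`` is set, since QN distorts CNA samples.
    force
        Run anyway (the ``--force-qn`` escape hatch).
    """
    if dataset.centered:
        raise ValueError("quantile normalization must run before centering")
    if cna_present and not force:
        raise ValueError(
            "refusing to quantile-normalize a cohort with CNA calls; "
            "QN assumes identical intensity distributions across samples, "
            "which CNAs violate (use force=True / --force-qn to override)"
        )
    raw = np.exp(np.vstack([dataset.a_log, dataset.b_log]))  # (2*n_snps, n_samples)
    normed = _qn_columns(raw)
    logged = np.log(normed)
    n = dataset.n_snps
    return replace(dataset, a_log=logged[:n], b_log=logged[n:])
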
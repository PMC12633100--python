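"""Count-matrix preprocessing.

Gene filtering on counts-per-million, median-of-ratios library-size
normalization, and PCA-based sample outlier flagging. These are the steps
applied to every differential-expression comparison before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterResult",
    "compute_size_factors",
    "cpm_filter",
    "normalize",
    "pca_outliers",
]


@dataclass
class FilterResult:
    """Outcome of the CPM low-expression filter.

    Attributes
    ----------
    retained
        Gene identifiers that pass the filter, in input order.
    low_flags
        genes x genotype-group boolean frame; ``True`` means the gene was
        below the CPM threshold in at least the required fraction of that
        group's samples.
    """

    retained: pd.Index
    low_flags: pd.DataFrame


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq-style estimator).

    For every gene with strictly positive counts in all samples, form the
    ratio of each sample's count to the gene's geometric mean; a sample's
    size factor is the median of those ratios. Factors are rescaled to have
    geometric mean 1 — a pure convention (a global constant cancels from
    fold-changes) that makes normalization idempotent: recomputing factors
    on normalized counts returns 1.

    Parameters
    ----------
    counts
        genes x samples non-negative count frame.

    Returns
    -------
    pandas.Series of positive factors indexed by sample.

    Raises
    ------
    ValueError
        If no gene has positive counts in every sample, so the geometric-mean
        reference cannot be formed.
    """
    x = counts.to_numpy(dtype=float)
    if x.size == 0:
        raise ValueError("empty count matrix")
    all_positive = (x > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; the median-of-ratios "
            "reference (per-gene geometric mean) is undefined"
        )
    logx = np.log(x[all_positive])
    log_geo_mean = logx.mean(axis=1)
    ratios = np.exp(logx - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def cpm_filter(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    threshold: float = 0.1,
    fraction: float = 0.5,
) -> FilterResult:
    """Remove genes lowly expressed in either genotype group.

    A gene is removed iff its CPM (count * 1e6 / library size) falls below
    ``threshold`` in at least ``fraction`` of the control samples OR in at
    least ``fraction`` of the disease (XDP) samples.

    ``sheet`` must carry a ``genotype`` column with levels ``XDP``/``CON``
    covering every column of ``counts``; both groups must be non-empty.
    """
    genotype = sheet.set_index("sample_id").loc[counts.columns, "genotype"]
    lib_sizes = counts.sum(axis=0).to_numpy(dtype=float)
    if (lib_sizes <= 0).any():
        bad = counts.columns[lib_sizes <= 0].tolist()
        raise ValueError(f"zero library size for sample(s) {bad}")
    cpm = counts.to_numpy(dtype=float) * 1e6 / lib_sizes
    low = cpm < threshold

    flags = {}
    for group in ("CON", "XDP"):
        mask = (genotype == group).to_numpy()
        if not mask.any():
            raise ValueError(f"genotype group {group!r} has no samples")
        flags[group] = low[:, mask].mean(axis=1) >= fraction
    low_flags = pd.DataFrame(flags, index=counts.index)
    removed = low_flags.any(axis=1)
    return FilterResult(retained=counts.index[~removed], low_flags=low_flags)


def normalize(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    missing = counts.columns.difference(size_factors.index)
    if len(missing):
        raise ValueError(f"no size factor for sample(s) {missing.tolist()}")
    return counts / size_factors.loc[counts.columns]


def pca_outliers(
    x: pd.DataFrame,
    n_pcs: int = 2,
    sd_mult: float = 2.0,
) -> pd.Index:
    """Flag samples far from the centroid in principal-component space.

    Samples are projected onto the top ``n_pcs`` principal components of
    ``log(x + 1)`` (genes x samples normalized expression). A sample is
    flagged when its Euclidean distance to the sample centroid exceeds
    mean + ``sd_mult`` * SD of all such distances.

    Returns the flagged sample identifiers (possibly empty).
    """
    n_samples = x.shape[1]
    if n_samples < 3:
        raise ValueError("need at least 3 samples for outlier detection")
    if n_pcs >= n_samples:
        raise ValueError(f"n_pcs={n_pcs} must be < number of samples ({n_samples})")
    y = np.log1p(x.to_numpy(dtype=float)).T  # samples x genes
    y = y - y.mean(axis=0)
    # PCA by SVD of the centered matrix; scores = U * S.
    u, s, _ = np.linalg.svd(y, full_matrices=False)
    scores = u[:, :n_pcs] * s[:n_pcs]
    centroid = scores.mean(axis=0)
    dist = np.linalg.norm(scores - centroid, axis=1)
    cutoff = dist.mean() + sd_mult * dist.std(ddof=0)
    # guard against flagging floating-point dust when samples coincide
    cutoff += 1e-9 * max(1.0, float(np.abs(y).max()))
    return x.columns[dist > cutoff]
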
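"""Median-of-ratios (size-factor) depth normalization for count matrices.

The estimator is the classic one used for bulk RNA-seq differential
expression: a pseudo-reference sample is formed by the per-gene geometric
mean across samples (genes with any zero count are excluded from the
reference), and each sample's size factor is the median across reference
genes of the ratio count / reference. Dividing each column by its factor
makes samples comparable across sequencing depths. Factors are rescaled to
unit geometric mean, which fixes the estimator's free global scale so that
normalization is idempotent (the factors of an already-normalized matrix
are all 1); the global scale cancels in fold changes either way. Even-length
medians use the midpoint of the two central values on the ratio scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counts_io import ConsistencyError, CountMatrix

__all__ = [
    "NormalizationError",
    "geometric_reference",
    "size_factors",
    "normalize_counts",
    "write_size_factors",
]


class NormalizationError(ValueError):
    """The median-of-ratios estimator is infeasible for this matrix."""


def geometric_reference(counts: CountMatrix) -> pd.Series:
    """Per-gene geometric mean across samples, for all-positive genes only.

    Genes containing any zero count are excluded (they carry no finite
    log-ratio information). Raises :class:`NormalizationError` when no gene
    has all-positive counts.
    """
    values = counts.values
    all_positive = (values > 0).all(axis=1)
    if not all_positive.any():
        raise NormalizationError(
            "no gene has all-positive counts; median-of-ratios reference undefined"
        )
    pos = values[all_positive]
    gmeans = np.exp(np.log(pos).mean(axis=1))
    return pd.Series(
        gmeans, index=counts.data.index[all_positive], name="geometric_reference"
    )


def size_factors(counts: CountMatrix) -> pd.Series:
    """Per-sample size factor: median over reference genes of count/reference.

    The raw medians are divided by their geometric mean, fixing the global
    scale so that renormalizing a normalized matrix yields unit factors.
    """
    reference = geometric_reference(counts)
    ratios = counts.data.loc[reference.index].to_numpy() / reference.to_numpy()[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.data.columns, name="size_factor")


def normalize_counts(
    counts: CountMatrix, factors: pd.Series | None = None
) -> CountMatrix:
    """Divide each sample column by its size factor.

    When ``factors`` is omitted they are estimated from ``counts``. Raises
    :class:`ConsistencyError` if a sample has no factor.
    """
    if factors is None:
        factors = size_factors(counts)
    missing = set(counts.sample_ids) - set(factors.index)
    if missing:
        raise ConsistencyError(f"no size factor for samples: {sorted(missing)}")
    if (factors.loc[counts.sample_ids] <= 0).any() or not np.isfinite(
        factors.loc[counts.sample_ids]
    ).all():
        raise NormalizationError("size factors must be positive and finite")
    normalized = counts.data / factors.loc[counts.sample_ids]
    return CountMatrix(normalized, normalized=True)


def write_size_factors(factors: pd.Series, path) -> None:
    factors.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)
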
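"""Median-of-ratios size-factor normalization.

Per-sample scale factors are estimated from the ratio of each sample's counts
to a geometric-mean pseudo-sample, taking the median over "reference" genes
(those with a nonzero count in every sample, so the geometric mean is
positive).  Counts divided by their sample's factor become comparable across
libraries of different sequencing depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["compute_size_factors", "normalize"]


def compute_size_factors(raw: CountMatrix, pseudocount: float = 0.0) -> pd.Series:
    """Estimate one positive scale factor per sample.

    factor_j = median_i( counts[i, j] / geomean_i ) over reference genes i,
    where geomean_i is the geometric mean of gene i across samples and the
    reference set holds genes with geomean > 0 (no zero count anywhere).

    A single-sample matrix gets factor 1.0 by convention.  ``pseudocount``
    is added to every count before the ratio computation; it rescues
    degenerate matrices in which every gene has at least one zero.
    """
    values = raw.values.to_numpy(dtype=float) + float(pseudocount)
    samples = raw.sample_ids
    if values.shape[1] == 1:
        return pd.Series([1.0], index=samples, name="size_factor")
    with np.errstate(divide="ignore"):
        log_counts = np.log(values)
    reference = np.all(np.isfinite(log_counts), axis=1)
    if not reference.any():
        raise ValueError(
            "no reference gene with nonzero counts in every sample; "
            "retry with a pseudocount (CLI --pseudocount)"
        )
    log_geomean = log_counts[reference].mean(axis=1, keepdims=True)
    log_ratios = log_counts[reference] - log_geomean
    factors = np.exp(np.median(log_ratios, axis=0))
    return pd.Series(factors, index=samples, name="size_factor")


def normalize(raw: CountMatrix, size_factors: pd.Series) -> CountMatrix:
    """Divide each sample's counts by its size factor."""
    if set(size_factors.index) != set(raw.sample_ids):
        raise ValueError("size factor sample set does not match count matrix")
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    scaled = raw.values / size_factors.reindex(raw.sample_ids)
    return CountMatrix(scaled, normalized=True)
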
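"""Normal-tissue expression summaries, none/low/high categorization and
enumeration of predicted potential adverse events (PPAEs).

A PPAE is the abstract event of a candidate antigen being low or highly
expressed (mean normalized count above the "none" threshold) in a
non-essential normal tissue.  Essential tissues (brain, heart, lung) are
never listed as PPAEs — they are screened by a separate hard filter.
"""

from __future__ import annotations

from typing import Literal

import numpy as np
import pandas as pd

from .io import CohortMetadata, CountMatrix, PipelineConfig, TissueWeightTable

__all__ = [
    "CATEGORY_INDICATOR",
    "tissue_averages",
    "categorize",
    "categorize_averages",
    "category_indicators",
    "enumerate_ppae",
]

Category = Literal["none", "low", "high"]

#: Expression indicator e(a, t) attached to each category.
CATEGORY_INDICATOR: dict[str, float] = {"none": 0.0, "low": 0.5, "high": 1.0}


def tissue_averages(norm: CountMatrix, meta: CohortMetadata) -> pd.DataFrame:
    """Mean normalized count per (gene, normal tissue).

    Tumor samples are excluded; every tissue must contribute at least one
    sample.  Returns a gene x tissue DataFrame.
    """
    meta.check_matches(norm)
    cols = {}
    for tissue in meta.tissues:
        samples = meta.samples_of_tissue(tissue)
        if not samples:
            raise ValueError(f"tissue {tissue!r} has no samples")
        cols[tissue] = norm.values[samples].mean(axis=1)
    if not cols:
        raise ValueError("cohort contains no normal samples")
    return pd.DataFrame(cols, index=norm.values.index)


def categorize(value: float, cfg: PipelineConfig | None = None) -> Category:
    """Bucket a mean count: none (<= t_none), low (<= t_high), high (above).

    Both boundaries belong to the lower bucket, so with defaults a mean of 10
    is "none" and a mean of 50 is "low".
    """
    cfg = cfg or PipelineConfig()
    if value < 0:
        raise ValueError(f"negative expression value: {value}")
    if value <= cfg.t_none:
        return "none"
    if value <= cfg.t_high:
        return "low"
    return "high"


def categorize_averages(
    averages: pd.DataFrame, cfg: PipelineConfig | None = None
) -> pd.DataFrame:
    """Vectorized :func:`categorize` over a gene x tissue mean table."""
    cfg = cfg or PipelineConfig()
    arr = averages.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative expression value in averages")
    out = np.where(arr > cfg.t_high, "high", np.where(arr > cfg.t_none, "low", "none"))
    return pd.DataFrame(out, index=averages.index, columns=averages.columns)


def category_indicators(categories: pd.DataFrame) -> pd.DataFrame:
    """Map categories to the numeric indicator e(a, t) in {0, 0.5, 1}."""
    return categories.map(lambda c: CATEGORY_INDICATOR[c]).astype(float)


def enumerate_ppae(
    categories: pd.DataFrame, weights: TissueWeightTable
) -> dict[str, list[tuple[str, str]]]:
    """Per-gene list of (non-essential tissue, category) with category low/high.

    ``categories`` is a gene x tissue frame as returned by
    :func:`categorize_averages`; tissues flagged essential in ``weights`` are
    skipped regardless of their category.
    """
    non_essential = [t for t in categories.columns if not weights.is_essential(t)]
    out: dict[str, list[tuple[str, str]]] = {}
    sub = categories[non_essential]
    for gene, row in sub.iterrows():
        out[gene] = [(t, c) for t, c in row.items() if c != "none"]
    return out
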
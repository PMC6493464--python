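"""Candidate filtering: from the full expression matrix to the pool of
tumor-specific antigens (TSAs).

A gene qualifies as candidate TSA when it is protein coding, highly expressed
(above the tumor threshold) in at least one tumor sample, near-silent in the
essential tissues brain/heart/lung, and has at most the permitted number of
predicted potential adverse events in non-essential tissues.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import (
    CATEGORY_INDICATOR,
    categorize_averages,
    enumerate_ppae,
    tissue_averages,
)
from .io import (
    CohortMetadata,
    CountMatrix,
    GeneAnnotation,
    PipelineConfig,
    TissueWeightTable,
)

logger = logging.getLogger("tsapool")

__all__ = [
    "AntigenProfile",
    "build_profiles",
    "filter_targets",
    "classify_target_type",
    "is_antibody_suitable",
    "ppae_distribution",
]


@dataclass
class AntigenProfile:
    """Everything the screen knows about one gene."""

    gene_id: str
    symbol: str
    gene_type: str
    target_type: str
    avg_tumor_expression: float
    tumor_indicators: pd.Series  # t(a, s) in {0, 1} per tumor sample
    essential_means: dict[str, float]
    tissue_means: pd.Series  # mean per normal tissue
    categories: pd.Series  # none/low/high per normal tissue
    ppae: list[tuple[str, str]]  # (non-essential tissue, low|high)

    @property
    def ppae_count(self) -> int:
        return len(self.ppae)

    @property
    def covered_count(self) -> int:
        return int(self.tumor_indicators.sum())

    @property
    def covered_samples(self) -> frozenset[str]:
        ind = self.tumor_indicators
        return frozenset(ind.index[ind == 1])

    @property
    def antibody_suitable(self) -> bool:
        return is_antibody_suitable(self.target_type)

    def weighted_ppae_numerator(self, weights: TissueWeightTable) -> float:
        """Sum over non-essential tissues of e(a, t) * w(t)."""
        return float(
            sum(CATEGORY_INDICATOR[c] * weights.weight(t) for t, c in self.ppae)
        )


def classify_target_type(localization: str) -> str:
    """Localization label -> target-type class (pass-through vocabulary)."""
    allowed = {
        "transmembrane_extracellular",
        "membrane_other",
        "intracellular",
        "secreted",
        "unknown",
    }
    if localization not in allowed:
        raise ValueError(f"unknown localization {localization!r}")
    return localization


def is_antibody_suitable(target_type: str) -> bool:
    """Only transmembrane proteins with a possible extracellular epitope are
    reachable by an antibody; every other class (including unknown) is not."""
    return target_type == "transmembrane_extracellular"


def build_profiles(
    norm: CountMatrix,
    meta: CohortMetadata,
    annot: GeneAnnotation,
    weights: TissueWeightTable,
    cfg: PipelineConfig | None = None,
) -> list[AntigenProfile]:
    """Assemble one :class:`AntigenProfile` per gene in the matrix.

    Genes absent from the annotation are profiled with gene_type/localization
    "unknown" (a later filter drops them) and counted in a warning.
    """
    cfg = cfg or PipelineConfig()
    meta.check_matches(norm)
    weights = weights.validate_against(meta.tissues)

    averages = tissue_averages(norm, meta)
    categories = categorize_averages(averages, cfg)
    ppae_sets = enumerate_ppae(categories, weights)

    tumor = norm.values[meta.tumor_samples]
    indicators = (tumor > cfg.tumor_high_threshold).astype(int)
    avg_tumor = tumor.mean(axis=1)

    essential_present = [t for t in averages.columns if weights.is_essential(t)]
    ann = annot.as_dict()

    profiles: list[AntigenProfile] = []
    n_unannotated = 0
    for gene in norm.gene_ids:
        entry = ann.get(gene)
        if entry is None:
            n_unannotated += 1
            entry = {"symbol": gene, "gene_type": "unknown", "localization": "unknown"}
        profiles.append(
            AntigenProfile(
                gene_id=gene,
                symbol=entry["symbol"],
                gene_type=entry["gene_type"],
                target_type=classify_target_type(entry["localization"]),
                avg_tumor_expression=float(avg_tumor.loc[gene]),
                tumor_indicators=indicators.loc[gene],
                essential_means={t: float(averages.loc[gene, t]) for t in essential_present},
                tissue_means=averages.loc[gene],
                categories=categories.loc[gene],
                ppae=ppae_sets[gene],
            )
        )
    if n_unannotated:
        logger.warning(
            "%d genes missing from annotation; treated as gene_type unknown",
            n_unannotated,
        )
    return profiles


def filter_targets(
    profiles: list[AntigenProfile], cfg: PipelineConfig | None = None
) -> list[AntigenProfile]:
    """Retain genes passing all four candidate predicates.

    protein coding AND covered in >= 1 tumor sample AND every essential-tissue
    mean <= essential_max_avg AND PPAE count <= max_ppae.
    """
    cfg = cfg or PipelineConfig()
    kept = []
    for p in profiles:
        if p.gene_type != "protein_coding":
            continue
        if p.covered_count < 1:
            continue
        if any(m > cfg.essential_max_avg for m in p.essential_means.values()):
            continue
        if p.ppae_count > cfg.max_ppae:
            continue
        kept.append(p)
    return kept


def ppae_distribution(
    targets: list[AntigenProfile],
) -> pd.DataFrame:
    """Histogram of targets per PPAE count, split by target type.

    Returns a DataFrame indexed by PPAE count with one column per target type
    present plus a 'total'; the total column sums to the number of targets.
    """
    if not targets:
        return pd.DataFrame(columns=["total"]).rename_axis("ppae_count")
    counts = Counter((t.ppae_count, t.target_type) for t in targets)
    types = sorted({tt for _, tt in counts})
    idx = sorted({k for k, _ in counts})
    df = pd.DataFrame(0, index=pd.Index(idx, name="ppae_count"), columns=types)
    for (k, tt), n in counts.items():
        df.loc[k, tt] = n
    df["total"] = df.sum(axis=1)
    return df
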
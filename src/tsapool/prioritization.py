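"""Target prioritization: adverse-event index, coverage index, combined score.

For each candidate antigen a over T non-essential normal tissues and M tumor
samples:

    I_PPAE(a) = sum_t e(a,t) * w(t)  /  max_pool( sum_t e(a,t) * w(t) )
    I_TSCR(a) = sum_s t(a,s) / M
    DTPF(a)   = (1 - I_PPAE(a)) + I_TSCR(a)

where e(a,t) in {0, 0.5, 1} encodes none/low/high normal-tissue expression,
w(t) is the tissue weight, and t(a,s) indicates high expression in tumor
sample s.  The I_PPAE denominator is the maximum weighted numerator over the
candidate pool (an explicit value may be supplied to score against a larger
reference pool); a pool with all-zero numerators yields I_PPAE = 0 for all.
"""

from __future__ import annotations

from dataclasses import dataclass

from .identification import AntigenProfile
from .io import PipelineConfig, TissueWeightTable

__all__ = [
    "PrioritizedTarget",
    "compute_ippae",
    "compute_itscr",
    "compute_dtpf",
    "classify_priority",
    "rank_targets",
    "prioritize",
    "solve_pool_denominator",
]


@dataclass
class PrioritizedTarget:
    gene_id: str
    i_ppae: float
    i_tscr: float
    dtpf: float
    priority: str  # high | low | none
    rank: int
    profile: AntigenProfile


def compute_ippae(
    targets: list[AntigenProfile],
    weights: TissueWeightTable,
    denominator: float | None = None,
) -> dict[str, float]:
    """Weighted, pool-max-normalized adverse-event index per target.

    ``denominator`` overrides the pool maximum (useful when scoring a subset
    against the numerator scale of a larger reference pool).
    """
    if not targets:
        return {}
    numerators = {t.gene_id: t.weighted_ppae_numerator(weights) for t in targets}
    denom = max(numerators.values()) if denominator is None else float(denominator)
    if denom <= 0:
        return {g: 0.0 for g in numerators}
    return {g: num / denom for g, num in numerators.items()}


def compute_itscr(profile: AntigenProfile, n_tumor: int) -> float:
    """Fraction of tumor samples with high expression of this antigen."""
    if n_tumor < 1:
        raise ValueError("tumor sample count must be >= 1")
    return profile.covered_count / n_tumor


def compute_dtpf(i_ppae: float, i_tscr: float) -> float:
    """Digital target prioritization factor (1 - I_PPAE) + I_TSCR in [0, 2]."""
    for name, v in (("i_ppae", i_ppae), ("i_tscr", i_tscr)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} outside [0, 1]: {v}")
    return (1.0 - i_ppae) + i_tscr


def classify_priority(
    i_ppae: float, i_tscr: float, cfg: PipelineConfig | None = None
) -> str:
    """high / low / none by the (1 - I_PPAE, I_TSCR) thresholds, strict '>';
    boundary cases fall to the lower class."""
    cfg = cfg or PipelineConfig()
    specific = (1.0 - i_ppae) > cfg.priority_ppae_threshold
    if not specific:
        return "none"
    return "high" if i_tscr > cfg.priority_tscr_threshold else "low"


def rank_targets(targets: list[PrioritizedTarget]) -> list[PrioritizedTarget]:
    """Descending DTPF; ties by higher I_TSCR, then lexicographic gene id."""
    ordered = sorted(targets, key=lambda t: (-t.dtpf, -t.i_tscr, t.gene_id))
    for i, t in enumerate(ordered, start=1):
        t.rank = i
    return ordered


def prioritize(
    targets: list[AntigenProfile],
    weights: TissueWeightTable,
    n_tumor: int,
    cfg: PipelineConfig | None = None,
    denominator: float | None = None,
) -> list[PrioritizedTarget]:
    """Score, classify and rank a candidate pool."""
    cfg = cfg or PipelineConfig()
    ippae = compute_ippae(targets, weights, denominator=denominator)
    scored = []
    for p in targets:
        i_ppae = ippae[p.gene_id]
        i_tscr = compute_itscr(p, n_tumor)
        scored.append(
            PrioritizedTarget(
                gene_id=p.gene_id,
                i_ppae=i_ppae,
                i_tscr=i_tscr,
                dtpf=compute_dtpf(i_ppae, i_tscr),
                priority=classify_priority(i_ppae, i_tscr, cfg),
                rank=0,
                profile=p,
            )
        )
    return rank_targets(scored)


def solve_pool_denominator(
    numerator: float, covered: int, n_tumor: int, dtpf: float
) -> float:
    """Recover the pool-max I_PPAE denominator implied by one scored target.

    Inverts DTPF = (1 - numerator/D) + covered/n_tumor for D.  Lets a known
    weighted numerator, coverage and reported score of a reference antigen fix
    the normalization scale of a pool that is not itself available.
    """
    residual = 1.0 + covered / n_tumor - dtpf
    if residual <= 0:
        raise ValueError("reported DTPF implies a non-positive I_PPAE")
    if numerator <= 0:
        raise ValueError("reference antigen must have a positive weighted numerator")
    return numerator / residual
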
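"""Multiparametric threshold search.

The candidate filter depends on three thresholds: per-sample tumor count,
essential-tissue mean cap and PPAE cap.  The search space is a small integer
grid (tumor threshold 10..100, essential cap 5..20, PPAE cap 0..8), so the
"ascent" is done exactly: exhaustive evaluation of three pool-quality
objectives at every grid point, Pareto filtering, and a documented
equal-weight scalarization for a single default pick, optionally refined by
coordinate hill-climbing (a no-op after exhaustive search, useful on coarse
grids).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .identification import AntigenProfile, build_profiles, filter_targets
from .io import (
    CohortMetadata,
    CountMatrix,
    GeneAnnotation,
    PipelineConfig,
    TissueWeightTable,
)

__all__ = [
    "ParameterPoint",
    "ObjectiveTriple",
    "GridResult",
    "evaluate_point",
    "pareto_front",
    "grid_search",
]

TUMOR_RANGE = (10, 100)
ESSENTIAL_RANGE = (5, 20)
PPAE_RANGE = (0, 8)


@dataclass(frozen=True)
class ParameterPoint:
    tumor_high_threshold: float
    essential_max_avg: float
    max_ppae: int

    def __post_init__(self) -> None:
        if not TUMOR_RANGE[0] <= self.tumor_high_threshold <= TUMOR_RANGE[1]:
            raise ValueError(f"tumor threshold outside {TUMOR_RANGE}")
        if not ESSENTIAL_RANGE[0] <= self.essential_max_avg <= ESSENTIAL_RANGE[1]:
            raise ValueError(f"essential cap outside {ESSENTIAL_RANGE}")
        if not PPAE_RANGE[0] <= self.max_ppae <= PPAE_RANGE[1]:
            raise ValueError(f"PPAE cap outside {PPAE_RANGE}")


@dataclass(frozen=True)
class ObjectiveTriple:
    n_tsa: int
    avg_tsa_per_sample: float
    avg_samples_per_tsa: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.n_tsa, self.avg_tsa_per_sample, self.avg_samples_per_tsa)


@dataclass
class GridResult:
    evaluated: list[tuple[ParameterPoint, ObjectiveTriple]]
    pareto: list[tuple[ParameterPoint, ObjectiveTriple]]
    best: tuple[ParameterPoint, ObjectiveTriple]


@dataclass
class DataBundle:
    """Inputs the filter needs, bundled for repeated evaluation."""

    norm: CountMatrix
    meta: CohortMetadata
    annot: GeneAnnotation
    weights: TissueWeightTable
    base_cfg: PipelineConfig


def evaluate_point(point: ParameterPoint, bundle: DataBundle) -> ObjectiveTriple:
    """Run the candidate filter at one threshold setting and score the pool.

    n_tsa: pool size; avg_tsa_per_sample: mean over tumor samples of the
    number of pool antigens covering each; avg_samples_per_tsa: mean over the
    pool of covered-sample counts.  An empty pool scores (0, 0, 0).
    """
    cfg = bundle.base_cfg.with_(
        tumor_high_threshold=point.tumor_high_threshold,
        essential_max_avg=point.essential_max_avg,
        max_ppae=point.max_ppae,
    )
    profiles = build_profiles(bundle.norm, bundle.meta, bundle.annot, bundle.weights, cfg)
    pool = filter_targets(profiles, cfg)
    if not pool:
        return ObjectiveTriple(0, 0.0, 0.0)
    tumor_samples = bundle.meta.tumor_samples
    per_sample = np.zeros(len(tumor_samples))
    covered_counts = []
    sample_pos = {s: i for i, s in enumerate(tumor_samples)}
    for p in pool:
        covered = p.covered_samples
        covered_counts.append(len(covered))
        for s in covered:
            per_sample[sample_pos[s]] += 1
    return ObjectiveTriple(
        n_tsa=len(pool),
        avg_tsa_per_sample=float(per_sample.mean()),
        avg_samples_per_tsa=float(np.mean(covered_counts)),
    )


def _dominates(a: ObjectiveTriple, b: ObjectiveTriple) -> bool:
    at, bt = a.as_tuple(), b.as_tuple()
    return all(x >= y for x, y in zip(at, bt)) and any(x > y for x, y in zip(at, bt))


def pareto_front(
    evaluated: Sequence[tuple[ParameterPoint, ObjectiveTriple]]
) -> list[tuple[ParameterPoint, ObjectiveTriple]]:
    """Non-dominated points under simultaneous maximization of all three
    objectives (pairwise comparison; duplicates of an objective vector are all
    retained)."""
    front = []
    for i, (pi, oi) in enumerate(evaluated):
        if not any(_dominates(oj, oi) for j, (_, oj) in enumerate(evaluated) if j != i):
            front.append((pi, oi))
    return front


def _scalarize(
    evaluated: Sequence[tuple[ParameterPoint, ObjectiveTriple]]
) -> tuple[ParameterPoint, ObjectiveTriple]:
    """Equal-weight sum of min-max normalized objectives; ties broken by the
    grid order (first occurrence wins)."""
    obj = np.array([o.as_tuple() for _, o in evaluated], dtype=float)
    lo, hi = obj.min(axis=0), obj.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scores = ((obj - lo) / span).sum(axis=1)
    return evaluated[int(np.argmax(scores))]


def grid_search(
    bundle: DataBundle,
    tumor_values: Iterable[float] | None = None,
    essential_values: Iterable[float] | None = None,
    ppae_values: Iterable[int] | None = None,
    hill_climb: bool = False,
) -> GridResult:
    """Exhaustive evaluation over the threshold grid.

    Default grids step by 10 counts on the tumor threshold, 5 counts on the
    essential cap and 1 on the PPAE cap; arbitrary integer grids within the
    stated ranges are accepted.  ``hill_climb`` refines the scalarized pick by
    +/-1-step coordinate moves on the supplied grid axes (exact search already
    covers the grid, so this matters only for coarse custom grids).
    """
    tumor_values = sorted(range(10, 101, 10) if tumor_values is None else tumor_values)
    essential_values = sorted(range(5, 21, 5) if essential_values is None else essential_values)
    ppae_values = sorted(range(0, 9) if ppae_values is None else ppae_values)
    points = [
        ParameterPoint(t, e, p)
        for t, e, p in product(tumor_values, essential_values, ppae_values)
    ]
    if not points:
        raise ValueError("empty grid")
    evaluated = [(pt, evaluate_point(pt, bundle)) for pt in points]
    front = pareto_front(evaluated)
    best = _scalarize(evaluated)
    if hill_climb:
        best = _coordinate_climb(best, evaluated)
    return GridResult(evaluated=evaluated, pareto=front, best=best)


def _coordinate_climb(
    start: tuple[ParameterPoint, ObjectiveTriple],
    evaluated: Sequence[tuple[ParameterPoint, ObjectiveTriple]],
) -> tuple[ParameterPoint, ObjectiveTriple]:
    obj = np.array([o.as_tuple() for _, o in evaluated], dtype=float)
    lo, hi = obj.min(axis=0), obj.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)

    def score(o: ObjectiveTriple) -> float:
        return float(((np.array(o.as_tuple()) - lo) / span).sum())

    by_point = {pt: o for pt, o in evaluated}
    tumor_axis = sorted({pt.tumor_high_threshold for pt, _ in evaluated})
    ess_axis = sorted({pt.essential_max_avg for pt, _ in evaluated})
    ppae_axis = sorted({pt.max_ppae for pt, _ in evaluated})

    current = start
    improved = True
    while improved:
        improved = False
        pt = current[0]
        for axis, attr in (
            (tumor_axis, "tumor_high_threshold"),
            (ess_axis, "essential_max_avg"),
            (ppae_axis, "max_ppae"),
        ):
            i = axis.index(getattr(pt, attr))
            for j in (i - 1, i + 1):
                if 0 <= j < len(axis):
                    cand = ParameterPoint(
                        **{
                            "tumor_high_threshold": pt.tumor_high_threshold,
                            "essential_max_avg": pt.essential_max_avg,
                            "max_ppae": pt.max_ppae,
                            attr: axis[j],
                        }
                    )
                    if cand in by_point and score(by_point[cand]) > score(current[1]):
                        current = (cand, by_point[cand])
                        improved = True
                        pt = cand
    return current
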
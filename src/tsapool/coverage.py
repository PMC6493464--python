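"""Patient-coverage analysis for antigen combinations ("cocktails").

Each antigen covers the tumor samples in which it is highly expressed; a
cocktail covers their union.  Besides the union fraction, the multiplicity
histogram (how many antigens cover each sample) and exclusive Venn regions
quantify redundancy within a combination.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

from .prioritization import PrioritizedTarget

__all__ = [
    "CoverageSet",
    "CocktailReport",
    "coverage_sets",
    "union_coverage",
    "multiplicity_histogram",
    "venn_counts",
    "greedy_cocktail",
]


@dataclass(frozen=True)
class CoverageSet:
    gene_id: str
    samples: frozenset[str]

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class CocktailReport:
    """Selected antigen sequence with cumulative and multiplicity coverage."""

    mode: str  # "rank" or "greedy"
    genes: list[str]
    cumulative_covered: list[int]  # union sizes after 1..k antigens
    multiplicity: dict[int, int]  # samples covered by exactly k antigens, k=0..n
    n_tumor: int

    @property
    def cumulative_fractions(self) -> list[float]:
        return [c / self.n_tumor for c in self.cumulative_covered]

    @property
    def total_coverage(self) -> float:
        return (self.n_tumor - self.multiplicity.get(0, 0)) / self.n_tumor


def coverage_sets(targets: Sequence[PrioritizedTarget]) -> list[CoverageSet]:
    """Coverage sets of ranked targets, in rank order."""
    return [CoverageSet(t.gene_id, t.profile.covered_samples) for t in targets]


def _check_cohort(sets: Sequence[CoverageSet], cohort: frozenset[str] | None) -> None:
    if cohort is None:
        return
    for s in sets:
        stray = s.samples - cohort
        if stray:
            raise ValueError(
                f"coverage set {s.gene_id!r} contains samples outside the "
                f"cohort: {sorted(stray)[:5]}"
            )


def union_coverage(
    sets: Sequence[CoverageSet], n_tumor: int, cohort: frozenset[str] | None = None
) -> float:
    """|union of covered samples| / M."""
    if n_tumor < 1:
        raise ValueError("tumor sample count must be >= 1")
    _check_cohort(sets, cohort)
    union: set[str] = set()
    for s in sets:
        union |= s.samples
    return len(union) / n_tumor


def multiplicity_histogram(
    sets: Sequence[CoverageSet], samples: Sequence[str]
) -> dict[int, int]:
    """For each tumor sample, the number of sets containing it; histogram over
    that count including k = 0 (uncovered).  Values sum to len(samples)."""
    counts = Counter(sum(smp in s.samples for s in sets) for smp in samples)
    return {k: counts.get(k, 0) for k in range(len(sets) + 1)}


def venn_counts(sets: Sequence[CoverageSet]) -> dict[frozenset[str], int]:
    """Exclusive region sizes of the Venn diagram over <= 6 sets.

    Keys are the nonempty subsets of gene ids; each sample is attributed to
    exactly the region of sets containing it, so region sizes sum to the
    union size.
    """
    if len(sets) > 6:
        raise ValueError("venn_counts supports at most 6 sets")
    union: set[str] = set()
    for s in sets:
        union |= s.samples
    regions: Counter[frozenset[str]] = Counter()
    for smp in union:
        members = frozenset(s.gene_id for s in sets if smp in s.samples)
        regions[members] += 1
    return dict(regions)


def greedy_cocktail(
    sets: Sequence[CoverageSet],
    n_tumor: int,
    k: int,
    mode: str = "rank",
    dtpf: Mapping[str, float] | None = None,
    cohort: frozenset[str] | None = None,
) -> CocktailReport:
    """Select a k-antigen cocktail and report its coverage structure.

    rank mode takes the first k sets in the given order (callers pass sets in
    score order).  greedy mode iteratively adds the set with the largest
    marginal union gain, breaking ties by higher DTPF (when given) then gene
    id — a maximum-coverage heuristic with the usual (1 - 1/e) guarantee.
    """
    if k < 1:
        raise ValueError("cocktail size k must be >= 1")
    if k > len(sets):
        raise ValueError(f"k={k} exceeds pool size {len(sets)}")
    if mode not in ("rank", "greedy"):
        raise ValueError(f"unknown mode {mode!r}")
    _check_cohort(sets, cohort)

    if mode == "rank":
        chosen = list(sets[:k])
    else:
        remaining = list(sets)
        chosen = []
        covered: set[str] = set()
        for _ in range(k):
            def key(s: CoverageSet):
                gain = len(s.samples - covered)
                score = dtpf.get(s.gene_id, 0.0) if dtpf else 0.0
                return (-gain, -score, s.gene_id)

            best = min(remaining, key=key)
            remaining.remove(best)
            chosen.append(best)
            covered |= best.samples

    cumulative = []
    union: set[str] = set()
    for s in chosen:
        union |= s.samples
        cumulative.append(len(union))

    all_samples = sorted(cohort) if cohort is not None else None
    if all_samples is None:
        # multiplicity over an anonymous cohort: uncovered count inferred from M
        mult = Counter()
        per_sample = Counter()
        for s in chosen:
            per_sample.update(s.samples)
        mult.update(per_sample.values())
        covered_total = len(per_sample)
        histogram = {0: n_tumor - covered_total}
        histogram.update({k_: mult.get(k_, 0) for k_ in range(1, len(chosen) + 1)})
    else:
        histogram = multiplicity_histogram(chosen, all_samples)

    return CocktailReport(
        mode=mode,
        genes=[s.gene_id for s in chosen],
        cumulative_covered=cumulative,
        multiplicity=histogram,
        n_tumor=n_tumor,
    )
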
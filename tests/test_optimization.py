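"""Threshold grid search: objective evaluation, Pareto filtering, monotonicity."""

import numpy as np
import pandas as pd
import pytest

import tsapool as tp
from tsapool.optimization import DataBundle, ObjectiveTriple, ParameterPoint, pareto_front
from conftest import make_counts


def _bundle_from(counts, meta, annot):
    sf = tp.compute_size_factors(counts)
    norm = tp.normalize(counts, sf)
    return DataBundle(norm, meta, annot, tp.default_weights(), tp.PipelineConfig())


@pytest.fixture(scope="module")
def small_bundle():
    cfg = tp.SimulationConfig(
        n_tumor=12,
        tissue_sizes={t: 4 for t in ("colon", "testis", "skin", "brain", "heart", "lung")},
        n_background_genes=40,
        n_tissue_specific_genes=4,
        planted_antigens=[
            tp.PlantedAntigen("AGA", 0.5, 300.0, (("colon", "low"),)),
            tp.PlantedAntigen("AGB", 0.25, 400.0, (("testis", "high"),)),
            tp.PlantedAntigen("AGC", 0.75, 200.0),
        ],
        dispersion=0.05,
        rng_seed=5,
    )
    counts, meta, annot, _ = tp.simulate_cohort(cfg)
    return _bundle_from(counts, meta, annot)


@pytest.fixture(scope="module")
def constructed_bundle():
    """Deterministic 4-gene cohort: antigen A (55 counts, no PPAE) visible
    only at tumor threshold 50; antigen B (200 counts, one colon PPAE)."""
    tumor = [f"t{i}" for i in range(4)]
    normals = ["colon_1", "brain_1", "heart_1", "lung_1"]
    samples = tumor + normals
    rows = {
        "A": [55, 55, 0, 0, 0, 0, 0, 0],
        "B": [200, 200, 0, 0, 25, 0, 0, 0],
        "BG1": [100] * 8,
        "BG2": [80] * 8,
    }
    counts = make_counts(
        np.array(list(rows.values())), genes=list(rows), samples=samples
    )
    meta = tp.CohortMetadata(
        pd.DataFrame(
            {
                "sample_id": samples,
                "class": ["tumor"] * 4 + ["normal"] * 4,
                "tissue": [""] * 4 + ["colon", "brain", "heart", "lung"],
            }
        )
    )
    annot = tp.GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": list(rows),
                "symbol": list(rows),
                "gene_type": ["protein_coding"] * 2 + ["lincRNA"] * 2,
                "localization": ["intracellular"] * 4,
            }
        )
    )
    return _bundle_from(counts, meta, annot)


class TestEvaluatePoint:
    def test_average_samples_per_tsa_arithmetic(self):
        objs = ObjectiveTriple(2, 1.0, (65 + 56) / 2)
        assert objs.avg_samples_per_tsa == 60.5

    def test_excluding_everything_scores_zero(self, constructed_bundle):
        # no gene exceeds 100 counts in any tumor sample
        obj = tp.evaluate_point(ParameterPoint(100, 5, 0), constructed_bundle)
        assert obj == ObjectiveTriple(0, 0.0, 0.0)

    def test_matches_brute_force(self, small_bundle):
        point = ParameterPoint(50, 10, 6)
        obj = tp.evaluate_point(point, small_bundle)
        cfg = small_bundle.base_cfg.with_(
            tumor_high_threshold=50, essential_max_avg=10, max_ppae=6
        )
        profiles = tp.build_profiles(
            small_bundle.norm, small_bundle.meta, small_bundle.annot,
            small_bundle.weights, cfg,
        )
        pool = tp.filter_targets(profiles, cfg)
        assert obj.n_tsa == len(pool)
        tumor = small_bundle.meta.tumor_samples
        cover = np.array(
            [[1 if s in p.covered_samples else 0 for s in tumor] for p in pool]
        )
        assert obj.avg_tsa_per_sample == pytest.approx(cover.sum(0).mean())
        assert obj.avg_samples_per_tsa == pytest.approx(cover.sum(1).mean())


class TestParetoFront:
    def test_single_point_grid(self, small_bundle):
        result = tp.grid_search(
            small_bundle, tumor_values=[50], essential_values=[10], ppae_values=[6]
        )
        assert len(result.evaluated) == 1
        assert result.pareto == result.evaluated
        assert result.best == result.evaluated[0]

    def test_matches_brute_force_dominance(self):
        rng = np.random.default_rng(3)
        evaluated = [
            (
                ParameterPoint(10 + i, 5, 0),
                ObjectiveTriple(
                    int(rng.integers(0, 5)),
                    float(rng.integers(0, 5)),
                    float(rng.integers(0, 5)),
                ),
            )
            for i in range(15)
        ]
        front = pareto_front(evaluated)

        def dominated(oi, pool):
            return any(
                all(x >= y for x, y in zip(oj.as_tuple(), oi.as_tuple()))
                and oj.as_tuple() != oi.as_tuple()
                for oj in pool
            )

        objs = [o for _, o in evaluated]
        expected = [
            (p, o) for p, o in evaluated if not dominated(o, objs)
        ]
        assert front == expected

    def test_constructed_dominating_point_is_unique_pareto(self, constructed_bundle):
        """One antigen is visible only below threshold 60 and the second
        needs one PPAE allowed: relaxing both knobs strictly improves every
        objective, so the relaxed corner is the unique Pareto element."""
        result = tp.grid_search(
            constructed_bundle,
            tumor_values=[50, 60], essential_values=[10], ppae_values=[0, 1],
        )
        assert len(result.pareto) == 1
        point, obj = result.pareto[0]
        assert (point.tumor_high_threshold, point.max_ppae) == (50, 1)
        assert obj.n_tsa == 2
        assert result.best[0] == point

    def test_returned_points_non_dominated(self, small_bundle):
        result = tp.grid_search(
            small_bundle,
            tumor_values=[20, 50, 80],
            essential_values=[5, 15],
            ppae_values=[0, 2, 6],
        )
        for _, oi in result.pareto:
            for _, oj in result.evaluated:
                assert not (
                    all(x >= y for x, y in zip(oj.as_tuple(), oi.as_tuple()))
                    and any(x > y for x, y in zip(oj.as_tuple(), oi.as_tuple()))
                )

    def test_empty_grid_rejected(self, small_bundle):
        with pytest.raises(ValueError, match="empty"):
            tp.grid_search(small_bundle, tumor_values=[], essential_values=[10],
                           ppae_values=[6])


class TestMonotonicity:
    def test_n_tsa_monotone_in_thresholds(self, small_bundle):
        result = tp.grid_search(
            small_bundle,
            tumor_values=[20, 50, 80],
            essential_values=[10],
            ppae_values=[0, 3, 6],
        )
        by_point = {pt: o for pt, o in result.evaluated}
        # non-increasing in tumor threshold
        for ppae in (0, 3, 6):
            ns = [by_point[ParameterPoint(t, 10, ppae)].n_tsa for t in (20, 50, 80)]
            assert ns == sorted(ns, reverse=True)
        # non-decreasing in the PPAE cap
        for t in (20, 50, 80):
            ns = [by_point[ParameterPoint(t, 10, p)].n_tsa for p in (0, 3, 6)]
            assert ns == sorted(ns)

    def test_hill_climb_cannot_worsen_scalarized_pick(self, small_bundle):
        grid = dict(tumor_values=[20, 50, 80], essential_values=[5, 15],
                    ppae_values=[0, 2, 6])
        plain = tp.grid_search(small_bundle, **grid)
        climbed = tp.grid_search(small_bundle, hill_climb=True, **grid)
        objs = np.array([o.as_tuple() for _, o in plain.evaluated], dtype=float)
        lo, hi = objs.min(0), objs.max(0)
        span = np.where(hi > lo, hi - lo, 1.0)

        def score(o):
            return (((np.array(o.as_tuple()) - lo) / span)).sum()

        assert score(climbed.best[1]) >= score(plain.best[1]) - 1e-12
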
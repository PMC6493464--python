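"""Adverse-event and coverage indices, DTPF, priority classes, ranking."""

import numpy as np
import pandas as pd
import pytest

import tsapool as tp
from test_identification import _profile


class TestIppae:
    def test_ratio_to_pool_max(self):
        targets = [
            _profile("a", ppae=[("salivary gland", "high")]),  # 1 * 0.5
            _profile("b", ppae=[("colon", "low")]),  # 0.5 * 0.8
            _profile("c", ppae=[]),
        ]
        ippae = tp.compute_ippae(targets, tp.default_weights())
        assert ippae == pytest.approx({"a": 1.0, "b": 0.8, "c": 0.0})

    def test_empty_ppae_set_scores_zero(self):
        ippae = tp.compute_ippae([_profile("a")], tp.default_weights())
        assert ippae["a"] == 0.0

    def test_zero_denominator_all_zero(self):
        targets = [_profile("a", ppae=[("testis", "high")]), _profile("b")]
        ippae = tp.compute_ippae(targets, tp.default_weights())
        assert ippae == {"a": 0.0, "b": 0.0}

    def test_explicit_denominator(self):
        t = _profile("a", ppae=[("colon", "low")])  # numerator 0.4
        ippae = tp.compute_ippae([t], tp.default_weights(), denominator=3.0438)
        assert ippae["a"] == pytest.approx(0.4 / 3.0438)

    def test_unique_argmax_scores_one(self):
        targets = [
            _profile("a", ppae=[("kidney", "high")]),  # 1.0
            _profile("b", ppae=[("colon", "low")]),  # 0.4
        ]
        ippae = tp.compute_ippae(targets, tp.default_weights())
        assert sum(v == 1.0 for v in ippae.values()) == 1


class TestItscrDtpf:
    def test_coverage_ratio_values(self):
        p65 = _profile(indicators=[1] * 65 + [0] * 33)
        p17 = _profile(indicators=[1] * 17 + [0] * 81)
        assert tp.compute_itscr(p65, 98) == pytest.approx(0.6633, abs=1e-4)
        assert tp.compute_itscr(p17, 98) == pytest.approx(0.1735, abs=1e-4)
        assert tp.compute_itscr(_profile(indicators=[0] * 10), 10) == 0.0
        with pytest.raises(ValueError):
            tp.compute_itscr(p65, 0)

    @pytest.mark.parametrize(
        "covered,expected",
        [(31, 1.316), (29, 1.296), (17, 1.173)],
    )
    def test_dtpf_with_zero_weighted_numerator(self, covered, expected):
        assert round(tp.compute_dtpf(0.0, covered / 98), 3) == expected

    def test_dtpf_worst_case_and_range(self):
        assert tp.compute_dtpf(1.0, 0.0) == 0.0
        assert tp.compute_dtpf(0.0, 1.0) == 2.0
        with pytest.raises(ValueError):
            tp.compute_dtpf(1.2, 0.0)

    def test_adding_positive_weight_ppae_never_raises_dtpf(self):
        """With the pool max held fixed, an extra weighted adverse event can
        only lower (or keep) the score."""
        rng = np.random.default_rng(9)
        w = tp.default_weights()
        weighted = [t for t, wt in w.weights.items() if wt > 0]
        for _ in range(30):
            n = rng.integers(0, 4)
            tissues = rng.choice(weighted, size=n, replace=False)
            ppae = [(t, rng.choice(["low", "high"])) for t in tissues]
            extra_tissue = rng.choice([t for t in weighted if t not in tissues])
            base = _profile("g", ppae=ppae)
            more = _profile("g", ppae=ppae + [(extra_tissue, "low")])
            denom = 5.0
            itscr = 0.4
            d_base = tp.compute_dtpf(
                min(base.weighted_ppae_numerator(w) / denom, 1.0), itscr
            )
            d_more = tp.compute_dtpf(
                min(more.weighted_ppae_numerator(w) / denom, 1.0), itscr
            )
            assert d_more <= d_base + 1e-12


class TestPriority:
    @pytest.mark.parametrize(
        "one_minus_ippae,itscr,expected",
        [
            (0.836, 0.663, "high"),
            (0.9, 0.20, "low"),
            (0.5, 0.9, "none"),  # boundary falls to the lower class
            (0.51, 0.25, "low"),  # I_TSCR boundary is also strict
            (0.2, 0.9, "none"),
        ],
    )
    def test_classes(self, one_minus_ippae, itscr, expected):
        assert tp.classify_priority(1 - one_minus_ippae, itscr) == expected


class TestRanking:
    def _target(self, gene, dtpf, itscr=0.5):
        return tp.PrioritizedTarget(
            gene_id=gene, i_ppae=0.0, i_tscr=itscr, dtpf=dtpf,
            priority="high", rank=0, profile=_profile(gene),
        )

    def test_descending_dtpf(self):
        ts = [self._target(g, d) for g, d in [("x", 1.316), ("y", 1.499), ("z", 1.440)]]
        ranked = tp.rank_targets(ts)
        assert [t.gene_id for t in ranked] == ["y", "z", "x"]
        assert [t.rank for t in ranked] == [1, 2, 3]

    def test_tie_broken_by_itscr_then_gene(self):
        ts = [
            self._target("b", 1.3, itscr=0.2),
            self._target("a", 1.3, itscr=0.3),
            self._target("c", 1.3, itscr=0.2),
        ]
        assert [t.gene_id for t in tp.rank_targets(ts)] == ["a", "b", "c"]

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(13)
        ts = [
            self._target(f"g{i}", float(rng.choice([1.1, 1.2, 1.3])),
                         float(rng.choice([0.2, 0.4])))
            for i in range(20)
        ]
        ranked = tp.rank_targets(list(ts))
        oracle = sorted(ts, key=lambda t: (-t.dtpf, -t.i_tscr, t.gene_id))
        assert [t.gene_id for t in ranked] == [t.gene_id for t in oracle]


class TestDenominatorCrossCheck:
    def test_solved_denominators_agree(self, table1_result):
        """The pool normalization implied by the rank-1 and rank-2 published
        rows (DTPF 1.499 at numerator 0.5 / 65 covered; DTPF 1.440 at
        numerator 0.4 / 56 covered) is one consistent constant (~3.04)."""
        w = tp.default_weights()
        by_gene = {p.gene_id: p for p in table1_result.pool}
        ct83, actl8 = by_gene["CT83L"], by_gene["ACTL8L"]
        d1 = tp.solve_pool_denominator(
            ct83.weighted_ppae_numerator(w), ct83.covered_count, 98, 1.499
        )
        d2 = tp.solve_pool_denominator(
            actl8.weighted_ppae_numerator(w), actl8.covered_count, 98, 1.440
        )
        assert d1 == pytest.approx(3.04, abs=0.01)
        assert abs(d1 - d2) < 0.01

    def test_pinned_denominator_ranks_most_covered_antigen_first(
        self, table1_cohort
    ):
        counts, meta, annot, _ = table1_cohort
        res = tp.run_all(counts, meta, annot, ippae_denominator=3.0438)
        assert res.ranked[0].gene_id == "CT83L"
        assert round(res.ranked[0].dtpf, 3) == pytest.approx(1.499, abs=0.001)
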
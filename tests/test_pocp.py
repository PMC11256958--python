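"""Conservation filtering, counting, the POCP formula, matrices, summaries."""

import numpy as np
import pytest

from pocp import (
    AlignmentHit,
    FilterCriteria,
    InputError,
    NonstandardCriteriaWarning,
    ProteinRecord,
    Proteome,
    compare_pair,
    compute_matrix,
    count_conserved,
    is_conserved,
    pocp_from_counts,
    summarize,
)
from pocp.pocp import nonstandard_criteria_message
from pocp.synthetic import generate_proteome
from reference_impls import reference_count_conserved


def make_hit(qid="q1", pident=90.0, qstart=1, qend=90, evalue=1e-20, qlen=100):
    return AlignmentHit(
        query_id=qid, subject_id="s", percent_identity=pident, align_columns=qend - qstart + 1,
        query_start=qstart, query_end=qend, evalue=evalue, score=100.0, query_len=qlen,
    )


class TestIsConserved:
    def test_passing_hit_just_inside_all_thresholds(self):
        hit = make_hit(pident=41.0, evalue=1e-6, qstart=1, qend=51, qlen=100)
        assert is_conserved(hit, FilterCriteria())

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(evalue=1e-5, pident=90.0, qstart=1, qend=90),  # e-value on boundary
            dict(evalue=1e-10, pident=40.0, qstart=1, qend=80),  # identity on boundary
            dict(evalue=1e-10, pident=90.0, qstart=1, qend=50),  # coverage exactly 50
        ],
    )
    def test_boundary_hits_are_rejected_by_strict_thresholds(self, kwargs):
        assert not is_conserved(make_hit(qlen=100, **kwargs))

    def test_non_strict_mode_accepts_boundary_hits(self):
        lax = FilterCriteria(strict=False)
        assert is_conserved(make_hit(evalue=1e-5, pident=40.0, qstart=1, qend=50), lax)

    def test_failing_any_single_criterion_fails_overall(self):
        assert not is_conserved(make_hit(evalue=1.0))
        assert not is_conserved(make_hit(pident=10.0))
        assert not is_conserved(make_hit(qstart=1, qend=20))


class TestCountConserved:
    def test_distinct_queries_counted_once(self):
        hits = [
            make_hit("q1"), make_hit("q1", qend=80),  # two passing rows, one query
            make_hit("q2", pident=10.0),  # failing
            make_hit("q3"),  # passing
        ]
        assert count_conserved(hits) == 2

    def test_empty_hit_list(self):
        assert count_conserved([]) == 0

    def test_upper_bound_is_number_of_distinct_queries(self):
        hits = [make_hit(f"q{i}") for i in range(50)]
        assert count_conserved(hits) == 50

    def test_agrees_with_bruteforce_row_scan_on_random_tables(self, rng):
        for _ in range(200):
            n_rows = int(rng.integers(0, 40))
            rows = []
            for _ in range(n_rows):
                qlen = int(rng.integers(50, 400))
                qstart = int(rng.integers(1, qlen))
                qend = int(rng.integers(qstart, qlen + 1))
                rows.append(
                    (
                        f"q{int(rng.integers(0, 12))}",
                        float(np.round(rng.uniform(0, 100), 2)),
                        qstart,
                        qend,
                        float(10.0 ** rng.uniform(-50, 1)),
                        qlen,
                    )
                )
            hits = [
                make_hit(qid, pident=p, qstart=a, qend=b, evalue=e, qlen=L)
                for qid, p, a, b, e, L in rows
            ]
            assert count_conserved(hits) == reference_count_conserved(rows)


class TestPocpFormula:
    @pytest.mark.parametrize(
        "c1,c2,t1,t2,expected",
        [
            (500, 600, 500, 600, 100.0),
            (0, 0, 500, 600, 0.0),
            (300, 320, 500, 600, 100 * 620 / 1100),
        ],
    )
    def test_formula(self, c1, c2, t1, t2, expected):
        assert pocp_from_counts(c1, c2, t1, t2) == pytest.approx(expected)

    def test_count_exceeding_total_signals_upstream_bug(self):
        with pytest.raises(ValueError, match="counting bug"):
            pocp_from_counts(501, 0, 500, 600)
        with pytest.raises(ValueError):
            pocp_from_counts(0, 0, 0, 10)


class TestComparePair:
    def test_relabelled_copy_gives_exactly_100(self):
        a = generate_proteome(6, (60, 120), seed=7, label="a")
        b = a.relabelled("b")
        result = compare_pair(a, b)
        assert result.pocp_pct == 100.0
        assert (result.c1, result.c2) == (6, 6)

    def test_no_hits_gives_zero(self):
        a = Proteome("a", [ProteinRecord("a1", "A" * 60), ProteinRecord("a2", "G" * 60)])
        b = Proteome("b", [ProteinRecord("b1", "W" * 60)])
        result = compare_pair(a, b)
        assert result.pocp_pct == 0.0
        assert (result.c1, result.c2, result.t1, result.t2) == (0, 0, 2, 1)

    def test_direction_independent(self):
        a = generate_proteome(5, (60, 100), seed=1, label="a")
        b = generate_proteome(5, (60, 100), seed=2, label="b")
        ab = compare_pair(a, b)
        ba = compare_pair(b, a)
        assert ab.pocp_pct == ba.pocp_pct
        assert {ab.c1, ab.c2} == {ba.c1, ba.c2}

    def test_same_label_rejected(self, tiny_proteome):
        with pytest.raises(InputError, match="itself"):
            compare_pair(tiny_proteome, tiny_proteome)


class TestComputeMatrix:
    @pytest.fixture
    def five_proteomes(self):
        return [generate_proteome(3, (60, 90), seed=i, label=f"g{i}") for i in range(5)]

    def test_all_vs_all_pair_count_and_symmetry(self, five_proteomes):
        m = compute_matrix(five_proteomes)
        assert len(m.pairs) == 10  # 5*4/2
        assert (np.diag(m.values.to_numpy()) == 100.0).all()
        assert m.values.equals(m.values.T)
        assert not m.values.isna().to_numpy().any()

    def test_one_vs_all_computes_only_target_pairs(self, five_proteomes):
        m = compute_matrix(five_proteomes, mode="one-vs-all", target="g2")
        assert len(m.pairs) == 4
        # uncomputed cells are missing, never zero-filled
        assert m.values.loc["g0", "g1"] != m.values.loc["g0", "g1"]  # NaN
        assert not np.isnan(m.values.loc["g2", "g0"])

    def test_two_proteomes_smallest_case(self, five_proteomes):
        m = compute_matrix(five_proteomes[:2])
        assert len(m.pairs) == 1
        assert m.values.shape == (2, 2)

    def test_unknown_target_lists_available_labels(self, five_proteomes):
        with pytest.raises(InputError, match="g0, g1, g2, g3, g4"):
            compute_matrix(five_proteomes, mode="one-vs-all", target="nope")

    def test_nonstandard_criteria_warn(self, five_proteomes):
        with pytest.warns(NonstandardCriteriaWarning, match="min_identity_pct=30"):
            compute_matrix(five_proteomes[:2], criteria=FilterCriteria(min_identity_pct=30.0))

    def test_default_criteria_do_not_warn(self):
        assert nonstandard_criteria_message(FilterCriteria()) is None


class TestThresholdMonotonicity:
    def test_tightening_any_criterion_never_increases_counts(self, rng):
        hits = []
        for i in range(300):
            qlen = int(rng.integers(60, 300))
            qstart = int(rng.integers(1, qlen // 2))
            qend = int(rng.integers(qstart, qlen + 1))
            hits.append(
                make_hit(
                    f"q{int(rng.integers(0, 40))}",
                    pident=float(rng.uniform(20, 100)),
                    qstart=qstart,
                    qend=qend,
                    evalue=float(10.0 ** rng.uniform(-30, 0)),
                    qlen=qlen,
                )
            )
        base = count_conserved(hits, FilterCriteria())
        tighter = [
            FilterCriteria(max_evalue=1e-8),
            FilterCriteria(min_identity_pct=60.0),
            FilterCriteria(min_coverage_pct=75.0),
        ]
        for crit in tighter:
            assert count_conserved(hits, crit) <= base


class TestSummarize:
    def _pair(self, v):
        from pocp import PairwiseResult

        return PairwiseResult("a", "b", 1, 1, 2, 2, v)

    def test_two_value_summary(self):
        s = summarize([self._pair(40.0), self._pair(60.0)])
        assert (s.min_pocp, s.max_pocp, s.mean_pocp) == (40.0, 60.0, 50.0)
        assert s.n_pairs_above_genus_threshold == 1

    def test_genus_threshold_is_strict(self):
        s = summarize([self._pair(50.0)])
        assert s.n_pairs_above_genus_threshold == 0

    def test_empty_input_marks_stats_undefined(self):
        s = summarize([])
        assert s.n_pairs == 0
        assert s.min_pocp is None and s.max_pocp is None and s.mean_pocp is None
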
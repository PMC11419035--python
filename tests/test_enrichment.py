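import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lcrep.enrichment import (
    bh_adjust,
    enrichment_table,
    gene_enrichment,
    tabulate_usage,
    usage_correlation,
    usage_frequencies,
)


def _assignments(rows):
    return pd.DataFrame(
        rows, columns=["sequence_id", "cohort", "v_call", "coverage_class"]
    )


def _usage_table(case_counts: dict, control_counts: dict,
                 case="AL", control="MM") -> pd.DataFrame:
    genes = sorted(set(case_counts) | set(control_counts))
    return pd.DataFrame(
        {case: [case_counts.get(g, 0) for g in genes],
         control: [control_counts.get(g, 0) for g in genes]},
        index=pd.Index(genes, name="v_gene"),
    )


class TestTabulateUsage:
    def test_counts_complete_plus_incomplete_only(self):
        rows = (
            [(f"c{i}", "A", "g", "complete") for i in range(3)]
            + [(f"i{i}", "A", "g", "incomplete") for i in range(2)]
            + [(f"x{i}", "A", "g", "excluded") for i in range(4)]
        )
        table = tabulate_usage(_assignments(rows), ["A"])
        assert table.at["g", "A"] == 5

    def test_empty_assignments_give_empty_table(self):
        table = tabulate_usage(_assignments([("r", "A", "g", "excluded")]), ["A"])
        assert table.empty

    def test_one_record_per_gene(self):
        rows = [(f"r{i}", "A", f"g{i}", "complete") for i in range(10)]
        table = tabulate_usage(_assignments(rows), ["A"])
        assert (table["A"] == 1).all()
        assert table["A"].sum() == 10

    def test_unknown_cohort_errors(self):
        with pytest.raises(ValueError, match="B"):
            tabulate_usage(_assignments([("r", "A", "g", "complete")]), ["A", "B"])


class TestGeneEnrichment:
    def test_hand_evaluated_two_by_two(self):
        # a=50 of A=781 vs b=5 of B=1122: OR = (50*1117)/(5*731)
        table = _usage_table({"g1": 50, "g2": 731}, {"g1": 5, "g2": 1117})
        results = gene_enrichment(table, "AL", "MM")
        r = {x.v_gene: x for x in results}["g1"]
        assert r.odds_ratio == pytest.approx((50 * 1117) / (5 * 731), rel=1e-12)
        assert r.odds_ratio == pytest.approx(15.2804, abs=1e-4)
        assert r.ci_low <= r.odds_ratio <= r.ci_high

    def test_identical_proportions_give_unit_or(self):
        table = _usage_table({"g1": 30, "g2": 60, "g3": 10},
                             {"g1": 60, "g2": 120, "g3": 20})
        for r in gene_enrichment(table, "AL", "MM"):
            assert r.odds_ratio == pytest.approx(1.0)
            assert r.direction == "none"

    def test_reciprocal_ors_without_continuity_correction(self):
        table = _usage_table({"g1": 40, "g2": 160}, {"g1": 10, "g2": 190})
        fwd = {r.v_gene: r for r in gene_enrichment(table, "AL", "MM")}
        rev = {r.v_gene: r for r in gene_enrichment(table, "MM", "AL")}
        for g in fwd:
            assert fwd[g].odds_ratio * rev[g].odds_ratio == pytest.approx(1.0)
            assert fwd[g].p_value == pytest.approx(rev[g].p_value, rel=1e-9)

    def test_zero_cell_gets_continuity_correction(self):
        table = _usage_table({"g1": 20, "g2": 80}, {"g1": 0, "g2": 100})
        r = {x.v_gene: x for x in gene_enrichment(table, "AL", "MM")}["g1"]
        assert np.isfinite(r.odds_ratio) and r.odds_ratio > 1
        assert np.isfinite(r.ci_high)

    def test_sorted_by_descending_or(self):
        table = _usage_table({"g1": 5, "g2": 50, "g3": 45},
                             {"g1": 30, "g2": 40, "g3": 30})
        ors = [r.odds_ratio for r in gene_enrichment(table, "AL", "MM")]
        assert ors == sorted(ors, reverse=True)

    def test_zero_total_errors(self):
        table = _usage_table({"g1": 0, "g2": 0}, {"g1": 5, "g2": 5})
        with pytest.raises(ValueError):
            gene_enrichment(table, "AL", "MM")

    def test_or_recovery_simulation(self):
        # cohorts drawn with one gene at true OR 4; median estimate near 4
        # and q <= 0.05 in >= 90% of seeds (scaled-down version of the
        # acceptance run)
        genes = [f"g{i}" for i in range(10)]
        control_p = np.full(10, 0.1)
        # focal gene odds = 4 * control odds (1/9) => p = 4/13; remainder even
        case_p = np.full(10, (1 - 4 / 13) / 9)
        case_p[0] = 4 / 13
        ors, hits = [], 0
        n = 2000
        for seed in range(10):
            rng = np.random.default_rng(seed)
            case_counts = rng.multinomial(n, case_p)
            control_counts = rng.multinomial(n, control_p / control_p.sum())
            table = _usage_table(dict(zip(genes, case_counts)),
                                 dict(zip(genes, control_counts)))
            r = {x.v_gene: x for x in gene_enrichment(table, "AL", "MM")}["g0"]
            ors.append(r.odds_ratio)
            hits += r.q_value <= 0.05
        assert 3.0 <= float(np.median(ors)) <= 5.3
        assert hits >= 9


class TestBhAdjust:
    def test_hand_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_equal_stay_equal(self):
        assert bh_adjust([0.2, 0.2, 0.2, 0.2]) == pytest.approx([0.2] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.042]) == pytest.approx([0.042])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=200, deadline=None)
    def test_q_at_least_p_and_order_preserving(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_null_calibration_quick(self):
        # under the null, expected fraction of q <= 0.05 discoveries <= 5%
        rng = np.random.default_rng(5)
        frac = []
        for _ in range(50):
            p = rng.uniform(size=20)
            frac.append(np.mean(bh_adjust(p) <= 0.05))
        assert np.mean(frac) <= 0.05


class TestUsageCorrelation:
    def test_identical_vectors(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        r, p = usage_correlation(x, x.copy())
        assert r == pytest.approx(1.0)

    def test_reversed_equally_spaced(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _ = usage_correlation(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        # oracle: direct covariance-formula evaluation
        x = np.array([0.12, 0.05, 0.2, 0.08, 0.1, 0.15, 0.02, 0.09, 0.11, 0.08])
        y = np.array([0.1, 0.07, 0.18, 0.1, 0.08, 0.17, 0.01, 0.1, 0.13, 0.06])
        r, _ = usage_correlation(x, y)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_series_aligned_over_gene_union(self):
        a = pd.Series({"g1": 0.5, "g2": 0.5})
        b = pd.Series({"g2": 0.4, "g3": 0.6})
        r, _ = usage_correlation(a, b)
        assert np.isfinite(r)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            usage_correlation(np.array([0.25] * 4), np.array([0.1, 0.2, 0.3, 0.4]))

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            usage_correlation(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestUsageFrequencies:
    def test_frequencies_sum_to_one(self):
        table = _usage_table({"g1": 30, "g2": 70}, {"g1": 50, "g2": 50})
        assert usage_frequencies(table, "AL").sum() == pytest.approx(1.0)

    def test_enrichment_table_schema(self):
        table = _usage_table({"g1": 30, "g2": 70}, {"g1": 50, "g2": 50})
        df = enrichment_table(gene_enrichment(table, "AL", "MM"))
        assert list(df.columns[:4]) == ["v_gene", "case_count", "control_count",
                                        "odds_ratio"]
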
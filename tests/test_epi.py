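"""Diagnostic-accuracy and descriptive-epidemiology statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import Table2x2

from msikit.epi import (
    TwoByTwoTable,
    accuracy_stats,
    marker_table,
    mmr,
    proportion_ci,
    relative_risk,
    score_mortality_from_counts,
    score_mortality_table,
)
from msikit.markers import CaseRecord


def brute_force_accuracy(positive, died):
    """Oracle: tally the 2x2 by explicit per-case enumeration and compute
    the four accuracy statistics from first principles."""
    tp = sum(p and d for p, d in zip(positive, died))
    fp = sum(p and not d for p, d in zip(positive, died))
    fn = sum((not p) and d for p, d in zip(positive, died))
    tn = sum((not p) and (not d) for p, d in zip(positive, died))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "sensitivity": sens, "specificity": spec,
        "plr": sens / (1 - spec) if spec < 1 else math.inf,
        "nlr": (1 - sens) / spec if spec > 0 else math.inf,
    }


class TestAccuracyStats:
    def test_matches_per_case_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(20, 200))
            positive = rng.random(n) < 0.3
            # make deaths associated with positivity but not perfectly
            died = rng.random(n) < np.where(positive, 0.5, 0.05)
            if died.all() or not died.any() or positive.all() or not positive.any():
                continue
            oracle = brute_force_accuracy(positive, died)
            t = TwoByTwoTable.from_cases(positive, died)
            assert (t.tp, t.fp, t.fn, t.tn) == (
                oracle["tp"], oracle["fp"], oracle["fn"], oracle["tn"]
            )
            got = accuracy_stats(t)
            for key in ("sensitivity", "specificity", "plr", "nlr"):
                if math.isfinite(oracle[key]):
                    assert got[key].point == pytest.approx(oracle[key])

    def test_reference_table_all_women(self):
        got = accuracy_stats(TwoByTwoTable(140, 770, 0, 81478))
        assert got["sensitivity"].point == 1.0
        assert got["sensitivity"].lo == pytest.approx(0.97, abs=5e-3)
        assert got["specificity"].point == pytest.approx(0.99, abs=5e-3)
        assert got["plr"].point == pytest.approx(106.8, abs=0.05)
        assert got["plr"].lo == pytest.approx(99.56, abs=0.01)
        assert got["plr"].hi == pytest.approx(114.6, abs=0.05)
        assert got["nlr"].point == 0.0

    def test_reference_table_complications(self):
        got = accuracy_stats(TwoByTwoTable(140, 770, 0, 8645))
        assert got["specificity"].point == pytest.approx(0.92, abs=5e-3)
        assert got["specificity"].lo == pytest.approx(0.91, abs=5e-3)
        assert got["specificity"].hi == pytest.approx(0.92, abs=5e-3)
        assert got["plr"].point == pytest.approx(12.2, abs=0.05)
        assert got["plr"].lo == pytest.approx(11.4, abs=0.05)
        assert got["plr"].hi == pytest.approx(13.1, abs=0.05)

    def test_perfect_test_flags_undefined_plr(self):
        got = accuracy_stats(TwoByTwoTable(10, 0, 0, 10))
        assert got["sensitivity"].point == 1.0
        assert got["specificity"].point == 1.0
        assert not got["plr"].defined and got["plr"].point == math.inf
        assert got["nlr"].point == 0.0

    def test_plr_nlr_association_direction(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            tp, fp, fn, tn = rng.integers(1, 100, size=4)
            got = accuracy_stats(TwoByTwoTable(tp, fp, fn, tn))
            sens, spec = got["sensitivity"].point, got["specificity"].point
            if 0 < sens < 1 and 0 < spec < 1:
                assert (got["plr"].point > 1) == (got["nlr"].point < 1) or (
                    got["plr"].point == 1
                )

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            accuracy_stats(TwoByTwoTable(0, 5, 0, 5))


class TestRelativeRisk:
    @pytest.mark.parametrize(
        "args,point,lo,hi",
        [
            ((74, 250, 66, 9305), 41.7, 30.7, 56.7),     # shock
            ((123, 295, 17, 9260), 227.1, 138.6, 372.1),  # intubation
            ((22, 171, 118, 9384), 10.2, 6.7, 15.7),      # hysterectomy
        ],
    )
    def test_reference_rows(self, args, point, lo, hi):
        rr = relative_risk(*args)
        assert rr.point == pytest.approx(point, abs=0.05)
        assert rr.lo == pytest.approx(lo, abs=0.06)
        assert rr.hi == pytest.approx(hi, abs=0.06)

    def test_equal_risks_identity(self):
        assert relative_risk(5, 100, 50, 1000).point == pytest.approx(1.0)

    def test_matches_statsmodels_table2x2(self):
        # independent route: statsmodels' risk-ratio CI (same log method)
        a, n1, c, n0 = 30, 120, 25, 400
        rr = relative_risk(a, n1, c, n0)
        t = Table2x2([[a, n1 - a], [c, n0 - c]])
        assert rr.point == pytest.approx(t.riskratio)
        lo, hi = t.riskratio_confint()
        assert rr.lo == pytest.approx(lo, rel=1e-6)
        assert rr.hi == pytest.approx(hi, rel=1e-6)

    def test_zero_deaths_flagged(self):
        rr = relative_risk(0, 50, 5, 100)
        assert rr.point == 0.0 and not rr.defined
        rr = relative_risk(5, 50, 0, 100)
        assert rr.point == math.inf and not rr.defined

    @given(
        a=st.integers(1, 50), extra1=st.integers(1, 50),
        c=st.integers(1, 50), extra0=st.integers(1, 50),
        factor=st.integers(2, 7),
    )
    @settings(max_examples=50, deadline=None)
    def test_point_invariant_under_count_scaling(self, a, extra1, c, extra0, factor):
        n1, n0 = a + extra1, c + extra0
        base = relative_risk(a, n1, c, n0).point
        scaled = relative_risk(a * factor, n1 * factor, c * factor, n0 * factor).point
        assert scaled == pytest.approx(base, rel=1e-12)


class TestProportionCI:
    @pytest.mark.parametrize(
        "k,n,point,lo,hi",
        [
            (14, 61, 0.23, 0.142, 0.349),
            (0, 402, 0.0, 0.0, 0.009),
        ],
    )
    def test_reference_rows(self, k, n, point, lo, hi):
        est = proportion_ci(k, n)
        assert est.point == pytest.approx(point, abs=5e-3)
        assert est.lo == pytest.approx(lo, abs=5e-4)
        assert est.hi == pytest.approx(hi, abs=5e-4)

    def test_degenerate_zero_of_one(self):
        est = proportion_ci(0, 1)
        assert est.point == 0.0 and est.lo == 0.0

    def test_n_zero_rejected(self):
        with pytest.raises(ValueError):
            proportion_ci(0, 0)

    @given(n=st.integers(1, 10**6), frac=st.floats(0, 1))
    @settings(max_examples=200, deadline=None)
    def test_wilson_respects_unit_interval(self, n, frac):
        k = min(n, int(frac * n))
        est = proportion_ci(k, n)
        assert 0.0 <= est.lo <= est.point <= est.hi <= 1.0


class TestMmr:
    def test_reference_value(self):
        est = mmr(140, 82144)
        assert est.point == pytest.approx(170.4, abs=0.05)
        assert round(est.lo) == 144
        assert round(est.hi) == 201

    def test_zero_event_poisson_upper_limit(self):
        est = mmr(0, 1000, method="poisson")
        assert est.point == 0.0
        # exact upper limit for 0 events is -ln(0.025) = 3.6889 events
        assert est.hi == pytest.approx(-math.log(0.025) / 1000 * 1e5, rel=1e-4)

    def test_scale(self):
        assert mmr(100000, 100000).point == pytest.approx(100000)

    def test_denominator_required(self):
        with pytest.raises(ValueError):
            mmr(1, 0)


class TestScoreMortality:
    def test_reference_counts_reproduce_published_correlation(self):
        from msikit import reference

        res = score_mortality_from_counts(
            [n for n, _ in reference.SCORE_DISTRIBUTION],
            [d for _, d in reference.SCORE_DISTRIBUTION],
        )
        assert res.pearson_r == pytest.approx(0.96, abs=5e-3)
        row4 = res.table.iloc[4]
        assert row4["mortality"] == pytest.approx(0.2295, abs=5e-4)
        assert row4["lo"] == pytest.approx(0.142, abs=5e-4)
        assert row4["hi"] == pytest.approx(0.349, abs=5e-4)

    def test_all_survivor_cohort_flagged_undefined(self):
        cohort = [CaseRecord(f"c{i}", {"shock"}) for i in range(10)]
        res = score_mortality_table(cohort)
        assert res.pearson_r is None and "undefined" in res.note

    def test_two_bins_increasing_gives_r_one(self):
        cohort = [CaseRecord(f"a{i}", {"shock"}) for i in range(10)]
        cohort += [
            CaseRecord(f"b{i}", {"shock", "cpr"}, died=i < 5) for i in range(10)
        ]
        res = score_mortality_table(cohort)
        assert res.pearson_r == pytest.approx(1.0)

    def test_open_bin_pools_high_scores(self):
        from msikit.markers import MARKER_IDS

        heavy = CaseRecord("h", set(sorted(MARKER_IDS)[:20]), died=True)
        res = score_mortality_table([heavy, CaseRecord("z", {"shock"})])
        assert res.table.iloc[-1]["n"] == 1
        assert res.table.iloc[-1]["bin"] == "15+"


class TestMarkerTable:
    def test_reconstructed_rows_from_constructed_cohort(self):
        # miniature cohort: 6 CPR cases (5 die), 14 others (1 dies)
        cohort = [
            CaseRecord(f"cpr{i}", {"cpr"}, died=i < 5) for i in range(6)
        ] + [CaseRecord(f"o{i}", {"shock"}, died=i < 1) for i in range(14)]
        table = marker_table(cohort, deliveries=1000).set_index("marker_id")
        cpr = table.loc["cpr"]
        assert cpr["deaths"] == 5 and cpr["survivors"] == 1
        assert cpr["mortality_pct"] == pytest.approx(5 / 6 * 100)
        assert cpr["prevalence_per_1000_deliveries"] == pytest.approx(6.0)
        expected_rr = (5 / 6) / (1 / 14)
        assert cpr["rr"] == pytest.approx(expected_rr)

    def test_absent_marker_reported_empty_not_dropped(self):
        cohort = [CaseRecord("c", {"shock"})]
        table = marker_table(cohort, deliveries=100).set_index("marker_id")
        assert len(table) == 25
        assert math.isnan(table.loc["stroke"]["mortality_pct"])

    def test_perfect_association_marker(self):
        cohort = [
            CaseRecord(f"m{i}", {"stroke"}, died=True) for i in range(3)
        ] + [CaseRecord(f"n{i}", {"shock"}, died=False) for i in range(7)]
        table = marker_table(cohort, deliveries=100).set_index("marker_id")
        assert table.loc["stroke"]["mortality_pct"] == 100.0
        # zero deaths in the unexposed arm: RR infinite, CI flagged
        assert table.loc["stroke"]["rr"] == math.inf
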
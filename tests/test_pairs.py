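"""Boolean pregnant-range calls, OR pairing, F1 and the stratified chi-square."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency
from statsmodels.stats.contingency_tables import StratifiedTable

from embryomet.datatypes import ConfusionCounts
from embryomet.errors import (
    InsufficientDataError,
    PairingError,
    UndefinedTestError,
)
from embryomet.pairs import (
    AGGREGATE,
    STRATIFIED,
    boolean_calls,
    combine_or,
    confusion,
    f1_score,
    mh_chi_square,
    nd_rule,
    pregnant_range,
    round_half_up,
    score_all_pairs,
    score_pair,
)


def series(values, ids=None):
    values = np.asarray(values, dtype=float)
    if ids is None:
        ids = [f"S{i:02d}" for i in range(values.size)]
    return pd.Series(values, index=ids)


class TestPregnantRange:
    def test_min_max_inclusive(self):
        vals = series([3, 5, 9, 1, 20])
        labels = pd.Series([True, True, True, False, False], index=vals.index)
        assert pregnant_range(vals, labels) == (3.0, 9.0)

    def test_degenerate_constant_range(self):
        vals = series([4, 4, 4, 1, 9])
        labels = pd.Series([True, True, True, False, False], index=vals.index)
        lo, hi = pregnant_range(vals, labels)
        assert lo == hi == 4.0
        calls = boolean_calls(vals, (lo, hi))
        assert list(calls.calls) == [1.0, 1.0, 1.0, 0.0, 0.0]

    def test_too_few_pregnant_values(self):
        vals = series([1, 2, 3])
        labels = pd.Series([True, False, False], index=vals.index)
        with pytest.raises(InsufficientDataError):
            pregnant_range(vals, labels)

    def test_range_after_upstream_outlier_removal(self):
        from embryomet.screen import remove_outliers

        raw = series([10.0, 12.0, 11.0, 12000.0, 3.0, 4.0])
        labels = pd.Series([True, True, True, True, False, False], index=raw.index)
        _, removed = remove_outliers(raw, threshold_fold=100, sample_ids=list(raw.index))
        assert removed == ["S03"]
        kept = raw.drop(index=removed)
        lo, hi = pregnant_range(kept, labels.drop(index=removed))
        assert hi == 12.0  # the 1200x-style sample no longer widens the range


class TestBooleanCalls:
    def test_boundary_inclusive(self):
        vals = series([2.0, 1.9999, 5.0, 5.0001])
        calls = boolean_calls(vals, (2.0, 5.0)).calls
        assert list(calls) == [1.0, 0.0, 1.0, 0.0]

    def test_missing_value_propagates(self):
        vals = series([2.0, np.nan, 3.0])
        calls = boolean_calls(vals, (1.0, 4.0)).calls
        assert calls.iloc[0] == 1.0 and calls.iloc[2] == 1.0
        assert np.isnan(calls.iloc[1])

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(0)
        vals = series(rng.normal(0, 1, 200))
        lo, hi = -0.5, 0.8
        calls = boolean_calls(vals, (lo, hi)).calls
        for v, c in zip(vals, calls):
            assert c == float(lo <= v <= hi)

    def test_n_true(self):
        vals = series([1, 2, 3, 4])
        assert boolean_calls(vals, (2, 3)).n_true == 2


class TestCombineOr:
    @pytest.mark.parametrize(
        "a, b, expected", [(0, 0, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1)]
    )
    def test_stated_truth_table(self, a, b, expected):
        out = combine_or(series([a, a]), series([b, b]))
        assert list(out) == [float(expected)] * 2

    def test_all_false_is_identity(self):
        rng = np.random.default_rng(1)
        x = series((rng.random(50) < 0.4).astype(float))
        assert list(combine_or(x, series(np.zeros(50)))) == list(x)

    def test_equals_elementwise_disjunction(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            a = (rng.random(20) < 0.5).astype(float)
            b = (rng.random(20) < 0.5).astype(float)
            out = combine_or(series(a), series(b))
            assert np.array_equal(out.to_numpy(), np.logical_or(a, b).astype(float))

    def test_commutative_associative_idempotent(self):
        rng = np.random.default_rng(3)
        a = series((rng.random(30) < 0.5).astype(float))
        b = series((rng.random(30) < 0.5).astype(float))
        c = series((rng.random(30) < 0.5).astype(float))
        assert combine_or(a, b).equals(combine_or(b, a))
        assert combine_or(combine_or(a, b), c).equals(combine_or(a, combine_or(b, c)))
        assert combine_or(a, a).equals(a.astype(float))

    def test_missing_call_excluded(self):
        a = series([1.0, np.nan, 0.0])
        b = series([0.0, 1.0, 0.0])
        out = combine_or(a, b)
        assert np.isnan(out.iloc[1])

    def test_disjoint_samples_error(self):
        with pytest.raises(PairingError):
            combine_or(series([1.0], ids=["A"]), series([1.0], ids=["B"]))


class TestConfusion:
    def test_perfect_classification(self):
        calls = series([1, 1, 1, 0, 0])
        outcomes = pd.Series([True, True, True, False, False], index=calls.index)
        c = confusion(calls, outcomes)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 0, 0, 2)

    def test_all_true_calls(self):
        calls = series(np.ones(7))
        outcomes = pd.Series([True] * 4 + [False] * 3, index=calls.index)
        c = confusion(calls, outcomes)
        assert c.tn == 0 and c.fp == 3 and c.tp == 4

    def test_random_fixture_matches_hand_tally(self):
        rng = np.random.default_rng(4)
        calls_arr = (rng.random(40) < 0.5).astype(float)
        outcomes_arr = rng.random(40) < 0.5
        calls = series(calls_arr)
        outcomes = pd.Series(outcomes_arr, index=calls.index)
        c = confusion(calls, outcomes)
        assert c.tp == int(((calls_arr > 0) & outcomes_arr).sum())
        assert c.fp == int(((calls_arr > 0) & ~outcomes_arr).sum())
        assert c.fn == int(((calls_arr == 0) & outcomes_arr).sum())
        assert c.tn == int(((calls_arr == 0) & ~outcomes_arr).sum())
        assert c.total == 40


def enumerate_confusions(true_count: int, n: int):
    """All nonnegative 2x2 tables with tp+tn = true_count and total n."""
    for tn in range(true_count + 1):
        tp = true_count - tn
        for fp in range(n - true_count + 1):
            fn = n - true_count - fp
            yield ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


class TestF1:
    @pytest.mark.parametrize(
        "true_count, printed",
        [(14, 0.848), (15, 0.882), (16, 0.914), (16, 0.889), (13, 0.813)],
    )
    def test_printed_f1_values_recovered_by_enumeration(self, true_count, printed):
        """Each printed correct/19 + F1 row pins a unique true-negative count."""
        matches = {
            (c.tp, c.tn)
            for c in enumerate_confusions(true_count, 19)
            if c.tp + c.fn > 0 and round_half_up(f1_score(c), 3) == printed
        }
        tn_values = {tn for _, tn in matches}
        assert len(tn_values) == 1
        tp, tn = next(iter(matches))
        # F1 depends only on tp and fp+fn, so any split of the errors
        # reproduces the printed value
        conf = ConfusionCounts(tp=tp, fp=19 - true_count, fn=0, tn=tn)
        assert round_half_up(f1_score(conf), 3) == printed

    def test_perfect(self):
        assert f1_score(ConfusionCounts(tp=10, fp=0, fn=0, tn=5)) == 1.0

    def test_undefined(self):
        with pytest.raises(UndefinedTestError):
            f1_score(ConfusionCounts(tp=0, fp=0, fn=0, tn=5))

    def test_bounds_and_perfection_condition(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 10, 4)
            if tp + fp + fn == 0:
                continue
            c = ConfusionCounts(int(tp), int(fp), int(fn), int(tn))
            f1 = f1_score(c)
            assert 0.0 <= f1 <= 1.0
            assert (f1 == 1.0) == (fp == 0 and fn == 0 and tp > 0)

    def test_half_up_rounding(self):
        assert round_half_up(0.8125, 3) == 0.813  # 13/19 row needs half-up
        assert round_half_up(0.84848, 3) == 0.848


class TestMantelHaenszel:
    def test_single_stratum_equals_yates(self):
        rng = np.random.default_rng(6)
        for _ in range(300):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 15, 4))
            c = ConfusionCounts(tp, fp, fn, tn)
            chi2, p = mh_chi_square([c])
            ref = chi2_contingency([[tp, fp], [fn, tn]], correction=True)
            assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_reference_example(self):
        chi2, p = mh_chi_square([ConfusionCounts(tp=10, fp=2, fn=1, tn=10)])
        ref = chi2_contingency([[10, 2], [1, 10]], correction=True)
        assert chi2 == pytest.approx(ref.statistic, abs=1e-12)
        assert p < 0.01

    def test_two_strata_vs_statsmodels_variance_convention(self):
        """Cochran variance differs from the hypergeometric one by (n-1)/n."""
        strata = [
            ConfusionCounts(tp=8, fp=3, fn=2, tn=7),
            ConfusionCounts(tp=6, fp=4, fn=3, tn=7),
        ]
        chi2, _ = mh_chi_square(strata)
        tables = [np.array([[s.tp, s.fp], [s.fn, s.tn]]) for s in strata]
        ref = StratifiedTable(tables).test_null_odds(correction=True)
        n = strata[0].total  # both strata have n = 20
        # hypergeometric variance = Cochran variance * n/(n-1) per stratum
        assert chi2 == pytest.approx(ref.statistic * n / (n - 1), rel=1e-9)

    def test_zero_margin_stratum_skipped(self):
        good = ConfusionCounts(tp=8, fp=1, fn=2, tn=9)
        degenerate = ConfusionCounts(tp=5, fp=5, fn=0, tn=0)  # no called-false row
        chi2_with, _ = mh_chi_square([good, degenerate])
        chi2_alone, _ = mh_chi_square([good])
        assert chi2_with == chi2_alone

    def test_all_degenerate_error(self):
        with pytest.raises(UndefinedTestError):
            mh_chi_square([ConfusionCounts(tp=5, fp=5, fn=0, tn=0)])

    def test_null_rejection_rate_not_inflated(self):
        """Independent calls/outcomes: rejection at 0.05 stays at or below nominal
        (the continuity correction makes the test conservative at small n)."""
        rng = np.random.default_rng(7)
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            strata = []
            for _ in range(2):
                calls = rng.random(20) < 0.5
                preg = rng.random(20) < 0.5
                strata.append(
                    ConfusionCounts(
                        tp=int((calls & preg).sum()),
                        fp=int((calls & ~preg).sum()),
                        fn=int((~calls & preg).sum()),
                        tn=int((~calls & ~preg).sum()),
                    )
                )
            try:
                _, p = mh_chi_square(strata)
            except UndefinedTestError:
                continue
            hits += p < 0.05
        assert hits / n_sim <= 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_sim)


class TestNdRule:
    def test_pair_at_least_as_good(self):
        assert nd_rule(14, (13, 12)) is False

    def test_pair_worse_than_one_single(self):
        assert nd_rule(12, (13, 12)) is True

    def test_boundary_equal_is_determined(self):
        assert nd_rule(13, (13, 12)) is False


class TestScorePair:
    @staticmethod
    def _fixture_perfect():
        ids = [f"S{i:02d}" for i in range(20)]
        preg = pd.Series([True] * 10 + [False] * 10, index=ids)
        cm = pd.Series(list(np.linspace(10, 11, 10)) + list(np.linspace(30, 40, 10)), index=ids)
        pl = pd.Series(list(np.linspace(5, 6, 10)) + list(np.linspace(50, 60, 10)), index=ids)
        return cm, pl, preg

    def test_perfect_pair(self):
        cm, pl, preg = self._fixture_perfect()
        res = score_pair(cm, pl, preg, mode=AGGREGATE)
        assert res.f1 == 1.0
        assert res.p < 0.001
        assert not res.nd
        assert res.true_count == 20

    def test_wide_null_ranges_hit_all_true_baseline(self):
        ids = [f"S{i:02d}" for i in range(12)]
        preg = pd.Series([True] * 7 + [False] * 5, index=ids)
        # pregnant values span the full observed range -> every call true
        cm = pd.Series([1, 100, 50, 60, 70, 80, 90, 20, 30, 40, 55, 65], index=ids, dtype=float)
        pl = pd.Series([2, 90, 40, 50, 60, 70, 80, 10, 20, 30, 45, 55], index=ids, dtype=float)
        res = score_pair(cm, pl, preg, mode=AGGREGATE)
        n_preg, n_open = 7, 5
        assert res.f1 == pytest.approx(2 * n_preg / (2 * n_preg + n_open))
        assert res.confusion.tn == 0

    def test_stratified_beats_aggregate_on_stage_dependent_ranges(self):
        """When the pregnant range shifts with Day-6 stage, per-stage ranges
        recover the separation that pooling destroys."""
        ids = [f"S{i:02d}" for i in range(24)]
        stage = pd.Series(["morula"] * 12 + ["early_blastocyst"] * 12, index=ids)
        preg = pd.Series(([True] * 6 + [False] * 6) * 2, index=ids)
        # morulae: pregnant low / open high; blastocysts: reversed
        cm_vals = [10, 11, 12, 10.5, 11.5, 12.5, 30, 31, 32, 30.5, 31.5, 32.5]
        cm_vals += [30, 31, 32, 30.5, 31.5, 32.5, 10, 11, 12, 10.5, 11.5, 12.5]
        cm = pd.Series(cm_vals, index=ids, dtype=float)
        pl = cm * 2.0
        agg = score_pair(cm, pl, preg, stages=stage, mode=AGGREGATE)
        strat = score_pair(cm, pl, preg, stages=stage, mode=STRATIFIED)
        assert strat.true_count > agg.true_count
        assert strat.f1 > agg.f1
        assert sum(s.total for s in strat.per_stratum) == strat.confusion.total

    def test_pooled_confusion_is_sum_of_strata(self):
        rng = np.random.default_rng(11)
        ids = [f"S{i:02d}" for i in range(30)]
        stage = pd.Series(rng.choice(["morula", "early_blastocyst"], 30), index=ids)
        preg = pd.Series(rng.random(30) < 0.55, index=ids)
        # ensure enough pregnant per stratum
        preg.iloc[:4] = True
        preg.iloc[-4:] = True
        stage.iloc[:2] = "morula"
        stage.iloc[2:4] = "early_blastocyst"
        stage.iloc[-2:] = "morula"
        stage.iloc[-4:-2] = "early_blastocyst"
        cm = pd.Series(rng.lognormal(3, 0.5, 30), index=ids)
        pl = pd.Series(rng.lognormal(3, 0.5, 30), index=ids)
        res = score_pair(cm, pl, preg, stages=stage, mode=STRATIFIED)
        pooled = res.per_stratum[0]
        for s in res.per_stratum[1:]:
            pooled = pooled + s
        assert (pooled.tp, pooled.fp, pooled.fn, pooled.tn) == (
            res.confusion.tp,
            res.confusion.fp,
            res.confusion.fn,
            res.confusion.tn,
        )

    def test_widening_range_monotone_in_n_true(self):
        rng = np.random.default_rng(12)
        vals = series(rng.normal(0, 1, 50))
        narrow = boolean_calls(vals, (-0.5, 0.5)).n_true
        wide = boolean_calls(vals, (-1.0, 1.0)).n_true
        assert wide >= narrow

    def test_nd_flag_from_solo_counts(self):
        cm, pl, preg = self._fixture_perfect()
        # degrade plasma into a near-all-true caller: opens inside pregnant range
        pl_bad = pl.copy()
        pl_bad.iloc[10:] = 5.5
        res = score_pair(cm, pl_bad, preg, mode=AGGREGATE)
        assert res.true_count < max(res.single_true_counts)
        assert res.nd


class TestScoreAllPairs:
    def _matrices(self, seed=13):
        from embryomet.datatypes import MetaboliteMatrix

        rng = np.random.default_rng(seed)
        ids = [f"S{i:02d}" for i in range(20)]
        cm = MetaboliteMatrix(
            compartment="CM",
            data=pd.DataFrame(
                rng.lognormal(3, 0.5, (20, 2)), index=ids, columns=["CM_A", "CM_B"]
            ),
        )
        pl_data = pd.DataFrame(
            rng.lognormal(3, 0.5, (20, 3)), index=ids, columns=["PL_A", "PL_B", "PL_C"]
        )
        d0 = MetaboliteMatrix(compartment="plasma_d0", data=pl_data)
        d7 = MetaboliteMatrix(compartment="plasma_d7", data=pl_data * 1.1)
        preg = pd.Series([True] * 11 + [False] * 9, index=ids)
        return cm, {"d0": d0, "d7": d7}, preg

    def test_pair_count_is_cartesian_product(self):
        cm, plasma, preg = self._matrices()
        results = score_all_pairs(cm, plasma, preg)
        assert len(results) == 2 * 3 * 2

    def test_sorted_by_f1_then_p(self):
        cm, plasma, preg = self._matrices()
        results = score_all_pairs(cm, plasma, preg)
        keys = [(-r.f1, r.p) for r in results]
        assert keys == sorted(keys)

    def test_candidate_restriction(self):
        cm, plasma, preg = self._matrices()
        results = score_all_pairs(
            cm,
            plasma,
            preg,
            cm_candidates=["CM_A"],
            plasma_candidates={"d0": ["PL_B"], "d7": []},
        )
        assert len(results) == 1
        assert results[0].cm_metabolite == "CM_A"
        assert results[0].plasma_metabolite == "PL_B"
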
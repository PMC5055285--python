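"""Unit and property tests for the categorical verification statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from oracles import (
    oracle_false_alarm_ratio,
    oracle_gerrity,
    oracle_heidke,
    oracle_hit_rate,
    oracle_peirce,
    table_to_events,
)

from musselskill import (
    CategoryScheme,
    ContingencyTable,
    GerrityUndefinedError,
    build_table,
    error_summaries,
    false_alarm_ratio,
    gerrity,
    gerrity_matrix,
    heidke,
    hit_rate,
    interlogger_baseline,
    peirce,
    skill_report,
)

HAND_TABLE = ContingencyTable(np.array([[3, 1, 0], [1, 4, 1], [0, 1, 3]]))


def _pairs(forecast, observed):
    n = len(forecast)
    return pd.DataFrame(
        {
            "date": pd.date_range("2007-07-01", periods=n).date,
            "forecast_max": forecast,
            "observed_max": observed,
        }
    )


class TestCategorize:
    @pytest.mark.parametrize(
        "temp, expected",
        [
            (-1.0, 0),  # below freezing -> low lethal
            (0.0, 1),  # lower-inclusive bound
            (9.99, 1),
            (10.0, 2),
            (17.0, 3),
            (18.0, 3),  # optimal range 17-22
            (22.0, 4),
            (32.0, 5),
            (38.0, 6),
            (38.2, 6),  # the median lethal temperature sits in high lethal
        ],
    )
    def test_examples(self, temp, expected):
        assert CategoryScheme().categorize(temp) == expected

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            CategoryScheme().categorize(float("nan"))

    def test_vectorized_matches_scalar(self):
        scheme = CategoryScheme()
        temps = np.linspace(-5, 45, 101)
        vec = scheme.categorize(temps)
        assert list(vec) == [scheme.categorize(float(t)) for t in temps]

    def test_bounds_must_increase(self):
        with pytest.raises(ValueError):
            CategoryScheme(labels=("a", "b", "c"), bounds=(10.0, 5.0))


class TestBuildTable:
    def test_empty_pairs(self):
        table = build_table(_pairs([], []), CategoryScheme())
        assert table.n == 0
        assert table.counts.shape == (7, 7)
        assert not table.counts.any()

    def test_single_category(self):
        table = build_table(_pairs([18.0] * 5, [19.0] * 5), CategoryScheme())
        assert table.counts[3, 3] == 5
        assert table.n == 5

    def test_hand_pairs_against_direct_count(self):
        scheme = CategoryScheme()
        f = [5.0, 15.0, 18.0, 25.0, 39.0]
        o = [12.0, 15.0, 20.0, 24.0, 35.0]
        table = build_table(_pairs(f, o), scheme)
        expected = np.zeros((7, 7), dtype=int)
        for fv, ov in zip(f, o):
            expected[scheme.categorize(fv), scheme.categorize(ov)] += 1
        assert (table.counts == expected).all()
        assert (table.counts == np.array(expected)).all()

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            ContingencyTable(np.array([[1, -1], [0, 2]]))


class TestHitRateFalseAlarm:
    def test_hand_table(self):
        assert hit_rate(HAND_TABLE, 1) == pytest.approx(4 / 6)
        assert false_alarm_ratio(HAND_TABLE, 1) == pytest.approx(2 / 6)

    def test_perfect_diagonal(self):
        table = ContingencyTable(np.diag([4, 6, 4]))
        for i in range(3):
            assert hit_rate(table, i) == 1.0
            assert false_alarm_ratio(table, i) == 0.0

    def test_undefined_are_nan_not_zero(self):
        table = ContingencyTable(np.array([[2, 0, 0], [1, 0, 0], [0, 0, 0]]))
        assert math.isnan(hit_rate(table, 1))  # never observed
        assert math.isnan(false_alarm_ratio(table, 2))  # never forecast


class TestHeidkePeirce:
    def test_hand_table(self):
        # Marginals coincide, so both scores equal 72/128.
        assert heidke(HAND_TABLE) == pytest.approx(0.5625, abs=1e-12)
        assert peirce(HAND_TABLE) == pytest.approx(0.5625, abs=1e-12)

    def test_perfect_forecast_scores_one(self):
        table = ContingencyTable(np.diag([2, 5, 1, 9]))
        assert heidke(table) == 1.0
        assert peirce(table) == 1.0

    def test_independence_scores_zero(self):
        # counts = outer(u, v) is an exact-independence table.
        u, v = np.array([1, 2, 1]), np.array([2, 4, 2])
        table = ContingencyTable(np.outer(u, v))
        assert heidke(table) == 0.0
        assert peirce(table) == 0.0

    def test_two_category_peirce_identity(self):
        # For k = 2 the Peirce score is hit rate minus false-alarm *rate*.
        counts = np.array([[13, 4], [3, 10]])
        table = ContingencyTable(counts)
        hits, misses = counts[0, 0], counts[1, 0]
        false_alarms, correct_neg = counts[0, 1], counts[1, 1]
        direct = hits / (hits + misses) - false_alarms / (false_alarms + correct_neg)
        assert peirce(table) == pytest.approx(direct, abs=1e-12)

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            heidke(ContingencyTable(np.zeros((3, 3), dtype=int)))


class TestGerrity:
    def test_hand_matrix(self):
        gm = gerrity_matrix(ContingencyTable(np.diag([4, 6, 4])))
        assert gm.a == pytest.approx([2.5, 0.4])
        assert np.diag(gm.s) == pytest.approx([1.45, 0.4, 1.45])
        assert gm.s[0, 1] == pytest.approx(-0.3)
        assert gm.s[0, 2] == pytest.approx(-1.0)
        assert gm.s[1, 2] == pytest.approx(-0.3)

    def test_hand_table_score(self):
        assert gerrity(HAND_TABLE) == pytest.approx(0.65, abs=1e-12)

    def test_perfect_forecast_scores_one(self):
        assert gerrity(ContingencyTable(np.diag([4, 6, 4]))) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_two_categories(self):
        gm = gerrity_matrix(ContingencyTable(np.array([[3, 3], [3, 3]])))
        assert gm.a == pytest.approx([1.0])
        assert gm.s == pytest.approx(np.array([[1.0, -1.0], [-1.0, 1.0]]))

    def test_constant_forecast_scores_zero(self):
        # All forecasts in one category; columns carry the observed marginal.
        counts = np.zeros((3, 3), dtype=int)
        counts[1] = [4, 6, 4]
        assert gerrity(ContingencyTable(counts)) == pytest.approx(0.0, abs=1e-12)

    def test_empty_observed_category_raises(self):
        counts = np.array([[0, 1, 0], [0, 5, 1], [0, 2, 3]])  # category 0 never observed
        with pytest.raises(GerrityUndefinedError, match="collaps"):
            gerrity(ContingencyTable(counts))

    def test_equitability_and_symmetry_random(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(2, 8))
            counts = rng.integers(0, 6, size=(k, k)) + np.eye(k, dtype=int)
            gm = gerrity_matrix(ContingencyTable(counts))
            assert np.allclose(gm.s, gm.s.T)
            assert np.allclose(gm.s @ gm.p, 0.0, atol=1e-12)


class TestOracleAgreement:
    def test_all_scores_match_bruteforce(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            k = int(rng.integers(2, 8))
            counts = rng.integers(0, 5, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            table = ContingencyTable(counts)
            events = table_to_events(counts)
            for i in range(k):
                for ours, theirs in (
                    (hit_rate(table, i), oracle_hit_rate(events, i)),
                    (false_alarm_ratio(table, i), oracle_false_alarm_ratio(events, i)),
                ):
                    if math.isnan(theirs):
                        assert math.isnan(ours)
                    else:
                        assert ours == pytest.approx(theirs, abs=1e-12)
            for ours, theirs in (
                (heidke(table), oracle_heidke(events, k)),
                (peirce(table), oracle_peirce(events, k)),
            ):
                if math.isnan(theirs):
                    assert math.isnan(ours)
                else:
                    assert ours == pytest.approx(theirs, abs=1e-12)
            if (counts.sum(axis=0) > 0).all():
                assert gerrity(table) == pytest.approx(oracle_gerrity(events, k), abs=1e-12)

    def test_scores_bounded_random(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            k = int(rng.integers(2, 8))
            counts = rng.integers(0, 9, size=(k, k)) + np.eye(k, dtype=int)
            table = ContingencyTable(counts)
            for score in (heidke(table), peirce(table), gerrity(table)):
                assert -1.0 - 1e-12 <= score <= 1.0 + 1e-12

    def test_heidke_equals_peirce_for_matching_marginals(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            k = int(rng.integers(2, 6))
            half = rng.integers(0, 5, size=(k, k))
            counts = half + half.T  # symmetric => forecast marginal == observed marginal
            if counts.sum() == 0:
                counts[0, 0] = 2
            table = ContingencyTable(counts)
            h, p = heidke(table), peirce(table)
            if math.isnan(h):
                assert math.isnan(p)
            else:
                assert h == pytest.approx(p, abs=1e-12)


class TestErrorSummaries:
    @pytest.mark.parametrize(
        "diffs, expected",
        [
            ([0.0, 0.0, 0.0], (0.0, 0.0, 0.0)),
            ([1.0, -1.0], (0.0, 1.0, 1.0)),
            ([-2.0, -4.0], (-3.0, 3.0, math.sqrt(10.0))),
        ],
    )
    def test_hand_values(self, diffs, expected):
        observed = [20.0] * len(diffs)
        forecast = [o + d for o, d in zip(observed, diffs)]
        bias, mae, rmse = error_summaries(_pairs(forecast, observed))
        assert (bias, mae, rmse) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            error_summaries(_pairs([], []))


class TestInterloggerBaseline:
    scheme = CategoryScheme(labels=("cold", "mid", "hot"), bounds=(10.0, 20.0))

    def _loggers(self, offset=0.0):
        # Daily maxima cycle through all three categories so every score is defined.
        idx = pd.date_range("2007-07-01", periods=240, freq="1h")
        day_levels = np.repeat([8.0, 15.0, 25.0] * 4, 24)[:240]
        ramp = 0.01 * (np.arange(240) % 24)
        base = pd.Series(day_levels + ramp, index=idx)
        return {"a": base, "b": base + offset}, pd.Series(True, index=idx)

    def test_identical_loggers_are_perfect(self):
        loggers, mask = self._loggers()
        out = interlogger_baseline(loggers, mask, self.scheme).set_index(
            ["forecast_id", "observed_id"]
        )
        for _, row in out.iterrows():
            assert row["bias"] == 0.0 and row["mae"] == 0.0 and row["rmse"] == 0.0
            assert row["heidke"] == 1.0 and row["peirce"] == 1.0
            assert row["gerrity"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_shift_and_antisymmetry(self):
        loggers, mask = self._loggers(offset=2.0)
        out = interlogger_baseline(loggers, mask, self.scheme).set_index(
            ["forecast_id", "observed_id"]
        )
        assert out.loc[("b", "a"), "bias"] == pytest.approx(2.0)
        assert out.loc[("b", "a"), "mae"] == pytest.approx(2.0)
        assert out.loc[("b", "a"), "rmse"] == pytest.approx(2.0)
        assert out.loc[("a", "b"), "bias"] == pytest.approx(-out.loc[("b", "a"), "bias"])

    def test_requires_two_loggers(self):
        loggers, mask = self._loggers()
        with pytest.raises(ValueError):
            interlogger_baseline({"a": loggers["a"]}, mask, self.scheme)


def test_skill_report_carries_undefined_gerrity_as_nan():
    # Summer-like daily maxima never reach the coldest categories, which
    # leaves the Gerrity odds ratios undefined; the report shows NA, not 0.
    pairs = _pairs([18.0, 25.0, 30.0], [19.0, 24.0, 33.0])
    report = skill_report(pairs, CategoryScheme())
    assert math.isnan(report.gerrity)
    assert not math.isnan(report.heidke)
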
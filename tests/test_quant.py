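import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from circpanel.quant import (
    QuantError,
    clr,
    compare_conditions,
    delta_delta_ct,
    flag_low_expression,
    pearson_correlation,
    qpcr_fold_changes,
    quantify,
    rpm,
)

counts_st = st.integers(min_value=0, max_value=10**6)


class TestRpm:
    def test_formula(self):
        assert rpm(10, 1_000_000) == pytest.approx(10.0)
        assert rpm(0, 1234) == 0.0

    def test_conservation(self):
        raw = [120, 30, 850]
        total = sum(raw)
        assert sum(rpm(r, total) for r in raw) == pytest.approx(1e6)

    def test_zero_denominator_rejected(self):
        with pytest.raises(QuantError):
            rpm(1, 0)

    def test_raw_above_total_rejected(self):
        with pytest.raises(QuantError):
            rpm(11, 10)


class TestClr:
    def test_examples(self):
        assert clr(5, 15) == pytest.approx(0.25)
        assert clr(7, 0) == 1.0
        assert clr(0, 0) is None

    def test_negative_rejected(self):
        with pytest.raises(QuantError):
            clr(-1, 5)

    @settings(max_examples=50, derandomize=True)
    @given(counts_st, counts_st, st.integers(min_value=1, max_value=1000))
    def test_scale_invariance(self, a, b, k):
        if a + b == 0:
            assert clr(a * k, b * k) is None
        else:
            assert clr(a * k, b * k) == pytest.approx(clr(a, b))

    @settings(max_examples=50, derandomize=True)
    @given(counts_st, counts_st)
    def test_bounded_and_monotone(self, a, b):
        v = clr(a, b)
        if v is not None:
            assert 0.0 <= v <= 1.0
            assert clr(a + 1, b) > v or b == 0


class TestLowExpression:
    def test_threshold_boundary(self):
        assert flag_low_expression(2, 3, 10) is True
        assert flag_low_expression(50, 50, 10) is False
        # boundary: 2+3 = 5 is not < 5, so the flag clears exactly at threshold 5
        assert flag_low_expression(2, 3, 5) is False
        assert flag_low_expression(2, 2, 5) is True


class TestQuantify:
    def _counts(self):
        return pd.DataFrame(
            {
                "target_id": ["a", "b", "c"],
                "sample_id": ["s1"] * 3,
                "n_chimeric": [5, 0, 0],
                "n_linear": [15, 0, 40],
                "n_non_junction": [10, 0, 20],
            }
        )

    def test_clr_and_flags(self):
        q = quantify(self._counts(), min_junction_reads=10)
        q = q.set_index("target_id")
        assert q.loc["a", "clr"] == pytest.approx(0.25)
        assert not q.loc["b", "clr_defined"] and math.isnan(q.loc["b", "clr"])
        assert q.loc["b", "low_expression"]
        assert not q.loc["a", "low_expression"]

    def test_rpm_denominator_recorded(self):
        q = quantify(self._counts(), total_unique=90)
        assert (q["rpm_denominator"] == 90).all()
        assert q.set_index("target_id").loc["c", "rpm_linear"] == pytest.approx(
            40 / 90 * 1e6
        )

    def test_include_non_junction_switch(self):
        q = quantify(self._counts(), include_non_junction=True).set_index("target_id")
        assert q.loc["a", "clr"] == pytest.approx(5 / 30)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula_on_fixture(self):
        x = np.array([2.0, 4.0, 4.0, 5.0, 7.0, 8.0, 9.0, 11.0, 12.0, 14.0])
        y = np.array([1.0, 3.0, 2.0, 6.0, 4.0, 9.0, 8.0, 10.0, 13.0, 15.0])
        n = len(x)
        r_hand = (n * (x * y).sum() - x.sum() * y.sum()) / math.sqrt(
            (n * (x**2).sum() - x.sum() ** 2) * (n * (y**2).sum() - y.sum() ** 2)
        )
        r, p = pearson_correlation(x, y)
        assert r == pytest.approx(r_hand, abs=1e-12)
        assert 0 <= p <= 1

    def test_exclusion_list(self):
        labels = ["t1", "t2", "outlier"]
        x = [1.0, 2.0, 100.0]
        y = [1.1, 2.2, -50.0]
        with pytest.raises(QuantError):  # only 2 points remain
            pearson_correlation(x, y, exclude=["outlier"], labels=labels)
        x, y = [1, 2, 3, 100], [1.1, 2.2, 2.9, -50]
        r_excl, _ = pearson_correlation(x, y, exclude=["out"],
                                        labels=["a", "b", "c", "out"])
        assert r_excl > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(QuantError, match="zero variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCompareConditions:
    def _quant(self, clr_by_sample):
        rows = []
        for sid, values in clr_by_sample.items():
            for tid, v in values.items():
                rows.append(
                    {
                        "target_id": tid, "sample_id": sid,
                        "n_chimeric": 50, "n_linear": 50,
                        "n_non_junction": 0, "rpm_chimeric": 100.0,
                        "rpm_linear": 100.0, "clr": v, "clr_defined": True,
                        "low_expression": False, "rpm_denominator": 1000,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_counts_zero_delta(self):
        q = self._quant({"s1": {"a": 0.4, "b": 0.6}, "s2": {"a": 0.4, "b": 0.6}})
        table = compare_conditions(q, {"s1": "ctl", "s2": "dis"},
                                   reference_condition="ctl")
        assert (table["clr_delta_dis_vs_ctl"].abs() < 1e-12).all()

    def test_low_expression_marks_excluded(self):
        q = self._quant({"s1": {"a": 0.4}, "s2": {"a": 0.5}})
        q.loc[q["sample_id"] == "s2", "low_expression"] = True
        table = compare_conditions(q, {"s1": "ctl", "s2": "dis"})
        assert table["excluded_low_expression"].all()

    def test_true_clr_shift_has_largest_delta(self, heart_refs):
        """Simulator ground truth: the target whose true CLR differs by 0.3
        between conditions shows the largest |CLR delta|."""
        from circpanel.classify import classify_reads
        from circpanel.simulate import SimConfig, simulate

        tids = [r.target_id for r in heart_refs[:3]]
        abund = {
            "ctl": {tids[0]: 0.5, tids[1]: 0.5, tids[2]: 0.5},
            "dis": {tids[0]: 0.8, tids[1]: 0.5, tids[2]: 0.5},
        }
        quants = []
        for i, cond_name in enumerate(("ctl", "dis")):
            cfg = SimConfig(
                true_circ={t: abund[cond_name][t] for t in tids},
                true_lin={t: 1 - abund[cond_name][t] for t in tids},
                n_reads=6000, seed=100 + i,
            )
            records, _ = simulate(heart_refs, cfg)
            res = classify_reads(records, heart_refs, keep_reads=False)
            q = quantify(res.counts,
                         total_unique=res.label_totals["uniquely_assigned"])
            q["sample_id"] = cond_name
            quants.append(q)
        table = compare_conditions(
            pd.concat(quants, ignore_index=True), {"ctl": "ctl", "dis": "dis"},
            reference_condition="ctl",
        )
        table = table[table["target_id"].isin(tids)]
        deltas = table.set_index("target_id")["clr_delta_dis_vs_ctl"].abs()
        assert deltas.idxmax() == tids[0]
        assert deltas[tids[0]] == pytest.approx(0.3, abs=0.06)

    def test_unknown_sample_rejected(self):
        q = self._quant({"s1": {"a": 0.4}})
        with pytest.raises(QuantError, match="without condition"):
            compare_conditions(q, {"other": "ctl"})


class TestDeltaDeltaCt:
    @pytest.mark.parametrize(
        "cts,expected",
        [
            ((20, 15, 20, 15), 1.0),   # all deltas equal
            ((21, 15, 20, 15), 0.5),   # ddCt = +1
            ((18, 15, 20, 15), 4.0),   # ddCt = -2
        ],
    )
    def test_fold_change(self, cts, expected):
        assert delta_delta_ct(*cts) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(QuantError):
            delta_delta_ct(float("nan"), 15, 20, 15)

    def test_table_normalized_to_control_mean(self):
        table = pd.DataFrame(
            {
                "sample": ["c1", "c2", "t1"],
                "condition": ["ctl", "ctl", "kd"],
                "target": ["g"] * 3,
                "ct_target": [20.0, 21.0, 23.0],
                "ct_reference": [15.0, 15.0, 15.0],
            }
        )
        out = qpcr_fold_changes(table, reference_condition="ctl")
        kd = out[out["sample"] == "t1"]["fold_change"].iloc[0]
        # control mean dCt = 5.5; treated dCt = 8 -> ddCt = 2.5
        assert kd == pytest.approx(2 ** -2.5)
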
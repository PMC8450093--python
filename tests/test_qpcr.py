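import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from risipipe.qpcr import (
    QpcrError,
    fold_change_vs_control,
    locus_ratio_vs_reference,
    percent_input,
    percent_input_table,
    relative_expression,
    summarize,
    t_test_two_tailed,
    treatment_ratio,
)
from risipipe.simulate import QpcrDesign, simulate_qpcr

finite_ct = st.floats(5.0, 40.0, allow_nan=False)


class TestPercentInput:
    def test_identity_case_is_100_percent(self):
        ct_ip = 20 - math.log2(100)
        assert percent_input(ct_ip, 20.0, 0.01) == pytest.approx(100.0)

    def test_one_cycle_later_is_50_percent(self):
        ct_ip = 20 - math.log2(100) + 1
        assert percent_input(ct_ip, 20.0, 0.01) == pytest.approx(50.0)

    @given(finite_ct, finite_ct, st.floats(1e-4, 0.5))
    @settings(max_examples=200, deadline=None)
    def test_arithmetic_oracle(self, ct_ip, ct_input, frac):
        expected = 100.0 * 2.0 ** (ct_input - math.log2(1.0 / frac) - ct_ip)
        got = percent_input(ct_ip, ct_input, frac)
        assert got == pytest.approx(expected, rel=1e-9)

    @given(finite_ct, st.floats(0.1, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_decreasing_in_ct_ip(self, ct_ip, delta):
        assert percent_input(ct_ip + delta, 20.0, 0.01) < percent_input(ct_ip, 20.0, 0.01)

    def test_doubling_per_cycle(self):
        assert percent_input(14.0, 20.0, 0.01) == pytest.approx(
            2 * percent_input(15.0, 20.0, 0.01)
        )

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.1, 2.0])
    def test_fraction_bounds(self, frac):
        with pytest.raises(QpcrError):
            percent_input(15.0, 20.0, frac)

    def test_non_finite_ct_rejected(self):
        with pytest.raises(QpcrError):
            percent_input(float("nan"), 20.0, 0.01)


class TestFoldChange:
    def test_equal_enrichments(self):
        assert fold_change_vs_control(0.8, 0.8) == pytest.approx(1.0)

    def test_half(self):
        assert fold_change_vs_control(0.4, 0.8) == pytest.approx(0.5)

    @given(st.floats(1e-6, 1e6), st.floats(1e-6, 1e6))
    @settings(max_examples=200, deadline=None)
    def test_reciprocal_property(self, a, b):
        assert fold_change_vs_control(a, b) * fold_change_vs_control(b, a) == pytest.approx(1.0)

    def test_zero_control_rejected(self):
        with pytest.raises(QpcrError):
            fold_change_vs_control(1.0, 0.0)


class TestLocusRatio:
    def test_all_equal_gives_one(self):
        r_plus = locus_ratio_vs_reference(2.0, 2.0)
        r_minus = locus_ratio_vs_reference(2.0, 2.0)
        assert treatment_ratio(r_plus, r_minus) == pytest.approx(1.0)

    def test_doubled_signal_gives_two(self):
        r_plus = locus_ratio_vs_reference(4.0, 2.0)
        r_minus = locus_ratio_vs_reference(2.0, 2.0)
        assert treatment_ratio(r_plus, r_minus) == pytest.approx(2.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(QpcrError):
            locus_ratio_vs_reference(1.0, 0.0)
        with pytest.raises(QpcrError):
            treatment_ratio(1.0, 0.0)

    @pytest.mark.parametrize("true_ratio", [0.25, 1.0, 3.5])
    def test_closed_form_round_trip_through_simulator(self, true_ratio):
        # +dsRNA locus enrichment scaled by true_ratio; eft-3 unchanged
        design = QpcrDesign(
            enrichments={
                ("wt", "plus_dsRNA", "18S"): 0.2 * true_ratio,
                ("wt", "plus_dsRNA", "eft-3"): 0.05,
                ("wt", "minus_dsRNA", "18S"): 0.2,
                ("wt", "minus_dsRNA", "eft-3"): 0.05,
            },
            ct_noise_sd=0.0,
            replicates=2,
            seed=0,
        )
        pct = percent_input_table(simulate_qpcr(design))
        g = pct.groupby(["treatment", "locus"])["percent_input"].mean()
        r_plus = locus_ratio_vs_reference(g["plus_dsRNA", "18S"], g["plus_dsRNA", "eft-3"])
        r_minus = locus_ratio_vs_reference(g["minus_dsRNA", "18S"], g["minus_dsRNA", "eft-3"])
        assert treatment_ratio(r_plus, r_minus) == pytest.approx(true_ratio)


class TestRelativeExpression:
    def test_all_equal_is_one(self):
        assert relative_expression(20, 20, 20, 20) == pytest.approx(1.0)

    def test_one_cycle_earlier_is_two(self):
        assert relative_expression(19, 20, 20, 20) == pytest.approx(2.0)

    @given(finite_ct, finite_ct, finite_ct, finite_ct)
    @settings(max_examples=200, deadline=None)
    def test_arithmetic_oracle(self, a, b, c, d):
        expected = 2.0 ** (-((a - b) - (c - d)))
        assert relative_expression(a, b, c, d) == pytest.approx(expected, rel=1e-9)


def permutation_p_value(a, b):
    """Exact two-sided permutation test on the difference of means."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = abs(np.mean(a) - np.mean(b))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        diff = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += diff >= observed - 1e-12
        total += 1
    return count / total


class TestTTest:
    def test_identical_groups(self):
        t, p = t_test_two_tailed([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_swap_symmetry(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 5.0]
        t1, p1 = t_test_two_tailed(a, b)
        t2, p2 = t_test_two_tailed(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(QpcrError, match="zero pooled variance"):
            t_test_two_tailed([1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(QpcrError):
            t_test_two_tailed([1.0], [1.0, 2.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_permutation_oracle_on_normal_data(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, size=8)
        b = rng.normal(0.7, 1.0, size=8)
        _, p_t = t_test_two_tailed(a, b)
        p_perm = permutation_p_value(a, b)
        assert abs(p_t - p_perm) < 0.02

    def test_matches_scipy_value(self):
        from scipy import stats

        a, b = [1.0, 2.0, 3.5], [2.2, 4.1, 5.0, 6.3]
        t, p = t_test_two_tailed(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, equal_var=True)
        assert (t, p) == (pytest.approx(t_ref), pytest.approx(p_ref))


def make_pct_table(groups):
    """groups: {(sample, treatment, locus): [per-replicate percent-input]}"""
    rows = []
    for (sample, treatment, locus), values in groups.items():
        for rep, v in enumerate(values, start=1):
            rows.append((sample, treatment, locus, rep, v))
    return pd.DataFrame(
        rows, columns=["sample", "treatment", "locus", "replicate", "percent_input"]
    )


class TestSummarize:
    def test_mean_and_sd(self):
        pct = make_pct_table({
            ("case", "t", "l"): [1.0, 2.0, 3.0],
            ("ctrl", "t", "l"): [1.0, 1.0, 1.0 + 1e-9],
        })
        [res] = summarize(pct, [{
            "name": "c",
            "case": {"sample": "case"},
            "control": {"sample": "ctrl"},
        }])
        assert res.case_mean == pytest.approx(2.0)
        assert res.case_sd == pytest.approx(1.0)
        assert res.n == 3

    def test_single_replicate_refused(self):
        pct = make_pct_table({("case", "t", "l"): [1.0], ("ctrl", "t", "l"): [1.0, 2.0]})
        with pytest.raises(QpcrError, match="n < 2"):
            summarize(pct, [{"name": "c", "case": {"sample": "case"},
                             "control": {"sample": "ctrl"}}])

    def test_mean_of_ratios_pairing(self):
        pct = make_pct_table({
            ("case", "t", "l"): [2.0, 6.0],
            ("ctrl", "t", "l"): [1.0, 2.0],
        })
        [res] = summarize(pct, [{"name": "c", "case": {"sample": "case"},
                                 "control": {"sample": "ctrl"}}])
        assert res.fold_change == pytest.approx((2.0 + 3.0) / 2)

    def test_ratio_of_means_option(self):
        pct = make_pct_table({
            ("case", "t", "l"): [2.0, 6.0],
            ("ctrl", "t", "l"): [1.0, 2.0],
        })
        [res] = summarize(pct, [{"name": "c", "case": {"sample": "case"},
                                 "control": {"sample": "ctrl"}}],
                          fold_method="ratio_of_means")
        assert res.fold_change == pytest.approx(4.0 / 1.5)
        assert res.fold_change_sd is None

    @given(st.lists(st.floats(0.1, 100.0), min_size=3, max_size=8),
           st.lists(st.floats(0.1, 100.0), min_size=3, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_aggregation_matches_direct_formula(self, case_vals, control_vals):
        pct = make_pct_table({
            ("case", "t", "l"): case_vals,
            ("ctrl", "t", "l"): control_vals,
        })
        try:
            [res] = summarize(pct, [{"name": "c", "case": {"sample": "case"},
                                     "control": {"sample": "ctrl"}}])
        except QpcrError:
            return  # zero-variance degenerate draw
        assert res.case_mean == pytest.approx(np.mean(case_vals))
        assert res.case_sd == pytest.approx(np.std(case_vals, ddof=1))
        n = min(len(case_vals), len(control_vals))
        ratios = np.array(case_vals[:n]) / np.array(control_vals[:n])
        assert res.fold_change == pytest.approx(np.mean(ratios))

    def test_dis3_vs_control_fold_change_from_simulation(self):
        # noise-free: fold change of case over control equals the programmed ratio
        design = QpcrDesign(
            enrichments={
                ("dis-3", "none", "18S"): 0.05,
                ("control", "none", "18S"): 0.20,
            },
            ct_noise_sd=0.0,
            replicates=4,
            seed=0,
        )
        pct = percent_input_table(simulate_qpcr(design))
        [res] = summarize(pct, [{
            "name": "dis-3 vs control at 18S",
            "case": {"sample": "dis-3", "locus": "18S"},
            "control": {"sample": "control", "locus": "18S"},
        }])
        assert res.fold_change == pytest.approx(0.25)
        assert res.case_mean == pytest.approx(5.0)  # percent input

    def test_unknown_selector_column(self):
        pct = make_pct_table({("a", "t", "l"): [1.0, 2.0]})
        with pytest.raises(QpcrError, match="unknown selector column"):
            summarize(pct, [{"name": "c", "case": {"bogus": "x"},
                             "control": {"sample": "a"}}])


class TestPercentInputTable:
    def test_empty_table_rejected(self):
        df = pd.DataFrame(columns=["sample", "treatment", "locus", "role",
                                   "fraction_input", "replicate", "ct"])
        with pytest.raises(QpcrError, match="empty"):
            percent_input_table(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(QpcrError, match="missing columns"):
            percent_input_table(pd.DataFrame({"sample": ["a"]}))

    def test_pairs_by_replicate(self):
        design = QpcrDesign(
            enrichments={("s", "t", "l"): 0.5}, ct_noise_sd=0.0, replicates=3, seed=1
        )
        pct = percent_input_table(simulate_qpcr(design))
        assert len(pct) == 3
        assert pct["percent_input"].to_numpy() == pytest.approx([50.0] * 3)
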
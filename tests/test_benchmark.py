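"""Benchmark summary statistics: deviations, errors, correlations, subsets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neqfe import (
    ValidationError,
    benchmark_table,
    count_small_corrections,
    deviation,
    flexibility_boxes,
    improvement_table,
    kde_curve,
    select_worst_performers,
    summary_stats,
)


def _table(exp, calc, corr=None, **extra):
    data = {"molecule_id": [f"m{i}" for i in range(len(exp))],
            "elements": ["C H"] * len(exp),
            "dG_exp": exp, "dG_calc_ff": calc}
    if corr is not None:
        data["dG_corr_ff"] = corr
    data.update(extra)
    return pd.DataFrame(data)


class TestDeviation:
    def test_sign_convention(self):
        # too-positive predictions give negative deviations
        assert deviation(-5.0, -4.0) == pytest.approx(-1.0)
        assert deviation(2.0, 2.0) == 0.0

    def test_biased_table_deviations_center_near_minus_bias(self):
        df = benchmark_table(n_molecules=800, bias=1.0, mm_noise_sd=0.9, seed=3)
        d = deviation(df["dG_exp"], df["dG_calc_openff"])
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean() + 1.0) < 3 * se


class TestSummaryStats:
    def test_perfect_agreement(self):
        df = _table([0.0, 1.0, 2.0, 5.0], [0.0, 1.0, 2.0, 5.0])
        s = summary_stats(df, "dG_calc_ff", n_boot=50, seed=0)
        assert s.rmse == 0.0 and s.mae == 0.0
        assert s.pearson == pytest.approx(1.0)
        assert s.spearman == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # deviations (-1, 1, 0): rmse = sqrt(2/3), mae = 2/3
        df = _table([0.0, 2.0, 4.0], [1.0, 1.0, 4.0])
        s = summary_stats(df, "dG_calc_ff", n_boot=50, seed=0)
        assert s.rmse == pytest.approx(np.sqrt(2.0 / 3.0))
        assert s.mae == pytest.approx(2.0 / 3.0)

    def test_constant_column_reports_missing_correlation(self):
        df = _table([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        s = summary_stats(df, "dG_calc_ff", n_boot=20, seed=0)
        assert s.pearson is None and s.spearman is None
        assert s.diagnostic is not None
        assert s.rmse >= s.mae >= 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValidationError):
            summary_stats(_table([0.0, 1.0], [0.0, 1.0]), "dG_calc_ff")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_bootstrap_ci_contains_the_point_estimate(self, seed):
        df = benchmark_table(n_molecules=200, seed=seed)
        s = summary_stats(df, "dG_calc_openff", n_boot=300, seed=seed)
        assert s.rmse_ci[0] <= s.rmse <= s.rmse_ci[1]
        assert s.mae_ci[0] <= s.mae <= s.mae_ci[1]
        assert s.pearson_ci[0] <= s.pearson <= s.pearson_ci[1]
        assert s.spearman_ci[0] <= s.spearman <= s.spearman_ci[1]

    def test_rmse_at_least_mae_and_shift_invariance(self):
        rng = np.random.default_rng(7)
        exp = rng.normal(-5, 3, 50)
        calc = exp + rng.normal(1, 1, 50)
        s1 = summary_stats(_table(exp, calc), "dG_calc_ff", n_boot=20, seed=0)
        s2 = summary_stats(_table(exp + 10, calc + 10), "dG_calc_ff",
                           n_boot=20, seed=0)
        assert s1.rmse >= s1.mae
        assert s2.rmse == pytest.approx(s1.rmse)
        assert s2.mae == pytest.approx(s1.mae)

    @given(power=st.sampled_from([1, 3]), scale=st.floats(0.1, 5),
           offset=st.floats(-3, 3))
    def test_spearman_invariant_under_monotone_transforms(self, power, scale,
                                                          offset):
        rng = np.random.default_rng(11)
        exp = rng.normal(0, 1, 30)
        calc = exp + rng.normal(0, 1, 30)
        base = summary_stats(_table(exp, calc), "dG_calc_ff",
                             n_boot=20, seed=0).spearman
        transformed = summary_stats(_table(exp, scale * calc ** power + offset),
                                    "dG_calc_ff", n_boot=20, seed=0).spearman
        assert transformed == pytest.approx(base, abs=1e-12)


class TestKde:
    def test_standard_normal_peak_near_zero(self):
        # the normal density is flat at its mode, so the argmax is only
        # localized to about one kernel bandwidth (Scott: n^(-1/5)·sd)
        rng = np.random.default_rng(0)
        sample = rng.normal(0, 1, 10000)
        grid, dens = kde_curve(sample)
        bandwidth = len(sample) ** (-0.2) * sample.std(ddof=1)
        assert abs(grid[np.argmax(dens)]) < 1.5 * bandwidth
        assert np.all(dens >= 0)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_biased_table_peak_near_minus_bias(self):
        df = benchmark_table(n_molecules=589, bias=1.0, seed=2)
        d = deviation(df["dG_exp"], df["dG_calc_openff"])
        grid, dens = kde_curve(d)
        assert abs(grid[np.argmax(dens)] + 1.0) < 0.3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            kde_curve([1.0, 1.0, 1.0])
        with pytest.raises(ValidationError):
            kde_curve([1.0])


class TestImprovement:
    def test_all_zero_corrections(self):
        df = _table([0.0, 1.0], [1.0, 2.0], corr=[0.0, 0.0])
        res = improvement_table(df, "dG_calc_ff", "dG_corr_ff")
        assert res.display == (0, 0, None)

    def test_hand_enumerated_five_row_fixture(self):
        # rows: improving small, improving large, worsening large-ish but
        # below threshold, neutral tie, worsening
        df = _table(
            exp=[0.0, 0.0, 0.0, 0.0, 0.0],
            calc=[1.0, 2.0, 0.3, 0.5, 1.0],
            corr=[-0.4, -0.8, 0.4, 0.0, 0.3])
        res = improvement_table(df, "dG_calc_ff", "dG_corr_ff", threshold=0.5)
        assert res.n_improving == 2
        assert res.n_large_corr == 1
        assert res.display == (40, 20, 100)

    def test_ties_count_as_non_improvement(self):
        df = _table([0.0], [1.0], corr=[0.0])
        res = improvement_table(df, "dG_calc_ff", "dG_corr_ff")
        assert res.n_improving == 0

    def test_percentages_cohere_with_counts(self):
        df = benchmark_table(n_molecules=400, seed=6)
        res = improvement_table(df, "dG_calc_openff", "dG_corr_openff")
        reconstructed = res.n_large_corr * res.pct_large_corr_improving / 100.0
        assert round(reconstructed) == res.n_large_corr_improving

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            improvement_table(_table([], []), "dG_calc_ff", "dG_corr_ff")


class TestWorstPerformers:
    def test_k_at_table_size_returns_everything_labelled_both(self):
        df = _table([0.0, 1.0, 2.0], [1.0, 3.0, 2.5])
        out = select_worst_performers({"a": df, "b": df}, k=3,
                                      calc_columns={"a": "dG_calc_ff",
                                                    "b": "dG_calc_ff"})
        assert len(out) == 3
        assert set(out["selected_by"]) == {"both"}

    def test_hand_enumerated_union(self):
        # |dev| per molecule: a -> m0:5, m1:4, m2:3, m3:2, m4:1, m5:0
        #                     b -> reversed
        exp = [0.0] * 6
        a = _table(exp, [5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        b = _table(exp, [0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        out = select_worst_performers({"a": a, "b": b}, k=2,
                                      calc_columns={"a": "dG_calc_ff",
                                                    "b": "dG_calc_ff"})
        assert sorted(out["molecule_id"]) == ["m0", "m1", "m4", "m5"]
        assert (out["selected_by"] == "a_only").sum() == 2
        assert (out["selected_by"] == "b_only").sum() == 2

    def test_element_filter_is_applied_before_ranking(self):
        df = _table([0.0] * 4, [9.0, 3.0, 2.0, 1.0])
        df.loc[0, "elements"] = "C H Br"  # worst row, but not allowed
        out = select_worst_performers({"a": df}, k=2,
                                      calc_columns={"a": "dG_calc_ff"})
        assert sorted(out["molecule_id"]) == ["m1", "m2"]

    def test_too_few_eligible_rows_rejected(self):
        df = _table([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValidationError):
            select_worst_performers({"a": df}, k=5,
                                    calc_columns={"a": "dG_calc_ff"})

    def test_shared_error_component_yields_partial_overlap(self):
        df = benchmark_table(n_molecules=589, seed=1)
        out = select_worst_performers(
            {"openff": df, "cgenff": df}, k=100,
            calc_columns={"openff": "dG_calc_openff",
                          "cgenff": "dG_calc_cgenff"})
        n_both = int((out["selected_by"] == "both").sum())
        assert 100 < len(out) < 200
        assert 10 < n_both < 90


class TestFlexibility:
    def test_symmetric_group_has_no_outliers(self):
        df = _table([0.0] * 5, [0.0] * 5, corr=[-2.0, -1.0, 0.0, 1.0, 2.0],
                    n_rot=[1] * 5)
        out = flexibility_boxes(df, "dG_corr_ff")
        assert out.loc[0, "outlier_ids"] == []

    def test_extreme_value_is_outlier_number_one(self):
        df = _table([0.0] * 6, [0.0] * 6,
                    corr=[-0.1, -0.05, 0.0, 0.05, 0.1, 5.0], n_rot=[2] * 6)
        out = flexibility_boxes(df, "dG_corr_ff")
        assert out.loc[0, "outlier_ids"] == ["m5"]
        assert out.loc[0, "outlier_ranks"] == [1]

    def test_flexibility_coupled_corrections_grow_with_n_rot(self):
        df = benchmark_table(n_molecules=3000, seed=4,
                             correction_model="flexibility_coupled")
        med = df.groupby("n_rot")["dG_corr_openff"].apply(
            lambda s: np.median(np.abs(s)))
        counts = df["n_rot"].value_counts()
        med = med[counts[med.index] >= 50]
        assert np.all(np.diff(med.to_numpy()) > -0.05)
        assert med.iloc[-1] > med.iloc[0]

    def test_missing_n_rot_rejected(self):
        df = _table([0.0] * 3, [0.0] * 3, corr=[0.0] * 3)
        with pytest.raises(ValidationError):
            flexibility_boxes(df, "dG_corr_ff")


class TestSmallCorrections:
    def test_all_zero(self):
        df = _table([0.0] * 3, [0.0] * 3, corr=[0.0] * 3)
        assert count_small_corrections(df, "dG_corr_ff") == 3

    def test_strict_boundary(self):
        df = _table([0.0] * 3, [0.0] * 3, corr=[0.4, 0.5, 0.6])
        assert count_small_corrections(df, "dG_corr_ff") == 1
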
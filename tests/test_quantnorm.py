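import numpy as np
import pandas as pd
import pytest

from diame.quantnorm import (
    NormalizationError,
    SpikeDesign,
    completeness_bins,
    dynamic_range,
    expected_log2_ratio,
    normalize_traces,
    pca_scores,
    protein_cv,
    ratio_deviation,
    sample_correlation,
    summarize_protein,
    summarize_proteins,
)

from conftest import make_report


def ladder_report(factors: dict[str, float], n_ions: int = 50, seed: int = 0):
    """Same ion ladder in every sample, scaled by a per-sample loading factor."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(4, 20, size=n_ions)
    rows = []
    for run, f in factors.items():
        for i in range(n_ions):
            rows.append(
                dict(
                    run_id=run,
                    protein_group=f"P{i % 10}",
                    precursor_id=f"ion{i}/2",
                    intensity=float(2.0 ** base[i] * f),
                )
            )
    return make_report(rows)


class TestNormalizeTraces:
    def test_single_sample_identity(self):
        table = ladder_report({"A": 1.0})
        out, shifts = normalize_traces(table)
        assert shifts["A"] == 0.0
        pd.testing.assert_frame_equal(out.df, table.df)

    def test_doubled_sample_shift_difference_one(self):
        table = ladder_report({"A": 1.0, "B": 2.0})
        out, shifts = normalize_traces(table)
        assert shifts["A"] - shifts["B"] == pytest.approx(1.0, abs=1e-12)
        # post-normalization the between-sample ion ratios are centred at zero
        piv = out.df.pivot(index="precursor_id", columns="run_id", values="intensity")
        ratios = np.log2(piv["B"] / piv["A"])
        assert np.median(ratios) == pytest.approx(0.0, abs=1e-12)

    def test_loading_factor_recovery_up_to_offset(self):
        table = ladder_report({"A": 0.25, "B": 1.0, "C": 4.0})
        _, shifts = normalize_traces(table)
        recovered = -shifts  # log2 loading estimates
        expected = pd.Series({"A": -2.0, "B": 0.0, "C": 2.0})
        centred = recovered - recovered.mean()
        assert float((centred - (expected - expected.mean())).abs().max()) < 0.05

    def test_disjoint_sample_errors_with_name(self):
        rows = [
            dict(run_id="A", protein_group="P", precursor_id="x/2", intensity=8.0),
            dict(run_id="A", protein_group="P", precursor_id="y/2", intensity=4.0),
            dict(run_id="lonely", protein_group="P", precursor_id="z/2", intensity=8.0),
        ]
        with pytest.raises(NormalizationError, match="lonely"):
            normalize_traces(make_report(rows))

    def test_shift_only_preserves_within_sample_ratios(self):
        table = ladder_report({"A": 1.0, "B": 3.0}, n_ions=20)
        out, _ = normalize_traces(table)
        for run in ("A", "B"):
            before = table.df.loc[table.df.run_id == run, "intensity"].to_numpy()
            after = out.df.loc[out.df.run_id == run, "intensity"].to_numpy()
            np.testing.assert_allclose(
                np.log2(after[1:] / after[0]), np.log2(before[1:] / before[0]), atol=1e-12
            )

    def test_idempotent(self):
        table = ladder_report({"A": 0.5, "B": 1.0, "C": 2.5})
        once, _ = normalize_traces(table)
        _, shifts2 = normalize_traces(once)
        assert float(shifts2.abs().max()) < 1e-9

    def test_median_method_available(self):
        table = ladder_report({"A": 1.0, "B": 2.0})
        _, shifts = normalize_traces(table, method="median")
        assert shifts["A"] - shifts["B"] == pytest.approx(1.0, abs=1e-9)


class TestSummarizeProtein:
    def test_single_ion_identity(self):
        trace = pd.DataFrame([[1.0, 2.0, 3.0]], index=["ion1"], columns=["A", "B", "C"])
        pd.testing.assert_series_equal(summarize_protein(trace), trace.iloc[0])

    def test_offset_ions_give_consistent_differences(self):
        trace = pd.DataFrame(
            [[10.0, 11.0, 12.5], [12.0, 13.0, 14.5]], index=["i1", "i2"], columns=["A", "B", "C"]
        )
        prot = summarize_protein(trace)
        np.testing.assert_allclose(np.diff(prot), np.diff(trace.iloc[0]))

    def test_outlier_sample_damped_by_median(self):
        trace = pd.DataFrame(
            [[10.0, 10.0, 10.0], [10.0, 10.0, 10.0], [10.0, 10.0, 15.0]],
            index=["i1", "i2", "i3"],
            columns=["A", "B", "C"],
        )
        prot = summarize_protein(trace)
        assert prot["C"] == pytest.approx(10.0)

    def test_missing_values_tolerated(self):
        trace = pd.DataFrame(
            [[10.0, np.nan, 12.0], [8.0, 9.0, np.nan]], index=["i1", "i2"], columns=["A", "B", "C"]
        )
        prot = summarize_protein(trace)
        assert prot.notna().all()


class TestProteinCv:
    def test_identical_values_zero(self):
        mat = pd.DataFrame([[3.0, 3.0, 3.0]], index=["P"])
        assert protein_cv(mat)["P"] == pytest.approx(0.0)

    def test_linear_scale_formula(self):
        # linear values {1, 2, 3}: sd (n-1) = 1, mean = 2 -> CV 0.5
        mat = pd.DataFrame([np.log2([1.0, 2.0, 3.0])], index=["P"])
        assert protein_cv(mat)["P"] == pytest.approx(0.5)

    def test_single_observation_undefined(self):
        mat = pd.DataFrame([[3.0, np.nan, np.nan]], index=["P"])
        assert np.isnan(protein_cv(mat)["P"])


class TestSpikeRatios:
    design = SpikeDesign({"low": (0.05, 1.0), "high": (0.20, 1.0), "high10": (0.20, 10.0)})

    def test_entrapment_ratio(self):
        assert expected_log2_ratio(self.design, "low", "high", "entrapment") == pytest.approx(2.0)

    def test_human_ratio(self):
        expected = np.log2(0.80 / 0.95)
        assert expected_log2_ratio(self.design, "low", "high", "human") == pytest.approx(expected)

    def test_identical_conditions_zero(self):
        assert expected_log2_ratio(self.design, "low", "low", "human") == 0.0

    def test_amount_enters_ratio(self):
        assert expected_log2_ratio(self.design, "high", "high10", "entrapment") == pytest.approx(np.log2(10))

    def test_non_spiked_entrapment_errors(self):
        design = SpikeDesign({"none": (0.0, 1.0), "low": (0.05, 1.0)})
        with pytest.raises(ValueError):
            expected_log2_ratio(design, "none", "low", "entrapment")

    def test_ratio_deviation_on_exact_data(self):
        ann = pd.DataFrame(
            {
                "run_id": ["l1", "l2", "h1", "h2"],
                "role": "analyte",
                "condition": ["low", "low", "high", "high"],
                "replicate": [1, 2, 1, 2],
            }
        )
        mat = pd.DataFrame(
            {
                "l1": [10.0, 8.0],
                "l2": [10.0, 8.0],
                "h1": [12.0, 8.0 + np.log2(0.80 / 0.95)],
                "h2": [12.0, 8.0 + np.log2(0.80 / 0.95)],
            },
            index=["ECOLI_P1", "HUMAN_P1"],
        )
        species = pd.Series({"ECOLI_P1": "entrapment", "HUMAN_P1": "human"})
        dev = ratio_deviation(mat, self.design, ann, species, "low", "high")
        np.testing.assert_allclose(dev["deviation"], 0.0, atol=1e-12)

    def test_protein_missing_in_a_condition_excluded(self):
        ann = pd.DataFrame(
            {
                "run_id": ["l1", "h1", "h2"],
                "role": "analyte",
                "condition": ["low", "high", "high"],
                "replicate": [1, 1, 2],
            }
        )
        mat = pd.DataFrame(
            {"l1": [np.nan], "h1": [12.0], "h2": [12.0]}, index=["HUMAN_P1"]
        )
        dev = ratio_deviation(mat, self.design, ann, pd.Series({"HUMAN_P1": "human"}), "low", "high")
        assert len(dev) == 0


class TestCompleteness:
    def test_complete_matrix_all_ones(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(12, 4)))
        assert (completeness_bins(mat, n_bins=6) == 1.0).all()

    def test_hand_enumerated_toy(self):
        mat = pd.DataFrame(
            {
                "s1": [10.0, 9.0, 8.0, 7.0, 6.0, np.nan],
                "s2": [10.0, 9.0, 8.0, 7.0, np.nan, np.nan],
            },
            index=[f"p{i}" for i in range(6)],
        )
        bins = completeness_bins(mat, n_bins=6)
        np.testing.assert_allclose(bins.to_numpy(), [1.0, 1.0, 1.0, 1.0, 0.5, 0.0])

    def test_single_bin_is_overall_completeness(self):
        mat = pd.DataFrame({"s1": [1.0, np.nan], "s2": [1.0, 1.0]})
        assert completeness_bins(mat, n_bins=1).iloc[0] == pytest.approx(0.75)

    def test_fewer_proteins_than_bins_errors(self):
        with pytest.raises(ValueError):
            completeness_bins(pd.DataFrame(np.ones((3, 2))), n_bins=6)


class TestSampleCorrelation:
    def test_duplicated_column(self):
        mat = pd.DataFrame({"a": [1.0, 2, 3, 4, 5], "b": [1.0, 2, 3, 4, 5]})
        assert sample_correlation(mat, min_pairwise=3).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_column(self):
        x = np.array([1.0, 2, 3, 4, 5])
        mat = pd.DataFrame({"a": x, "b": -x})
        assert sample_correlation(mat, min_pairwise=3).loc["a", "b"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        mat = pd.DataFrame({"x": [1.0, 2, 3, 4, 5], "y": [2.0, 1, 4, 3, 6]})
        # r = 10 / sqrt(10 * 14.8)
        assert sample_correlation(mat, min_pairwise=3).loc["x", "y"] == pytest.approx(
            10 / np.sqrt(148), abs=1e-9
        )

    def test_pair_below_min_n_undefined(self):
        mat = pd.DataFrame({"a": [1.0, 2, np.nan, np.nan], "b": [np.nan, 2.0, 3, 4]})
        corr = sample_correlation(mat, min_pairwise=2)
        assert np.isnan(corr.loc["a", "b"]) and corr.loc["a", "a"] == 1.0


class TestPca:
    def test_identical_samples_identical_scores(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=10)
        mat = pd.DataFrame({"a": col, "b": col, "c": rng.normal(size=10)})
        scores, _ = pca_scores(mat)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["b"], atol=1e-9)

    def test_first_component_separates_groups(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 6)) * 0.01
        mat = pd.DataFrame(base, columns=[f"s{i}" for i in range(6)])
        mat.iloc[0, :3] += 5.0  # one protein offsets the first three samples
        scores, var = pca_scores(mat)
        g1, g2 = scores.iloc[:3, 0], scores.iloc[3:, 0]
        assert min(g1) > max(g2) or max(g1) < min(g2)
        assert var.sum() <= 1.0 + 1e-12

    def test_only_complete_rows_used(self):
        mat = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan], "b": [2.0, 1.0, 5.0], "c": [3.0, 0.0, 6.0]}
        )
        scores, _ = pca_scores(mat)  # third protein dropped
        assert scores.shape[0] == 3

    def test_too_few_complete_rows_errors(self):
        mat = pd.DataFrame({"a": [1.0, np.nan], "b": [np.nan, 1.0]})
        with pytest.raises(ValueError):
            pca_scores(mat)


class TestDynamicRange:
    def test_equal_medians_zero(self):
        mat = pd.DataFrame(np.full((5, 3), 7.0))
        assert dynamic_range(mat) == pytest.approx(0.0)

    def test_orders_of_magnitude(self):
        mat = pd.DataFrame({"s": np.log2([1.0, 50.0, 1000.0])})
        assert dynamic_range(mat) == pytest.approx(3.0)


def test_summarize_proteins_matches_single_protein_alignment(toy_report, toy_annotations):
    mat = summarize_proteins(toy_report, toy_annotations)
    assert mat.shape == (3, 2)
    assert list(mat.columns) == ["A", "B"]
    # intensities identical across runs -> identical per-run values
    np.testing.assert_allclose(mat["A"], mat["B"])
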
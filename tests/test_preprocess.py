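import numpy as np
import pandas as pd
import pytest

from tiernet.cohort import CohortTable, VariableSpec
from tiernet.preprocess import (
    InvalidDataError,
    NotApplicableError,
    OrderOfOperationsError,
    SeparationError,
    UnimputableColumnError,
    clean_biomarkers,
    detect_outliers,
    iterative_impute,
    little_mcar_test,
    remove_outliers,
    residualize_outcome,
)
from tiernet.synthetic_cohort import (
    inject_missingness,
    inject_outliers,
    nesda_like_truth,
    sample_cohort,
)


class TestLittleMcar:
    def test_complete_table_not_applicable(self, gauss_table_factory):
        with pytest.raises(NotApplicableError):
            little_mcar_test(gauss_table_factory(100, 3, seed=0))

    def test_mcar_masking_is_not_rejected_too_often(self, gauss_table_factory):
        rng = np.random.default_rng(0)
        rej = 0
        reps = 60
        for _ in range(reps):
            tab = gauss_table_factory(800, 4, seed=int(rng.integers(2**31)))
            masked = inject_missingness(tab, 0.1, "MCAR", seed=int(rng.integers(2**31)))
            rej += little_mcar_test(masked).p <= 0.05
        assert rej / reps < 0.15

    def test_exposure_dependent_missingness_detected(self):
        truth = nesda_like_truth(1, n_biomarkers=6)
        rej = 0
        for rep in range(20):
            tab = sample_cohort(truth, 2000, seed=rep)
            masked = inject_missingness(tab, 0.1, "MAR", seed=rep)
            rej += little_mcar_test(masked).p <= 0.05
        assert rej >= 18

    def test_statistic_invariant_to_affine_rescaling(self, gauss_table_factory):
        tab = gauss_table_factory(500, 4, seed=1)
        masked = inject_missingness(tab, 0.15, "MCAR", seed=2)
        res = little_mcar_test(masked)
        scaled = masked.copy()
        scaled.df["v0"] = scaled.df["v0"] * 10 + 3
        scaled.df["v2"] = scaled.df["v2"] * -2 + 1
        res2 = little_mcar_test(scaled)
        assert res2.statistic == pytest.approx(res.statistic, rel=1e-4)
        assert res2.df == res.df


class TestIterativeImpute:
    def test_complete_table_returned_unchanged(self, gauss_table_factory):
        tab = gauss_table_factory(100, 3, seed=0)
        assert iterative_impute(tab) is tab

    def test_observed_cells_preserved_and_no_missing_left(self, gauss_table_factory):
        tab = gauss_table_factory(500, 5, seed=1, r=0.6)
        masked = inject_missingness(tab, 0.1, "MCAR", seed=3)
        obs_mask = masked.df.notna().to_numpy()
        imp = iterative_impute(masked, seed=0)
        assert imp.n_missing() == 0
        assert np.array_equal(
            imp.df.to_numpy()[obs_mask], masked.df.to_numpy()[obs_mask]
        )

    def test_beats_column_mean_imputation_on_correlated_data(self, gauss_table_factory):
        tab = gauss_table_factory(2000, 8, seed=2, r=0.6)
        masked = inject_missingness(tab, 0.1, "MCAR", seed=4)
        mask = masked.df.isna().to_numpy()
        truth_vals = tab.df.to_numpy()
        imp = iterative_impute(masked, seed=0)
        rmse_it = np.sqrt(np.mean((imp.df.to_numpy()[mask] - truth_vals[mask]) ** 2))
        col_means = np.nanmean(masked.df.to_numpy(), axis=0)
        rmse_mean = np.sqrt(
            np.mean((np.broadcast_to(col_means, tab.df.shape)[mask] - truth_vals[mask]) ** 2)
        )
        assert rmse_it < rmse_mean

    def test_binary_columns_thresholded(self):
        truth = nesda_like_truth(1, n_biomarkers=4)
        tab = sample_cohort(truth, 400, seed=5)
        masked = tab.copy()
        masked.df.loc[::7, "bm01"] = np.nan
        imp = iterative_impute(masked, seed=1)
        assert set(np.unique(imp.df["MDD"])) <= {0.0, 1.0}

    def test_fully_missing_column_named_in_error(self, gauss_table_factory):
        tab = gauss_table_factory(50, 3, seed=0)
        tab.df["v1"] = np.nan
        with pytest.raises(UnimputableColumnError, match="v1"):
            iterative_impute(tab)


class TestDetectOutliers:
    def test_flag_count_is_exact_ceiling(self, gauss_table_factory):
        tab = gauss_table_factory(500, 4, seed=0)
        rep = detect_outliers(tab, 0.01, seed=0)
        assert len(rep.flagged) == int(np.ceil(0.01 * 500))

    def test_seed_determinism(self, gauss_table_factory):
        tab = gauss_table_factory(300, 4, seed=1)
        a = detect_outliers(tab, 0.05, seed=9)
        b = detect_outliers(tab, 0.05, seed=9)
        assert a.flagged == b.flagged

    def test_missing_cells_are_an_ordering_error(self, gauss_table_factory):
        tab = gauss_table_factory(200, 3, seed=2)
        masked = inject_missingness(tab, 0.1, "MCAR", seed=0)
        with pytest.raises(OrderOfOperationsError):
            detect_outliers(masked, 0.05)

    def test_recovers_injected_inflammation_spikes(self):
        truth = nesda_like_truth(5)
        tab = sample_cohort(truth, 1200, seed=3)
        cont, idx = inject_outliers(tab, 60, seed=4)
        rep = detect_outliers(cont, 60 / 1200, seed=0)
        recall = len(set(rep.flagged) & set(idx)) / 60
        assert recall >= 0.9
        cleaned = remove_outliers(cont, rep)
        assert cleaned.n == 1200 - 60

    def test_contamination_bounds(self, gauss_table_factory):
        tab = gauss_table_factory(100, 3, seed=0)
        for bad in (0.0, 0.5):
            with pytest.raises(ValueError):
                detect_outliers(tab, bad)


class TestCleanBiomarkers:
    def _table(self, values, role="biomarker"):
        specs = [VariableSpec("b", "continuous", 1, role)]
        return CohortTable(pd.DataFrame({"b": values}), specs)

    def test_zeros_map_to_zeros(self):
        out = clean_biomarkers(self._table(np.zeros(10)))
        assert (out.df["b"] == 0).all()

    def test_log1p_closed_forms(self):
        out = clean_biomarkers(self._table([0.0, np.e - 1.0] + [1.0] * 50, role="inflammatory"))
        assert out.df["b"].iloc[0] == pytest.approx(0.0)
        assert out.df["b"].iloc[1] == pytest.approx(1.0)

    def test_cell_beyond_five_sds_censored(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(1.0, 0.1, size=1000))  # tight post-log spread
        vals[0] = np.exp(5.0)  # far beyond 5 post-log SDs
        out = clean_biomarkers(self._table(vals))
        assert np.isnan(out.df["b"].iloc[0])
        assert out.df["b"].iloc[1:].notna().all()

    def test_inflammatory_columns_not_censored_by_default(self):
        rng = np.random.default_rng(0)
        vals = np.exp(rng.normal(1.0, 0.1, size=1000))
        vals[0] = np.exp(5.0)
        out = clean_biomarkers(self._table(vals, role="inflammatory"))
        assert not np.isnan(out.df["b"].iloc[0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(InvalidDataError):
            clean_biomarkers(self._table([-0.1, 1.0]))

    def test_idempotent_on_cleaned_gaussianized_data(self):
        rng = np.random.default_rng(1)
        tab = self._table(np.exp(rng.normal(2.0, 0.5, size=2000)))
        once = clean_biomarkers(tab)
        # second pass works on already-log values; censoring removes nothing new
        again = once.copy()
        x = again.df["b"].to_numpy()
        mean, sd = np.nanmean(x), np.nanstd(x)
        assert (np.abs(x[~np.isnan(x)] - mean) <= 5 * sd).all()


class TestResidualizeOutcome:
    def _cohort(self, n, seed, beta=1.0):
        rng = np.random.default_rng(seed)
        age = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(-1.0 + beta * age)))).astype(float)
        specs = [
            VariableSpec("age", "continuous", 0, "covariate"),
            VariableSpec("cvd", "binary", 1, "outcome"),
        ]
        return CohortTable(pd.DataFrame({"age": age, "cvd": y}), specs)

    def test_null_adjusters_leave_centered_outcome(self):
        tab = self._cohort(5000, 0, beta=0.0)
        out = residualize_outcome(tab, "cvd", ["age"])
        raw = tab.df["cvd"].to_numpy()
        resid = out.df["cvd"].to_numpy()
        centered = (raw - raw.mean()) / raw.std()
        assert np.corrcoef(resid, centered)[0, 1] > 0.99

    def test_residuals_orthogonal_to_adjusters(self):
        tab = self._cohort(5000, 1, beta=1.0)
        out = residualize_outcome(tab, "cvd", ["age"])
        r = np.corrcoef(out.df["cvd"], out.df["age"])[0, 1]
        assert abs(r) < 0.02

    def test_intercept_only_residualization(self):
        tab = self._cohort(500, 2, beta=0.0)
        out = residualize_outcome(tab, "cvd", [])
        raw = tab.df["cvd"].to_numpy()
        expect = raw - raw.mean()
        assert np.corrcoef(out.df["cvd"], expect)[0, 1] > 0.999999
        assert out.spec("cvd").kind == "continuous"
        assert out.spec("cvd_raw").kind == "binary"

    def test_perfect_separation_raises(self):
        n = 200
        age = np.linspace(-1, 1, n)
        y = (age > 0).astype(float)
        specs = [
            VariableSpec("age", "continuous", 0, "covariate"),
            VariableSpec("cvd", "binary", 1, "outcome"),
        ]
        tab = CohortTable(pd.DataFrame({"age": age, "cvd": y}), specs)
        with pytest.raises(SeparationError):
            residualize_outcome(tab, "cvd", ["age"])
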
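"""Pot-trial statistics: summaries, fold change, one-way ANOVA, PCA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pgpscreen import growth_trial
from pgpscreen.errors import DegenerateColumnError, DomainError
from pgpscreen.growth_trial import (
    PARAMETERS,
    GrowthRecord,
    anova_table,
    fold_change_table,
    log2_fold_change,
    one_way_anova,
    pca,
    records_to_frame,
    summarize_treatments,
    trial_pca,
)
from pgpscreen.synthetic_data import TrialSimConfig, simulate_trial


def _records(cells):
    """cells: {(treatment, timepoint): [replicate values]} on one parameter,
    all other parameters held at 1."""
    records = []
    for (trt, tp), values in cells.items():
        for i, v in enumerate(values, start=1):
            params = {p: 1.0 for p in PARAMETERS}
            params["shoot_length"] = v
            records.append(
                GrowthRecord(treatment=trt, timepoint=tp, replicate=i,
                             parameters=params)
            )
    return records


class TestSummaries:
    def test_constant_replicates(self):
        recs = _records({("control", 35): [2.0, 2.0, 2.0]})
        s = summarize_treatments(recs)
        row = s[s.parameter == "shoot_length"].iloc[0]
        assert row["mean"] == 2.0 and row["se"] == 0.0 and row["n"] == 3

    def test_se_is_sd_over_sqrt_n(self):
        recs = _records({("control", 35): [1.0, 2.0, 3.0]})
        s = summarize_treatments(recs)
        row = s[s.parameter == "shoot_length"].iloc[0]
        assert row["se"] == pytest.approx(1.0 / math.sqrt(3), abs=1e-4)

    def test_single_replicate_cell_rejected(self):
        recs = _records({("control", 35): [1.0]})
        with pytest.raises(DomainError):
            summarize_treatments(recs)

    def test_duplicate_replicate_index_rejected(self):
        params = {p: 1.0 for p in PARAMETERS}
        recs = [
            GrowthRecord("control", 35, 1, params),
            GrowthRecord("control", 35, 1, params),
        ]
        with pytest.raises(DomainError):
            records_to_frame(recs)

    def test_negative_parameter_rejected(self):
        params = {p: 1.0 for p in PARAMETERS} | {"root_length": -0.1}
        with pytest.raises(DomainError):
            GrowthRecord("control", 35, 1, params)


class TestFoldChange:
    @pytest.mark.parametrize(
        "t, c, expected", [(2.0, 2.0, 0.0), (4.0, 1.0, 2.0), (2.5, 1.0, 1.3219)]
    )
    def test_log2_values(self, t, c, expected):
        assert log2_fold_change(t, c) == pytest.approx(expected, abs=1e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.uniform(0.1, 10, size=2)
            assert log2_fold_change(a, b) == pytest.approx(
                -log2_fold_change(b, a)
            )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            log2_fold_change(0.0, 1.0)

    def test_noiseless_trial_recovers_configuration_exactly(self):
        cfg = TrialSimConfig(noise_cv=0.0, seed=5)
        table = fold_change_table(simulate_trial(cfg))
        for trt, fc in cfg.fold_changes.items():
            if trt == "control":
                continue
            got = table[table.treatment == trt]["fold_change"]
            assert np.allclose(got, fc)

    def test_missing_control_rejected(self):
        recs = _records({("T1", 35): [1.0, 2.0]})
        with pytest.raises(DomainError):
            fold_change_table(recs)


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0

    def test_hand_computed_sums_of_squares(self):
        # groups {1,2,3},{2,3,4},{3,4,5}: SSB = 6, SSW = 6, df = (2, 6)
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)
        assert res.p == pytest.approx(stats.f.sf(3.0, 2, 6))
        assert res.p == pytest.approx(0.125, abs=0.001)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(19)
        for _ in range(25):
            groups = [rng.normal(rng.uniform(0, 2), 1.0, size=5) for _ in range(3)]
            ours = one_way_anova(groups)
            ref = stats.f_oneway(*groups)
            assert ours.F == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_all_values_identical(self):
        res = one_way_anova([[2, 2], [2, 2]])
        assert res.F == 0.0 and res.p == 1.0

    def test_zero_within_variance_unequal_means(self):
        res = one_way_anova([[1, 1], [2, 2]])
        assert math.isinf(res.F) and res.p == 0.0

    def test_location_and_scale_invariance(self):
        rng = np.random.default_rng(23)
        groups = [rng.normal(i, 1.0, size=5) for i in range(3)]
        base = one_way_anova(groups).F
        shifted = one_way_anova([g + 100.0 for g in groups]).F
        scaled = one_way_anova([g * 7.5 for g in groups]).F
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_too_small_groups_rejected(self):
        with pytest.raises(DomainError):
            one_way_anova([[1.0], [2.0, 3.0]])

    def test_anova_table_runs_per_parameter_per_timepoint(self):
        recs = simulate_trial(TrialSimConfig(seed=2))
        table = anova_table(recs)
        assert len(table) == len(PARAMETERS) * 2
        assert set(table.df_between) == {3} and set(table.df_within) == {16}


class TestPca:
    def test_perfectly_correlated_columns_put_everything_on_pc1(self):
        x = np.linspace(0, 1, 20)
        res = pca(np.column_stack([x, 2 * x + 1]))
        assert res.explained_variance_pct[0] == pytest.approx(100.0)

    def test_independent_columns_split_evenly(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(20000, 2))
        res = pca(X)
        assert res.explained_variance_pct[0] == pytest.approx(50.0, abs=2.0)

    def test_matches_eigendecomposition_oracle(self):
        X = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [3.0, 3.5, 0.2], [4.0, 3.0, 2.0]]
        )
        res = pca(X)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        eigvals = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
        expected = 100.0 * eigvals / eigvals.sum()
        assert np.allclose(res.explained_variance_pct, expected, atol=1e-8)

    def test_matches_sklearn_on_standardized_data(self):
        from sklearn.decomposition import PCA as SkPCA

        rng = np.random.default_rng(37)
        X = rng.normal(size=(30, 5)) @ rng.normal(size=(5, 5))
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        ours = pca(X).explained_variance_pct
        ref = 100.0 * SkPCA().fit(Z).explained_variance_ratio_
        assert np.allclose(ours, ref, atol=1e-8)

    def test_percentages_sum_to_100_and_non_increasing(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(10, 9))
        pct = pca(X).explained_variance_pct
        assert pct.sum() == pytest.approx(100.0, abs=1e-6)
        assert np.all(np.diff(pct) <= 1e-12)

    def test_constant_column_named_in_error(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.raises(DegenerateColumnError) as err:
            pca(X)
        assert err.value.column == "b"

    def test_trial_pca_over_replicates(self):
        recs = simulate_trial(TrialSimConfig(seed=13))
        res = trial_pca(recs, 35)
        assert res.loadings.shape == (9, 9)
        # treatments scale all parameters jointly, so PC1 dominates
        assert res.explained_variance_pct[0] > 50.0
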
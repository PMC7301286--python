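"""Statistical chain against hand oracles: log10, KS, ANOVA, Bonferroni, PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocx.complexity import FEATURE_COLUMNS
from neurocx.stats import (
    bonferroni_posthoc,
    feature_matrix,
    global_anova,
    group_scatter_ratio,
    ks_normality,
    log10_normalize,
    one_way_anova,
    pca_top3,
    per_electrode_anova,
)

from conftest import anova_by_sums_of_squares


class TestLog10Normalize:
    def test_definition(self):
        np.testing.assert_allclose(
            log10_normalize([1.064, 1.0, 0.2066]),
            [0.02694, 0.0, -0.68487],
            atol=5e-6,
        )

    def test_nonpositive_value_names_offending_row(self):
        with pytest.raises(ValueError, match=r"\[2\]"):
            log10_normalize([1.0, 2.0, 0.0, 3.0])


class TestKsNormality:
    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ks_normality([3.0, 3.0, 3.0])

    def test_single_point_against_fixed_standard_normal(self):
        # empirical CDF jumps 0 -> 1 at 0 where Phi(0) = 0.5
        d, _ = ks_normality([0.0], mean=0.0, sd=1.0)
        assert d == pytest.approx(0.5)

    def test_large_normal_sample_has_small_statistic(self):
        x = np.random.default_rng(8).standard_normal(10_000)
        d, p = ks_normality(x)
        assert d < 0.02


class TestOneWayAnova:
    def test_hand_computed_example(self):
        # SSB = 6, SSW = 6, df = (2, 6)  =>  F = (6/2)/(6/6) = 3
        res = one_way_anova([[1, 2, 3], [2, 3, 4], [3, 4, 5]])
        assert res.F == pytest.approx(3.0, abs=1e-12)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_identical_groups_give_zero_f(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_huge_separation_drives_p_to_zero(self):
        res = one_way_anova([[0.0, 0.01, -0.01], [100.0, 100.01, 99.99]])
        assert res.p < 1e-12

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [1.0, 2.0]])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_agrees_with_sums_of_squares_oracle(self, seed):
        gen = np.random.default_rng(seed)
        groups = [
            gen.normal(gen.uniform(-1, 1), 1.0, size=int(gen.integers(2, 12)))
            for _ in range(int(gen.integers(2, 5)))
        ]
        res = one_way_anova(groups)
        f, dfb, dfw, p = anova_by_sums_of_squares(groups)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert (res.df_between, res.df_within) == (dfb, dfw)
        assert res.p == pytest.approx(p, abs=1e-10)


class TestBonferroniPosthoc:
    def test_adjustment_is_raw_p_times_pair_count(self):
        gen = np.random.default_rng(9)
        groups = [gen.normal(m, 1.0, 20) for m in (0.0, 0.3, 0.8)]
        table = bonferroni_posthoc(groups, ["a", "b", "c"])
        assert len(table) == 3
        np.testing.assert_allclose(
            table["p_adjusted"], np.minimum(1.0, table["p_raw"] * 3)
        )

    def test_capping_at_one(self):
        gen = np.random.default_rng(10)
        groups = [gen.normal(0.0, 1.0, 15) for _ in range(3)]
        table = bonferroni_posthoc(groups, ["a", "b", "c"])
        assert (table["p_adjusted"] <= 1.0).all()
        assert (table.loc[table["p_raw"] > 1 / 3, "p_adjusted"] == 1.0).all()

    def test_significance_flag_respects_alpha(self):
        groups = [[0.0, 0.1, -0.1, 0.05], [5.0, 5.1, 4.9, 5.05]]
        table = bonferroni_posthoc(groups, ["a", "b"], alpha=0.05)
        assert bool(table.loc[0, "significant"])
        assert table.loc[0, "mean_difference"] == pytest.approx(-5.0, abs=0.1)


def _feature_table(effect=1.0, n_subjects=4, channels=("Cz", "Pz"), seed=0,
                   measure="HFD"):
    gen = np.random.default_rng(seed)
    rows = []
    for gi, grp in enumerate(("C", "E", "R")):
        for s in range(n_subjects):
            for ch in channels:
                for ep in range(3):
                    value = np.exp(gen.normal(gi * effect, 0.3))
                    rows.append((f"{grp}{s}", grp, ch, ep, measure, value, True))
    return pd.DataFrame(rows, columns=list(FEATURE_COLUMNS))


class TestPerElectrodeAnova:
    def test_strong_uniform_effect_flags_every_channel(self):
        table = _feature_table(effect=2.0, n_subjects=6,
                               channels=("Fp1", "Cz", "O2"))
        anova, posthoc, all_sig = per_electrode_anova(table, "HFD")
        assert len(anova) == 3
        assert sorted(all_sig) == ["Cz", "Fp1", "O2"]
        assert (anova["p"] < 0.05).all()

    def test_single_channel_table(self):
        table = _feature_table(channels=("Cz",))
        anova, posthoc, _ = per_electrode_anova(table, "HFD")
        assert len(anova) == 1 and len(posthoc) == 3

    def test_missing_cells_are_listed(self):
        table = _feature_table(channels=("Cz", "Pz"))
        table = table[~((table["channel"] == "Pz") & (table["group"] == "E"))]
        with pytest.raises(ValueError, match="Pz"):
            per_electrode_anova(table, "HFD")

    def test_null_false_positive_rate_near_alpha_per_family(self):
        # no effect built in: expected fully-significant-channel count
        # over replicates stays near the Bonferroni-controlled rate
        n_false = 0
        n_families = 0
        for rep in range(150):
            table = _feature_table(effect=0.0, n_subjects=5,
                                   channels=("Cz",), seed=rep)
            _, _, all_sig = per_electrode_anova(table, "HFD", alpha=0.05)
            n_false += len(all_sig)
            n_families += 1
        # requiring all 3 contrasts significant is far stricter than alpha
        assert n_false / n_families <= 0.05


class TestGlobalAnova:
    def test_aggregate_channels_reduces_units_to_subject_epoch(self):
        table = _feature_table(n_subjects=7)
        res_none, _ = global_anova(table, "HFD", aggregate="none")
        res_agg, _ = global_anova(table, "HFD", aggregate="channels")
        # 3 groups x 7 subjects x 3 epochs = 63 units when averaging channels
        assert res_agg.df_within == 63 - 3
        assert res_none.df_within == 63 * 2 - 3
        with pytest.raises(ValueError):
            global_anova(table, "HFD", aggregate="bogus")


class TestPca:
    def test_rank_one_line_explains_everything(self):
        gen = np.random.default_rng(11)
        direction = gen.standard_normal(5)
        x = np.outer(gen.standard_normal(50), direction)
        res = pca_top3(x)
        assert res.explained_variance_ratio == pytest.approx(1.0, abs=1e-10)
        assert res.rank_deficient

    def test_isotropic_gaussian_ratio_is_three_tenths(self):
        x = np.random.default_rng(12).standard_normal((10_000, 10))
        res = pca_top3(x)
        assert res.explained_variance_ratio == pytest.approx(0.3, abs=0.02)

    def test_full_reconstruction_with_all_components(self):
        x = np.random.default_rng(13).standard_normal((40, 6))
        res = pca_top3(x, n_components=6)
        centered = x - x.mean(axis=0)
        np.testing.assert_allclose(
            res.scores @ res.loadings.T, centered, atol=1e-10
        )

    def test_loadings_columns_orthonormal_and_variances_sorted(self):
        x = np.random.default_rng(14).standard_normal((200, 8)) * np.arange(1, 9)
        res = pca_top3(x)
        np.testing.assert_allclose(
            res.loadings.T @ res.loadings, np.eye(3), atol=1e-10
        )
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)

    def test_ratio_invariant_to_reordering_and_constant_shift(self):
        gen = np.random.default_rng(15)
        x = gen.standard_normal((100, 6)) @ gen.standard_normal((6, 6))
        base = pca_top3(x).explained_variance_ratio
        perm = gen.permutation(6)
        assert pca_top3(x[:, perm]).explained_variance_ratio == pytest.approx(base)
        shifted = x.copy()
        shifted[:, 2] += 42.0
        assert pca_top3(shifted).explained_variance_ratio == pytest.approx(base)

    def test_matches_sklearn_cross_check(self):
        from sklearn.decomposition import PCA

        x = np.random.default_rng(16).standard_normal((80, 7)) * np.arange(1, 8)
        res = pca_top3(x)
        ref = PCA(n_components=3).fit(x)
        assert res.explained_variance_ratio == pytest.approx(
            ref.explained_variance_ratio_.sum(), abs=1e-10
        )
        # loadings match up to sign
        for j in range(3):
            dot = abs(float(res.loadings[:, j] @ ref.components_[j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="4 observations"):
            pca_top3(np.ones((2, 5)))
        with pytest.raises(ValueError, match="variables"):
            pca_top3(np.ones((10, 2)))
        bad = np.ones((10, 5))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pca_top3(bad)


class TestFeatureMatrixAndScatter:
    def test_layout_is_subject_epoch_by_channel_measure(self):
        table = _feature_table(n_subjects=4, channels=("Cz", "Pz"))
        matrix, obs, variables = feature_matrix(table, measures=["HFD"])
        assert matrix.shape == (3 * 4 * 3, 2)
        assert sorted(variables) == ["Cz:HFD", "Pz:HFD"]
        assert set(obs.columns) == {"subject", "group", "epoch"}

    def test_scatter_ratio_separated_vs_mixed(self):
        gen = np.random.default_rng(17)
        scores = np.concatenate(
            [gen.normal(0, 1, (50, 3)), gen.normal(8, 1, (50, 3))]
        )
        labels = np.array(["a"] * 50 + ["b"] * 50)
        assert group_scatter_ratio(scores, labels) > 1.0
        mixed = gen.permutation(scores)
        assert group_scatter_ratio(mixed, labels) < 0.2
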
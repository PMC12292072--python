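"""Preprocessing chain and moderated differential expression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_ms_dataset
from trimciv import expression as xp


def df(rows, columns=None):
    return pd.DataFrame(rows, columns=columns)


class TestLog2Transform:
    def test_powers_of_two(self):
        out = xp.log2_transform(df([[1.0, 2.0], [4.0, 8.0]]))
        assert np.allclose(out.values, [[0, 1], [2, 3]])

    def test_missing_cells_stay_missing(self):
        out = xp.log2_transform(df([[1.0, np.nan], [4.0, 8.0]]))
        assert np.isnan(out.iloc[0, 1]) and not np.isnan(out.iloc[0, 0])

    def test_zero_with_offset_one(self):
        assert xp.log2_transform(df([[0.0]]), offset=1.0).iloc[0, 0] == 0.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            xp.log2_transform(df([[-1.0]]))
        with pytest.raises(ValueError):
            xp.log2_transform(df([[0.0]]))  # offset 0


class TestFilterMissing:
    def test_boundary_is_strictly_greater(self):
        m = df(
            [
                [1, 1, 1, np.nan, np.nan, np.nan],  # 3/6 = 0.5 -> kept
                [1, 1, np.nan, np.nan, np.nan, np.nan],  # 4/6 -> removed
            ]
        )
        out = xp.filter_missing(m, max_frac=0.5)
        assert list(out.index) == [0]

    def test_complete_matrix_unchanged(self):
        m = df([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(xp.filter_missing(m), m)


class TestKnnImpute:
    def test_identity_on_complete_input(self):
        m = df([[1.0, 2.0], [3.0, 4.0]])
        pd.testing.assert_frame_equal(xp.knn_impute(m), m)

    def test_identical_rows_share_value(self):
        m = df([[5.0, 7.0, 9.0], [5.0, 7.0, 9.0], [5.0, 7.0, np.nan]])
        assert xp.knn_impute(m, k=2).iloc[2, 2] == pytest.approx(9.0)

    def test_nearest_row_wins(self):
        # r2 is at distance 0 from r1 on the observed columns; r3 is far
        m = df([[1.0, 1.0, np.nan], [1.0, 1.0, 4.0], [9.0, 9.0, 9.0]])
        assert xp.knn_impute(m, k=1).iloc[0, 2] == pytest.approx(4.0)

    def test_all_missing_row_names_gene(self):
        m = pd.DataFrame([[np.nan, np.nan]], index=["BRCA1"])
        with pytest.raises(ValueError, match="BRCA1"):
            xp.knn_impute(m)


class TestFilterLowCounts:
    def test_designed_keep_set(self):
        # equal library sizes of 1000 -> CPM cutoff equals raw count 10;
        # smaller group has 2 samples, so a gene needs >= 10 in >= 2 samples
        m = pd.DataFrame(
            {
                "s1": [0, 50, 12, 9, 11, 918],
                "s2": [0, 50, 13, 9, 0, 928],
                "s3": [0, 50, 0, 9, 0, 941],
                "s4": [0, 50, 0, 9, 0, 941],
            },
            index=["zero", "high", "partial", "low", "single", "fill"],
        )
        group = pd.Series(["tumor", "tumor", "normal", "normal"], index=m.columns)
        out = xp.filter_low_counts(m, group, min_count=10)
        assert list(out.index) == ["high", "partial", "fill"]

    def test_all_zero_removed_and_uniform_kept(self):
        m = pd.DataFrame({"a": [0, 100], "b": [0, 100]})
        group = pd.Series(["tumor", "normal"], index=m.columns)
        out = xp.filter_low_counts(m, group)
        assert list(out.index) == [1]


class TestTmmFactors:
    def test_identical_libraries_give_unit_factors(self):
        m = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        assert np.allclose(xp.tmm_factors(m).values, 1.0)

    def test_pure_depth_difference_gives_unit_factors(self):
        # doubling every count changes depth, not composition
        a = np.array([13, 25, 8, 40, 100, 7])
        m = pd.DataFrame({"a": a, "b": 2 * a})
        assert np.allclose(xp.tmm_factors(m).values, 1.0, atol=1e-12)

    def test_matches_reference_implementation_on_fixture(self):
        # factors computed by the standard R implementation for this exact
        # seeded matrix (composition shift planted in library 3)
        rng = np.random.default_rng(123)
        m = rng.poisson(
            rng.lognormal(4, 1.2, 80)[:, None] * np.array([1.0, 0.6, 1.8, 1.1])[None, :]
        )
        m[:6, 2] *= 15
        expected = [1.1695236034, 1.1939790173, 0.5956626167, 1.2022477395]
        assert np.allclose(xp.tmm_factors(pd.DataFrame(m)).values, expected, atol=1e-6)

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.poisson(50, size=(100, 6)))
        f = xp.tmm_factors(m)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-10)

    def test_zero_total_library_rejected(self):
        m = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            xp.tmm_factors(m)


class TestAverageDuplicates:
    def test_pairwise_mean(self):
        m = pd.DataFrame([[1.0, 3.0], [3.0, 5.0]], index=["GAPDH", "GAPDH"])
        out = xp.average_duplicates(m)
        assert list(out.index) == ["GAPDH"]
        assert np.allclose(out.values, [[2.0, 4.0]])

    def test_triplicate_mean_and_order(self):
        m = pd.DataFrame(
            [[3.0], [1.0], [2.0], [7.0]], index=["A", "B", "A", "A"]
        )
        out = xp.average_duplicates(m)
        assert list(out.index) == ["A", "B"]
        assert out.loc["A"].iloc[0] == pytest.approx(4.0)

    def test_no_duplicates_unchanged(self):
        m = pd.DataFrame([[1.0], [2.0]], index=["A", "B"])
        pd.testing.assert_frame_equal(xp.average_duplicates(m), m)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        # 0.01*3/1, 0.02*3/2, 0.03*3/3 -> cummin from the largest = 0.03 each
        assert np.allclose(xp.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert xp.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_never_decreases_and_preserves_order(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(rng.integers(2, 40))
            q = xp.bh_adjust(p)
            assert (q >= p - 1e-15).all() and (q <= 1.0).all()
            # adjusted values are a monotone transform of the p-value ranking
            order = np.argsort(p)
            assert (np.diff(q[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            xp.bh_adjust([0.1, 1.5])


class TestModeratedDe:
    def test_equal_group_means_not_deg(self):
        rng = np.random.default_rng(1)
        base = rng.normal(8, 1, (50, 40))
        ds = make_ms_dataset(base, 20, 20)
        res = xp.moderated_de(ds, lfc_cut=0.5)
        null_gene = res.iloc[0]
        assert abs(null_gene["logFC"]) < 2  # sanity: no huge effects
        assert not res["is_deg"].all()

    def test_no_shrinkage_limit_equals_pooled_t(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(0, 1, (30, 20))
        ds = make_ms_dataset(mat, 12, 8)
        res = xp.moderated_de(ds, lfc_cut=0.5, prior_df=0)
        t_ref, p_ref = stats.ttest_ind(mat[:, :12], mat[:, 12:], axis=1, equal_var=True)
        assert np.allclose(res["t"].values, t_ref, atol=1e-8)
        assert np.allclose(res["p"].values, p_ref, atol=1e-8)

    def test_infinite_shrinkage_limit_closed_form(self):
        rng = np.random.default_rng(3)
        mat = rng.normal(0, 1, (30, 20))
        ds = make_ms_dataset(mat, 12, 8)
        v0 = 2.5
        res = xp.moderated_de(ds, lfc_cut=0.5, prior_df=np.inf, prior_var=v0)
        lfc = mat[:, :12].mean(axis=1) - mat[:, 12:].mean(axis=1)
        t_expected = lfc / np.sqrt(v0 * (1 / 12 + 1 / 8))
        assert np.allclose(res["t"].values, t_expected, atol=1e-10)

    def test_planted_effects_recovered(self):
        rng = np.random.default_rng(4)
        n = 30
        mat = rng.normal(8, 0.8, (100, 2 * n))
        mat[:20, :n] += 2.0  # planted 2-fold-change genes, tumour side
        ds = make_ms_dataset(mat, n, n)
        res = xp.moderated_de(ds, lfc_cut=1.0, p_cut=0.01)
        assert res["is_deg"][:20].mean() >= 0.9
        assert res["is_deg"][20:].mean() <= 0.02

    def test_single_group_rejected(self):
        ds = make_ms_dataset(np.ones((5, 4)), 4, 0)
        with pytest.raises(ValueError):
            xp.moderated_de(ds, lfc_cut=0.5)


class TestPreprocessChains:
    def test_ms_chain_produces_complete_log_matrix(self, small_world):
        _, _, datasets, _ = small_world
        ds = datasets[("AAA", xp.MS)]
        proc = xp.preprocess_ms(ds)
        assert not proc.matrix.isna().any().any()
        # log2 of positive intensities: values in a plausible log range
        assert proc.matrix.values.max() < 64

    def test_rnaseq_chain_normalises_depth(self, small_world):
        _, _, datasets, _ = small_world
        ds = datasets[("AAA", xp.RNASEQ)]
        proc = xp.preprocess_rnaseq(ds)
        # per-sample median log-CPM varies far less than raw depth does
        med = proc.matrix.median(axis=0)
        assert med.std() < 0.5
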
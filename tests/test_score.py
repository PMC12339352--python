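import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hyp

import saltol as st


def _score_from_index(index_matrix, threshold=0.8):
    """Membership/weights composition applied to a given index matrix."""
    res = st.index_pca_scores(index_matrix, retain_threshold=threshold)
    k = res.n_retained
    comps = list(res.scores.columns[:k])
    U = pd.DataFrame({c: st.membership(res.scores[c]) for c in comps},
                     index=res.scores.index)
    W = st.component_weights(res.proportion[:k])
    return st.comprehensive_score(U, W)


class TestToleranceIndex:
    def test_equal_values_give_100(self, noiseless_trial):
        table, _ = noiseless_trial
        same = table.copy()
        # make AK identical to CK
        ck = same[same.treatment == "CK"].copy()
        ak = ck.copy()
        ak["treatment"] = "AK"
        idx = st.tolerance_index(pd.concat([ck, ak]), 2016)
        assert np.allclose(idx.to_numpy(), 100.0)

    def test_formula(self):
        table = pd.DataFrame({
            "accession": ["a", "a"], "year": 2016, "treatment": ["CK", "AK"],
            "DW": [100.0, 50.0], "PH": [80.0, 80.0],
        })
        idx = st.tolerance_index(table, 2016)
        assert idx.loc["a", "DW"] == pytest.approx(50.0)
        assert idx.loc["a", "PH"] == pytest.approx(100.0)

    def test_known_ratio_recovered_exactly(self, noiseless_trial, noiseless_cfg):
        table, truth = noiseless_trial
        idx = st.tolerance_index(table, 2017)
        expected = 100.0 * truth.tolerance_ratio.loc[idx.index]
        for col in idx.columns:
            np.testing.assert_allclose(idx[col], expected, rtol=1e-10)

    def test_accession_missing_a_treatment_excluded(self, small_trial):
        table, _ = small_trial
        drop = table[~((table.accession == "S1") & (table.treatment == "AK"))]
        with pytest.warns(UserWarning, match="missing a treatment"):
            idx = st.tolerance_index(drop, 2016)
        assert "S1" not in idx.index

    def test_drop_sr(self, small_trial):
        table, _ = small_trial
        idx = st.tolerance_index(table, 2016, drop_sr=True)
        assert "SR" not in idx.columns and idx.shape[1] == 8


class TestMembership:
    def test_min_max(self):
        np.testing.assert_allclose(st.membership([2.0, 4.0, 6.0]), [0.0, 0.5, 1.0])

    @settings(derandomize=True, max_examples=30)
    @given(hyp.lists(hyp.floats(-1000, 1000).map(lambda v: round(v, 3)),
                     min_size=2, max_size=40, unique=True),
           hyp.floats(0.1, 50.0), hyp.floats(-100.0, 100.0))
    def test_affine_invariance_and_contract(self, scores, a, b):
        u = st.membership(scores)
        assert u.min() == 0.0 and u.max() == 1.0
        np.testing.assert_allclose(
            st.membership(a * np.asarray(scores) + b), u, atol=1e-7)

    def test_negative_scale_flips(self):
        s = np.array([1.0, 3.0, 7.0])
        np.testing.assert_allclose(st.membership(-s), 1.0 - st.membership(s))

    def test_degenerate_component(self):
        with pytest.warns(UserWarning, match="degenerate"):
            np.testing.assert_allclose(st.membership([2.0, 2.0, 2.0]), 0.5)


class TestWeights:
    def test_normalisation(self):
        np.testing.assert_allclose(
            st.component_weights([40.0, 30.0, 10.0]), [0.5, 0.375, 0.125])

    def test_single_component(self):
        np.testing.assert_allclose(st.component_weights([0.63]), [1.0])

    def test_permutation_equivariant(self):
        pv = np.array([0.4, 0.25, 0.15])
        perm = [2, 0, 1]
        np.testing.assert_allclose(
            st.component_weights(pv[perm]), st.component_weights(pv)[perm])

    def test_empty_or_nonpositive_raise(self):
        with pytest.raises(ValueError):
            st.component_weights([])
        with pytest.raises(ValueError):
            st.component_weights([0.5, 0.0])


class TestComprehensiveScore:
    def test_unit_and_zero_rows(self):
        U = pd.DataFrame([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]], index=["hi", "lo"])
        d, rank = st.comprehensive_score(U, [0.6, 0.3, 0.1])
        assert d["hi"] == pytest.approx(1.0)
        assert d["lo"] == pytest.approx(0.0)
        assert rank["hi"] == 1 and rank["lo"] == 2

    def test_dense_ranking_with_ties(self):
        U = pd.DataFrame({"PC1": [0.9, 0.9, 0.1]}, index=["a", "b", "c"])
        d, rank = st.comprehensive_score(U, [1.0])
        assert list(rank) == [1, 1, 2]

    def test_dimension_mismatch(self):
        U = pd.DataFrame(np.ones((3, 2)))
        with pytest.raises(ValueError):
            st.comprehensive_score(U, [1.0])


class TestScorePipeline:
    def test_identical_accessions_get_identical_scores(self, toy_index_matrix):
        table = []
        rng = np.random.default_rng(7)
        vals = rng.uniform(5, 20, size=(8, 4))
        traits = ["DW", "PH", "PL", "PW"]
        for i in range(8):
            for treat, mult in (("CK", 1.0), ("AK", 0.8 + 0.02 * i)):
                table.append({"accession": f"S{i}", "year": 2016, "treatment": treat,
                              **{t: vals[i, j] * mult for j, t in enumerate(traits)}})
        # clone accession S0 as S9
        clones = [dict(row, accession="S9") for row in table if row["accession"] == "S0"]
        df = pd.DataFrame(table + clones)
        res = st.ToleranceScoreModel(df, 2016).fit()
        assert res.D["S0"] == pytest.approx(res.D["S9"], abs=1e-12)
        assert res.rank["S0"] == res.rank["S9"]

    def test_bounds_and_weight_sum(self, small_trial):
        table, _ = small_trial
        res = st.ToleranceScoreModel(table, 2016).fit()
        assert res.W.sum() == pytest.approx(1.0)
        assert res.D.between(0, 1).all()
        for c in res.U.columns:
            assert res.U[c].min() == pytest.approx(0.0)
            assert res.U[c].max() == pytest.approx(1.0)
        assert res.pca.cumulative[res.n_retained - 1] >= 0.80

    def test_invariant_to_accession_and_trait_order(self, small_trial):
        table, _ = small_trial
        res = st.ToleranceScoreModel(table, 2016).fit()
        rng = np.random.default_rng(0)
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        cols = list(table.columns[:3]) + list(rng.permutation(table.columns[3:]))
        shuffled = shuffled[cols]
        res2 = st.ToleranceScoreModel(shuffled, 2016).fit()
        pd.testing.assert_series_equal(
            res.D.sort_index(), res2.D.sort_index(), atol=1e-10)

    def test_invariant_to_positive_column_rescaling(self, toy_index_matrix):
        d1, _ = _score_from_index(toy_index_matrix)
        scaled = toy_index_matrix.copy()
        scaled["PH"] = scaled["PH"] * 7.5
        d2, _ = _score_from_index(scaled)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    def test_rank_one_index_matches_raw_ordering(self):
        """Single latent direction: D ordering equals the index ordering."""
        base = np.linspace(40, 160, 10)
        mat = pd.DataFrame(
            {t: base * f for t, f in zip(["DW", "PH", "PL"], [1.0, 0.5, 2.0])},
            index=[f"S{i}" for i in range(10)],
        )
        d, rank = _score_from_index(mat)
        assert (d.loc[mat.index].diff().dropna() > 0).all()

    def test_shifting_one_trait_changes_index_not_flagged_invariant(self, small_trial):
        """Adding a constant to AK and CK of one trait changes Si and may move D."""
        table, _ = small_trial
        idx1 = st.tolerance_index(table, 2016)
        bumped = table.copy()
        bumped["DW"] = bumped["DW"] + 50.0
        idx2 = st.tolerance_index(bumped, 2016)
        assert not np.allclose(idx1["DW"], idx2["DW"])

    def test_golden_regression(self, small_trial):
        """Frozen end-to-end D values for the fixed small-trial seed."""
        table, _ = small_trial
        res = st.ToleranceScoreModel(table, 2016).fit()
        top = res.summary().head(3)
        # values computed by this pipeline at the fixture seed and locked in
        assert res.n_retained == 5
        expected = {"S63": 0.817351, "S118": 0.735780, "S42": 0.724489}
        for acc, val in expected.items():
            assert float(res.D[acc]) == pytest.approx(val, abs=1e-5)
        assert list(top.index[:1]) == ["S63"]

    def test_recovers_true_tolerance_ranking(self, small_trial):
        table, truth = small_trial
        from scipy.stats import spearmanr
        res = st.ToleranceScoreModel(table, 2016).fit()
        rho = spearmanr(res.D, truth.tolerance_ratio.loc[res.D.index]).statistic
        assert rho >= 0.8
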
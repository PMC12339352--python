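import numpy as np
import pandas as pd
import pytest
from scipy import stats

import saltol as st


VCF_TEXT = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=1,length=1000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc
1\t100\tm1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t200\tm2\tC\tT\t.\tPASS\t.\tGT\t./.\t0/0\t0/1
1\t300\tm3\tG\tA,C\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t400\tm4\tT\tC\t.\tPASS\t.\tGT\t1/1\t1/1\t1/1
"""


class TestReadGenotypes:
    @pytest.fixture()
    def vcf_path(self, tmp_path):
        p = tmp_path / "toy.vcf"
        p.write_text(VCF_TEXT)
        return p

    def test_gt_coding_and_missing(self, vcf_path):
        with pytest.warns(UserWarning, match="multiallelic"):
            gm = st.read_genotypes(vcf_path)
        assert list(gm.accessions) == ["a", "b", "c"]
        np.testing.assert_array_equal(gm.dosages["m1"], [0.0, 1.0, 2.0])
        assert np.isnan(gm.dosages.loc["a", "m2"])
        assert "m3" not in gm.dosages.columns  # multiallelic skipped
        assert gm.maf()["m1"] == pytest.approx(0.5)

    def test_filter_markers(self, vcf_path):
        with pytest.warns(UserWarning):
            gm = st.read_genotypes(vcf_path)
        # identity filter
        same = st.filter_markers(gm, maf_min=0.0, missing_max=1.0)
        assert same.n_markers == gm.n_markers
        # m4 monomorphic -> removed; m2 has 1/3 missing -> removed at 0.2
        filtered = st.filter_markers(gm, maf_min=0.05, missing_max=0.2)
        assert list(filtered.dosages.columns) == ["m1"]
        # brute-force recount of removals
        maf, miss = gm.maf(), gm.missing_rate()
        brute = sum(1 for m in gm.dosages.columns
                    if maf[m] < 0.05 or miss[m] > 0.2)
        assert filtered.filter_report["n_input"] - filtered.filter_report["n_kept"] == brute


class TestKinship:
    def test_hand_computed_oracle(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 3, size=(5, 8)).astype(float)
        markers = pd.DataFrame({
            "marker": [f"S1_{100 + i}" for i in range(8)], "chrom": "1",
            "pos": np.arange(100, 108), "ref": "A", "alt": "G"})
        gm = st.GenotypeMatrix(
            pd.DataFrame(M, index=[f"s{i}" for i in range(5)],
                         columns=markers["marker"]), markers)
        K = st.kinship(gm).to_numpy()
        p = M.mean(axis=0) / 2
        Z = M - 2 * p
        expected = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = np.dot(Z[i], Z[j]) / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, expected, atol=1e-12)
        np.testing.assert_allclose(K, K.T, atol=1e-12)

    def test_duplicated_accession_rows(self, small_geno):
        dos = small_geno.dosages.iloc[:10].copy()
        dos.iloc[1] = dos.iloc[0]
        gm = st.GenotypeMatrix(dos, small_geno.markers.copy())
        K = st.kinship(gm)
        assert K.iloc[0, 1] == pytest.approx(K.iloc[0, 0])

    def test_mean_diagonal_near_one(self, small_geno):
        K = st.kinship(small_geno)
        assert np.diag(K.to_numpy()).mean() == pytest.approx(1.0, abs=0.15)


class TestBonferroni:
    def test_values(self):
        assert round(st.bonferroni_threshold(189_019), 2) == 5.28
        assert st.bonferroni_threshold(10) == pytest.approx(1.0)
        assert st.bonferroni_threshold(1) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            st.bonferroni_threshold(0)


def _identity_kinship(accessions):
    n = len(accessions)
    return pd.DataFrame(np.eye(n), index=accessions, columns=accessions)


class TestMlmScan:
    def test_reduces_to_ols_with_identity_kinship(self, small_geno, small_trial):
        table, _ = small_trial
        d = st.ToleranceScoreModel(table, 2016).fit().D
        gm = small_geno.filter_markers()
        res = st.MixedLMGwas(d, gm, K=_identity_kinship(list(gm.accessions)),
                             n_pcs=0).fit()
        y = d.loc[gm.accessions].to_numpy()
        M = gm.imputed()
        for j in [0, 5, 50, 120]:
            ols = stats.linregress(M[:, j], y)
            assert res.table["p"].iloc[j] == pytest.approx(ols.pvalue, abs=1e-6)
            assert res.table["beta"].iloc[j] == pytest.approx(ols.slope, rel=1e-8)

    def test_accession_permutation_invariance(self, small_geno, small_trial):
        table, _ = small_trial
        d = st.ToleranceScoreModel(table, 2016).fit().D
        gm = small_geno.filter_markers()
        res1 = st.MixedLMGwas(d, gm, n_pcs=2).fit()
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(d))
        gm2 = st.GenotypeMatrix(gm.dosages.iloc[perm], gm.markers.copy())
        res2 = st.MixedLMGwas(d.iloc[perm], gm2, n_pcs=2).fit()
        np.testing.assert_allclose(res1.table["p"], res2.table["p"], rtol=1e-6)

    def test_significance_flagging_matches_brute_force(self, small_geno, small_trial):
        table, _ = small_trial
        d = st.ToleranceScoreModel(table, 2016).fit().D
        res = st.MixedLMGwas(d, small_geno.filter_markers(), n_pcs=2).fit()
        brute = {rec.marker for rec in res.table.itertuples()
                 if rec.neglog10p >= res.threshold}
        assert set(res.significant["marker"]) == brute
        assert (res.table["p"] > 0).all() and (res.table["p"] <= 1).all()
        assert (res.table["neglog10p"] >= 0).all()

    def test_planted_causal_marker_is_top_hit(self, small_geno, small_trial):
        table, truth = small_trial
        d = st.ToleranceScoreModel(table, 2016).fit().D
        res = st.MixedLMGwas(d, small_geno.filter_markers(), n_pcs=3).fit()
        top = res.table.loc[res.table["p"].idxmin(), "marker"]
        assert top in truth.causal_marker_ids

    def test_misaligned_phenotype_raises(self, small_geno):
        bad = pd.Series(np.zeros(5), index=list("abcde"))
        with pytest.raises(ValueError, match="accessions"):
            st.MixedLMGwas(bad, small_geno)


class TestExports:
    @pytest.fixture()
    def uniform_result(self):
        rng = np.random.default_rng(10)
        m = 2000
        chroms = np.repeat([str(c) for c in range(1, 5)], m // 4)
        pos = np.concatenate([np.sort(rng.choice(10**6, m // 4, replace=False))
                              for _ in range(4)])
        p = rng.uniform(size=m)
        tab = pd.DataFrame({
            "marker": [f"S{c}_{x}" for c, x in zip(chroms, pos)],
            "chrom": chroms, "pos": pos, "beta": 0.0, "se": 1.0, "p": p,
            "neglog10p": -np.log10(p)})
        from saltol.gwas import GwasResults
        return GwasResults(tab, st.bonferroni_threshold(m), 1.0, 1.0, 100, 0)

    def test_qq_near_diagonal_for_uniform_p(self, uniform_result):
        qq = uniform_result.qq_frame()
        assert len(qq) == uniform_result.table.shape[0]
        # DKW-style bound on the bulk of the distribution
        mask = qq["expected_neglog10p"] < 2
        dev = (qq["expected_neglog10p"] - qq["observed_neglog10p"])[mask]
        assert np.abs(dev).max() < 0.35

    def test_qq_expected_column_sorted(self, uniform_result):
        qq = uniform_result.qq_frame()
        assert (np.diff(qq["expected_neglog10p"]) <= 0).all()

    def test_manhattan_cumulative_coordinates_increase(self, uniform_result):
        man = uniform_result.manhattan_frame()
        assert (np.diff(man["cum_pos"]) > 0).all()

    def test_export_writes_files(self, uniform_result, tmp_path):
        uniform_result.export(tmp_path)
        for name in ("gwas_scan.tsv", "gwas_significant.tsv",
                     "manhattan.tsv", "qq.tsv"):
            assert (tmp_path / name).exists()
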
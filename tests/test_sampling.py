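"""Quantile normalization, correlation estimation, and copula sampling."""

import numpy as np
import pytest
from scipy import stats

from popfba.proteomics import CalibrationModel, ProteinMarginal
from popfba.sampling import (CellCounts, CorrelationModel, ExpressionMatrix,
                             compute_correlations, nearest_psd_correlation,
                             quantile_normalize, sample_population)

IDENT = CalibrationModel(a=1.0, b=1.0, floor=1e-12)


def gamma_marginal(pid, mean, cv):
    shape = 1.0 / cv ** 2
    return ProteinMarginal(pid, shape, mean / shape, 18)


class TestQuantileNormalize:
    def test_identical_arrays_unchanged(self):
        m = ExpressionMatrix(np.array([[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]]),
                             ["g1", "g2", "g3"], ["a1", "a2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_order_statistic_means(self):
        """[1,3,5] and [2,4,8] both become [1.5,3.5,6.5] in rank order."""
        m = ExpressionMatrix(np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 8.0]]),
                             ["g1", "g2", "g3"], ["a1", "a2"])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values,
                                   [[1.5, 1.5], [3.5, 3.5], [6.5, 6.5]])

    def test_rank_order_preserved_tie_free(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 100, size=(40, 5))
        m = ExpressionMatrix(x, [f"g{i}" for i in range(40)],
                             [f"a{j}" for j in range(5)])
        out = quantile_normalize(m)
        ref = np.sort(out.values[:, 0])
        for j in range(5):
            # within-array ranks preserved
            assert (np.argsort(x[:, j]) == np.argsort(out.values[:, j])).all()
            # all arrays share one empirical distribution afterwards
            np.testing.assert_allclose(np.sort(out.values[:, j]), ref)

    def test_ties_get_mean_of_target_values(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, size=(30, 4))
        x[3] = x[7]  # tie within every array
        m = ExpressionMatrix(x, [f"g{i}" for i in range(30)],
                             [f"a{j}" for j in range(4)])
        out = quantile_normalize(m)
        target = np.sort(x, axis=0).mean(axis=1)
        for j in range(4):
            np.testing.assert_allclose(out.values[3, j], out.values[7, j])
            # tied pair receives the mean of its two target order statistics
            k = np.searchsorted(np.sort(x[:, j]), x[3, j])
            np.testing.assert_allclose(out.values[3, j],
                                       0.5 * (target[k] + target[k + 1]))


class TestCorrelations:
    def arrays(self, n=40):
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        return x, rng

    def test_duplicate_and_anticorrelated_genes(self):
        x, rng = self.arrays()
        vals = np.vstack([x, x + 0.0, -x, rng.normal(size=x.size)])
        m = ExpressionMatrix(vals, ["g1", "g1b", "g1neg", "g2"],
                             [f"a{i}" for i in range(x.size)])
        cm = compute_correlations(m)
        i = cm.gene_ids.index
        assert cm.R[i("g1"), i("g1b")] == pytest.approx(1.0)
        assert cm.R[i("g1"), i("g1neg")] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(cm.R), 1.0)

    def test_probe_averaging(self):
        x, rng = self.arrays()
        noise = rng.normal(scale=0.1, size=x.size)
        vals = np.vstack([x + noise, x - noise, rng.normal(size=x.size)])
        m = ExpressionMatrix(vals, ["p1", "p2", "p3"],
                             [f"a{i}" for i in range(x.size)])
        cm = compute_correlations(m, probe_map={"gA": ["p1", "p2"],
                                                "gB": ["p3"]})
        assert cm.gene_ids == ["gA", "gB"]
        # probe mean is exactly x, so gA correlates 1 with itself only
        assert abs(cm.R[0, 1]) < 0.5

    def test_zero_variance_gene_zeroed(self, caplog):
        x, rng = self.arrays()
        vals = np.vstack([x, np.full(x.size, 3.0)])
        m = ExpressionMatrix(vals, ["g1", "gflat"],
                             [f"a{i}" for i in range(x.size)])
        with caplog.at_level("WARNING"):
            cm = compute_correlations(m)
        assert cm.R[0, 1] == 0.0
        assert cm.R[1, 1] == 1.0
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_psd_repair_clips_negative_eigenvalues(self):
        """An indefinite pseudo-correlation matrix is repaired to PSD with
        unit diagonal; oracle: eigendecomposition of the repaired matrix."""
        R = np.array([[1.0, 0.95, 0.0],
                      [0.95, 1.0, 0.95],
                      [0.0, 0.95, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0  # genuinely indefinite
        fixed = nearest_psd_correlation(R)
        w = np.linalg.eigvalsh(fixed)
        assert w.min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)
        cm = CorrelationModel(["a", "b", "c"], R)
        np.testing.assert_allclose(cm.L @ cm.L.T, nearest_psd_correlation(R),
                                   atol=1e-8)


class TestCopulaSampling:
    def test_independent_pair_uncorrelated(self):
        margs = [gamma_marginal("A", 100, 0.3), gamma_marginal("B", 50, 0.5)]
        cm = CorrelationModel.identity(["A", "B"])
        n = 10_000
        cc = sample_population(n, margs, cm, IDENT, seed=0)
        r = np.corrcoef(cc.values.T)[0, 1]
        assert abs(r) < 3 / np.sqrt(n)

    def test_marginal_mean_recovered(self):
        """gamma(shape=4, scale=25): sample mean within 3 SE of 100."""
        margs = [ProteinMarginal("A", 4.0, 25.0, 18)]
        n = 10_000
        cc = sample_population(n, margs, None, IDENT, seed=1)
        se = np.sqrt(4) * 25 / np.sqrt(n)
        assert abs(cc.values.mean() - 100.0) < 3 * se

    def test_spearman_matches_copula_closed_form(self):
        """Normal-scale rho=0.9 gives Spearman 6/pi*arcsin(rho/2)."""
        margs = [gamma_marginal("A", 100, 0.4), gamma_marginal("B", 20, 0.8)]
        R = np.array([[1.0, 0.9], [0.9, 1.0]])
        cm = CorrelationModel(["A", "B"], R)
        cc = sample_population(50_000, margs, cm, IDENT, seed=2)
        rho_s = stats.spearmanr(cc.values[:, 0], cc.values[:, 1]).statistic
        assert rho_s == pytest.approx(6 / np.pi * np.arcsin(0.45), abs=0.03)

    def test_marginals_preserved_under_correlation(self):
        """Correlated and independent sampling give the same per-protein
        count distribution (two-sample KS p > 0.01 at n=10,000)."""
        margs = [gamma_marginal("A", 100, 0.3), gamma_marginal("B", 50, 0.5),
                 gamma_marginal("C", 2000, 0.2)]
        R = np.array([[1.0, 0.8, -0.5], [0.8, 1.0, -0.3], [-0.5, -0.3, 1.0]])
        cm = CorrelationModel(["A", "B", "C"], R)
        corr_cc = sample_population(10_000, margs, cm, IDENT, seed=3)
        ind_cc = sample_population(10_000, margs, None, IDENT, seed=4)
        for j in range(3):
            p = stats.ks_2samp(corr_cc.values[:, j], ind_cc.values[:, j]).pvalue
            assert p > 0.01

    def test_latent_correlation_recovered(self):
        """Imposed normal-scale correlations are recovered entrywise to
        +/-0.02 at n=50,000 on the latent z (checked via normal scores)."""
        margs = [gamma_marginal(g, 100, 0.4) for g in "ABCD"]
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.7
        R[2, 3] = R[3, 2] = -0.4
        cm = CorrelationModel(list("ABCD"), R)
        cc = sample_population(50_000, margs, cm, IDENT, seed=5)
        # invert the marginal transform back to the latent normal scale
        z = np.empty_like(cc.values)
        for j, m in enumerate(margs):
            u = stats.gamma.cdf(cc.values[:, j], a=m.shape, scale=m.scale)
            z[:, j] = stats.norm.ppf(np.clip(u, 1e-12, 1 - 1e-12))
        Rhat = np.corrcoef(z.T)
        assert np.abs(Rhat - R).max() < 0.02

    def test_bit_reproducible(self):
        margs = [gamma_marginal("A", 100, 0.3), gamma_marginal("B", 50, 0.5)]
        cm = CorrelationModel(["A", "B"], np.array([[1.0, 0.5], [0.5, 1.0]]))
        a = sample_population(500, margs, cm, IDENT, seed=11)
        b = sample_population(500, margs, cm, IDENT, seed=11)
        np.testing.assert_array_equal(a.values, b.values)

    def test_floor_and_subset_handling(self):
        cal = CalibrationModel(a=2.87, b=1.5577)
        margs = [gamma_marginal("A", 0.5, 0.9), gamma_marginal("X", 100, 0.3)]
        cm = CorrelationModel.identity(["A", "B"])  # X absent from corr
        cc = sample_population(2000, margs, cm, cal, seed=6)
        assert cc.values.min() >= cal.floor
        assert set(cc.protein_ids) == {"A", "X"}

    def test_invalid_inputs(self):
        margs = [gamma_marginal("A", 100, 0.3)]
        with pytest.raises(ValueError):
            sample_population(0, margs, None, IDENT, seed=0)
        with pytest.raises(ValueError):
            sample_population(10, [], None, IDENT, seed=0)

    def test_cell_counts_roundtrip(self, tmp_path):
        cc = CellCounts(np.array([[1.0, 2.0], [3.0, 4.0]]), ["A", "B"], 0)
        path = tmp_path / "counts.tsv"
        cc.to_tsv(path)
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(df.to_numpy(), cc.values)
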
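"""Preprocessing: TMM/CPM, metabolite filters, KNN imputation, QC."""

import numpy as np
import pandas as pd
import pytest

from omicsblup.preprocess import (
    FeatureModelSpec,
    GenotypeQCError,
    LibrarySizeError,
    filter_metabolites,
    knn_impute,
    normalize_counts,
    qc_genotypes,
    residualize_features,
    tmm_factors,
    validate_imputation,
)

from conftest import toy_design


class TestNormalizeCounts:
    def test_identical_rows_give_identical_output_and_unit_factors(self, rng):
        row = rng.poisson(50, size=30)
        counts = pd.DataFrame([row, row], index=["a", "b"])
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)
        out = normalize_counts(counts)
        assert np.allclose(out.loc["a"], out.loc["b"])

    def test_cpm_arithmetic_on_dominant_gene(self):
        # one gene carries 999,999 of a million reads: its log-CPM is
        # log2(999999 * 1e6 / 1e6 + 1) = log2(1e6)
        counts = pd.DataFrame(
            {"g1": [999_999, 999_999], "g2": [1, 1]}, index=["a", "b"]
        )
        out = normalize_counts(counts)
        assert out.loc["a", "g1"] == pytest.approx(np.log2(1e6))
        assert out.loc["a", "g1"] == pytest.approx(19.93, abs=0.01)

    def test_library_scaling_invariance(self, rng):
        # doubling one animal's counts must not change its profile
        base = rng.poisson(rng.gamma(2, 30, size=200), size=(5, 200))
        counts = pd.DataFrame(base, dtype=float)
        doubled = counts.copy()
        doubled.iloc[2] = counts.iloc[2] * 2
        # pin the reference (doubling a library shifts the automatic
        # 75th-percentile pick) and use unweighted TMM: the precision
        # weights depend on absolute counts, so exact invariance holds
        # only for the unweighted mean of M-values
        a = normalize_counts(counts, ref_animal=0, weighted=False)
        b = normalize_counts(doubled, ref_animal=0, weighted=False)
        assert np.abs(a.to_numpy() - b.to_numpy()).max() < 1e-6

    def test_tmm_matches_direct_definition(self, rng):
        # independent re-derivation: weighted trimmed mean of M-values
        # against the reference, on a small matrix
        mu = rng.gamma(2, 40, size=80)
        X = np.vstack([rng.poisson(mu * s) for s in (1.0, 2.0, 0.5)]) + 1
        counts = pd.DataFrame(X, index=["a", "b", "c"])
        f = tmm_factors(counts)
        lib = X.sum(axis=1)
        r = int(np.argmin(np.abs(lib - np.percentile(lib, 75))))
        raw = np.ones(3)
        for i in range(3):
            if i == r:
                continue
            fi, fr = X[i] / lib[i], X[r] / lib[r]
            M = np.log2(fi / fr)
            A = 0.5 * (np.log2(fi) + np.log2(fr))
            n = M.size
            rank_m = np.argsort(np.argsort(M)) + 1
            rank_a = np.argsort(np.argsort(A)) + 1
            lo_m = np.floor(n * 0.30) + 1
            lo_a = np.floor(n * 0.05) + 1
            keep = ((rank_m >= lo_m) & (rank_m <= n + 1 - lo_m)
                    & (rank_a >= lo_a) & (rank_a <= n + 1 - lo_a))
            w = 1.0 / ((lib[i] - X[i]) / (lib[i] * X[i])
                       + (lib[r] - X[r]) / (lib[r] * X[r]))
            raw[i] = 2 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f.to_numpy(), expected, atol=1e-12)

    def test_zero_library_rejected(self):
        counts = pd.DataFrame({"g1": [0, 5], "g2": [0, 5]}, index=["a", "b"])
        with pytest.raises(LibrarySizeError):
            normalize_counts(counts)


class TestFilterMetabolites:
    def _matrix(self):
        return pd.DataFrame(
            np.ones((10, 3)) * 4.0,
            index=[f"a{i}" for i in range(10)],
            columns=["keep", "missing20", "lod20"],
        )

    def test_missing_boundary_is_inclusive(self):
        vals = self._matrix()
        vals.iloc[0:2, 1] = np.nan  # exactly 20% generic missing -> drop
        out, report = filter_metabolites(vals)
        assert "missing20" not in out.columns
        assert report.set_index("feature_id").loc[
            "missing20", "drop_reason"] == "missing>=threshold"

    def test_lod_boundary_is_exclusive(self):
        vals = self._matrix()
        lod = pd.DataFrame(False, index=vals.index, columns=vals.columns)
        vals.iloc[0:2, 2] = np.nan  # exactly 20% sub-LOD -> retained
        lod.iloc[0:2, 2] = True
        out, _ = filter_metabolites(vals, lod)
        assert "lod20" in out.columns
        vals.iloc[2, 2] = np.nan  # 30% sub-LOD -> dropped
        lod.iloc[2, 2] = True
        out2, _ = filter_metabolites(vals, lod)
        assert "lod20" not in out2.columns

    def test_median_imputation(self):
        vals = pd.DataFrame({
            "f": [1.0, 2.0, np.nan, 4.0],
            "pad1": [1.0] * 4, "pad2": [1.0] * 4, "pad3": [1.0] * 4,
            "pad4": [1.0] * 4, "pad5": [1.0] * 4, "pad6": [1.0] * 4,
            "pad7": [1.0] * 4, "pad8": [1.0] * 4, "pad9": [1.0] * 4,
        })
        out, _ = filter_metabolites(vals)
        # 25% missing would be dropped at n=4; use threshold above it
        out, _ = filter_metabolites(vals, missing_threshold=0.3)
        assert 2 ** out.loc[2, "f"] == pytest.approx(2.0)

    def test_all_missing_feature_dropped(self):
        vals = self._matrix()
        vals.iloc[:, 1] = np.nan
        out, report = filter_metabolites(vals)
        assert "missing20" not in out.columns

    def test_idempotence(self, rng):
        vals = pd.DataFrame(
            rng.lognormal(1, 0.5, size=(20, 8)),
            columns=[f"m{j}" for j in range(8)],
        )
        vals[vals < 0.8] = np.nan
        once, _ = filter_metabolites(vals)
        twice, _ = filter_metabolites(2 ** once)
        pd.testing.assert_frame_equal(once, twice)


class TestKnnImpute:
    def test_complete_matrix_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(size=(15, 6)))
        out = knn_impute(df, k=3)
        pd.testing.assert_frame_equal(out, df)

    def test_perfect_neighbor_k1(self):
        # feature b = 2*a + 5: after mean/SD alignment the imputed value
        # equals the value implied by the neighbor
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        df = pd.DataFrame({
            "a": a, "b": 2 * a + 5.0, "c": [9.0, 1.0, 7.0, 3.0, 5.0],
        })
        df.loc[2, "b"] = np.nan
        out = knn_impute(df, k=1)
        mu_b = np.nanmean(df["b"])
        sd_b = np.nanstd(df["b"])
        mu_a, sd_a = df["a"].mean(), df["a"].std(ddof=0)
        expected = mu_b + (df.loc[2, "a"] - mu_a) / sd_a * sd_b
        assert out.loc[2, "b"] == pytest.approx(expected)

    def test_matches_bruteforce_oracle(self, rng):
        df = pd.DataFrame(rng.normal(size=(50, 20)),
                          columns=[f"f{j}" for j in range(20)])
        mask = rng.random(df.shape) < 0.05
        holed = df.mask(mask)
        out = knn_impute(holed, k=5)
        expected = _bruteforce_knn(holed.to_numpy(), k=5)
        assert np.allclose(out.to_numpy(), expected, atol=1e-10)

    def test_rejects_oversized_k(self, rng):
        df = pd.DataFrame(rng.normal(size=(10, 4)))
        df.iloc[0, 0] = np.nan
        with pytest.raises(ValueError):
            knn_impute(df, k=4)


def _bruteforce_knn(X: np.ndarray, k: int) -> np.ndarray:
    """Naive loop re-implementation of feature-wise KNN imputation."""
    n, p = X.shape
    out = X.copy()
    mu = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    Z = (X - mu) / sd  # distances computed on z-scored features
    for j in range(p):
        for i in range(n):
            if not np.isnan(X[i, j]):
                continue
            dists = []
            for q in range(p):
                if q == j or np.isnan(X[i, q]):
                    continue
                both = ~np.isnan(X[:, j]) & ~np.isnan(X[:, q])
                if both.sum() == 0:
                    continue
                d = np.sqrt(np.mean((Z[both, j] - Z[both, q]) ** 2))
                dists.append((d, q))
            dists.sort(key=lambda t: t[0])
            vals = [
                mu[j] + (X[i, q] - mu[q]) / sd[q] * sd[j]
                for _, q in dists[:k]
            ]
            out[i, j] = np.mean(vals)
    return out


class TestValidateImputation:
    def test_linear_copies_fully_recoverable(self, rng):
        # ten exact linear transforms of one base vector: whichever
        # features are masked, a perfect neighbor remains observed
        z = rng.normal(size=40)
        df = pd.DataFrame(
            {f"f{j}": (j + 1.0) * z + j for j in range(10)}
        )
        acc, retained = validate_imputation(
            df, n_masked_features=4, n_repeats=5, seed=1, k=1
        )
        masked = acc.dropna()
        assert (masked > 0.99).all()
        assert set(retained) == set(masked.index)

    def test_pure_noise_not_retained(self, rng):
        df = pd.DataFrame(rng.normal(size=(100, 30)),
                          columns=[f"f{j}" for j in range(30)])
        acc, retained = validate_imputation(
            df, n_masked_features=10, n_repeats=20, seed=2, k=5
        )
        assert abs(acc.dropna().mean()) < 0.1
        assert retained == []

    def test_correlated_block_retained_noise_dropped(self, rng):
        # 10 features sharing a latent factor (pairwise r ~ 0.9) among
        # 20 independent features: the block is recoverable, the rest not
        n = 80
        z = rng.normal(size=n)
        block = np.sqrt(0.9) * z[:, None] + np.sqrt(0.1) * rng.normal(
            size=(n, 10)
        )
        noise = rng.normal(size=(n, 20))
        df = pd.DataFrame(
            np.hstack([block, noise]),
            columns=[f"b{j}" for j in range(10)]
            + [f"n{j}" for j in range(20)],
        )
        acc, retained = validate_imputation(
            df, n_masked_features=30, n_repeats=20, seed=3, k=5
        )
        assert set(retained) == {f"b{j}" for j in range(10)}

    def test_retention_monotone_in_generating_correlation(self, rng):
        # stronger latent correlation -> higher imputation accuracy
        n = 80
        accs = []
        for rho in (0.1, 0.5, 0.9):
            z = rng.normal(size=n)
            X = (np.sqrt(rho) * z[:, None]
                 + np.sqrt(1 - rho) * rng.normal(size=(n, 8)))
            df = pd.DataFrame(X, columns=[f"f{j}" for j in range(8)])
            acc, _ = validate_imputation(
                df, n_masked_features=8, n_repeats=10, seed=4, k=3
            )
            accs.append(acc.mean())
        assert accs[0] < accs[1] < accs[2]

    def test_warns_when_fewer_features_than_requested(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)))
        with pytest.warns(UserWarning, match="fewer features"):
            validate_imputation(df, n_masked_features=100, n_repeats=2,
                                seed=0, k=2)


class TestResidualizeFeatures:
    def test_columns_standardized(self, rng):
        design = toy_design(48)
        vals = pd.DataFrame(
            rng.normal(size=(48, 12)), index=design["animal_id"],
            columns=[f"f{j}" for j in range(12)],
        )
        M = residualize_features(vals, FeatureModelSpec("proteome"), design)
        assert np.abs(M.values.mean(axis=0)).max() < 1e-8
        assert np.abs(M.values.var(axis=0) - 1.0).max() < 1e-6

    def test_zero_pen_variance_collapses_to_ols(self, rng):
        # features with no pen structure: residuals equal OLS residuals
        design = toy_design(40, pens_per_batch=2)
        vals = pd.DataFrame(
            rng.normal(size=(40, 6)), index=design["animal_id"],
            columns=[f"f{j}" for j in range(6)],
        )
        spec = FeatureModelSpec("metabolome", fixed_terms=["batch"])
        M = residualize_features(vals, spec, design)
        X = pd.get_dummies(design["batch"], drop_first=True)
        X = np.hstack([np.ones((40, 1)), X.to_numpy(float)])
        H = X @ np.linalg.solve(X.T @ X, X.T)
        R = vals.to_numpy() - H @ vals.to_numpy()
        R = (R - R.mean(axis=0)) / R.std(axis=0, ddof=0)
        # most features should sit at the lambda=0 boundary; compare those
        at_zero = M.report["pen_to_residual_ratio"].to_numpy() == 0.0
        assert at_zero.mean() > 0.5
        assert np.allclose(M.values[:, at_zero], R[:, at_zero], atol=1e-8)

    def test_fixed_covariate_feature_dropped_as_degenerate(self, rng):
        design = toy_design(30)
        vals = pd.DataFrame(
            rng.normal(size=(30, 3)), index=design["animal_id"],
            columns=["ok1", "aliased", "ok2"],
        )
        vals["aliased"] = design["entry_age"].to_numpy(dtype=float)
        spec = FeatureModelSpec("proteome", fixed_terms=["entry_age"])
        with pytest.warns(UserWarning, match="degenerate"):
            M = residualize_features(vals, spec, design)
        assert "aliased" not in M.feature_ids

    def test_ratio_recovery_and_gls_oracle(self, rng):
        # 60 animals in 6 pens, true pen/residual ratio 1: the fitted
        # ratios bracket the truth, and residuals match a direct
        # V-inverse GLS computation at the fitted ratio
        n, n_pens, n_feat = 60, 6, 50
        design = toy_design(n, n_batches=1, pens_per_batch=n_pens, seed=5)
        Z = pd.get_dummies(design["pen"]).to_numpy(float)
        Y = np.empty((n, n_feat))
        for j in range(n_feat):
            pen_eff = rng.normal(0, 1, size=n_pens)
            Y[:, j] = 0.5 + Z @ pen_eff + rng.normal(0, 1, size=n)
        vals = pd.DataFrame(Y, index=design["animal_id"],
                            columns=[f"f{j}" for j in range(n_feat)])
        spec = FeatureModelSpec("metabolome", fixed_terms=["entry_age"])
        M = residualize_features(vals, spec, design)
        lam = M.report["pen_to_residual_ratio"].to_numpy()
        assert abs(np.mean(lam) - 1.0) <= 2 * np.std(lam, ddof=1)

        # GLS oracle: direct V^-1 path at the fitted ratio, per feature
        X = np.hstack([
            np.ones((n, 1)),
            (design["entry_age"] - design["entry_age"].mean())
            .to_numpy(float)[:, None],
        ])
        ZZt = Z @ Z.T
        for j in (0, 17, 42):
            V = np.eye(n) + lam[j] * ZZt
            Vinv = np.linalg.inv(V)
            b = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ Y[:, j])
            e_marg = Y[:, j] - X @ b
            cond = e_marg - lam[j] * ZZt @ Vinv @ e_marg
            cond = (cond - cond.mean()) / cond.std(ddof=0)
            assert np.allclose(M.values[:, j], cond, atol=1e-8)

    def test_residuals_orthogonal_to_fixed_design(self, rng):
        design = toy_design(36)
        vals = pd.DataFrame(
            rng.normal(size=(36, 8)), index=design["animal_id"],
            columns=[f"f{j}" for j in range(8)],
        )
        spec = FeatureModelSpec("proteome", fixed_terms=["entry_age"],
                                random_pen=False)
        M = residualize_features(vals, spec, design)
        age = (design["entry_age"] - design["entry_age"].mean()).to_numpy()
        for j in range(M.p):
            r = np.corrcoef(M.values[:, j], age)[0, 1]
            assert abs(r) < 1e-6


class TestQcGenotypes:
    def test_maf_boundary_exclusive(self):
        # SNP with MAF exactly 0.05 is removed (rule is strictly greater)
        dos = pd.DataFrame({
            "maf05": [1] + [0] * 9,          # MAF = 0.05
            "maf10": [1, 1] + [0] * 8,       # MAF = 0.10
            "common": [0, 1, 2, 1, 0, 1, 2, 1, 0, 1],
        }, index=[f"a{i}" for i in range(10)], dtype=float)
        out, _ = qc_genotypes(dos)
        assert "maf05" not in out.columns
        assert "maf10" in out.columns

    def test_individual_call_rate(self):
        rng = np.random.default_rng(0)
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(10, 20)).astype(float),
            index=[f"a{i}" for i in range(10)],
        )
        dos.iloc[0, :3] = np.nan  # 15% missing -> removed
        out, rep = qc_genotypes(dos)
        assert "a0" not in out.index
        assert rep["n_animals_removed"] == 1

    def test_constructed_fixture_counts(self):
        # 10 animals x 8 SNPs built so exactly 3 SNPs and 1 animal fail:
        # s1 has call rate 9/10 (removed); animal a9 misses 1/8 calls
        # (rate 0.875, removed); s2 is monomorphic (MAF 0); s3 is
        # polymorphic only through a9, so after the animal filter its
        # MAF drops to 0 (removed) -- 5 SNPs x 9 animals survive
        data = {
            "s1": [1, 1, 0, 1, 2, 1, 0, 1, 2, np.nan],
            "s2": [0.0] * 10,
            "s3": [0, 0, 0, 0, 0, 0, 0, 0, 0, 2],
            "s4": [0, 1, 2, 1, 0, 1, 2, 1, 0, 1],
            "s5": [1, 1, 0, 2, 1, 0, 1, 2, 0, 1],
            "s6": [2, 1, 1, 0, 2, 1, 0, 1, 2, 0],
            "s7": [0, 0, 1, 1, 2, 2, 0, 1, 1, 2],
            "s8": [1, 2, 0, 1, 1, 0, 2, 1, 0, 1],
        }
        dos = pd.DataFrame(data, index=[f"a{i}" for i in range(10)],
                           dtype=float)
        out, rep = qc_genotypes(dos)
        assert out.shape == (9, 5)
        assert "a9" not in out.index
        assert set(out.columns) == {"s4", "s5", "s6", "s7", "s8"}
        assert not out.isna().any().any()

    def test_idempotence(self):
        rng = np.random.default_rng(1)
        dos = pd.DataFrame(
            rng.integers(0, 3, size=(30, 40)).astype(float),
            index=[f"a{i}" for i in range(30)],
        )
        dos[rng.random(dos.shape) < 0.05] = np.nan
        once, _ = qc_genotypes(dos)
        twice, _ = qc_genotypes(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_all_snps_removed_raises(self):
        dos = pd.DataFrame({"s": [0.0] * 10})
        with pytest.raises(GenotypeQCError):
            qc_genotypes(dos)
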
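"""Empirical-Bayes batch correction and surrogate-variable removal."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from diaq import ComBat, SurrogateVariableCorrector, TruthParams, simulate
from diaq.batch import fit_combat
from diaq.io import InputError
from diaq.pipeline import run_pipeline


def frame(Y, prefix="f"):
    Y = np.asarray(Y, dtype=float)
    return pd.DataFrame(Y, index=[f"r{i}" for i in range(Y.shape[0])],
                        columns=[f"{prefix}{j}" for j in range(Y.shape[1])])


def standardization_oracle(V: pd.DataFrame, batch: np.ndarray) -> pd.DataFrame:
    """Brute-force no-shrink corrector: per feature, standardize within batch
    (sample SD), then restore the batch-size-weighted pooled location and the
    pooled residual scale."""
    out = V.copy()
    levels, counts = np.unique(batch, return_counts=True)
    w = counts / counts.sum()
    for col in V.columns:
        y = V[col]
        means = {b: y[batch == b].mean() for b in levels}
        alpha = sum(wi * means[b] for wi, b in zip(w, levels))
        sigma = np.sqrt(np.mean([(v - means[b]) ** 2
                                 for v, b in zip(y, batch)]))
        for b in levels:
            sd_b = y[batch == b].std(ddof=1)
            out.loc[batch == b, col] = \
                sigma * (y[batch == b] - means[b]) / sd_b + alpha
    return out


class TestComBatNoShrink:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(0)
        X = frame(rng.normal(10, 1, (8, 5)))
        out = ComBat(shrink=False).fit(X, batch=np.repeat("b1", 8)).transform(X)
        np.testing.assert_allclose(out.to_numpy(), X.to_numpy(), atol=1e-9)

    def test_two_batches_equalize_to_pooled_mean(self):
        # one feature, batch means 10 and 12, equal spread
        y = np.array([9.0, 10.0, 11.0, 11.0, 12.0, 13.0])
        X = frame(y[:, None])
        batch = np.array(["a"] * 3 + ["b"] * 3)
        cb = ComBat(shrink=False).fit(X, batch=batch)
        out = cb.transform(X)
        assert out.iloc[:3, 0].mean() == pytest.approx(11.0, abs=1e-9)
        assert out.iloc[3:, 0].mean() == pytest.approx(11.0, abs=1e-9)
        # fitting constraint: batch-size-weighted gamma estimates sum to zero
        n = cb.batch_sizes_.to_numpy()
        assert float((n @ cb.gamma_hat_.to_numpy())[0]) == pytest.approx(
            0.0, abs=1e-9)

    def test_matches_standardization_oracle_on_random_instances(self):
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n_runs = int(rng.integers(8, 21))
            n_feat = int(rng.integers(2, 11))
            n_b = int(rng.integers(2, 4))
            batch = rng.permutation(
                np.concatenate([np.repeat(f"b{i}", 2) for i in range(n_b)]
                               + [rng.choice([f"b{i}" for i in range(n_b)],
                                             n_runs - 2 * n_b)]))
            X = frame(rng.normal(10, 1, (n_runs, n_feat))
                      + rng.normal(0, 1, (1, n_feat)))
            out = ComBat(shrink=False).fit(X, batch=batch).transform(X)
            oracle = standardization_oracle(X, batch)
            np.testing.assert_allclose(out.to_numpy(), oracle.to_numpy(),
                                       atol=1e-8)

    def test_batch_moments_equalized_after_correction(self):
        rng = np.random.default_rng(3)
        X = frame(rng.normal(0, 1, (20, 6))
                  + np.r_[np.zeros(10), np.full(10, 2.0)][:, None])
        batch = np.array(["a"] * 10 + ["b"] * 10)
        out = ComBat(shrink=False).fit(X, batch=batch).transform(X)
        for col in out.columns:
            a, b = out[col][:10], out[col][10:]
            assert a.mean() == pytest.approx(b.mean(), abs=1e-9)
            assert a.std(ddof=1) == pytest.approx(b.std(ddof=1), rel=1e-9)


class TestComBatShrink:
    def test_gamma_star_is_convex_combination(self):
        ds = simulate(TruthParams(n_proteins=40, n_strains=6,
                                  replicates_per_strain=6, seed=9))
        res = run_pipeline(ds.report, ds.design,
                           {"selection_enabled": False, "qc_enabled": False})
        cb = res.models["correct"]
        for i, b in enumerate(cb.batch_levels_):
            ok = cb.corrected_mask_.to_numpy()
            g_hat = cb.gamma_hat_.iloc[i].to_numpy()[ok]
            g_star = cb.gamma_star_.iloc[i].to_numpy()[ok]
            g_bar = float(cb.priors_.loc[b, "gamma_bar"])
            # gamma* lies between the feature estimate and the batch prior
            assert ((g_star - g_hat) * (g_star - g_bar) <= 1e-12).all()
            assert (np.abs(g_star) <=
                    np.maximum(np.abs(g_hat), abs(g_bar)) + 1e-12).all()

    def test_additive_recovery_two_batches(self):
        # >=500 features with planted N(0, 0.5^2) additive offsets
        ds = simulate(TruthParams(n_proteins=120, peptides_per_protein=(4, 5, 6),
                                  n_strains=8, replicates_per_strain=6,
                                  n_batches=2, batch_add_sd=0.5, seed=10))
        res = run_pipeline(ds.report, ds.design,
                           {"selection_enabled": False, "qc_enabled": False})
        cb = res.models["correct"]
        common = cb.gamma_star_.columns
        assert len(common) >= 500
        est = (cb.gamma_star_ * cb.sigma_).to_numpy()
        truth = ds.truth["batch_additive"][common]
        w = (cb.batch_sizes_ / cb.batch_sizes_.sum()).to_numpy()
        centered = truth.to_numpy() - (w[:, None] * truth.to_numpy()).sum(
            axis=0, keepdims=True)
        r = np.corrcoef(est.ravel(), centered.ravel())[0, 1]
        assert r > 0.9

    def test_covariate_contrast_preserved(self):
        # planted genotype effect must survive correction
        rng = np.random.default_rng(12)
        n_per = 10
        genotype = np.array((["wt"] * n_per + ["mut"] * n_per) * 2)
        batch = np.array(["b1"] * 2 * n_per + ["b2"] * 2 * n_per)
        effect = 1.5
        Y = (rng.normal(10, 0.3, (4 * n_per, 30))
             + np.where(genotype == "mut", effect, 0.0)[:, None]
             + np.where(batch == "b2", 2.0, 0.0)[:, None])
        X = frame(Y)
        cov = pd.DataFrame({"genotype": genotype}, index=X.index)
        out = ComBat(shrink=True).fit(X, batch=batch,
                                      covariates=cov).transform(X)
        diff = out[genotype == "mut"].mean() - out[genotype == "wt"].mean()
        np.testing.assert_allclose(diff, effect, atol=0.15)

    def test_matches_bioconductor_sva_combat(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        rng = np.random.default_rng(5)
        X = frame(rng.normal(12, 1, (12, 8))
                  + np.r_[np.zeros(6), np.full(6, 0.8)][:, None]
                  * rng.normal(1, 0.3, (1, 8)))
        batch = np.array(["A"] * 6 + ["B"] * 6)
        ours = ComBat(shrink=True, tol=1e-8, max_iter=500).fit(
            X, batch=batch).transform(X)
        X.T.to_csv(tmp_path / "m.csv")
        script = f"""
suppressMessages(library(sva))
m <- as.matrix(read.csv("{tmp_path}/m.csv", row.names=1))
out <- ComBat(dat=m, batch=c(rep("A",6), rep("B",6)), mod=NULL,
              par.prior=TRUE)
write.csv(out, "{tmp_path}/out.csv")
"""
        subprocess.run(["Rscript", "-e", script], check=True,
                       capture_output=True)
        theirs = pd.read_csv(tmp_path / "out.csv", index_col=0).T
        np.testing.assert_allclose(ours.to_numpy(), theirs.to_numpy(),
                                   atol=1e-4)


class TestComBatEdges:
    def test_missing_cells_stay_missing(self):
        rng = np.random.default_rng(4)
        X = frame(rng.normal(10, 1, (12, 6)))
        X.iloc[1, 2] = np.nan
        X.iloc[7, 0] = np.nan
        batch = np.array(["a"] * 6 + ["b"] * 6)
        out = ComBat(shrink=False).fit(X, batch=batch).transform(X)
        assert (out.isna() == X.isna()).all().all()

    def test_feature_with_sparse_batch_passes_through(self):
        rng = np.random.default_rng(6)
        X = frame(rng.normal(10, 1, (12, 4)))
        X.iloc[6:11, 0] = np.nan                 # batch b: single observation
        batch = np.array(["a"] * 6 + ["b"] * 6)
        cb = ComBat(shrink=False).fit(X, batch=batch)
        assert "f0" in cb.uncorrected_features_
        out = cb.transform(X)
        pd.testing.assert_series_equal(out["f0"], X["f0"])
        assert not out["f1"].equals(X["f1"])

    def test_confounded_covariate_reported(self):
        rng = np.random.default_rng(7)
        X = frame(rng.normal(10, 1, (10, 4)))
        batch = np.array(["a"] * 5 + ["b"] * 5)
        cov = pd.DataFrame({"site": ["x"] * 5 + ["y"] * 5}, index=X.index)
        with pytest.raises(InputError, match="site"):
            ComBat().fit(X, batch=batch, covariates=cov)

    def test_unknown_run_at_transform_rejected(self):
        rng = np.random.default_rng(8)
        X = frame(rng.normal(10, 1, (8, 4)))
        batch = np.array(["a"] * 4 + ["b"] * 4)
        cb = ComBat(shrink=False).fit(X, batch=batch)
        other = X.copy()
        other.index = [f"q{i}" for i in range(8)]
        with pytest.raises(InputError, match="absent"):
            cb.transform(other)

    def test_batch_with_single_run_rejected(self):
        rng = np.random.default_rng(9)
        X = frame(rng.normal(10, 1, (5, 3)))
        with pytest.raises(InputError, match="fewer than 2"):
            ComBat().fit(X, batch=np.array(["a"] * 4 + ["b"]))


class TestSurrogates:
    def test_rank_one_batch_pattern_recovered(self):
        rng = np.random.default_rng(13)
        n_runs, n_feat = 30, 80
        b = np.r_[np.zeros(15), np.ones(15)]
        load = rng.normal(0, 0.8, n_feat)
        X = frame(rng.normal(0, 0.05, (n_runs, n_feat)) + np.outer(b, load))
        sva = SurrogateVariableCorrector(control_fraction=1.0, k=1).fit(X)
        r = np.corrcoef(sva.surrogates_["SV1"], b)[0, 1]
        assert abs(r) > 0.95

    def test_iid_noise_yields_k_zero_under_permutation_rule(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = frame(rng.normal(0, 1, (15, 40)))
            sva = SurrogateVariableCorrector(control_fraction=1.0, k="auto",
                                             random_state=seed).fit(X)
            hits += sva.k_ == 0
        assert hits >= 18

    def test_constant_matrix_gives_k_zero_and_identity(self):
        X = frame(np.full((6, 12), 3.0))
        sva = SurrogateVariableCorrector(k="auto").fit(X)
        assert sva.k_ == 0
        pd.testing.assert_frame_equal(sva.transform(X), X)

    def test_k_zero_transform_is_identity(self):
        rng = np.random.default_rng(14)
        X = frame(rng.normal(0, 1, (8, 10)))
        sva = SurrogateVariableCorrector(k="auto", random_state=0).fit(X)
        if sva.k_ == 0:
            pd.testing.assert_frame_equal(sva.transform(X), X)

    def test_feature_equal_to_surrogate_becomes_constant(self):
        rng = np.random.default_rng(15)
        X = frame(rng.normal(0, 1, (20, 30)))
        sva = SurrogateVariableCorrector(control_fraction=1.0, k=1).fit(X)
        X2 = X.copy()
        X2["probe"] = sva.surrogates_["SV1"] + 5.0
        out = sva.transform(X2)
        np.testing.assert_allclose(out["probe"], 5.0, atol=1e-9)

    def test_residuals_orthogonal_to_surrogates(self):
        rng = np.random.default_rng(16)
        X = frame(rng.normal(0, 1, (25, 40)))
        sva = SurrogateVariableCorrector(control_fraction=0.5, k=2).fit(X)
        out = sva.transform(X)
        sv = sva.surrogates_.to_numpy()
        resid = out.to_numpy() - out.to_numpy().mean(axis=0, keepdims=True)
        inner = sv.T @ resid
        assert np.abs(inner).max() < 1e-9

    def test_surrogate_vectors_orthonormal(self):
        rng = np.random.default_rng(17)
        X = frame(rng.normal(0, 1, (20, 50)))
        sva = SurrogateVariableCorrector(control_fraction=0.5, k=3).fit(X)
        sv = sva.surrogates_.to_numpy()
        np.testing.assert_allclose(sv.T @ sv, np.eye(3), atol=1e-9)

    def test_control_set_is_least_variable_half(self):
        rng = np.random.default_rng(18)
        X = frame(rng.normal(0, 1, (15, 20)))
        X.iloc[:, :5] *= 10.0                     # high-variance features
        sva = SurrogateVariableCorrector(control_fraction=0.5, k=1).fit(X)
        assert len(sva.controls_) == 10
        assert not set(X.columns[:5]) & set(sva.controls_)

    def test_k_at_least_run_count_rejected(self):
        rng = np.random.default_rng(19)
        X = frame(rng.normal(0, 1, (6, 10)))
        with pytest.raises(InputError, match="k"):
            SurrogateVariableCorrector(k=6).fit(X)


class TestFitCombatFromDesign:
    def test_qc_anchoring_uses_condition_covariate(self, small_dataset):
        res = run_pipeline(small_dataset.report, small_dataset.design,
                           {"selection_enabled": False, "qc_enabled": False})
        cb = res.models["correct"]
        assert any(c.startswith("strain_") for c in cb.beta_.index)

    def test_strain_contrasts_survive_pipeline_correction(self, small_dataset):
        ds = small_dataset
        res = run_pipeline(ds.report, ds.design,
                           {"selection_enabled": False, "qc_enabled": False})
        corrected = res.peptide_matrix.values
        design = ds.design.data.loc[corrected.index]
        study = design[design.sample_type == "study"]
        eff = ds.truth["effects"]
        feats = [f for f in corrected.columns if f in eff.index][:150]
        est, truth = [], []
        strains = sorted(study["strain"].unique())
        for f in feats:
            col = corrected[f]
            means = {s: col[study[study.strain == s].index].mean()
                     for s in strains}
            grand = np.mean(list(means.values()))
            for s in strains:
                est.append(means[s] - grand)
                truth.append(eff.loc[f, s] - eff.loc[f, strains].mean())
        r = np.corrcoef(est, truth)[0, 1]
        assert r > 0.8
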
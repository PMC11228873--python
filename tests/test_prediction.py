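"""Gibbs RKHS samplers: conjugate oracle, shrinkage, reproducibility."""

import numpy as np
import pandas as pd
import pytest

import phenogp as pg
from phenogp.kernels import KernelSet, assemble_model, genomic_relationship
from phenogp.prediction import (
    GibbsConfig,
    fit_multitrait,
    fit_rkhs,
    predict_records,
)


def _m1_kernelset(n_hybrids=60, n_markers=300, seed=0, envs=("E1", "E2")):
    mk = pg.simulate_markers(n_hybrids, n_markers, seed=seed)
    G = genomic_relationship(mk)
    records = pd.DataFrame(
        {"hybrid": np.tile(mk.hybrids, len(envs)),
         "environment": np.repeat(envs, n_hybrids)}
    )
    return assemble_model("M1", records, G=G)


class TestFitRkhs:
    def test_identity_kernel_matches_conjugate_closed_form(self):
        # single identity kernel with variances pinned by a huge prior df:
        # the posterior mean of (mu, u) has a closed form (ridge/GLS solve)
        rng = np.random.default_rng(5)
        n = 12
        y = rng.normal(1.0, 1.0, n)
        rec = pd.DataFrame({"hybrid": [f"h{i}" for i in range(n)], "environment": "E"})
        ks = KernelSet(records=rec, kernels={"g": np.eye(n)}, model_id="M1")
        cfg = GibbsConfig(n_iter=6000, burn_in=1000, thin=1, df0=1e7, seed=3)
        fit = fit_rkhs(y, ks, cfg)
        vy = np.var(y)
        s_u, s_e = vy * 0.5, vy * 0.5      # prior modes, pinned by df0
        A = np.zeros((n + 1, n + 1))
        A[0, 0] = n / s_e
        A[0, 1:] = A[1:, 0] = 1.0 / s_e
        A[1:, 1:] = np.eye(n) * (1.0 / s_e + 1.0 / s_u)
        rhs = np.concatenate([[y.sum() / s_e], y / s_e])
        sol = np.linalg.solve(A, rhs)
        expect = sol[0] + sol[1:]
        assert np.allclose(fit.fitted, expect, atol=0.05)
        assert fit.variance_components["g"] == pytest.approx(s_u, rel=0.02)

    def test_pure_noise_shrinks_genomic_share(self):
        shares = []
        for seed in range(5):
            ks = _m1_kernelset(40, 200, seed=seed)
            y = np.random.default_rng(100 + seed).standard_normal(80)
            fit = fit_rkhs(y, ks, GibbsConfig(n_iter=1500, burn_in=400, thin=2,
                                              seed=seed))
            vc = fit.variance_components
            shares.append(vc["g"] / (vc["g"] + vc["residual"]))
        assert np.mean(shares) < 0.2

    def test_seeded_chains_bit_reproducible(self):
        ks = _m1_kernelset(30, 150, seed=1)
        y = np.random.default_rng(7).standard_normal(60)
        cfg = GibbsConfig(n_iter=500, burn_in=100, thin=2, seed=11)
        a, b = fit_rkhs(y, ks, cfg), fit_rkhs(y, ks, cfg)
        assert np.array_equal(a.fitted, b.fitted)
        assert a.variance_components == b.variance_components

    def test_posterior_total_variance_tracks_sample_variance(self):
        ks = _m1_kernelset(50, 250, seed=2)
        rng = np.random.default_rng(8)
        L = np.linalg.cholesky(ks.kernels["g"] + 1e-8 * np.eye(100))
        y = L @ rng.standard_normal(100) + rng.standard_normal(100)
        y = (y - y.mean()) / y.std()
        fit = fit_rkhs(y, ks, GibbsConfig(n_iter=2000, burn_in=500, thin=2, seed=0))
        diag_total = sum(
            fit.variance_components[t] * np.diag(ks.kernels[t]).mean()
            for t in ks.kernels
        ) + fit.variance_components["residual"]
        assert diag_total == pytest.approx(np.var(y), rel=0.25)

    def test_missing_responses_predicted(self):
        ks = _m1_kernelset(40, 200, seed=3)
        rng = np.random.default_rng(9)
        L = np.linalg.cholesky(ks.kernels["g"] + 1e-8 * np.eye(80))
        y = L @ rng.standard_normal(80) + 0.3 * rng.standard_normal(80)
        y_mask = y.copy()
        y_mask[:16] = np.nan
        fit = fit_rkhs(y_mask, ks, GibbsConfig(n_iter=2000, burn_in=500, thin=2,
                                               seed=4))
        r = np.corrcoef(fit.fitted[:16], y[:16])[0, 1]
        assert r > 0.4                      # masked records genuinely predicted
        assert np.isfinite(fit.fitted).all()

    def test_all_missing_rejected(self):
        ks = _m1_kernelset(10, 60, seed=4)
        with pytest.raises(ValueError, match="missing"):
            fit_rkhs(np.full(20, np.nan), ks, GibbsConfig(n_iter=50, burn_in=10))


class TestFitMultitrait:
    def test_duplicated_trait_gives_unit_genetic_correlation(self):
        ks = _m1_kernelset(40, 200, seed=5)
        rng = np.random.default_rng(10)
        L = np.linalg.cholesky(ks.kernels["g"] + 1e-8 * np.eye(80))
        y = L @ rng.standard_normal(80) + 0.1 * rng.standard_normal(80)
        Y = np.column_stack([y, y])
        fit = fit_multitrait(Y, ks, GibbsConfig(n_iter=1500, burn_in=400, thin=2,
                                                seed=6))
        assert fit.genetic_correlation > 0.95
        assert fit.genetic_cov.shape == (2, 2)
        assert np.all(np.linalg.eigvalsh(fit.genetic_cov) > 0)

    def test_missing_secondary_rejected(self):
        ks = _m1_kernelset(10, 60, seed=6)
        Y = np.ones((20, 2))
        Y[0, 1] = np.nan
        with pytest.raises(ValueError, match="secondary"):
            fit_multitrait(Y, ks, GibbsConfig(n_iter=50, burn_in=10))

    def test_secondary_helps_predict_masked_primary(self):
        # the mechanism behind the multitrait model: an always-observed
        # genetically correlated secondary trait sharpens predictions for
        # records whose primary value is masked
        gains = []
        for seed in range(3):
            ks = _m1_kernelset(60, 300, seed=20 + seed)
            rng = np.random.default_rng(30 + seed)
            L = np.linalg.cholesky(ks.kernels["g"] + 1e-8 * np.eye(120))
            C = np.array([[1.0, 0.9], [0.9, 1.0]])
            U = L @ rng.standard_normal((120, 2)) @ np.linalg.cholesky(C).T
            Y = U + 0.6 * rng.standard_normal((120, 2))
            mask = rng.choice(120, 24, replace=False)
            Y_obs = Y.copy()
            Y_obs[mask, 0] = np.nan
            cfg = GibbsConfig(n_iter=1500, burn_in=400, thin=2, seed=seed)
            fit_mt = fit_multitrait(Y_obs, ks, cfg)
            fit_uni = fit_rkhs(Y_obs[:, 0], ks, cfg)
            r_mt = np.corrcoef(fit_mt.fitted[mask], Y[mask, 0])[0, 1]
            r_uni = np.corrcoef(fit_uni.fitted[mask], Y[mask, 0])[0, 1]
            gains.append(r_mt - r_uni)
        assert np.mean(gains) > 0


@pytest.fixture(scope="module")
def fit():
    ks = _m1_kernelset(20, 100, seed=7)
    y = np.random.default_rng(12).standard_normal(40)
    return fit_rkhs(y, ks, GibbsConfig(n_iter=400, burn_in=100, thin=2, seed=1))


class TestPredictRecords:
    def test_training_targets_return_fitted(self, fit):
        idx = np.arange(10)
        assert np.array_equal(predict_records(fit, idx), fit.fitted[:10])

    def test_empty_target(self, fit):
        assert predict_records(fit, []).size == 0

    def test_order_invariance(self, fit):
        fwd = predict_records(fit, [1, 5, 9])
        rev = predict_records(fit, [9, 5, 1])
        assert np.array_equal(fwd, rev[::-1])

    def test_unknown_record_raises(self, fit):
        with pytest.raises(IndexError):
            predict_records(fit, [999])
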